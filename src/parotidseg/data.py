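"""Canonical in-memory containers shared across the pipeline.

Axis convention: volumes are indexed ``(slice, row, col)``, 0-based. The
laterality axis is the column axis, with the anatomical-left structure on the
image-right half (high column indices), i.e. radiological display convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import MaskValidationError, MissingSequenceError, RegistrationError

#: Canonical MRI sequence order; input channels always follow this order.
SEQUENCES = ("T1w", "T2w", "T1wC")

#: Canonical ROI channel order of every 4-channel label array.
ROI_NAMES = ("parotid_left", "parotid_right", "tumor_left", "tumor_right")

#: Channel permutation that swaps left/right structures (used by mirroring).
LATERALITY_SWAP = (1, 0, 3, 2)


@dataclass
class MultiSequenceVolume:
    """Co-registered scalar volumes of one patient, one per MRI sequence.

    ``sequences`` maps sequence name -> (slices, height, width) array; all
    arrays share one grid and one anisotropic ``spacing`` in millimetres
    ``(slice_thickness, row, col)``.
    """

    patient_id: str
    sequences: dict[str, np.ndarray]
    spacing: tuple[float, float, float]

    def __post_init__(self):
        ordered = {}
        for name in SEQUENCES:
            if name in self.sequences:
                ordered[name] = np.asarray(self.sequences[name])
        unknown = set(self.sequences) - set(SEQUENCES)
        if unknown:
            from .errors import FormatError

            raise FormatError(f"unknown sequence name(s): {sorted(unknown)}")
        self.sequences = ordered
        shapes = {a.shape for a in self.sequences.values()}
        if len(shapes) > 1:
            raise RegistrationError(
                f"sequences of {self.patient_id} differ in grid shape: {shapes}"
            )
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return next(iter(self.sequences.values())).shape

    def get(self, name: str) -> np.ndarray:
        if name not in self.sequences:
            raise MissingSequenceError(
                f"case {self.patient_id} has no {name} sequence"
            )
        return self.sequences[name]

    def stack(self, subset=None) -> np.ndarray:
        """(slices, height, width, C) stack in canonical sequence order."""
        names = [s for s in SEQUENCES if s in (subset or self.sequences)]
        if subset is not None:
            for name in subset:
                self.get(name)
        return np.stack([self.get(n) for n in names], axis=-1)


@dataclass
class RoiLabelVolume:
    """Four binary masks on the volume grid, canonical channel order."""

    masks: np.ndarray  # (slices, height, width, 4), values in {0, 1}
    spacing: tuple[float, float, float]

    def __post_init__(self):
        self.masks = np.asarray(self.masks)
        if self.masks.ndim != 4 or self.masks.shape[-1] != 4:
            raise MaskValidationError(
                f"label volume must be (S, H, W, 4); got {self.masks.shape}"
            )
        values = np.unique(self.masks)
        if not np.isin(values, (0, 1)).all():
            raise MaskValidationError(
                f"label volume contains values outside {{0, 1}}: {values[:8]}"
            )
        self.masks = self.masks.astype(np.uint8)
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.masks.shape[:3]

    def roi(self, name: str) -> np.ndarray:
        return self.masks[..., ROI_NAMES.index(name)]


@dataclass
class SliceSample:
    """One axial slice: the training unit.

    ``image`` is (height, width, C_in) with values in [0, 1]; ``label`` is the
    matching (height, width, 4) binary array.
    """

    image: np.ndarray
    label: np.ndarray
    patient_id: str
    slice_index: int
    spacing: tuple[float, float]  # (row_mm, col_mm)
    grid_transform: "object | None" = field(default=None, repr=False)

    def __post_init__(self):
        if self.image.shape[:2] != self.label.shape[:2]:
            raise MaskValidationError(
                f"image/label spatial mismatch: {self.image.shape} vs {self.label.shape}"
            )
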