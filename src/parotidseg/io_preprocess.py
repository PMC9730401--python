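"""Reading, writing and preprocessing of multi-sequence volumes and masks.

Disk format is NIfTI (.nii.gz) with a JSON manifest per cohort; the manifest
schema written for phantoms is also the entry point for real co-registered
data. In memory, volumes are (slice, row, col) arrays; on disk they are stored
in nibabel's (x=col, y=row, z=slice) order with voxel spacing in the affine.

Intensity normalization maps each sequence volume onto [0, 1] by a per-volume
min-max rescale, so the mid-gray of every patient sits at 0.5 regardless of
scanner scaling; a constant volume maps to all 0.5.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

from .data import (
    MultiSequenceVolume,
    ROI_NAMES,
    RoiLabelVolume,
    SEQUENCES,
    SliceSample,
)
from .errors import FormatError, MissingSequenceError, RegistrationError

MANIFEST_NAME = "manifest.json"
_CONVENTIONS = {
    "axes": "(slice, row, col)",
    "anatomical_left_image_side": "right",
    "roi_channels": list(ROI_NAMES),
}


# -- NIfTI round-trip ---------------------------------------------------------


def write_nifti(array: np.ndarray, spacing, path):
    """Write a (S, H, W) or (S, H, W, C) array with (slice, row, col) spacing."""
    arr = np.asarray(array)
    if arr.ndim == 3:
        data = arr.transpose(2, 1, 0)
    elif arr.ndim == 4:
        data = arr.transpose(2, 1, 0, 3)
    else:
        raise FormatError(f"cannot write array of ndim {arr.ndim} as NIfTI")
    affine = np.diag([float(spacing[2]), float(spacing[1]), float(spacing[0]), 1.0])
    nib.save(nib.Nifti1Image(data, affine), str(path))


def read_nifti(path):
    """Read a NIfTI file back to ((S, H, W[, C]) array, (slice, row, col) spacing)."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    zooms = img.header.get_zooms()[:3]
    # zooms are float32 in the header; round off the representation noise
    spacing = tuple(round(float(z), 6) for z in (zooms[2], zooms[1], zooms[0]))
    if data.ndim == 3:
        return data.transpose(2, 1, 0), spacing
    if data.ndim == 4:
        return data.transpose(2, 1, 0, 3), spacing
    raise FormatError(f"{path}: unsupported NIfTI dimensionality {data.ndim}")


# -- cohort write / manifest ---------------------------------------------------


def write_case(case, out_dir, label_dialect: str = "stacked") -> dict:
    """Write one case's sequences and labels; return its manifest entry."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pid = case.patient_id
    entry = {
        "patient_id": pid,
        "laterality": getattr(case, "laterality", None),
        "spacing": list(case.volume.spacing),
        "grid_shape": list(case.volume.grid_shape),
        "sequences": {},
    }
    for name, arr in case.volume.sequences.items():
        fname = f"{pid}_{name}.nii.gz"
        write_nifti(arr, case.volume.spacing, out_dir / fname)
        entry["sequences"][name] = fname
    if label_dialect == "stacked":
        fname = f"{pid}_labels.nii.gz"
        write_nifti(case.labels.masks.astype(np.uint8), case.labels.spacing,
                    out_dir / fname)
        entry["labels"] = fname
    elif label_dialect == "split":
        entry["labels"] = {}
        for i, roi in enumerate(ROI_NAMES):
            fname = f"{pid}_{roi}.nii.gz"
            write_nifti(case.labels.masks[..., i].astype(np.uint8),
                        case.labels.spacing, out_dir / fname)
            entry["labels"][roi] = fname
    else:
        raise FormatError(f"unknown label dialect {label_dialect!r}")
    return entry


def write_cohort(cases, out_dir, label_dialect: str = "stacked") -> Path:
    """Write all cases plus the JSON manifest; return the manifest path."""
    out_dir = Path(out_dir)
    entries = [write_case(c, out_dir, label_dialect) for c in cases]
    manifest = {
        "format": "parotidseg-manifest-v1",
        "conventions": dict(_CONVENTIONS),
        "cases": entries,
    }
    path = out_dir / MANIFEST_NAME
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path


def read_manifest(path) -> list[dict]:
    """Load manifest entries with a ``_base`` key for path resolution."""
    path = Path(path)
    doc = json.loads(path.read_text())
    if "cases" not in doc:
        raise FormatError(f"{path} is not a cohort manifest")
    entries = []
    for entry in doc["cases"]:
        entry = dict(entry)
        entry["_base"] = str(path.parent)
        entries.append(entry)
    return entries


def read_case(entry: dict, sequences=None) -> tuple[MultiSequenceVolume, RoiLabelVolume]:
    """Load one manifest entry into canonical containers.

    ``sequences`` restricts loading to a subset (canonical order is enforced
    regardless of manifest order). Grid-shape disagreement between files is a
    registration error; label values outside {0, 1} are rejected.
    """
    base = Path(entry.get("_base", "."))
    listed = entry["sequences"]
    unknown = set(listed) - set(SEQUENCES)
    if unknown:
        raise FormatError(f"unknown sequence name(s) in manifest: {sorted(unknown)}")
    wanted = [s for s in SEQUENCES if s in (sequences or listed)]
    arrays, spacings = {}, []
    for name in wanted:
        if name not in listed:
            raise MissingSequenceError(
                f"case {entry['patient_id']}: sequence {name} not in manifest"
            )
        arr, spacing = read_nifti(base / listed[name])
        arrays[name] = arr
        spacings.append(spacing)
    shapes = {a.shape for a in arrays.values()}
    if len(shapes) > 1:
        raise RegistrationError(
            f"case {entry['patient_id']}: sequence grids differ: {shapes}"
        )
    labels_field = entry["labels"]
    if isinstance(labels_field, str):
        masks, lspacing = read_nifti(base / labels_field)
    else:
        stack, lspacing = [], None
        for roi in ROI_NAMES:
            arr, lspacing = read_nifti(base / labels_field[roi])
            stack.append(arr)
        masks = np.stack(stack, axis=-1)
    if masks.shape[:3] != next(iter(shapes)):
        raise RegistrationError(
            f"case {entry['patient_id']}: label grid {masks.shape[:3]} does not "
            f"match volume grid {next(iter(shapes))}"
        )
    volume = MultiSequenceVolume(
        patient_id=entry["patient_id"], sequences=arrays, spacing=spacings[0]
    )
    labels = RoiLabelVolume(masks=np.rint(masks).astype(np.int64), spacing=lspacing)
    return volume, labels


# -- normalization --------------------------------------------------------------


def normalize_intensity(volume: np.ndarray) -> np.ndarray:
    """Per-volume min-max rescale onto [0, 1] (mid-gray centered at 0.5).

    A constant volume maps to all 0.5. Non-finite input is rejected.
    """
    arr = np.asarray(volume, dtype=np.float64)
    if arr.size == 0:
        raise FormatError("cannot normalize an empty volume")
    if not np.isfinite(arr).all():
        raise FormatError("volume contains non-finite values")
    lo, hi = arr.min(), arr.max()
    if hi == lo:
        return np.full_like(arr, 0.5)
    return (arr - lo) / (hi - lo)


# -- grid fitting ----------------------------------------------------------------


@dataclass
class GridTransform:
    """Record of the center-crop / zero-pad that fit a slice to the model grid,
    invertible back onto the native grid."""

    native_shape: tuple[int, int]
    target_shape: tuple[int, int]
    crop_start: tuple[int, int]
    pad_before: tuple[int, int]

    def apply(self, arr: np.ndarray) -> np.ndarray:
        out = arr
        for axis in (0, 1):
            n, t = out.shape[axis], self.target_shape[axis]
            if n > t:
                start = self.crop_start[axis]
                out = out[(slice(None),) * axis + (slice(start, start + t),)]
            elif n < t:
                before = self.pad_before[axis]
                width = [(0, 0)] * out.ndim
                width[axis] = (before, t - n - before)
                out = np.pad(out, width)
        return out

    def inverse(self, arr: np.ndarray) -> np.ndarray:
        """Map a model-grid array back onto the native grid (zero outside any
        cropped region; padded borders removed)."""
        out = arr
        for axis in (0, 1):
            n, t = self.native_shape[axis], self.target_shape[axis]
            if n > t:
                start = self.crop_start[axis]
                width = [(0, 0)] * out.ndim
                width[axis] = (start, n - t - start)
                out = np.pad(out, width)
            elif n < t:
                before = self.pad_before[axis]
                out = out[(slice(None),) * axis + (slice(before, before + n),)]
        return out


def fit_to_grid(slice_image: np.ndarray, slice_label: np.ndarray | None,
                target_size: int):
    """Center-crop / symmetrically zero-pad a slice (and its label) to
    ``target_size`` square; returns (image, label, transform)."""
    h, w = slice_image.shape[:2]
    transform = GridTransform(
        native_shape=(h, w),
        target_shape=(target_size, target_size),
        crop_start=(max(0, (h - target_size) // 2), max(0, (w - target_size) // 2)),
        pad_before=(max(0, (target_size - h) // 2), max(0, (target_size - w) // 2)),
    )
    image = transform.apply(slice_image)
    label = transform.apply(slice_label) if slice_label is not None else None
    return image, label, transform


# -- slice dataset ----------------------------------------------------------------


def make_slice_dataset(cases, sequence_subset=None, target_size: int | None = None
                       ) -> list[SliceSample]:
    """Turn cases into per-slice training samples.

    ``cases`` may be PhantomCase objects or (MultiSequenceVolume,
    RoiLabelVolume-or-None) pairs. Every axial slice becomes one sample with
    C_in = number of requested sequences (canonical order). Volumes are
    intensity-normalized per sequence; no inter-slice resampling is performed,
    so the anisotropic native spacing is preserved.
    """
    if sequence_subset is not None:
        subset = list(sequence_subset)
        if not subset:
            raise FormatError("sequence_subset must be a nonempty subset")
        unknown = set(subset) - set(SEQUENCES)
        if unknown:
            raise FormatError(f"unknown sequence name(s): {sorted(unknown)}")
    samples: list[SliceSample] = []
    for case in cases:
        if hasattr(case, "volume"):
            volume, labels = case.volume, case.labels
        else:
            volume, labels = case
        names = [s for s in SEQUENCES if s in (sequence_subset or volume.sequences)]
        channels = [normalize_intensity(volume.get(n)) for n in names]
        image_vol = np.stack(channels, axis=-1)
        n_slices = image_vol.shape[0]
        label_vol = (
            labels.masks
            if labels is not None
            else np.zeros(volume.grid_shape + (len(ROI_NAMES),), dtype=np.uint8)
        )
        for k in range(n_slices):
            image, label = image_vol[k], label_vol[k]
            transform = None
            if target_size is not None:
                image, label, transform = fit_to_grid(image, label, target_size)
            samples.append(
                SliceSample(
                    image=image,
                    label=label,
                    patient_id=volume.patient_id,
                    slice_index=k,
                    spacing=volume.spacing[1:],
                    grid_transform=transform,
                )
            )
    return samples
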