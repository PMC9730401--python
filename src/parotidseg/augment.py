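"""Training-time augmentation: gray-level disturbance, affine shape
disturbance, and mirroring with left/right label swap.

Gray disturbance draws one multiplicative factor in [0.9, 1.1] and one
additive shift in [-0.1, 0.1] per sample (not per pixel), applies them to the
normalized image and clips back to [0, 1]; labels are untouched. The affine
disturbance applies one in-plane rotation + isotropic scale + translation to
image (bilinear) and label (nearest neighbor, re-binarized) alike. Mirroring
flips the laterality (column) axis with probability 0.5 and swaps the
left/right label channels so the anatomy stays consistent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .data import LATERALITY_SWAP
from .errors import MaskValidationError


@dataclass
class AffineParams:
    """Maximum magnitudes of the random in-plane affine disturbance."""

    max_rotation_deg: float = 10.0
    scale_range: tuple[float, float] = (0.95, 1.05)
    max_translation_fraction: float = 0.05


@dataclass
class AugmentConfig:
    gray_scale_range: tuple[float, float] = (0.9, 1.1)
    gray_shift_range: tuple[float, float] = (-0.1, 0.1)
    affine_params: AffineParams = field(default_factory=AffineParams)
    mirror_probability: float = 0.5
    seed: int = 0

    def __post_init__(self):
        for lo, hi in (self.gray_scale_range, self.gray_shift_range,
                       self.affine_params.scale_range):
            if hi < lo:
                raise ValueError(f"empty interval ({lo}, {hi})")
        if not 0.0 <= self.mirror_probability <= 1.0:
            raise ValueError("mirror_probability must be in [0, 1]")


# -- gray disturbance -----------------------------------------------------------


def apply_gray(image: np.ndarray, scale: float, shift: float) -> np.ndarray:
    """clip(scale * image + shift, 0, 1); deterministic core of the disturbance."""
    return np.clip(scale * image + shift, 0.0, 1.0)


def gray_disturbance(image: np.ndarray, rng: np.random.Generator,
                     scale_range=(0.9, 1.1), shift_range=(-0.1, 0.1)) -> np.ndarray:
    """One (scale, shift) pair per sample, applied to all pixels and channels."""
    scale = rng.uniform(*scale_range)
    shift = rng.uniform(*shift_range)
    return apply_gray(image, scale, shift)


# -- affine disturbance -----------------------------------------------------------


def apply_affine(image: np.ndarray, label: np.ndarray | None,
                 rotation_deg: float, scale: float,
                 translation: tuple[float, float]):
    """Apply one in-plane affine map (about the image center) to image and
    label identically; bilinear for the image, nearest for the label."""
    h, w = image.shape[:2]
    t = np.deg2rad(rotation_deg)
    # output->input matrix for scipy.ndimage.affine_transform
    rot = np.array([[np.cos(t), -np.sin(t)], [np.sin(t), np.cos(t)]])
    matrix = rot / scale
    center = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    offset = center - matrix @ (center + np.asarray(translation, dtype=np.float64))

    def warp(arr, order):
        if arr.ndim == 2:
            return ndimage.affine_transform(arr.astype(np.float64), matrix,
                                            offset=offset, order=order, cval=0.0)
        out = np.empty(arr.shape, dtype=np.float64)
        for c in range(arr.shape[2]):
            out[..., c] = ndimage.affine_transform(
                arr[..., c].astype(np.float64), matrix, offset=offset,
                order=order, cval=0.0)
        return out

    image_out = warp(image, order=1)
    if label is None:
        return image_out, None
    label_out = (warp(label, order=0) > 0.5).astype(label.dtype)
    return image_out, label_out


def affine_disturbance(image: np.ndarray, label: np.ndarray | None,
                       rng: np.random.Generator,
                       params: AffineParams | None = None):
    """Sample one affine disturbance and apply it to image and label."""
    p = params or AffineParams()
    h, w = image.shape[:2]
    rotation = rng.uniform(-p.max_rotation_deg, p.max_rotation_deg)
    scale = rng.uniform(*p.scale_range)
    tmax = p.max_translation_fraction
    translation = (rng.uniform(-tmax, tmax) * h, rng.uniform(-tmax, tmax) * w)
    return apply_affine(image, label, rotation, scale, translation)


# -- mirroring with label swap ------------------------------------------------------


def mirror_with_label_swap(image: np.ndarray, label: np.ndarray,
                           rng: np.random.Generator | None = None,
                           probability: float = 0.5):
    """Flip image and label along the laterality (column) axis and swap the
    left/right label channels, with the given probability."""
    if label.ndim != 3 or label.shape[2] != len(LATERALITY_SWAP):
        raise MaskValidationError(
            f"label must have {len(LATERALITY_SWAP)} channels, got {label.shape}"
        )
    if probability < 1.0:
        if probability <= 0.0:
            return image, label
        if rng is None or rng.uniform() >= probability:
            return image, label
    return image[:, ::-1].copy(), label[:, ::-1][:, :, list(LATERALITY_SWAP)].copy()


# -- composed pipeline ----------------------------------------------------------------


def augment_sample(image: np.ndarray, label: np.ndarray,
                   rng: np.random.Generator, config: AugmentConfig):
    """Apply the full training pipeline: affine -> mirror -> gray."""
    image, label = affine_disturbance(image, label, rng, config.affine_params)
    image, label = mirror_with_label_swap(image, label, rng,
                                          config.mirror_probability)
    image = gray_disturbance(image, rng, config.gray_scale_range,
                             config.gray_shift_range)
    return image, label
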