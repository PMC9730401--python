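"""Segmentation evaluation: DICE, JACCARD, HD95 and AHD, plus cohort
aggregation.

Overlap metrics are exact voxel-count ratios:

    DICE    = 2|A n B| / (|A| + |B|)
    JACCARD = |A n B| / |A u B|

Distance metrics operate on mask surfaces (foreground voxels with a
background 6-neighbor) in millimetres, honoring anisotropic voxel spacing,
computed in 3D on the native grid. HD95 is the 95th percentile of the pooled
directed surface-to-surface distances A->B and B->A; AHD is the mean of the
two directed average surface distances. Degenerate cases are deterministic
and flagged: both masks empty gives overlap 1, exactly one empty gives 0, and
the distance metrics are undefined (NaN) unless both masks are nonempty.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .data import ROI_NAMES
from .errors import MaskValidationError

_METRIC_NAMES = ("dice", "jaccard", "hd95_mm", "ahd_mm")


def _check_pair(mask_a, mask_b):
    a = np.asarray(mask_a).astype(bool)
    b = np.asarray(mask_b).astype(bool)
    if a.shape != b.shape:
        raise MaskValidationError(f"mask shape mismatch: {a.shape} vs {b.shape}")
    return a, b


def dice(mask_a, mask_b) -> float:
    """Dice similarity coefficient; 1.0 when both masks are empty."""
    a, b = _check_pair(mask_a, mask_b)
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / (na + nb)


def jaccard(mask_a, mask_b) -> float:
    """Jaccard index; 1.0 when both masks are empty."""
    a, b = _check_pair(mask_a, mask_b)
    union = int((a | b).sum())
    if union == 0:
        return 1.0
    return int((a & b).sum()) / union


_STRUCT6 = ndimage.generate_binary_structure(3, 1)  # 6-connectivity


def surface_voxels(mask) -> np.ndarray:
    """Boolean array of foreground voxels with at least one background
    6-neighbor; voxels outside the grid count as background.

    A 2D mask is treated as a single-slice volume (4-neighborhood), which
    gives the per-slice metric mode."""
    m = np.asarray(mask).astype(bool)
    if m.ndim == 2:
        return surface_voxels(m[None])[0]
    if m.ndim != 3:
        raise MaskValidationError(f"surface_voxels expects a 3D mask, got {m.ndim}D")
    interior = ndimage.binary_erosion(m, structure=_STRUCT6, border_value=0)
    return m & ~interior


def _directed_distances(surf_from: np.ndarray, surf_to: np.ndarray, spacing):
    """Euclidean mm distances from each voxel of `surf_from` to the nearest
    voxel of `surf_to` (voxel centers, anisotropic spacing)."""
    dt = ndimage.distance_transform_edt(~surf_to, sampling=spacing)
    return dt[surf_from]


def _surface_distance_sets(mask_a, mask_b, spacing):
    a, b = _check_pair(mask_a, mask_b)
    if a.ndim == 2:  # per-slice (2D) mode
        a, b = a[None], b[None]
        spacing = (1.0, *spacing)
    if not a.any() or not b.any():
        return None
    sa, sb = surface_voxels(a), surface_voxels(b)
    return (_directed_distances(sa, sb, spacing),
            _directed_distances(sb, sa, spacing))


def hd95(mask_a, mask_b, spacing, pooling: str = "pooled") -> float:
    """95th percentile Hausdorff distance in mm; NaN if either mask is empty.

    ``pooling='pooled'`` (default) takes the percentile of the union of both
    directed distance sets; ``'max_directed'`` takes the max of the two
    directed percentiles.
    """
    sets = _surface_distance_sets(mask_a, mask_b, spacing)
    if sets is None:
        return float("nan")
    d_ab, d_ba = sets
    if pooling == "pooled":
        return float(np.percentile(np.concatenate([d_ab, d_ba]), 95))
    if pooling == "max_directed":
        return float(max(np.percentile(d_ab, 95), np.percentile(d_ba, 95)))
    raise ValueError(f"unknown pooling {pooling!r}")


def ahd(mask_a, mask_b, spacing) -> float:
    """Average Hausdorff distance in mm: mean of the two directed average
    surface distances; NaN if either mask is empty."""
    sets = _surface_distance_sets(mask_a, mask_b, spacing)
    if sets is None:
        return float("nan")
    d_ab, d_ba = sets
    return float(0.5 * (d_ab.mean() + d_ba.mean()))


# -- per-case / cohort ----------------------------------------------------------


@dataclass
class CaseMetrics:
    """Per-ROI metric values of one patient; flags note degenerate masks."""

    patient_id: str
    per_roi: dict[str, dict[str, float]]
    flags: dict[str, str] = field(default_factory=dict)


def evaluate_case(patient_id: str, truth, prediction, spacing=None) -> CaseMetrics:
    """All four metrics for every ROI channel of one case.

    ``truth``/``prediction`` are RoiLabelVolume objects or (S, H, W, 4)
    arrays. Distances use the truth volume's spacing unless overridden.
    """
    t = truth.masks if hasattr(truth, "masks") else np.asarray(truth)
    p = prediction.masks if hasattr(prediction, "masks") else np.asarray(prediction)
    if spacing is None:
        spacing = getattr(truth, "spacing", (1.0, 1.0, 1.0))
    if t.shape != p.shape:
        raise MaskValidationError(f"grid mismatch: truth {t.shape} vs pred {p.shape}")
    per_roi, flags = {}, {}
    for i, roi in enumerate(ROI_NAMES):
        a, b = t[..., i], p[..., i]
        na, nb = int(np.count_nonzero(a)), int(np.count_nonzero(b))
        per_roi[roi] = {
            "dice": dice(a, b),
            "jaccard": jaccard(a, b),
            "hd95_mm": hd95(a, b, spacing),
            "ahd_mm": ahd(a, b, spacing),
        }
        if na == 0 and nb == 0:
            flags[roi] = "both-empty"
        elif na == 0 or nb == 0:
            flags[roi] = "one-empty"
    return CaseMetrics(patient_id=patient_id, per_roi=per_roi, flags=flags)


@dataclass
class CohortReport:
    """Cohort aggregation: per-ROI means and 95% ranges plus the per-case table."""

    per_case: pd.DataFrame  # columns: patient_id, roi, dice, jaccard, hd95_mm, ahd_mm, flags
    summary: pd.DataFrame  # index: roi; columns: <metric>_mean/_lo/_hi/_n_undefined

    def to_csv(self, per_case_path, summary_path):
        self.per_case.to_csv(per_case_path, index=False)
        self.summary.to_csv(summary_path)

    def mean(self, roi: str, metric: str = "dice") -> float:
        return float(self.summary.loc[roi, f"{metric}_mean"])


def aggregate(cases: list[CaseMetrics], interval: str = "percentile",
              n_boot: int = 2000, seed: int = 0) -> CohortReport:
    """Aggregate per-case metrics into a cohort report.

    The 95% range is the empirical 2.5th-97.5th percentile of the per-case
    values (``interval='percentile'``, default) or a bootstrap CI of the mean
    (``interval='bootstrap'``). Undefined (NaN) values are excluded from the
    statistics and counted.
    """
    if not cases:
        raise ValueError("aggregate needs at least one CaseMetrics")
    rows = []
    for cm in cases:
        for roi, vals in cm.per_roi.items():
            rows.append({"patient_id": cm.patient_id, "roi": roi, **vals,
                         "flags": cm.flags.get(roi, "")})
    per_case = pd.DataFrame(rows)
    rng = np.random.default_rng(seed)
    summary_rows = {}
    for roi, group in per_case.groupby("roi", sort=False):
        row = {}
        for metric in _METRIC_NAMES:
            values = group[metric].to_numpy(dtype=float)
            defined = values[~np.isnan(values)]
            row[f"{metric}_n_undefined"] = int(np.isnan(values).sum())
            if defined.size == 0:
                row[f"{metric}_mean"] = np.nan
                row[f"{metric}_lo"] = np.nan
                row[f"{metric}_hi"] = np.nan
                continue
            row[f"{metric}_mean"] = float(defined.mean())
            if interval == "percentile":
                lo, hi = np.percentile(defined, [2.5, 97.5])
            elif interval == "bootstrap":
                means = rng.choice(defined, size=(n_boot, defined.size)).mean(axis=1)
                lo, hi = np.percentile(means, [2.5, 97.5])
            else:
                raise ValueError(f"unknown interval {interval!r}")
            row[f"{metric}_lo"] = float(lo)
            row[f"{metric}_hi"] = float(hi)
        summary_rows[roi] = row
    summary = pd.DataFrame.from_dict(summary_rows, orient="index")
    summary.index.name = "roi"
    return CohortReport(per_case=per_case, summary=summary)
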