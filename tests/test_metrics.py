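"""Metrics: worked overlap values, brute-force oracles for surfaces and
distances, algebraic identities, degenerate-mask conventions, aggregation."""

import numpy as np
import pytest
from scipy import ndimage

from parotidseg.data import ROI_NAMES
from parotidseg.errors import MaskValidationError
from parotidseg.metrics import (
    CaseMetrics,
    aggregate,
    ahd,
    dice,
    evaluate_case,
    hd95,
    jaccard,
    surface_voxels,
)

SPACINGS = [(1.0, 1.0, 1.0), (5.0, 0.8, 0.8)]


# -- independent oracles -------------------------------------------------------


def naive_overlap_counts(a, b):
    """Triple-loop voxel counting, independent of any numpy set operation."""
    na = nb = ninter = nunion = 0
    for z in range(a.shape[0]):
        for y in range(a.shape[1]):
            for x in range(a.shape[2]):
                av, bv = bool(a[z, y, x]), bool(b[z, y, x])
                na += av
                nb += bv
                ninter += av and bv
                nunion += av or bv
    return na, nb, ninter, nunion


def naive_surface(mask):
    """Neighbor-scan surface extraction; out-of-bounds counts as background."""
    out = np.zeros_like(mask, dtype=bool)
    S, H, W = mask.shape
    for z in range(S):
        for y in range(H):
            for x in range(W):
                if not mask[z, y, x]:
                    continue
                for dz, dy, dx in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0),
                                   (0, 0, 1), (0, 0, -1)):
                    zz, yy, xx = z + dz, y + dy, x + dx
                    if not (0 <= zz < S and 0 <= yy < H and 0 <= xx < W) or not mask[zz, yy, xx]:
                        out[z, y, x] = True
                        break
    return out


def naive_surface_distances(a, b, spacing):
    """All-pairs directed distance sets between the two naive surfaces."""
    sa = np.argwhere(naive_surface(a)) * np.asarray(spacing)
    sb = np.argwhere(naive_surface(b)) * np.asarray(spacing)
    diff = sa[:, None, :] - sb[None, :, :]
    d = np.sqrt((diff**2).sum(axis=2))
    return d.min(axis=1), d.min(axis=0)


def _pair(rng, shape=(6, 7, 5), p=0.3):
    a = rng.random(shape) < p
    b = rng.random(shape) < p
    if not a.any():
        a[tuple(s // 2 for s in shape)] = True
    if not b.any():
        b[0, 0, 0] = True
    return a, b


# -- dice / jaccard -------------------------------------------------------------


def test_dice_identity_case():
    a = np.zeros((5, 5, 5), bool)
    a[1:3, 1:4, :2] = True
    assert a.sum() > 0
    assert dice(a, a) == 1.0 and jaccard(a, a) == 1.0


def test_dice_jaccard_worked_arithmetic():
    # |A| = |B| = 100, |A n B| = 50
    a = np.zeros((1, 10, 20), bool)
    b = np.zeros((1, 10, 20), bool)
    a[0, :, :10] = True
    b[0, :, 5:15] = True
    assert a.sum() == b.sum() == 100 and (a & b).sum() == 50
    assert dice(a, b) == 0.5
    assert jaccard(a, b) == pytest.approx(1.0 / 3.0, abs=0)


def test_overlap_metrics_match_naive_loop_oracle(rng):
    for _ in range(10):
        a, b = _pair(rng, shape=(8, 8, 8))
        na, nb, ninter, nunion = naive_overlap_counts(a, b)
        assert dice(a, b) == (2 * ninter / (na + nb))
        assert jaccard(a, b) == (ninter / nunion)


def test_jaccard_dice_algebraic_identity(rng):
    for _ in range(20):
        a, b = _pair(rng)
        d, j = dice(a, b), jaccard(a, b)
        assert abs(j - d / (2.0 - d)) < 1e-12


def test_shape_mismatch_rejected():
    with pytest.raises(MaskValidationError):
        dice(np.zeros((2, 2, 2)), np.zeros((2, 2, 3)))


# -- surfaces --------------------------------------------------------------------


def test_surface_of_single_voxel_is_itself():
    m = np.zeros((3, 3, 3), bool)
    m[1, 1, 1] = True
    np.testing.assert_array_equal(surface_voxels(m), m)


def test_surface_of_solid_cube_excludes_center():
    m = np.zeros((5, 5, 5), bool)
    m[1:4, 1:4, 1:4] = True
    surf = surface_voxels(m)
    assert surf.sum() == 26
    assert not surf[2, 2, 2]


def test_surface_matches_naive_neighbor_scan(rng):
    for _ in range(5):
        m = ndimage.binary_dilation(rng.random((6, 6, 6)) < 0.15)
        np.testing.assert_array_equal(surface_voxels(m), naive_surface(m))


# -- distance metrics ---------------------------------------------------------------


@pytest.mark.parametrize("spacing", SPACINGS)
def test_identical_masks_have_zero_distance(spacing):
    m = np.zeros((4, 6, 6), bool)
    m[1:3, 2:5, 2:5] = True
    assert hd95(m, m, spacing) == 0.0
    assert ahd(m, m, spacing) == 0.0


def test_2d_slice_mode_matches_single_slice_volume(rng):
    a = rng.random((7, 9)) < 0.3
    b = rng.random((7, 9)) < 0.3
    a[3, 4] = b[2, 2] = True
    sp2, sp3 = (0.8, 0.8), (5.0, 0.8, 0.8)
    assert hd95(a, b, sp2) == pytest.approx(hd95(a[None], b[None], sp3), abs=1e-12)
    assert ahd(a, b, sp2) == pytest.approx(ahd(a[None], b[None], sp3), abs=1e-12)
    np.testing.assert_array_equal(surface_voxels(a), surface_voxels(a[None])[0])


def test_single_voxel_pairs_give_exact_distances():
    a = np.zeros((1, 1, 8), bool)
    b = np.zeros((1, 1, 8), bool)
    a[0, 0, 2] = True
    b[0, 0, 5] = True  # 3 columns apart at 1 mm pixels
    assert hd95(a, b, (1.0, 1.0, 1.0)) == pytest.approx(3.0)
    b2 = np.zeros((1, 1, 8), bool)
    b2[0, 0, 7] = True  # 5 columns at 0.8 mm = 4.0 mm
    assert ahd(a, b2, (1.0, 1.0, 0.8)) == pytest.approx(4.0)


@pytest.mark.parametrize("spacing", SPACINGS)
def test_distance_metrics_match_bruteforce_oracle(rng, spacing):
    for _ in range(8):
        a, b = _pair(rng)
        d_ab, d_ba = naive_surface_distances(a, b, spacing)
        pooled = np.concatenate([d_ab, d_ba])
        assert hd95(a, b, spacing) == pytest.approx(
            np.percentile(pooled, 95), abs=1e-9
        )
        assert hd95(a, b, spacing, pooling="max_directed") == pytest.approx(
            max(np.percentile(d_ab, 95), np.percentile(d_ba, 95)), abs=1e-9
        )
        assert ahd(a, b, spacing) == pytest.approx(
            0.5 * (d_ab.mean() + d_ba.mean()), abs=1e-9
        )


def test_hd95_bounded_by_full_hausdorff(rng):
    for _ in range(10):
        a, b = _pair(rng)
        d_ab, d_ba = naive_surface_distances(a, b, (1, 1, 1))
        full = max(d_ab.max(), d_ba.max())
        assert hd95(a, b, (1, 1, 1)) <= full + 1e-12


def test_metrics_symmetric_and_mirror_invariant(rng):
    a, b = _pair(rng)
    sp = (5.0, 0.8, 0.8)
    assert dice(a, b) == dice(b, a)
    assert hd95(a, b, sp) == pytest.approx(hd95(b, a, sp), abs=1e-12)
    assert ahd(a, b, sp) == pytest.approx(ahd(b, a, sp), abs=1e-12)
    am, bm = a[:, :, ::-1], b[:, :, ::-1]
    assert dice(am, bm) == dice(a, b)
    assert hd95(am, bm, sp) == pytest.approx(hd95(a, b, sp), abs=1e-12)
    assert ahd(am, bm, sp) == pytest.approx(ahd(a, b, sp), abs=1e-12)


def test_dilation_strictly_degrades_overlap():
    truth = np.zeros((4, 10, 10), bool)
    truth[1:3, 3:7, 3:7] = True
    once = ndimage.binary_dilation(truth)
    twice = ndimage.binary_dilation(once)
    assert dice(truth, truth) > dice(truth, once) > dice(truth, twice)
    assert jaccard(truth, truth) > jaccard(truth, once) > jaccard(truth, twice)


# -- degenerate conventions ------------------------------------------------------------


def test_empty_mask_conventions():
    empty = np.zeros((3, 3, 3), bool)
    some = empty.copy()
    some[1, 1, 1] = True
    assert dice(empty, empty) == 1.0 and jaccard(empty, empty) == 1.0
    assert dice(empty, some) == 0.0 and jaccard(some, empty) == 0.0
    assert np.isnan(hd95(empty, some, (1, 1, 1)))
    assert np.isnan(ahd(some, empty, (1, 1, 1)))


def test_evaluate_case_flags_and_ordering(small_case):
    truth = small_case.labels
    pred = truth.masks.copy()
    pred[..., 3] = 0  # drop the right tumor
    cm = evaluate_case("p0", truth, pred)
    assert set(cm.per_roi) == set(ROI_NAMES)
    for roi in ROI_NAMES:
        d, j = cm.per_roi[roi]["dice"], cm.per_roi[roi]["jaccard"]
        assert j <= d
    assert cm.per_roi["tumor_right"]["dice"] == 0.0
    assert cm.flags["tumor_right"] == "one-empty"
    assert np.isnan(cm.per_roi["tumor_right"]["hd95_mm"])


# -- aggregation ----------------------------------------------------------------------


def _case(pid, d):
    per_roi = {roi: {"dice": d, "jaccard": d / (2 - d), "hd95_mm": 1.0, "ahd_mm": 0.5}
               for roi in ROI_NAMES}
    return CaseMetrics(patient_id=pid, per_roi=per_roi)


def test_aggregate_single_case_collapses():
    rep = aggregate([_case("a", 0.8)])
    assert rep.mean("parotid_left") == pytest.approx(0.8)
    assert rep.summary.loc["parotid_left", "dice_lo"] == pytest.approx(0.8)
    assert rep.summary.loc["parotid_left", "dice_hi"] == pytest.approx(0.8)


def test_aggregate_mean_of_two_cases():
    rep = aggregate([_case("a", 0.8), _case("b", 0.9)])
    assert rep.mean("tumor_left") == pytest.approx(0.85)


def sorted_percentile(values, q):
    """Independent linear-interpolation percentile on a sorted copy."""
    v = sorted(values)
    pos = (len(v) - 1) * q / 100.0
    lo = int(np.floor(pos))
    hi = int(np.ceil(pos))
    frac = pos - lo
    return v[lo] * (1 - frac) + v[hi] * frac


def test_aggregate_percentiles_match_sorted_array_reference(rng):
    values = rng.beta(8, 2, size=100)
    cases = [_case(f"p{i}", float(v)) for i, v in enumerate(values)]
    rep = aggregate(cases)
    assert rep.summary.loc["parotid_left", "dice_lo"] == pytest.approx(
        sorted_percentile(values, 2.5), abs=1e-12
    )
    assert rep.summary.loc["parotid_left", "dice_hi"] == pytest.approx(
        sorted_percentile(values, 97.5), abs=1e-12
    )
    # range bounds lie within the per-case min/max
    assert values.min() <= rep.summary.loc["parotid_left", "dice_lo"]
    assert rep.summary.loc["parotid_left", "dice_hi"] <= values.max()


def test_aggregate_counts_undefined_and_bootstrap_mode(rng):
    cases = [_case("a", 0.8), _case("b", 0.9)]
    cases[0].per_roi["tumor_left"]["hd95_mm"] = float("nan")
    rep = aggregate(cases, interval="bootstrap", seed=1)
    assert rep.summary.loc["tumor_left", "hd95_mm_n_undefined"] == 1
    assert rep.summary.loc["tumor_left", "hd95_mm_mean"] == pytest.approx(1.0)
    lo = rep.summary.loc["parotid_left", "dice_lo"]
    hi = rep.summary.loc["parotid_left", "dice_hi"]
    assert 0.8 <= lo <= hi <= 0.9
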