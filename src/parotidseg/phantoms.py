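"""Synthetic multi-sequence MR phantoms with paired parotid/tumor masks.

Real parotid MR studies are not publicly distributable, so every downstream
stage (preprocessing, augmentation, training, metrics) is exercised on
procedurally generated phantoms: two lateral ellipsoidal "parotids" placed
symmetrically about the midline on an anisotropic-voxel grid (slice thickness
well above in-plane pixel size, as in clinical head-and-neck protocols), with
optional smaller tumor ellipsoids strictly inside one or both glands. The
three channels emulate T1w / T2w / T1wC by giving each tissue a different
mean intensity per sequence — e.g. the tumor is brightest on the
contrast-enhanced channel and dark on plain T1w.

Axis/laterality convention: arrays are (slice, row, col); the anatomical-left
gland sits on the image-right half (high columns), i.e. radiological display.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .data import MultiSequenceVolume, ROI_NAMES, RoiLabelVolume, SEQUENCES
from .errors import InvalidSpecError

LATERALITIES = ("left", "right", "both", "none")

#: Cohort laterality proportions (left, right, both) emulating a parotid-tumor
#: case mix dominated by unilateral disease.
DEFAULT_LATERALITY_PROPORTIONS = {"left": 0.446, "right": 0.491, "both": 0.063}

#: Per-sequence mean intensity of each tissue class on the normalized [0, 1]
#: scale. Values are package choices (no public per-tissue statistics exist):
#: parotid is bright on T1w (fatty gland), tumor is T2-bright and enhances
#: strongly post-contrast.
DEFAULT_CONTRAST_PROFILE = {
    "T1w": {"background": 0.20, "parotid": 0.60, "tumor": 0.35},
    "T2w": {"background": 0.25, "parotid": 0.50, "tumor": 0.75},
    "T1wC": {"background": 0.20, "parotid": 0.50, "tumor": 0.85},
}


@dataclass
class PhantomSpec:
    """Parameters of one synthetic case.

    ``grid_shape`` is (slices, height, width); ``spacing`` is millimetres
    (slice_thickness, row, col) with slice thickness >= pixel size, matching
    the anisotropic acquisition the pipeline must respect. ``tumor_fraction``
    scales tumor semi-axes relative to the host parotid (0 disables tumors).
    """

    grid_shape: tuple[int, int, int] = (32, 512, 512)
    spacing: tuple[float, float, float] = (5.0, 0.8, 0.8)
    laterality: str = "both"
    contrast_profile: dict = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_CONTRAST_PROFILE.items()}
    )
    noise_sd: float = 0.02
    seed: int = 0
    tumor_fraction: float = 0.45
    rotation_max_deg: float = 0.0

    def __post_init__(self):
        self.validate()

    def validate(self):
        if len(self.grid_shape) != 3 or any(int(g) <= 0 for g in self.grid_shape):
            raise InvalidSpecError(f"grid_shape must be 3 positive ints: {self.grid_shape}")
        if len(self.spacing) != 3 or any(float(s) <= 0 for s in self.spacing):
            raise InvalidSpecError(f"spacing must be 3 positive floats: {self.spacing}")
        if self.spacing[0] < max(self.spacing[1], self.spacing[2]):
            raise InvalidSpecError(
                "slice thickness must be >= in-plane pixel size "
                f"(got {self.spacing})"
            )
        if self.laterality not in LATERALITIES:
            raise InvalidSpecError(f"laterality must be one of {LATERALITIES}")
        if self.laterality == "none" and self.tumor_fraction > 0:
            raise InvalidSpecError(
                "laterality='none' but a nonzero tumor radius was requested; "
                "set tumor_fraction=0 for tumor-free phantoms"
            )
        if not 0 <= self.tumor_fraction < 1:
            raise InvalidSpecError("tumor_fraction must be in [0, 1)")
        if self.noise_sd < 0:
            raise InvalidSpecError("noise_sd must be >= 0")
        for name in SEQUENCES:
            tissues = self.contrast_profile.get(name)
            if tissues is None:
                raise InvalidSpecError(f"contrast_profile missing sequence {name}")
            for tissue in ("background", "parotid", "tumor"):
                v = tissues.get(tissue)
                if v is None or not 0 <= v <= 1:
                    raise InvalidSpecError(
                        f"contrast_profile[{name}][{tissue}] must be in [0, 1]"
                    )


def small_preset(**overrides) -> PhantomSpec:
    """Fast-test preset: 8 x 64 x 64 grid, same anisotropy."""
    kwargs = dict(grid_shape=(8, 64, 64))
    kwargs.update(overrides)
    return PhantomSpec(**kwargs)


def full_preset(**overrides) -> PhantomSpec:
    """Native-resolution preset: 32 x 512 x 512 grid."""
    return PhantomSpec(**overrides)


PRESETS = {"small": small_preset, "full": full_preset}


@dataclass
class PhantomCase:
    """A generated case: volume + labels + the geometry that produced them."""

    patient_id: str
    volume: MultiSequenceVolume
    labels: RoiLabelVolume
    ground_truth_params: dict
    laterality: str


# -- geometry ----------------------------------------------------------------


def _ellipsoid_mask(grid_shape, center, radii, rotation_deg: float = 0.0) -> np.ndarray:
    """Boolean mask of an ellipsoid, optionally rotated in the axial plane."""
    S, H, W = grid_shape
    z = np.arange(S, dtype=np.float64)[:, None, None] - center[0]
    y = np.arange(H, dtype=np.float64)[None, :, None] - center[1]
    x = np.arange(W, dtype=np.float64)[None, None, :] - center[2]
    if rotation_deg:
        t = np.deg2rad(rotation_deg)
        yr = np.cos(t) * y + np.sin(t) * x
        xr = -np.sin(t) * y + np.cos(t) * x
        y, x = yr, xr
    return (
        (z / radii[0]) ** 2 + (y / radii[1]) ** 2 + (x / radii[2]) ** 2
    ) <= 1.0


def _sample_geometry(spec: PhantomSpec, rng: np.random.Generator) -> dict:
    """Draw ellipsoid centers/radii. Parotids are mirror-symmetric about the
    midline column; tumors (if any) jitter independently inside their gland
    under a conservative containment bound."""
    S, H, W = spec.grid_shape
    mid = (W - 1) / 2.0
    lateral = W * (0.22 + 0.02 * rng.uniform(-1, 1))
    radii = np.array([0.30 * S, 0.14 * H, 0.10 * W]) * rng.uniform(0.9, 1.1, 3)
    radii = np.maximum(radii, 1.0)
    cz = S / 2.0 + 0.05 * S * rng.uniform(-1, 1)
    cy = H / 2.0 + 0.04 * H * rng.uniform(-1, 1)
    rot = spec.rotation_max_deg * rng.uniform(-1, 1)
    parotid = {
        # anatomical-left at high columns (image right)
        "left": {"center": (cz, cy, mid + lateral), "radii": tuple(radii),
                 "rotation_deg": rot},
        "right": {"center": (cz, cy, mid - lateral), "radii": tuple(radii),
                  "rotation_deg": -rot},
    }
    tumor = {"left": None, "right": None}
    sides = {"left": ("left",), "right": ("right",), "both": ("left", "right"),
             "none": ()}[spec.laterality]
    tf = spec.tumor_fraction
    for side in sides:
        if tf <= 0:
            continue
        p = parotid[side]
        rt = np.maximum(np.array(p["radii"]) * tf, 0.75)
        # |offset_i|/rp_i + rt_i/rp_i summed in quadrature must stay <= ~0.95
        # so every tumor voxel remains inside the parotid ellipsoid.
        frac = rt / np.array(p["radii"])
        dmax = np.maximum(np.sqrt(0.9 / 3.0) - frac, 0.0)
        delta = rng.uniform(-1, 1, 3) * dmax * np.array(p["radii"])
        tumor[side] = {
            "center": tuple(np.array(p["center"]) + delta),
            "radii": tuple(rt),
            "rotation_deg": p["rotation_deg"],
        }
    return {"parotid": parotid, "tumor": tumor}


def mirror_geometry(params: dict, width: int) -> dict:
    """Reflect a geometry about the midline column and swap sides."""
    def flip(entry):
        if entry is None:
            return None
        cz, cy, cx = entry["center"]
        return {
            "center": (cz, cy, (width - 1) - cx),
            "radii": entry["radii"],
            "rotation_deg": -entry["rotation_deg"],
        }

    return {
        "parotid": {"left": flip(params["parotid"]["right"]),
                    "right": flip(params["parotid"]["left"])},
        "tumor": {"left": flip(params["tumor"]["right"]),
                  "right": flip(params["tumor"]["left"])},
    }


# -- rendering ----------------------------------------------------------------


def render_phantom(spec: PhantomSpec, params: dict, patient_id: str = "phantom") -> PhantomCase:
    """Render volume and masks from explicit ellipsoid geometry."""
    shape = tuple(spec.grid_shape)
    masks = np.zeros(shape + (4,), dtype=np.uint8)
    regions = {}
    for side in ("left", "right"):
        p = params["parotid"][side]
        pm = _ellipsoid_mask(shape, p["center"], p["radii"], p["rotation_deg"])
        masks[..., ROI_NAMES.index(f"parotid_{side}")] = pm
        regions[f"parotid_{side}"] = pm
        t = params["tumor"][side]
        if t is not None:
            tm = _ellipsoid_mask(shape, t["center"], t["radii"], t["rotation_deg"])
            tm &= pm  # containment is guaranteed geometrically; enforce anyway
            masks[..., ROI_NAMES.index(f"tumor_{side}")] = tm
            regions[f"tumor_{side}"] = tm

    rng = np.random.default_rng(spec.seed + 1)  # noise stream, distinct from geometry
    sequences = {}
    parotid_any = regions["parotid_left"] | regions["parotid_right"]
    tumor_any = np.zeros(shape, dtype=bool)
    for side in ("left", "right"):
        if f"tumor_{side}" in regions:
            tumor_any |= regions[f"tumor_{side}"]
    for name in SEQUENCES:
        tissues = spec.contrast_profile[name]
        vol = np.full(shape, tissues["background"], dtype=np.float64)
        vol[parotid_any] = tissues["parotid"]
        vol[tumor_any] = tissues["tumor"]
        if spec.noise_sd > 0:
            vol = vol + rng.normal(0.0, spec.noise_sd, shape)
        sequences[name] = vol.astype(np.float32)

    return PhantomCase(
        patient_id=patient_id,
        volume=MultiSequenceVolume(patient_id=patient_id, sequences=sequences,
                                   spacing=spec.spacing),
        labels=RoiLabelVolume(masks=masks, spacing=spec.spacing),
        ground_truth_params=params,
        laterality=spec.laterality,
    )


def generate_phantom(spec: PhantomSpec, patient_id: str = "phantom") -> PhantomCase:
    """Generate one reproducible case: same spec (same seed) -> identical output."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    params = _sample_geometry(spec, rng)
    return render_phantom(spec, params, patient_id)


def generate_cohort(n_cases: int, base_spec: PhantomSpec, seed: int,
                    proportions: dict | None = None, out_dir=None):
    """Generate ``n_cases`` phantoms with laterality sampled per the cohort mix.

    Per-case seeds derive deterministically from ``seed``. If ``out_dir`` is
    given the cases are written as NIfTI with a JSON manifest (see
    ``io_preprocess.write_cohort``) and the manifest path is returned alongside
    the cases.
    """
    if n_cases < 1:
        raise InvalidSpecError("n_cases must be >= 1")
    props = dict(proportions or DEFAULT_LATERALITY_PROPORTIONS)
    names = sorted(props)
    p = np.array([props[k] for k in names], dtype=np.float64)
    p /= p.sum()
    rng = np.random.default_rng(seed)
    cases = []
    for i in range(n_cases):
        laterality = str(rng.choice(names, p=p))
        case_seed = int(rng.integers(0, 2**31 - 1))
        spec = dataclasses.replace(base_spec, laterality=laterality, seed=case_seed)
        cases.append(generate_phantom(spec, patient_id=f"case_{i:03d}"))
    if out_dir is not None:
        from .io_preprocess import write_cohort

        manifest = write_cohort(cases, out_dir)
        return cases, manifest
    return cases
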