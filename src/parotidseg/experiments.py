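"""Sequence-ablation experiment, model registry and report writing.

The ablation trains one cross-validated model per MRI-sequence combination —
each single sequence, each pair, and all three — with the input channel count
following the subset size, and assembles the per-combination cohort summaries
into one table (rows = combination, columns = ROI x metric).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .data import ROI_NAMES, SEQUENCES
from .errors import ConfigError, MissingSequenceError
from .metrics import CohortReport
from .model import AttentionUNet, ModelConfig, build_model
from .train import TrainConfig, run_cross_validation

#: The seven studied channel combinations: singles, pairs, and the full triple.
DEFAULT_COMBINATIONS = (
    ("T1w",),
    ("T2w",),
    ("T1wC",),
    ("T1w", "T2w"),
    ("T1w", "T1wC"),
    ("T2w", "T1wC"),
    ("T1w", "T2w", "T1wC"),
)


def _canonical(subset) -> tuple[str, ...]:
    subset = tuple(s for s in SEQUENCES if s in set(subset))
    return subset


@dataclass
class AblationPlan:
    combinations: tuple[tuple[str, ...], ...] = DEFAULT_COMBINATIONS

    def __post_init__(self):
        canon = []
        for subset in self.combinations:
            unknown = set(subset) - set(SEQUENCES)
            if unknown:
                raise ConfigError(f"unknown sequence(s) {sorted(unknown)}")
            c = _canonical(subset)
            if not c:
                raise ConfigError("empty sequence subset in ablation plan")
            canon.append(c)
        if len(set(canon)) != len(canon):
            raise ConfigError("duplicate sequence subsets in ablation plan")
        self.combinations = tuple(canon)

    @staticmethod
    def name(subset) -> str:
        return "+".join(subset)


# -- model registry -------------------------------------------------------------

_REGISTRY: dict[str, callable] = {}


def register_model(name: str, builder):
    """Register a model builder ``(ModelConfig) -> model`` under a unique name."""
    if name in _REGISTRY:
        raise ConfigError(f"model {name!r} already registered")
    _REGISTRY[name] = builder


def get_model_builder(name: str):
    if name not in _REGISTRY:
        raise KeyError(
            f"unknown model {name!r}; registered: {sorted(_REGISTRY)}"
        )
    return _REGISTRY[name]


def list_models() -> list[str]:
    return sorted(_REGISTRY)


def _builtin(gate_source):
    def build(config: ModelConfig) -> AttentionUNet:
        return build_model(dataclasses.replace(config, gate_source=gate_source))

    return build


register_model("attention_unet.bottleneck", _builtin("bottleneck"))
register_model("attention_unet.adjacent_decoder", _builtin("adjacent_decoder"))


# -- ablation ---------------------------------------------------------------------


def run_ablation(cases, plan: AblationPlan, model_config: ModelConfig,
                 train_config: TrainConfig, augment_config=None):
    """One cross-validation per sequence combination.

    Returns (reports, table, failures): ``reports`` maps combination name to
    its CohortReport; ``table`` is the combination x (ROI, metric) summary
    matrix; combinations whose sequences are missing from the cohort are
    recorded in ``failures`` and the run continues. Fold splits are shared
    across combinations (same seed), so results are comparable and invariant
    to the order combinations are listed.
    """
    reports: dict[str, CohortReport] = {}
    failures: dict[str, str] = {}
    for subset in plan.combinations:
        name = AblationPlan.name(subset)
        cfg = dataclasses.replace(model_config, in_channels=len(subset))
        try:
            reports[name] = run_cross_validation(
                cases, cfg, train_config, augment_config, sequences=list(subset)
            )
        except MissingSequenceError as exc:
            failures[name] = str(exc)
    rows = {}
    for subset in plan.combinations:
        name = AblationPlan.name(subset)
        if name not in reports:
            continue
        summary = reports[name].summary
        row = {}
        for roi in ROI_NAMES:
            for metric in ("dice", "jaccard", "hd95_mm", "ahd_mm"):
                row[(roi, metric)] = summary.loc[roi, f"{metric}_mean"]
        rows[name] = row
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "combination"
    return reports, table, failures


# -- reporting --------------------------------------------------------------------


def report(reports: dict[str, CohortReport], out_dir) -> list[Path]:
    """Write per-run CSV tables and a JSON summary with deterministic names."""
    if not reports:
        raise ValueError("no reports to write")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    summary_doc = {}
    for name in sorted(reports):
        rep = reports[name]
        safe = name.replace("+", "_")
        per_case = out_dir / f"{safe}_per_case.csv"
        summary = out_dir / f"{safe}_summary.csv"
        rep.to_csv(per_case, summary)
        written.extend([per_case, summary])
        def _num(x):
            x = float(x)
            return None if np.isnan(x) else x  # keep the JSON strict

        summary_doc[name] = {
            roi: {
                key: _num(rep.summary.loc[roi, key])
                for key in ("dice_mean", "jaccard_mean", "hd95_mm_mean", "ahd_mm_mean")
            }
            for roi in rep.summary.index
        }
    summary_path = out_dir / "summary.json"
    summary_path.write_text(json.dumps(summary_doc, indent=2, sort_keys=True))
    written.append(summary_path)
    return written
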