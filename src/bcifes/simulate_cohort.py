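"""Synthetic three-arm clinical cohort generator.

Emulates the longitudinal score structure of a stroke-rehabilitation trial:
three arms (BCI-FES / FES / control), baseline FMA-UE, MBI and MoCA drawn
per patient, and per-arm change-from-baseline distributions at five follow-up
time points (G2..G6).  Each patient carries one latent severity draw per
metric shared across time points (``delta = mean_t + sd_t * z``), so
individual trajectories are coherent while arm-level moments at every time
point equal the configured ones.  Scores are clamped to instrument ranges
after noise addition; clamp events are counted in ``table.attrs``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

METRICS = ("FMA", "MBI", "MoCA")
TIMEPOINTS = ("G1", "G2", "G3", "G4", "G5", "G6")
FOLLOWUPS = TIMEPOINTS[1:]

#: Instrument ranges: FMA-UE 0-66, MBI 0-100, MoCA 0-30.
INSTRUMENT_RANGES: dict[str, tuple[float, float]] = {
    "FMA": (0.0, 66.0),
    "MBI": (0.0, 100.0),
    "MoCA": (0.0, 30.0),
}

GENDERS = ("female", "male")
STROKE_TYPES = ("ischemic", "hemorrhagic")
LESION_SIDES = ("left", "right", "bilateral")


def score_column(metric: str, timepoint: str) -> str:
    """Column name for ``metric`` at ``timepoint`` (e.g. ``fma_g6``)."""
    return f"{metric.lower()}_{timepoint.lower()}"


@dataclass(frozen=True)
class ResponderProfile:
    """Threshold rule separating likely responders: younger than ``age_max``,
    onset shorter than ``onset_max_months``, baseline MBI above ``mbi_min``;
    actual responders are patients with delta-FMA >= ``delta_fma_min``."""

    age_max: float = 70.0
    onset_max_months: float = 23.0
    mbi_min: float = 40.0
    delta_fma_min: float = 5.0


@dataclass(frozen=True)
class CohortConfig:
    """Cohort generator configuration.

    ``deltas[arm][metric][timepoint]`` holds (mean, sd) of the change from
    G1.  ``eeg_outcome_coupling`` is the target Pearson correlation between
    Cz theta-power change and delta-FMA used by the EEG coupling stage.
    ``profile_effect`` adds a delta-FMA bonus/penalty for patients meeting /
    missing the responder profile (0 disables covariate-outcome coupling).
    """

    arms: tuple[tuple[str, int], ...]
    prescore: dict[str, tuple[float, float]]
    deltas: dict[str, dict[str, dict[str, tuple[float, float]]]]
    eeg_outcome_coupling: float = 0.68
    responder_profile: ResponderProfile = field(default_factory=ResponderProfile)
    profile_effect: float = 0.0
    age_mean: float = 72.0
    age_sd: float = 7.0
    age_range: tuple[float, float] = (60.0, 90.0)
    onset_log_mean: float = 2.5
    onset_log_sd: float = 0.8
    ischemic_fraction: float = 0.75
    lesion_side_probs: tuple[float, float, float] = (0.55, 0.37, 0.08)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.arms:
            raise ValueError("at least one arm required")
        for name, n in self.arms:
            if n < 1:
                raise ValueError(f"arm {name!r} must have n >= 1")
            if name not in self.deltas:
                raise ValueError(f"no delta distributions for arm {name!r}")
        for metric, (_, sd) in self.prescore.items():
            if sd < 0:
                raise ValueError(f"negative prescore SD for {metric}")
        for arm, per_metric in self.deltas.items():
            for metric, per_tp in per_metric.items():
                for tp, (_, sd) in per_tp.items():
                    if sd < 0:
                        raise ValueError(f"negative SD for {arm}/{metric}/{tp}")
        if not -1.0 < self.eeg_outcome_coupling < 1.0:
            raise ValueError("eeg_outcome_coupling must lie in (-1, 1)")

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        deltas = {
            arm: {m: {tp: tuple(v) for tp, v in per_tp.items()}
                  for m, per_tp in per_metric.items()}
            for arm, per_metric in d["deltas"].items()
        }
        return cls(
            arms=tuple((a, int(n)) for a, n in d["arms"]),
            prescore={m: tuple(v) for m, v in d["prescore"].items()},
            deltas=deltas,
            eeg_outcome_coupling=d.get("eeg_outcome_coupling", 0.68),
            responder_profile=ResponderProfile(**d.get("responder_profile", {})),
            profile_effect=d.get("profile_effect", 0.0),
            seed=d.get("seed", 0),
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "CohortConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def with_arms(self, arms: tuple[tuple[str, int], ...]) -> "CohortConfig":
        return replace(self, arms=arms)


def default_cohort_config(**overrides) -> CohortConfig:
    """Shipped default configuration (``bcifes/data/default_cohort.json``)."""
    text = resources.files("bcifes.data").joinpath("default_cohort.json").read_text()
    cfg = CohortConfig.from_dict(json.loads(text))
    return replace(cfg, **overrides) if overrides else cfg


def generate_cohort(config: CohortConfig, seed: int | None = None) -> pd.DataFrame:
    """Generate one synthetic cohort table.

    Returns a DataFrame with one row per patient: demographics plus
    ``fma_g1..fma_g6``, ``mbi_g1..g6``, ``moca_g1..g6``.  ``attrs`` records
    ``clamp_events`` (score values clipped to instrument range) and the seed.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    rows: list[dict] = []
    clamp_events = 0
    pid = 0
    for arm, n in config.arms:
        for _ in range(n):
            pid += 1
            age = float(np.clip(rng.normal(config.age_mean, config.age_sd),
                                *config.age_range))
            onset = float(np.clip(
                rng.lognormal(config.onset_log_mean, config.onset_log_sd), 1.0, 240.0))
            row: dict = {
                "patient_id": f"P{pid:05d}",
                "arm": arm,
                "age": round(age, 1),
                "gender": GENDERS[int(rng.integers(0, 2))],
                "stroke_type": ("ischemic" if rng.uniform() < config.ischemic_fraction
                                else "hemorrhagic"),
                "lesion_side": str(rng.choice(LESION_SIDES,
                                              p=config.lesion_side_probs)),
                "onset_months": round(onset, 1),
            }
            # baseline scores
            g1: dict[str, float] = {}
            for metric in METRICS:
                mean, sd = config.prescore[metric]
                lo, hi = INSTRUMENT_RANGES[metric]
                raw = rng.normal(mean, sd)
                val = float(np.clip(raw, lo, hi))
                clamp_events += int(val != raw)
                g1[metric] = val
                row[score_column(metric, "G1")] = round(val, 1)
            favorable = (
                row["age"] < config.responder_profile.age_max
                and row["onset_months"] < config.responder_profile.onset_max_months
                and g1["MBI"] > config.responder_profile.mbi_min
            )
            # one latent severity draw per metric, shared across time points
            for metric in METRICS:
                z = rng.standard_normal()
                lo, hi = INSTRUMENT_RANGES[metric]
                per_tp = config.deltas[arm][metric]
                for tp in FOLLOWUPS:
                    mean, sd = per_tp[tp]
                    delta = mean + sd * z
                    if metric == "FMA" and config.profile_effect != 0.0:
                        delta += config.profile_effect * (1.0 if favorable else -1.0)
                    raw = g1[metric] + delta
                    val = float(np.clip(raw, lo, hi))
                    clamp_events += int(val != raw)
                    row[score_column(metric, tp)] = round(val, 1)
            rows.append(row)
    table = pd.DataFrame(rows)
    table.attrs["clamp_events"] = clamp_events
    table.attrs["seed"] = int(config.seed if seed is None else seed)
    return table
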