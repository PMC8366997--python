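"""Configuration objects for the synthetic cohort generator and the pipeline.

All configs are frozen dataclasses with strict validation and exact JSON
round-tripping (unknown keys are rejected, not ignored), so a run is fully
described by one file plus the global seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

EVENT_TYPES: tuple[str, ...] = ("AF", "CAD", "HF", "MI", "stroke")

#: Default split of the per-subgroup total cardiac-event hazard across the
#: five event types (heart failure dominates in cardio-oncology cohorts).
EVENT_TYPE_WEIGHTS: dict[str, float] = {
    "HF": 0.35,
    "AF": 0.25,
    "CAD": 0.20,
    "MI": 0.12,
    "stroke": 0.08,
}

#: Per-subgroup total de novo cardiac-event hazard (1/year), lowest- to
#: highest-risk subgroup.
DEFAULT_EVENT_TOTALS: tuple[float, ...] = (0.02, 0.05, 0.10, 0.20)


def _default_event_hazards(
    n_subgroups: int = 4, totals: tuple[float, ...] = DEFAULT_EVENT_TOTALS
) -> dict[str, tuple[float, ...]]:
    return {
        ev: tuple(round(w * t, 10) for t in totals[:n_subgroups])
        for ev, w in EVENT_TYPE_WEIGHTS.items()
    }


class ConfigError(ValueError):
    """Raised for invalid configuration values."""


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of the synthetic cardio-oncology cohort.

    The defaults encode the study conditions the pipeline is designed
    around: four latent subgroups with cardiac-biomarker mean shifts of
    1.5 z-units on five signal variables (NT-proBNP, Troponin T,
    creatinine, LVEF, BMI), de novo cardiac-event hazards of
    0.02/0.05/0.10/0.20 per year, subgroup-graded death hazards, annual
    echo visits over a 20-year horizon, MCAR missingness and independent
    exponential right-censoring.  ``noise_corr`` is the log-sd of a
    patient-level multiplicative severity factor applied to all of a
    patient's deviations from the cohort mean; it induces correlated
    noise across variables (the kind that disrupts k-means on raw
    features but largely cancels in cosine similarity).
    """

    n_patients: int = 2000
    n_subgroups: int = 4
    subgroup_proportions: tuple[float, ...] | None = None
    feature_shift: float = 1.5
    visit_rate: float = 1.0  # expected visits per year (after year 1)
    #: True: structured surveillance with bi-monthly visits during the
    #: first on-therapy year; False: sparse opportunistic follow-up only
    #: (retrospective-EMR-like), i.e. a pure Poisson visit process.
    intensive_first_year: bool = True
    followup_horizon: float = 20.0  # years
    death_hazards: tuple[float, ...] = (0.015, 0.03, 0.05, 0.10)  # 1/year
    event_hazards: Mapping[str, tuple[float, ...]] = field(
        default_factory=_default_event_hazards
    )
    #: Within-subgroup variability multipliers (one per subgroup): set a
    #: rising ramp to emulate cohorts whose high-risk phenotypes are more
    #: heterogeneous.  None -> homoscedastic subgroups (all 1).
    subgroup_spread: tuple[float, ...] | None = None
    #: Per-subgroup loading of a latent cardiorenal-stress factor shared by
    #: NT-proBNP, Troponin T and creatinine: their mutual correlation rises
    #: with subgroup risk (None -> ramp 0 .. 0.75).
    stress_coupling: tuple[float, ...] | None = None
    preexisting_prob: float = 0.15
    censor_rate: float = 0.04  # 1/year
    missing_rate: float = 0.10  # MCAR per measurement
    measurement_noise: float = 0.30  # per-visit noise, units of variable sd
    noise_corr: float = 0.20  # log-sd of the patient-level severity factor
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subgroups < 2:
            raise ConfigError("n_subgroups must be >= 2")
        if self.n_patients < 1:
            raise ConfigError("n_patients must be >= 1")
        props = self.subgroup_proportions
        if props is None:
            props = tuple(1.0 / self.n_subgroups for _ in range(self.n_subgroups))
            object.__setattr__(self, "subgroup_proportions", props)
        if len(props) != self.n_subgroups:
            raise ConfigError(
                f"subgroup_proportions has {len(props)} entries for "
                f"{self.n_subgroups} subgroups"
            )
        if any(p < 0 for p in props) or abs(sum(props) - 1.0) > 1e-12:
            raise ConfigError("subgroup_proportions must be a simplex vector")
        if len(self.death_hazards) != self.n_subgroups:
            raise ConfigError("death_hazards must have one rate per subgroup")
        spread = self.subgroup_spread
        if spread is None:
            spread = (1.0,) * self.n_subgroups
            object.__setattr__(self, "subgroup_spread", spread)
        if len(spread) != self.n_subgroups or any(s <= 0 for s in spread):
            raise ConfigError("subgroup_spread needs one positive factor per subgroup")
        coupling = self.stress_coupling
        if coupling is None:
            coupling = tuple(
                round(0.75 * g / max(self.n_subgroups - 1, 1), 6)
                for g in range(self.n_subgroups)
            )
            object.__setattr__(self, "stress_coupling", coupling)
        if len(coupling) != self.n_subgroups or any(c < 0 for c in coupling):
            raise ConfigError("stress_coupling needs one nonnegative loading per subgroup")
        for name, rates in self.event_hazards.items():
            if name not in EVENT_TYPES:
                raise ConfigError(f"unknown event type {name!r}")
            if len(rates) != self.n_subgroups:
                raise ConfigError(f"event_hazards[{name!r}] length != n_subgroups")
        for r in (
            *self.death_hazards,
            *(r for rates in self.event_hazards.values() for r in rates),
            self.censor_rate,
            self.visit_rate,
        ):
            if r < 0:
                raise ConfigError("all rates must be >= 0")
        if not 0 <= self.preexisting_prob <= 1:
            raise ConfigError("preexisting_prob must be in [0, 1]")
        if not 0 <= self.missing_rate < 1:
            raise ConfigError("missing_rate must be in [0, 1)")
        if self.followup_horizon <= 0:
            raise ConfigError("followup_horizon must be positive")
        object.__setattr__(
            self, "event_hazards", {k: tuple(v) for k, v in self.event_hazards.items()}
        )

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["event_hazards"] = {k: list(v) for k, v in self.event_hazards.items()}
        d["subgroup_proportions"] = list(self.subgroup_proportions)
        d["death_hazards"] = list(self.death_hazards)
        d["subgroup_spread"] = list(self.subgroup_spread)
        d["stress_coupling"] = list(self.stress_coupling)
        return d

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "CohortConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown CohortConfig keys: {sorted(unknown)}")
        d = dict(d)
        for key in (
            "subgroup_proportions",
            "death_hazards",
            "subgroup_spread",
            "stress_coupling",
        ):
            if d.get(key) is not None:
                d[key] = tuple(d[key])
        if "event_hazards" in d:
            d["event_hazards"] = {k: tuple(v) for k, v in d["event_hazards"].items()}
        return cls(**d)

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "CohortConfig":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        return cls.from_dict(json.loads(text))


@dataclass(frozen=True)
class RunConfig:
    """End-to-end pipeline configuration (simulate through validate)."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    window_days: int = 92
    z_limit: float = 4.0
    metric: str = "cosine"  # or "pcc"
    cutoff_grid: tuple[float, float, float] = (0.0, 0.95, 0.05)  # lo, hi, step
    k: int | str = 4  # integer, or "auto" to run K selection
    k_range: tuple[int, int] = (3, 8)
    alpha: float = 0.05
    varnet_fraction: float = 0.15
    n_stability_runs: int = 100
    split_mode: str = "random"
    split_fractions: tuple[float, float] = (0.5, 0.5)
    split_repeats: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.metric not in ("cosine", "pcc"):
            raise ConfigError("metric must be 'cosine' or 'pcc'")
        if self.k != "auto" and (not isinstance(self.k, int) or self.k < 2):
            raise ConfigError("k must be an integer >= 2 or 'auto'")
        if not 0 < self.varnet_fraction <= 1:
            raise ConfigError("varnet_fraction must be in (0, 1]")
        if self.split_mode not in ("random", "time"):
            raise ConfigError("split_mode must be 'random' or 'time'")
        if abs(sum(self.split_fractions) - 1.0) > 1e-9:
            raise ConfigError("split_fractions must sum to 1")
        if min(self.split_fractions) <= 0:
            raise ConfigError("split_fractions must be positive")
        if self.k_range[0] < 2 or self.k_range[1] < self.k_range[0]:
            raise ConfigError("invalid k_range")

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["cohort"] = self.cohort.to_dict()
        d["cutoff_grid"] = list(self.cutoff_grid)
        d["k_range"] = list(self.k_range)
        d["split_fractions"] = list(self.split_fractions)
        return d

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown RunConfig keys: {sorted(unknown)}")
        d = dict(d)
        if "cohort" in d:
            d["cohort"] = CohortConfig.from_dict(d["cohort"])
        for key in ("cutoff_grid", "k_range", "split_fractions"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "RunConfig":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        return cls.from_dict(json.loads(text))
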