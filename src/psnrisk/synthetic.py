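"""Seeded synthetic cardio-oncology cohort generator.

Emulates the statistical structure the downstream analysis assumes: latent
patient subgroups with graded cardiac-biomarker levels and graded
cause-specific hazards, irregular echo-visit schedules, MCAR missingness
and independent right-censoring.  Longitudinal variables follow per-patient
linear trajectories ``value(t) = baseline + slope * t + noise`` where the
baseline and slope means are subgroup-specific for the signal variables.

Cardiac-event times are exponential with the subgroup's cause-specific de
novo rate, truncated at the end of follow-up (min of death, censoring,
horizon).  Preexisting events — cardiac diagnoses that predate therapy
start — are drawn independently with probability ``preexisting_prob`` and
dated uniformly within the two years before therapy start.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from psnrisk._seeds import child_rng
from psnrisk.config import EVENT_TYPES, CohortConfig

DAYS_PER_YEAR = 365.25

#: Longitudinal variable catalogue: name -> (unit, category, mean, sd,
#: subgroup-shift direction, physical floor, physical ceiling).
#: Direction 0 marks nuisance variables that carry no subgroup signal.
VARIABLES: dict[str, tuple[str, str, float, float, float, float, float]] = {
    "nt_probnp": ("pg/mL", "cardiac", 1000.0, 300.0, 1.0, 0.0, np.inf),
    "troponin_t": ("ug/L", "cardiac", 0.045, 0.012, 1.0, 0.0, np.inf),
    "creatinine": ("mg/dL", "lab", 1.1, 0.25, 1.0, 0.2, np.inf),
    "lvef": ("%", "echocardiogram", 55.0, 6.0, -1.0, 10.0, 80.0),
    "bmi": ("kg/m2", "demographics", 27.0, 5.0, 0.5, 12.0, np.inf),
    # physiologically coupled correlates: weaker shifts along a mix of
    # phenotype contrasts (systolic remodelling tracks event risk; the
    # other contrasts separate phenotypes without following the risk ramp)
    "lvedv": ("mL", "echocardiogram", 110.0, 25.0, 0.6, 20.0, np.inf),
    "lvesv": ("mL", "echocardiogram", 45.0, 15.0, 0.6, 5.0, np.inf),
    "e_over_eprime": ("ratio", "echocardiogram", 9.0, 3.0, 0.6, 1.0, np.inf),
    "la_diameter": ("cm", "echocardiogram", 3.8, 0.6, 0.5, 1.5, 8.0),
    "heart_rate": ("bpm", "cardiac", 75.0, 12.0, 0.4, 30.0, 220.0),
    "sodium": ("mmol/L", "lab", 140.0, 3.0, 0.3, 110.0, 170.0),
    "hemoglobin": ("g/dL", "lab", 12.5, 1.8, 0.4, 3.0, 22.0),
    "albumin": ("g/dL", "lab", 4.0, 0.5, 0.4, 1.0, 6.0),
    "glucose": ("mg/dL", "lab", 105.0, 25.0, 0.3, 20.0, np.inf),
    "alt": ("U/L", "lab", 28.0, 12.0, 0.3, 1.0, np.inf),
    "ast": ("U/L", "lab", 30.0, 12.0, 0.3, 1.0, np.inf),
    # uninformative labs: no subgroup structure
    "potassium": ("mmol/L", "lab", 4.2, 0.4, 0.0, 2.0, 8.0),
    "wbc": ("1e9/L", "lab", 7.0, 2.5, 0.0, 0.1, np.inf),
    "platelets": ("1e9/L", "lab", 250.0, 70.0, 0.0, 1.0, np.inf),
    "calcium": ("mg/dL", "lab", 9.4, 0.5, 0.0, 5.0, 15.0),
}

#: Variables whose subgroup means are shifted by ``feature_shift`` z-units.
SIGNAL_VARIABLES: tuple[str, ...] = tuple(
    name for name, spec in VARIABLES.items() if spec[4] != 0.0
)

#: Per-subgroup mean-shift multipliers for the default four-subgroup design
#: (subgroups ordered by increasing cardiac-event hazard).  The cardiac
#: biomarkers NT-proBNP and Troponin T rise monotonically with event risk;
#: the remaining signal variables follow distinct non-monotone phenotype
#: patterns — mirroring cohorts where the worst-survival subgroup is not
#: the highest-cardiotoxicity subgroup.  Rows are balanced so every
#: subgroup pair is separated in at least three variables.
SIGNAL_PATTERNS: dict[str, tuple[float, ...]] = {
    # primary signal variables: cardiac biomarkers rise monotonically with
    # event risk; the others follow distinct phenotype contrasts
    "nt_probnp": (-1.5, -0.5, 0.5, 1.5),
    "troponin_t": (-1.5, -0.5, 0.5, 1.5),
    "creatinine": (-1.0, 1.0, -1.0, 1.0),
    "lvef": (1.0, 1.0, -1.0, -1.0),
    "bmi": (-1.0, 1.0, 1.0, -1.0),
    # physiologically coupled correlates: weaker mixed contrasts
    "lvedv": (-0.9, -0.3, 0.3, 0.9),
    "lvesv": (-0.9, -0.3, 0.3, 0.9),
    "e_over_eprime": (-0.9, -0.3, 0.3, 0.9),
    "la_diameter": (-0.5, 0.5, -0.5, 0.5),
    "heart_rate": (-0.4, 0.4, 0.4, -0.4),
    "sodium": (0.3, 0.3, -0.3, -0.3),
    "hemoglobin": (0.4, -0.4, 0.4, -0.4),
    "albumin": (0.4, -0.4, -0.4, 0.4),
    "glucose": (-0.3, 0.3, 0.3, -0.3),
    "alt": (-0.3, -0.3, 0.3, 0.3),
    "ast": (-0.3, -0.3, 0.3, 0.3),
}

STATIC_NUMERIC: tuple[str, ...] = ("age", "sex_female", "tumor_hematologic", "tumor_stage")

# Per-year subgroup slope drift and patient-level slope jitter, in units of
# the variable's sd; small so baselines dominate but the slope feature is
# informative.
_SLOPE_DRIFT = 0.05
_SLOPE_JITTER = 0.02

#: Fraction of patients in the severity distribution's decompensated tail.
_DECOMPENSATED_FRAC = 0.15


def variable_categories() -> dict[str, str]:
    """Category tag (cardiac / echocardiogram / lab / demographics) per variable."""
    cats = {name: spec[1] for name, spec in VARIABLES.items()}
    cats.update(
        age="demographics",
        sex_female="demographics",
        tumor_hematologic="demographics",
        tumor_stage="demographics",
    )
    return cats


def variable_units() -> dict[str, str]:
    return {name: spec[0] for name, spec in VARIABLES.items()}


@dataclass
class SyntheticCohort:
    """Generated cohort: static table, long-format measurements, events,
    planted subgroup labels and the true per-patient trajectory parameters."""

    config: CohortConfig
    static: pd.DataFrame
    measurements: pd.DataFrame
    events: pd.DataFrame
    truth_labels: pd.Series
    trajectory_params: pd.DataFrame

    @property
    def patient_ids(self) -> np.ndarray:
        return self.static["patient_id"].to_numpy()

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "static": outdir / "static.csv",
            "measurements": outdir / "measurements.csv",
            "events": outdir / "events.csv",
            "truth": outdir / "truth.csv",
            "config": outdir / "cohort_config.json",
        }
        self.static.to_csv(paths["static"], index=False)
        self.measurements.to_csv(paths["measurements"], index=False)
        self.events.to_csv(paths["events"], index=False)
        self.truth_labels.rename("subgroup").rename_axis("patient_id").to_csv(
            paths["truth"]
        )
        self.config.to_json(paths["config"])
        return paths

    @classmethod
    def read(cls, indir: str | Path) -> "SyntheticCohort":
        indir = Path(indir)
        truth = pd.read_csv(indir / "truth.csv", index_col="patient_id")["subgroup"]
        return cls(
            config=CohortConfig.from_json(indir / "cohort_config.json"),
            static=pd.read_csv(indir / "static.csv"),
            measurements=pd.read_csv(indir / "measurements.csv"),
            events=pd.read_csv(indir / "events.csv"),
            truth_labels=truth,
            trajectory_params=pd.DataFrame(),
        )


def _subgroup_offsets(n_subgroups: int) -> np.ndarray:
    """Symmetric unit-spaced subgroup positions, e.g. [-1.5,-0.5,0.5,1.5]."""
    return np.arange(n_subgroups) - (n_subgroups - 1) / 2.0


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate a seeded synthetic cohort.

    Identical configs (including seed) produce byte-identical tables.
    """
    g = config.n_subgroups
    n = config.n_patients
    offsets = _subgroup_offsets(g)

    rng_assign = child_rng(config.seed, "assign")
    labels = rng_assign.choice(g, size=n, p=np.asarray(config.subgroup_proportions))

    pids = np.array([f"P{i:05d}" for i in range(n)])

    # --- static table -----------------------------------------------------
    rng_static = child_rng(config.seed, "static")
    age = np.clip(rng_static.normal(63, 11, n), 18, 90).round(1)
    sex_female = (rng_static.random(n) < 0.59).astype(int)
    hematologic = (rng_static.random(n) < 0.39).astype(int)
    stage = rng_static.choice([1, 2, 3, 4], size=n, p=[0.30, 0.30, 0.25, 0.15])
    start_span_days = int((pd.Timestamp("2016-12-31") - pd.Timestamp("1997-03-01")).days)
    therapy_start = pd.Timestamp("1997-03-01") + pd.to_timedelta(
        rng_static.integers(0, start_span_days + 1, n), unit="D"
    )
    cancer_dx_days = -rng_static.integers(30, 366, n)  # dx precedes therapy
    static = pd.DataFrame(
        {
            "patient_id": pids,
            "age": age,
            "sex_female": sex_female,
            "tumor_hematologic": hematologic,
            "tumor_stage": stage,
            "therapy_start_date": therapy_start.strftime("%Y-%m-%d"),
            "cancer_dx_days": cancer_dx_days,
        }
    )

    # --- survival, censoring and follow-up --------------------------------
    rng_surv = child_rng(config.seed, "survival")
    death_rate = np.asarray(config.death_hazards)[labels]
    t_death = np.where(
        death_rate > 0, rng_surv.exponential(1.0 / np.maximum(death_rate, 1e-300)), np.inf
    )
    t_censor = (
        rng_surv.exponential(1.0 / config.censor_rate, n)
        if config.censor_rate > 0
        else np.full(n, np.inf)
    )
    horizon = config.followup_horizon
    fu_end = np.minimum(np.minimum(t_death, t_censor), horizon)
    is_death = (t_death <= t_censor) & (t_death <= horizon)

    # --- de novo cardiac events (cause-specific, truncated at follow-up) --
    rng_ev = child_rng(config.seed, "events")
    event_rows: list[tuple[str, str, float, int, int]] = []
    for ev in EVENT_TYPES:
        rates = np.asarray(config.event_hazards.get(ev, (0.0,) * g))[labels]
        t_ev = np.where(
            rates > 0, rng_ev.exponential(1.0 / np.maximum(rates, 1e-300)), np.inf
        )
        seen = t_ev <= fu_end
        for i in np.flatnonzero(seen):
            event_rows.append(
                (pids[i], ev, round(t_ev[i] * DAYS_PER_YEAR, 1), 0, 0)
            )
    # preexisting events: independent draw, dated before therapy start
    rng_pre = child_rng(config.seed, "preexisting")
    has_pre = rng_pre.random(n) < config.preexisting_prob
    type_weights = np.array(
        [[config.event_hazards.get(ev, (0.0,) * g)[s] for ev in EVENT_TYPES] for s in range(g)]
    )
    row_sums = type_weights.sum(axis=1, keepdims=True)
    type_probs = np.where(
        row_sums > 0, type_weights / np.maximum(row_sums, 1e-300), 1.0 / len(EVENT_TYPES)
    )
    for i in np.flatnonzero(has_pre):
        ev = EVENT_TYPES[rng_pre.choice(len(EVENT_TYPES), p=type_probs[labels[i]])]
        t_days = -rng_pre.uniform(0.0, 2.0 * DAYS_PER_YEAR)
        event_rows.append((pids[i], ev, round(t_days, 1), 0, 0))
    # terminal row per patient (death or censoring)
    for i in range(n):
        event_rows.append(
            (
                pids[i],
                "death" if is_death[i] else "censor",
                round(fu_end[i] * DAYS_PER_YEAR, 1),
                int(is_death[i]),
                int(not is_death[i]),
            )
        )
    events = pd.DataFrame(
        event_rows,
        columns=["patient_id", "event_type", "days_from_therapy_start", "is_death", "is_censor"],
    ).sort_values(["patient_id", "days_from_therapy_start"], kind="stable")
    events = events.reset_index(drop=True)

    # --- longitudinal trajectories ----------------------------------------
    rng_traj = child_rng(config.seed, "trajectories")
    var_names = list(VARIABLES)
    n_vars = len(var_names)
    mus = np.array([VARIABLES[v][2] for v in var_names])
    sds = np.array([VARIABLES[v][3] for v in var_names])
    dirs = np.array([VARIABLES[v][4] for v in var_names])
    floors = np.array([VARIABLES[v][5] for v in var_names])
    ceils = np.array([VARIABLES[v][6] for v in var_names])

    # subgroup mean-shift pattern: explicit per-subgroup multipliers for the
    # default 4-subgroup design, symmetric ramp along the variable's clinical
    # direction otherwise
    pattern = offsets[:, None] * dirs[None, :]  # (g, n_vars) ramp fallback
    if g == 4:
        for j, v in enumerate(var_names):
            if v in SIGNAL_PATTERNS:
                pattern[:, j] = SIGNAL_PATTERNS[v]
    shift = config.feature_shift * pattern[labels] * sds[None, :]
    # Patient-level multiplicative severity factor: a log-normal scale
    # (mean 1) applied to every deviation from the cohort mean, inducing
    # correlated noise across all of a patient's variables, with a small
    # heavy tail of clinically decompensated patients whose deviations are
    # globally extreme.  Severity stretches subgroups radially in feature
    # space while leaving each patient's *direction* — what cosine
    # similarity measures — unchanged.
    severity = np.exp(
        config.noise_corr * rng_traj.standard_normal(n) - config.noise_corr**2 / 2
    )
    if config.noise_corr > 0:
        # fat tail of clinically decompensated patients whose deviations
        # are moderately amplified across the board (correlated noise)
        decomp = rng_traj.random(n) < _DECOMPENSATED_FRAC
        severity = severity * np.where(decomp, rng_traj.uniform(2.0, 3.0, n), 1.0)
    # within-subgroup spread: higher-risk phenotypes are more heterogeneous
    spread = np.asarray(config.subgroup_spread)[labels]
    baselines = mus[None, :] + severity[:, None] * (
        shift + spread[:, None] * rng_traj.standard_normal((n, n_vars)) * sds[None, :]
    )
    # latent cardiorenal-stress factor: couples the cardiac biomarkers and
    # creatinine within a subgroup, increasingly so at higher risk
    stress = rng_traj.standard_normal(n)
    coupling = np.asarray(config.stress_coupling)[labels]
    stress_vars = [
        j for j, v in enumerate(var_names) if v in ("nt_probnp", "troponin_t", "creatinine")
    ]
    for j in stress_vars:
        baselines[:, j] += severity * coupling * stress * sds[j]
    # subgroup slope drift is part of the planted signal and scales with
    # feature_shift (a null cohort has no drift), jitter is patient noise
    drift_scale = config.feature_shift / 1.5 if config.feature_shift > 0 else 0.0
    slopes = severity[:, None] * (
        drift_scale * _SLOPE_DRIFT * offsets[labels][:, None] * (dirs * sds)[None, :]
        + spread[:, None] * rng_traj.standard_normal((n, n_vars)) * _SLOPE_JITTER * sds[None, :]
    )

    # Visit schedule: mandatory baseline at t=0, intensive monitoring during
    # the first on-therapy year (bi-monthly grid with jitter, as long as the
    # patient remains under follow-up), then a homogeneous Poisson process at
    # ``visit_rate`` for long-term surveillance.
    rng_vis = child_rng(config.seed, "visits")
    first_year_grid = np.arange(1, 7) / 6.0  # bi-monthly through year 1
    visit_times = []
    for i in range(n):
        fu = fu_end[i]
        if config.intensive_first_year:
            early = first_year_grid + rng_vis.normal(0.0, 0.02, len(first_year_grid))
            early = early[(early > 0) & (early < min(fu, 1.0))]
            n_late = rng_vis.poisson(config.visit_rate * max(fu - 1.0, 0.0))
            late = rng_vis.uniform(1.0, fu, n_late) if n_late > 0 else np.empty(0)
            t = np.concatenate([[0.0], np.sort(np.concatenate([early, late]))])
        else:
            n_vis = rng_vis.poisson(config.visit_rate * fu)
            t = np.concatenate([[0.0], np.sort(rng_vis.uniform(0.0, fu, n_vis))])
        if len(t) < 2:  # guarantee >= 2 visits even for very early dropout
            t = np.concatenate([[0.0], rng_vis.uniform(0.0, fu, 1)])
        visit_times.append(t)

    pid_rep = np.repeat(pids, [len(t) for t in visit_times])
    lab_rep = np.repeat(labels, [len(t) for t in visit_times])
    t_all = np.concatenate(visit_times)  # years
    n_obs = len(t_all)
    idx = np.repeat(np.arange(n), [len(t) for t in visit_times])
    rng_noise = child_rng(config.seed, "noise")
    # visit-to-visit variability carries the subgroup's heterogeneity
    # factor but not the patient's severity (assay noise is patient-free)
    values = (
        baselines[idx]
        + slopes[idx] * t_all[:, None]
        + spread[idx, None]
        * rng_noise.standard_normal((n_obs, n_vars))
        * (config.measurement_noise * sds)[None, :]
    )
    values = np.clip(values, floors[None, :], ceils[None, :])

    meas = pd.DataFrame(
        {
            "patient_id": np.repeat(pid_rep, n_vars),
            "variable": np.tile(var_names, n_obs),
            "value": values.ravel().round(6),
            "days_from_therapy_start": np.repeat(
                np.round(t_all * DAYS_PER_YEAR, 1), n_vars
            ),
        }
    )
    if config.missing_rate > 0:
        rng_miss = child_rng(config.seed, "missing")
        keep = rng_miss.random(len(meas)) >= config.missing_rate
        meas = meas.loc[keep].reset_index(drop=True)
    del lab_rep

    truth = pd.Series(labels, index=pids, name="subgroup")
    truth.index.name = "patient_id"
    params = pd.DataFrame(
        {
            "patient_id": np.repeat(pids, n_vars),
            "variable": np.tile(var_names, n),
            "baseline": baselines.ravel(),
            "slope_per_year": slopes.ravel(),
        }
    )
    return SyntheticCohort(
        config=config,
        static=static,
        measurements=meas,
        events=events,
        truth_labels=truth,
        trajectory_params=params,
    )
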