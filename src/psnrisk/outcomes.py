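"""Clinical validation of patient subgroups against cardiac outcomes.

Event classification (preexisting vs de novo), Kaplan-Meier survival and
Nelson-Aalen cumulative-hazard curves with omnibus and pairwise log-rank
tests (Benjamini-Hochberg adjusted), Cox proportional-hazards ratios,
chi-square enrichment of binary outcomes across subgroups, per-period
event breakdowns, and biomarker-threshold survival comparisons.

Death before a cardiac event censors the event endpoint (cause-specific
framing); competing-risk cumulative incidence is out of scope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter, NelsonAalenFitter
from lifelines.statistics import logrank_test, multivariate_logrank_test
from scipy import stats
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.proportion import proportion_confint

from psnrisk.config import EVENT_TYPES
from psnrisk.synthetic import DAYS_PER_YEAR

DEFAULT_PERIODS: tuple[tuple[float, float], ...] = ((0, 1), (2, 5), (6, 10), (11, 20))

#: Guideline-style biomarker bins (unit-bearing, lowest bin is reference).
NT_PROBNP_BINS: tuple[float, ...] = (0.0, 125.0, 900.0, np.inf)  # pg/mL
TROPONIN_T_BINS: tuple[float, ...] = (-np.inf, 0.01, 0.05, np.inf)  # ug/L


@dataclass
class OutcomeTable:
    """Per-patient outcome summary derived from the raw event table.

    ``frame`` is indexed by patient id with columns: ``os_time_years``
    (overall survival from cancer diagnosis), ``death``,
    ``followup_years`` (therapy start to death/censor), ``preexisting``,
    ``de_novo_ctrcd``, ``denovo_time_years`` (therapy start to first de
    novo event, censored at follow-up end) and ``denovo_event``, plus one
    ``first_<type>_days`` column per cardiac event type.
    """

    frame: pd.DataFrame

    @property
    def patient_ids(self) -> pd.Index:
        return self.frame.index


@dataclass
class HazardEstimate:
    covariate: str
    hr: float
    ci95: tuple[float, float]
    p: float

    def __post_init__(self) -> None:
        lo, hi = self.ci95
        if not (lo <= self.hr <= hi) or self.hr <= 0:
            raise ValueError(f"inconsistent hazard estimate for {self.covariate}")


@dataclass
class GroupSurvivalResult:
    """Survival (or cumulative-hazard) curves per group with log-rank tests."""

    curves: dict[object, pd.DataFrame]  # group -> columns: time, estimate, lo95, hi95
    omnibus_p: float
    pairwise: pd.DataFrame  # columns: group_a, group_b, p_raw, p_bh
    dropped_groups: list = field(default_factory=list)


def classify_events(events: pd.DataFrame, cancer_dx_days: pd.Series | None = None) -> OutcomeTable:
    """Classify cardiac events relative to therapy start (day 0).

    Events dated before day 0 are preexisting; events on or after day 0
    are de novo (a boundary event on the therapy-start day counts as de
    novo).  A patient may hold both flags.  Overall survival runs from
    the cancer diagnosis date when ``cancer_dx_days`` (negative offsets
    from therapy start) is given, otherwise from therapy start.
    """
    ev = events.copy()
    bad_types = set(ev["event_type"]) - set(EVENT_TYPES) - {"death", "censor"}
    if bad_types:
        raise ValueError(f"unknown event types: {sorted(bad_types)}")
    terminal = ev[ev["event_type"].isin(["death", "censor"])]
    counts = terminal.groupby("patient_id").size()
    if (counts != 1).any():
        raise ValueError(
            f"each patient needs exactly one death/censor row; offenders: "
            f"{counts.index[counts != 1].tolist()[:5]}"
        )
    terminal = terminal.set_index("patient_id")
    cardiac = ev[ev["event_type"].isin(EVENT_TYPES)]
    end_days = terminal["days_from_therapy_start"]
    late = cardiac.merge(end_days.rename("end"), left_on="patient_id", right_index=True)
    offenders = late.loc[late["days_from_therapy_start"] > late["end"], "patient_id"]
    if len(offenders):
        raise ValueError(
            f"cardiac event dated after death/censor for patients: "
            f"{sorted(set(offenders))[:5]}"
        )

    out = pd.DataFrame(index=end_days.index)
    out.index.name = "patient_id"
    out["followup_years"] = end_days / DAYS_PER_YEAR
    out["death"] = terminal["is_death"].astype(int)
    dx_offset = (
        cancer_dx_days.reindex(out.index).fillna(0.0) if cancer_dx_days is not None else 0.0
    )
    out["os_time_years"] = (end_days - dx_offset) / DAYS_PER_YEAR

    first = (
        cardiac.groupby(["patient_id", "event_type"])["days_from_therapy_start"]
        .min()
        .unstack()
    )
    for evt in EVENT_TYPES:
        col = first[evt] if evt in first else pd.Series(dtype=float)
        out[f"first_{evt}_days"] = col.reindex(out.index)
    pre = cardiac[cardiac["days_from_therapy_start"] < 0].groupby("patient_id").size()
    dn = cardiac[cardiac["days_from_therapy_start"] >= 0].groupby("patient_id").size()
    out["preexisting"] = out.index.isin(pre.index).astype(int)
    out["de_novo_ctrcd"] = out.index.isin(dn.index).astype(int)
    first_dn = (
        cardiac[cardiac["days_from_therapy_start"] >= 0]
        .groupby("patient_id")["days_from_therapy_start"]
        .min()
        .reindex(out.index)
    )
    out["denovo_event"] = out["de_novo_ctrcd"]
    out["denovo_time_years"] = (
        first_dn.fillna(end_days).clip(lower=0) / DAYS_PER_YEAR
    )
    return OutcomeTable(frame=out.sort_index())


def _bh(p: np.ndarray) -> np.ndarray:
    return multipletests(p, method="fdr_bh")[1] if len(p) else np.array([])


def _group_logrank(
    times: np.ndarray, flags: np.ndarray, groups: np.ndarray
) -> tuple[float, pd.DataFrame]:
    levels = np.unique(groups)
    omnibus = multivariate_logrank_test(times, groups, flags)
    pairs = list(combinations(levels, 2))
    raw = np.array(
        [
            logrank_test(
                times[groups == a], times[groups == b],
                flags[groups == a], flags[groups == b],
            ).p_value
            for a, b in pairs
        ]
    )
    pairwise = pd.DataFrame(
        {
            "group_a": [a for a, _ in pairs],
            "group_b": [b for _, b in pairs],
            "p_raw": raw,
            "p_bh": _bh(raw),
        }
    )
    return float(omnibus.p_value), pairwise


def km_by_group(
    times: np.ndarray, event_flags: np.ndarray, groups: np.ndarray
) -> GroupSurvivalResult:
    """Kaplan-Meier product-limit curves per group with Greenwood 95%
    bands, omnibus log-rank and BH-adjusted pairwise log-rank tests."""
    times = np.asarray(times, dtype=float)
    flags = np.asarray(event_flags, dtype=int)
    groups = np.asarray(groups)
    if np.any(times < 0):
        raise ValueError("times must be >= 0")
    curves: dict[object, pd.DataFrame] = {}
    dropped = []
    for lev in np.unique(groups):
        m = groups == lev
        if m.sum() == 0:
            dropped.append(lev)
            continue
        kmf = KaplanMeierFitter()
        kmf.fit(times[m], flags[m])
        ci = kmf.confidence_interval_survival_function_
        curves[lev] = pd.DataFrame(
            {
                "time": kmf.survival_function_.index,
                "estimate": kmf.survival_function_["KM_estimate"].to_numpy(),
                "lo95": ci.iloc[:, 0].to_numpy(),
                "hi95": ci.iloc[:, 1].to_numpy(),
            }
        ).reset_index(drop=True)
    kept = np.isin(groups, list(curves))
    if len(curves) >= 2:
        omnibus_p, pairwise = _group_logrank(times[kept], flags[kept], groups[kept])
    else:
        omnibus_p, pairwise = np.nan, pd.DataFrame(
            columns=["group_a", "group_b", "p_raw", "p_bh"]
        )
    if dropped:
        warnings.warn(f"dropped empty group(s): {dropped}", stacklevel=2)
    return GroupSurvivalResult(
        curves=curves, omnibus_p=omnibus_p, pairwise=pairwise, dropped_groups=dropped
    )


def cumulative_hazard_by_group(
    times: np.ndarray, event_flags: np.ndarray, groups: np.ndarray
) -> GroupSurvivalResult:
    """Nelson-Aalen cumulative-hazard curves per group with log-rank tests.

    For a cause-specific endpoint, pass times/flags in which competing
    deaths appear as censorings.
    """
    times = np.asarray(times, dtype=float)
    flags = np.asarray(event_flags, dtype=int)
    groups = np.asarray(groups)
    curves: dict[object, pd.DataFrame] = {}
    dropped = []
    for lev in np.unique(groups):
        m = groups == lev
        if m.sum() == 0:
            dropped.append(lev)
            continue
        naf = NelsonAalenFitter(nelson_aalen_smoothing=False)
        naf.fit(times[m], flags[m])
        ci = naf.confidence_interval_cumulative_hazard_
        curves[lev] = pd.DataFrame(
            {
                "time": naf.cumulative_hazard_.index,
                "estimate": naf.cumulative_hazard_.iloc[:, 0].to_numpy(),
                "lo95": ci.iloc[:, 0].to_numpy(),
                "hi95": ci.iloc[:, 1].to_numpy(),
            }
        ).reset_index(drop=True)
    if len(curves) >= 2:
        kept = np.isin(groups, list(curves))
        omnibus_p, pairwise = _group_logrank(times[kept], flags[kept], groups[kept])
    else:
        omnibus_p, pairwise = np.nan, pd.DataFrame(
            columns=["group_a", "group_b", "p_raw", "p_bh"]
        )
    return GroupSurvivalResult(
        curves=curves, omnibus_p=omnibus_p, pairwise=pairwise, dropped_groups=dropped
    )


def cox_hr(
    data: pd.DataFrame,
    duration_col: str,
    event_col: str,
    covariates: list[str] | None = None,
) -> list[HazardEstimate]:
    """Cox proportional-hazards fit; Wald 95% CI and p per coefficient.

    ``data`` must be complete-case.  Categorical covariates (e.g. the
    subgroup label) should be passed pre-encoded as indicator columns
    against the chosen reference level.  Exactly collinear covariates
    raise a rank-deficiency error.
    """
    cols = covariates or [c for c in data.columns if c not in (duration_col, event_col)]
    x = data[cols].to_numpy(dtype=float)
    if np.linalg.matrix_rank(np.column_stack([np.ones(len(x)), x])) < len(cols) + 1:
        raise np.linalg.LinAlgError(
            f"covariate matrix is rank-deficient (condition number "
            f"{np.linalg.cond(x):.3g}); remove collinear columns"
        )
    cph = CoxPHFitter()
    cph.fit(data[[duration_col, event_col] + cols], duration_col=duration_col, event_col=event_col)
    s = cph.summary
    return [
        HazardEstimate(
            covariate=name,
            hr=float(row["exp(coef)"]),
            ci95=(float(row["exp(coef) lower 95%"]), float(row["exp(coef) upper 95%"])),
            p=float(row["p"]),
        )
        for name, row in s.iterrows()
    ]


def encode_subgroups(labels: pd.Series, reference: object) -> pd.DataFrame:
    """Indicator columns for each subgroup against a reference level."""
    levels = [lev for lev in sorted(labels.unique()) if lev != reference]
    return pd.DataFrame(
        {f"cluster_{lev}": (labels == lev).astype(int) for lev in levels},
        index=labels.index,
    )


def chi2_enrichment(cluster_labels: np.ndarray, binary_outcome: np.ndarray) -> pd.DataFrame:
    """Per-cluster outcome rate (Wilson 95% CI) and cluster-vs-rest
    Pearson chi-square p (no continuity correction; exact fallback when an
    expected cell drops below 1)."""
    labels = np.asarray(cluster_labels)
    y = np.asarray(binary_outcome, dtype=int)
    rows = []
    for lev in np.unique(labels):
        m = labels == lev
        a, b = int(y[m].sum()), int((~y[m].astype(bool)).sum())
        c, d = int(y[~m].sum()), int((~y[~m].astype(bool)).sum())
        table = np.array([[a, b], [c, d]])
        expected = stats.contingency.expected_freq(table)
        if (expected < 1).any():
            warnings.warn(
                f"expected cell < 1 for cluster {lev}; using Fisher exact test",
                stacklevel=2,
            )
            p = stats.fisher_exact(table)[1]
            chi2 = np.nan
        else:
            chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
        lo, hi = proportion_confint(a, a + b, method="wilson")
        rows.append(
            {
                "cluster": lev,
                "n": a + b,
                "n_positive": a,
                "rate": a / (a + b),
                "rate_lo95": lo,
                "rate_hi95": hi,
                "chi2": chi2,
                "p": p,
            }
        )
    return pd.DataFrame(rows)


def period_breakdown(
    outcomes: OutcomeTable,
    cluster_labels: pd.Series,
    periods: tuple[tuple[float, float], ...] = DEFAULT_PERIODS,
) -> pd.DataFrame:
    """Percentage of each cluster whose FIRST de novo event (and death)
    falls in each follow-up period (years since therapy start).

    A period ``(a, b)`` covers whole event-years ``a..b`` inclusive
    (an event at 1.4 years falls in year 1), so the default periods
    0-1 / 2-5 / 6-10 / 11-20 tile the follow-up horizon without overlap.
    Periods must be disjoint and ordered; Wilson 95% CIs accompany each
    percentage.  Denominator is the full cluster size.
    """
    for (a0, a1), (b0, b1) in zip(periods, periods[1:]):
        if a1 >= b0 or a0 > a1:
            raise ValueError("periods must be disjoint and ordered")
    frame = outcomes.frame.loc[cluster_labels.index]
    rows = []
    for lev in sorted(cluster_labels.unique()):
        m = cluster_labels == lev
        sub = frame.loc[m.index[m]]
        n = len(sub)
        dn_t = sub.loc[sub["denovo_event"] == 1, "denovo_time_years"]
        death_t = sub.loc[sub["death"] == 1, "followup_years"]
        for lo_p, hi_p in periods:
            for endpoint, tser in (("de_novo_ctrcd", dn_t), ("death", death_t)):
                year = np.floor(tser)
                cnt = int(((year >= lo_p) & (year <= hi_p)).sum())
                lo, hi = proportion_confint(cnt, n, method="wilson")
                rows.append(
                    {
                        "cluster": lev,
                        "period": f"{lo_p:g}-{hi_p:g}",
                        "endpoint": endpoint,
                        "n": n,
                        "count": cnt,
                        "percent": 100.0 * cnt / n,
                        "lo95": 100.0 * lo,
                        "hi95": 100.0 * hi,
                    }
                )
    return pd.DataFrame(rows)


def biomarker_km(
    outcomes: OutcomeTable,
    biomarker: pd.Series,
    bin_edges: tuple[float, ...],
    duration_col: str = "os_time_years",
    event_col: str = "death",
) -> tuple[GroupSurvivalResult, list[HazardEstimate]]:
    """Survival stratified by guideline-style biomarker bins.

    Patients are binned by ``bin_edges`` (right-closed); empty bins are
    dropped with a warning.  Returns KM curves with BH-adjusted log-rank
    tests plus Cox hazard ratios of each bin against the lowest bin.  With
    a single populated bin only the curve is returned (no comparison).
    """
    frame = outcomes.frame.loc[biomarker.index]
    bins = pd.cut(biomarker, bins=list(bin_edges), include_lowest=True)
    empty = [str(c) for c in bins.cat.categories if (bins == c).sum() == 0]
    if empty:
        warnings.warn(f"dropping empty biomarker bin(s): {empty}", stacklevel=2)
    bins = bins.cat.remove_unused_categories()
    groups = bins.astype(str).to_numpy()
    res = km_by_group(
        frame[duration_col].to_numpy(), frame[event_col].to_numpy(), groups
    )
    hazards: list[HazardEstimate] = []
    if len(bins.cat.categories) >= 2:
        ref = bins.cat.categories[0]
        ind = pd.DataFrame(
            {f"bin_{c}": (bins == c).astype(int) for c in bins.cat.categories[1:]},
            index=frame.index,
        )
        data = pd.concat([frame[[duration_col, event_col]], ind], axis=1)
        hazards = cox_hr(data, duration_col, event_col, list(ind.columns))
        del ref
    return res, hazards
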