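"""Train/test evaluation of the similarity-network clustering model.

Patients are split at random or by calendar time (earlier block trains).
All preprocessing statistics (imputation means, scaling means/sds) are
fitted on the training set only; test patients are represented by their
similarity profile *against the training patients*, which keeps the
centroid space dimensionally consistent, and are assigned to the nearest
fitted centroid.  Subgroup separation on the held-out set is then tested
with omnibus log-rank statistics for overall survival and de novo
cardiac events.  Discrimination of scalar risk scores is summarised with
the IPCW cumulative/dynamic time-dependent AUROC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sksurv.metrics import cumulative_dynamic_auc
from sksurv.util import Surv

from psnrisk._seeds import child_rng, child_seed
from psnrisk.clustering import assign, fit_kmeans
from psnrisk.network import cross_similarity, similarity_matrix
from psnrisk.outcomes import OutcomeTable, km_by_group
from psnrisk.preprocess import (
    apply_scaling,
    build_feature_matrix,
    impute_and_scale,
    remove_outliers,
)
from psnrisk.synthetic import SyntheticCohort


@dataclass(frozen=True)
class SplitPlan:
    """Train/test split specification.

    ``mode='time'`` orders patients by cancer-diagnosis date and trains on
    the earlier block; ``mode='random'`` draws ``n_repeats`` independent
    random splits.
    """

    mode: str = "random"
    fractions: tuple[float, float] = (0.5, 0.5)
    n_repeats: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("random", "time"):
            raise ValueError("mode must be 'random' or 'time'")
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1")
        if min(self.fractions) <= 0:
            raise ValueError("both fractions must be positive (no degenerate split)")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")


@dataclass
class SplitResult:
    """One split's held-out evaluation."""

    split_label: str
    train_ids: list[str]
    test_ids: list[str]
    test_labels: pd.Series
    logrank_p_survival: float
    logrank_p_denovo: float
    ari_vs_truth: float | None = None


@dataclass
class ValidationReport:
    plan: SplitPlan
    splits: list[SplitResult] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "split": s.split_label,
                    "n_train": len(s.train_ids),
                    "n_test": len(s.test_ids),
                    "logrank_p_survival": s.logrank_p_survival,
                    "logrank_p_denovo": s.logrank_p_denovo,
                    "ari_vs_truth": s.ari_vs_truth,
                }
                for s in self.splits
            ]
        )


def _split_ids(cohort: SyntheticCohort, plan: SplitPlan, repeat: int) -> tuple[list[str], list[str]]:
    static = cohort.static
    ids = static["patient_id"].to_numpy()
    n_train = int(round(plan.fractions[0] * len(ids)))
    n_train = min(max(n_train, 1), len(ids) - 1)
    if plan.mode == "time":
        dx_date = pd.to_datetime(static["therapy_start_date"]) + pd.to_timedelta(
            static["cancer_dx_days"], unit="D"
        )
        order = np.argsort(dx_date.to_numpy(), kind="stable")  # earlier block trains
        ordered = ids[order]
        return list(ordered[:n_train]), list(ordered[n_train:])
    rng = child_rng(plan.seed, "split", repeat)
    perm = rng.permutation(ids)
    return list(perm[:n_train]), list(perm[n_train:])


def _evaluate_split(
    cohort: SyntheticCohort,
    outcomes: OutcomeTable,
    train_ids: list[str],
    test_ids: list[str],
    label: str,
    k: int,
    metric: str,
    window_days: float,
    z_limit: float,
    seed: int,
) -> SplitResult:
    meas = cohort.measurements
    train_raw = build_feature_matrix(
        meas[meas["patient_id"].isin(train_ids)],
        cohort.static[cohort.static["patient_id"].isin(train_ids)],
        window_days=window_days,
    )
    train_feat = impute_and_scale(remove_outliers(train_raw, z_limit))
    test_raw = build_feature_matrix(
        meas[meas["patient_id"].isin(test_ids)],
        cohort.static[cohort.static["patient_id"].isin(test_ids)],
        window_days=window_days,
    )
    test_feat = apply_scaling(test_raw, train_feat)

    sim_train = similarity_matrix(train_feat, metric)
    model = fit_kmeans(sim_train, k, seed=child_seed(seed, "fit", label))
    sim_cross = cross_similarity(test_feat, train_feat, metric)
    test_labels = assign(model, sim_cross)

    sub = outcomes.frame.loc[test_labels.index]
    groups = test_labels.to_numpy()
    os_res = km_by_group(sub["os_time_years"].to_numpy(), sub["death"].to_numpy(), groups)
    dn_res = km_by_group(
        sub["denovo_time_years"].to_numpy(), sub["denovo_event"].to_numpy(), groups
    )
    ari = None
    if cohort.truth_labels is not None and len(cohort.truth_labels):
        from sklearn.metrics import adjusted_rand_score

        truth = cohort.truth_labels.loc[test_labels.index].to_numpy()
        ari = float(adjusted_rand_score(truth, groups))
    return SplitResult(
        split_label=label,
        train_ids=train_ids,
        test_ids=test_ids,
        test_labels=test_labels,
        logrank_p_survival=os_res.omnibus_p,
        logrank_p_denovo=dn_res.omnibus_p,
        ari_vs_truth=ari,
    )


def run_split_validation(
    cohort: SyntheticCohort,
    outcomes: OutcomeTable,
    plan: SplitPlan,
    k: int = 4,
    metric: str = "cosine",
    window_days: float = 92,
    z_limit: float = 4.0,
) -> ValidationReport:
    """Run the split plan end to end and report held-out subgroup
    separation (log-rank p for survival and de novo events per split)."""
    report = ValidationReport(plan=plan)
    n_splits = 1 if plan.mode == "time" else plan.n_repeats
    for r in range(n_splits):
        label = "time" if plan.mode == "time" else f"random_{r}"
        train_ids, test_ids = _split_ids(cohort, plan, r)
        report.splits.append(
            _evaluate_split(
                cohort, outcomes, train_ids, test_ids, label,
                k=k, metric=metric, window_days=window_days, z_limit=z_limit,
                seed=child_seed(plan.seed, "eval", r),
            )
        )
    return report


def time_dependent_auroc(
    risk_scores: np.ndarray,
    test_times: np.ndarray,
    test_events: np.ndarray,
    eval_times: np.ndarray,
    train_times: np.ndarray | None = None,
    train_events: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Cumulative/dynamic AUC(t) with inverse-probability-of-censoring
    weights.

    Evaluation times with no prior events, or outside the observed
    follow-up, are undefined and skipped (noted by their absence from the
    returned time vector).  Returns (times used, AUC(t), mean AUC).
    """
    scores = np.asarray(risk_scores, dtype=float)
    if not np.isfinite(scores).all():
        raise ValueError("risk scores must be finite")
    t = np.asarray(test_times, dtype=float)
    e = np.asarray(test_events, dtype=bool)
    if train_times is None:
        train_times, train_events = t, e
    surv_train = Surv.from_arrays(np.asarray(train_events, dtype=bool), np.asarray(train_times))
    surv_test = Surv.from_arrays(e, t)
    event_times = t[e]
    if event_times.size == 0:
        return np.array([]), np.array([]), np.nan
    lo = event_times.min()
    hi = t.max()
    use = np.asarray(
        [tt for tt in np.atleast_1d(eval_times) if lo <= tt < hi], dtype=float
    )
    if use.size == 0:
        return np.array([]), np.array([]), np.nan
    auc, mean_auc = cumulative_dynamic_auc(surv_train, surv_test, scores, use)
    return use, auc, float(mean_auc)
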