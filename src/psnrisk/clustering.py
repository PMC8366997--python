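"""K-means subgrouping of patients on their similarity-network profiles.

Each patient's feature vector is its row of the *full* (unthresholded)
patient-patient similarity matrix — the "similarity profile".  K is
selected by refitting across a range and keeping the largest K whose
subgroups remain statistically separable on both clinical endpoints
(overall survival and de novo cardiac events) by omnibus and pairwise
log-rank tests with Benjamini-Hochberg adjustment.  Stability across
random initialisations is summarised with the adjusted Rand index (ARI)
and adjusted mutual information (AMI) against the lowest-SSE run.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_mutual_info_score, adjusted_rand_score

from psnrisk._seeds import child_seed
from psnrisk.network import SimilarityMatrix
from psnrisk.outcomes import OutcomeTable, km_by_group


@dataclass
class ClusterModel:
    """Fitted k-means model in similarity-profile space.

    The centroid dimension equals the number of training patients, whose
    order defines the profile axis for out-of-sample assignment.  Cluster
    labels are canonicalized by descending cluster size (1 = largest).
    """

    k: int
    centroids: np.ndarray  # (k, n_train)
    training_ids: list[str]
    labels: pd.Series  # patient_id -> 1..k
    seed: int
    sse: float

    def to_json(self, path: str | Path) -> None:
        payload = {
            "k": self.k,
            "seed": self.seed,
            "sse": self.sse,
            "training_ids": list(self.training_ids),
            "labels": {p: int(c) for p, c in self.labels.items()},
            "centroids": self.centroids.tolist(),
        }
        Path(path).write_text(json.dumps(payload) + "\n")


@dataclass
class StabilityReport:
    """Per-run agreement with the lowest-SSE reference clustering."""

    reference_run: int
    runs: pd.DataFrame  # columns: run, seed, sse, ari, ami
    ari_threshold: float
    n_stable: int  # runs with ARI >= threshold


def _canonicalize(labels: np.ndarray, centroids: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Relabel clusters 1..K by descending size; reorder centroids to match."""
    k = centroids.shape[0]
    sizes = np.bincount(labels, minlength=k)
    order = np.argsort(-sizes, kind="stable")
    remap = np.empty(k, dtype=int)
    remap[order] = np.arange(1, k + 1)
    return remap[labels], centroids[order]


def fit_kmeans(
    sim: SimilarityMatrix, k: int, seed: int, n_init: int = 10
) -> ClusterModel:
    """Lloyd k-means (k-means++ init) on similarity-profile rows.

    SSE is the within-cluster sum of squared distances to centroids.
    Refitting with the same seed reproduces the labels exactly.
    """
    n = sim.n
    if not 2 <= k <= n:
        raise ValueError(f"k must be in [2, {n}], got {k}")
    km = KMeans(n_clusters=k, random_state=seed % 2**31, n_init=n_init)
    raw = km.fit_predict(sim.values)
    if len(np.unique(raw)) < k:  # empty cluster: re-seed once, then fail
        km = KMeans(n_clusters=k, random_state=(seed + 1) % 2**31, n_init=n_init)
        raw = km.fit_predict(sim.values)
        if len(np.unique(raw)) < k:
            raise RuntimeError(f"k-means produced an empty cluster for k={k}")
    labels, centroids = _canonicalize(raw, km.cluster_centers_)
    return ClusterModel(
        k=k,
        centroids=centroids,
        training_ids=list(sim.patient_ids),
        labels=pd.Series(labels, index=sim.patient_ids, name="cluster"),
        seed=seed,
        sse=float(km.inertia_),
    )


def select_k(
    sim: SimilarityMatrix,
    outcomes: OutcomeTable,
    k_range: tuple[int, int] = (3, 20),
    alpha: float = 0.05,
    seed: int = 0,
    n_init: int = 10,
) -> tuple[int | None, pd.DataFrame]:
    """Choose the number of subgroups by clinical separability.

    For every K in ``k_range`` the model is refit and the subgroups are
    compared on overall survival and on de novo cardiac events with
    omnibus log-rank tests and all-pairs log-rank tests (BH-adjusted).
    The selection is the LARGEST K for which both omnibus p-values and
    every pairwise adjusted p-value fall below ``alpha`` — preferring
    more, still clinically distinct, subgroups.  The full per-K report
    (including the SSE elbow curve) is always returned; the selected K is
    None when no K qualifies.
    """
    table = outcomes.frame.loc[list(sim.patient_ids)]
    rows = []
    for k in range(k_range[0], k_range[1] + 1):
        model = fit_kmeans(sim, k, seed=child_seed(seed, "select_k", k), n_init=n_init)
        groups = model.labels.to_numpy()
        os_res = km_by_group(
            table["os_time_years"].to_numpy(), table["death"].to_numpy(), groups
        )
        dn_res = km_by_group(
            table["denovo_time_years"].to_numpy(),
            table["denovo_event"].to_numpy(),
            groups,
        )
        qualifies = (
            os_res.omnibus_p < alpha
            and dn_res.omnibus_p < alpha
            and (os_res.pairwise["p_bh"] < alpha).all()
            and (dn_res.pairwise["p_bh"] < alpha).all()
        )
        rows.append(
            {
                "k": k,
                "sse": model.sse,
                "omnibus_p_survival": os_res.omnibus_p,
                "omnibus_p_denovo": dn_res.omnibus_p,
                "max_pairwise_p_bh_survival": float(os_res.pairwise["p_bh"].max()),
                "max_pairwise_p_bh_denovo": float(dn_res.pairwise["p_bh"].max()),
                "qualifies": bool(qualifies),
            }
        )
    report = pd.DataFrame(rows)
    qualified = report.loc[report["qualifies"], "k"]
    selected = int(qualified.max()) if len(qualified) else None
    return selected, report


def stability_analysis(
    sim: SimilarityMatrix,
    k: int,
    n_runs: int = 100,
    base_seed: int = 0,
    ari_threshold: float = 0.8,
    n_init: int = 10,
) -> StabilityReport:
    """Repeat k-means under different random initial states.

    Each run is a full k-means fit (``n_init`` restarts, keeping the best,
    as the standard k-means implementations do); the run with the lowest
    SSE serves as the reference, and every run's ARI and AMI against the
    reference quantify stability.
    """
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2")
    fits = []
    for r in range(n_runs):
        seed_r = child_seed(base_seed, "stability", r)
        fits.append((r, seed_r, fit_kmeans(sim, k, seed=seed_r, n_init=n_init)))
    ref_idx = min(fits, key=lambda t: t[2].sse)[0]
    ref_labels = fits[ref_idx][2].labels.to_numpy()
    rows = [
        {
            "run": r,
            "seed": s,
            "sse": m.sse,
            "ari": adjusted_rand_score(ref_labels, m.labels.to_numpy()),
            "ami": adjusted_mutual_info_score(ref_labels, m.labels.to_numpy()),
        }
        for r, s, m in fits
    ]
    runs = pd.DataFrame(rows)
    return StabilityReport(
        reference_run=ref_idx,
        runs=runs,
        ari_threshold=ari_threshold,
        n_stable=int((runs["ari"] >= ari_threshold).sum()),
    )


def _nearest_centroid(profiles: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    d2 = ((profiles[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    return d2.argmin(axis=1) + 1  # labels are 1-based


def assign(model: ClusterModel, sim_test_vs_train: pd.DataFrame | np.ndarray) -> pd.Series:
    """Assign new patients to the nearest centroid (Euclidean).

    Test profiles must be similarities against the training patients, in
    training order (columns).  Deterministic.
    """
    if isinstance(sim_test_vs_train, pd.DataFrame):
        profiles = sim_test_vs_train.to_numpy(dtype=float)
        index = sim_test_vs_train.index
    else:
        profiles = np.asarray(sim_test_vs_train, dtype=float)
        index = pd.RangeIndex(len(profiles))
    n_train = model.centroids.shape[1]
    if profiles.shape[1] != n_train:
        raise ValueError(
            f"profile dimension {profiles.shape[1]} != training-set size {n_train}"
        )
    return pd.Series(_nearest_centroid(profiles, model.centroids), index=index, name="cluster")
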