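"""Patient-patient similarity matrix and density-selected network.

The similarity between two patients is the cosine of their derived
feature vectors (or, alternatively, the Pearson correlation, i.e. the
cosine after row-centering).  For visualization-style exports, a cutoff
is chosen by scanning a grid and keeping the cutoff that minimizes the
network density — retained edges divided by n(n-1)/2 possible edges —
computed over the nodes that keep at least one edge.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from psnrisk.preprocess import FeatureMatrix


@dataclass
class SimilarityMatrix:
    """Dense symmetric patient similarity matrix with its metric tag."""

    patient_ids: pd.Index
    values: np.ndarray  # (n, n), symmetric, diagonal 1
    metric: str  # "cosine" | "pcc"

    @property
    def n(self) -> int:
        return len(self.patient_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.patient_ids, columns=self.patient_ids)


@dataclass
class PatientNetwork:
    """Thresholded similarity network: nodes with >= 1 retained edge."""

    nodes: list[str]
    edges: pd.DataFrame  # columns: source, target, weight
    cutoff: float
    isolated: list[str]

    @property
    def density(self) -> float:
        return network_density(len(self.edges), len(self.nodes)) if len(self.nodes) >= 2 else 0.0

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_weighted_edges_from(
            self.edges[["source", "target", "weight"]].itertuples(index=False, name=None)
        )
        return g

    def write(self, outdir: str | Path, prefix: str = "patient_network") -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.edges.to_csv(outdir / f"{prefix}_edges.tsv", sep="\t", index=False)
        nx.write_graphml(self.to_graph(), outdir / f"{prefix}.graphml")


def similarity_matrix(features: FeatureMatrix, metric: str = "cosine") -> SimilarityMatrix:
    """Pairwise patient similarity over the derived feature vectors.

    cosine(A, B) = sum_i A_i B_i / (sqrt(sum_i A_i^2) sqrt(sum_i B_i^2));
    the Pearson variant centers each patient's vector first.  A zero-norm
    patient vector yields similarity 0 to everyone (with a warning) and 1
    on the diagonal.
    """
    if metric not in ("cosine", "pcc"):
        raise ValueError(f"unknown metric {metric!r}")
    x = features.values.to_numpy(dtype=float)
    if x.shape[0] < 2:
        raise ValueError("need at least 2 patients")
    if metric == "pcc":
        x = x - x.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(x, axis=1)
    zero = norms == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} patient vector(s) have zero norm; similarities set to 0",
            stacklevel=2,
        )
    xn = x / np.where(zero, 1.0, norms)[:, None]
    sim = xn @ xn.T
    sim[zero, :] = 0.0
    sim[:, zero] = 0.0
    sim = np.clip((sim + sim.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(sim, 1.0)
    return SimilarityMatrix(patient_ids=features.patient_ids.copy(), values=sim, metric=metric)


def cross_similarity(
    test: FeatureMatrix, train: FeatureMatrix, metric: str = "cosine"
) -> pd.DataFrame:
    """Similarity of each test patient against every training patient.

    Rows are test patients; the column order is the training patient order,
    which defines the profile axis used by a fitted cluster model.
    """
    a = test.values.to_numpy(dtype=float)
    b = train.values.to_numpy(dtype=float)
    if metric == "pcc":
        a = a - a.mean(axis=1, keepdims=True)
        b = b - b.mean(axis=1, keepdims=True)
    elif metric != "cosine":
        raise ValueError(f"unknown metric {metric!r}")
    na = np.linalg.norm(a, axis=1)
    nb = np.linalg.norm(b, axis=1)
    an = a / np.where(na == 0, 1.0, na)[:, None]
    bn = b / np.where(nb == 0, 1.0, nb)[:, None]
    sim = np.clip(an @ bn.T, -1.0, 1.0)
    sim[na == 0, :] = 0.0
    sim[:, nb == 0] = 0.0
    return pd.DataFrame(sim, index=test.patient_ids, columns=train.patient_ids)


def network_density(n_edges: int, n_nodes: int) -> float:
    """Edges retained divided by the n(n-1)/2 possible links."""
    if n_nodes < 2:
        raise ValueError("need at least 2 nodes")
    possible = n_nodes * (n_nodes - 1) // 2
    if n_edges > possible:
        raise ValueError(f"{n_edges} edges exceed the {possible} possible links")
    return n_edges / possible


def _edge_stats(sim: np.ndarray, cutoff: float) -> tuple[int, int]:
    """(edge count, node count with degree >= 1) at a strict cutoff."""
    adj = np.triu(sim > cutoff, k=1)
    n_edges = int(adj.sum())
    deg = adj.sum(axis=0) + adj.sum(axis=1)
    return n_edges, int((deg > 0).sum())


def select_density_cutoff(
    sim: SimilarityMatrix,
    grid_step: float = 0.05,
    grid_range: tuple[float, float] | None = None,
) -> tuple[float, pd.DataFrame]:
    """Scan cutoffs on a grid and return the density-minimizing cutoff.

    Density at each cutoff is computed over the nodes that retain at least
    one edge; cutoffs whose network is empty are excluded from the argmin
    (and an error is raised if every candidate is empty).  Ties break
    toward the smaller cutoff, which retains more patients.
    """
    if grid_range is None:
        off_diag = sim.values[~np.eye(sim.n, dtype=bool)]
        grid_range = (0.0, float(off_diag.max()))
    lo, hi = grid_range
    cutoffs = np.round(np.arange(lo, hi + 1e-9, grid_step), 10)
    rows = []
    for c in cutoffs:
        n_edges, n_nodes = _edge_stats(sim.values, float(c))
        dens = network_density(n_edges, n_nodes) if n_nodes >= 2 else np.nan
        rows.append({"cutoff": float(c), "n_edges": n_edges, "n_nodes": n_nodes, "density": dens})
    profile = pd.DataFrame(rows)
    valid = profile.dropna(subset=["density"])
    valid = valid[valid["n_edges"] > 0]
    if valid.empty:
        raise ValueError(f"all candidate networks are empty; profile:\n{profile}")
    best = valid.loc[valid["density"].idxmin()]  # idxmin takes first == smaller cutoff
    return float(best["cutoff"]), profile


def build_network(sim: SimilarityMatrix, cutoff: float) -> PatientNetwork:
    """Connect patient pairs with similarity strictly above ``cutoff``.

    Patients left without any edge are excluded from the node list but
    reported in ``isolated``.
    """
    if not -1.0 <= cutoff < 1.0:
        raise ValueError("cutoff must be in [-1, 1)")
    ids = np.asarray(sim.patient_ids)
    iu, ju = np.triu_indices(sim.n, k=1)
    keep = sim.values[iu, ju] > cutoff
    edges = pd.DataFrame(
        {
            "source": ids[iu[keep]],
            "target": ids[ju[keep]],
            "weight": sim.values[iu[keep], ju[keep]],
        }
    )
    connected = set(edges["source"]).union(edges["target"])
    nodes = [p for p in ids if p in connected]
    isolated = [p for p in ids if p not in connected]
    return PatientNetwork(nodes=nodes, edges=edges, cutoff=cutoff, isolated=isolated)
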