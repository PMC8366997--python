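"""Per-subgroup clinical-variable correlation networks.

Within each patient subgroup, Pearson correlations between all pairs of
noncategorical variables define a variable-variable network: the top
fraction of pairs by |PCC| (default 15%) are connected, and variables are
ranked by degree and betweenness centrality.  Families of derived
features are collapsed to their base variable with the maximum-absolute
PCC (sign of the achieving member retained).  Degree profiles across the
subgroup networks are clustered by complete-linkage agglomeration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy


@dataclass
class VariableNetwork:
    """Thresholded variable-correlation network for one patient subgroup."""

    cluster_id: object
    nodes: pd.DataFrame  # index: variable; columns: category, degree, betweenness
    edges: pd.DataFrame  # columns: var_a, var_b, pcc, p
    fraction: float
    threshold: float  # |PCC| at the retained-edge quantile
    max_edge_p: float

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes.index)
        for row in self.edges.itertuples(index=False):
            g.add_edge(row.var_a, row.var_b, pcc=row.pcc, p=row.p)
        return g

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.edges.to_csv(outdir / f"varnet_{self.cluster_id}_edges.tsv", sep="\t", index=False)
        g = self.to_graph()
        for name, cat in self.nodes["category"].items():
            g.nodes[name]["category"] = str(cat)
        nx.write_graphml(g, outdir / f"varnet_{self.cluster_id}.graphml")


def cluster_pcc(
    features: pd.DataFrame, noncategorical: list[str] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson r and two-sided p for all variable pairs within one subgroup.

    ``features`` holds the subgroup's patients only (rows).  Constant
    columns are excluded.  Requires at least 3 patients.
    """
    if len(features) < 3:
        raise ValueError(f"cluster has {len(features)} patients; need >= 3")
    cols = noncategorical if noncategorical is not None else list(features.columns)
    x = features[cols]
    x = x.loc[:, x.std(ddof=0) > 0]
    r = x.corr(method="pearson")
    n = len(x)
    rv = r.to_numpy(copy=True)
    np.fill_diagonal(rv, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rv * np.sqrt((n - 2) / np.maximum(1.0 - rv**2, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    np.fill_diagonal(p, 0.0)
    return r, pd.DataFrame(p, index=r.index, columns=r.columns)


def aggregate_derived_family(
    pcc: pd.DataFrame,
    p: pd.DataFrame,
    families: dict[str, list[str]],
    family_family: str = "aggregate",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Collapse each derived-feature family to its base variable.

    The correlation between a base variable and any other node is the
    member correlation of maximum absolute value, sign retained; the p of
    the achieving member is carried.  Pairs of two families are likewise
    aggregated over all member cross-pairs when ``family_family`` is
    ``"aggregate"``, or dropped when ``"exclude"``.  Empty families are
    skipped.
    """
    if family_family not in ("aggregate", "exclude"):
        raise ValueError("family_family must be 'aggregate' or 'exclude'")
    families = {
        base: [m for m in members if m in pcc.columns]
        for base, members in families.items()
    }
    families = {b: m for b, m in families.items() if m}
    member_cols = {c for m in families.values() for c in m}
    plain = [c for c in pcc.columns if c not in member_cols]
    nodes = plain + list(families)
    out_r = pd.DataFrame(np.eye(len(nodes)), index=nodes, columns=nodes)
    out_p = pd.DataFrame(np.zeros((len(nodes), len(nodes))), index=nodes, columns=nodes)

    def signed_max(sub_r: pd.DataFrame, sub_p: pd.DataFrame) -> tuple[float, float]:
        flat = sub_r.to_numpy().ravel()
        k = int(np.nanargmax(np.abs(flat)))
        return float(flat[k]), float(sub_p.to_numpy().ravel()[k])

    for i, a in enumerate(nodes):
        for b in nodes[i + 1 :]:
            a_m = families.get(a, [a])
            b_m = families.get(b, [b])
            if a in families and b in families and family_family == "exclude":
                out_r.loc[a, b] = out_r.loc[b, a] = np.nan
                out_p.loc[a, b] = out_p.loc[b, a] = np.nan
                continue
            rv, pv = signed_max(pcc.loc[a_m, b_m], p.loc[a_m, b_m])
            out_r.loc[a, b] = out_r.loc[b, a] = rv
            out_p.loc[a, b] = out_p.loc[b, a] = pv
    return out_r, out_p


def topk_edges(
    pcc: pd.DataFrame,
    p: pd.DataFrame | None = None,
    fraction: float = 0.15,
    categories: dict[str, str] | None = None,
    cluster_id: object = None,
) -> VariableNetwork:
    """Connect the top ``fraction`` of variable pairs by |PCC|.

    The threshold is the ceil(fraction x n_pairs)-th largest |PCC| among
    candidate pairs; every pair tied with the threshold is included, so
    the edge count equals the nominal count up to ties.  NaN pairs are
    not candidates.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    names = list(pcc.columns)
    iu, ju = np.triu_indices(len(names), k=1)
    vals = pcc.to_numpy()[iu, ju]
    pvals = (p.to_numpy()[iu, ju] if p is not None else np.full(len(vals), np.nan))
    cand = ~np.isnan(vals)
    abs_vals = np.abs(vals[cand])
    n_keep = max(1, math.ceil(fraction * len(abs_vals)))
    threshold = float(np.sort(abs_vals)[::-1][n_keep - 1])
    keep = cand.copy()
    keep[cand] = abs_vals >= threshold
    edges = pd.DataFrame(
        {
            "var_a": [names[i] for i in iu[keep]],
            "var_b": [names[j] for j in ju[keep]],
            "pcc": vals[keep],
            "p": pvals[keep],
        }
    )
    g = nx.Graph()
    g.add_nodes_from(names)
    g.add_edges_from(edges[["var_a", "var_b"]].itertuples(index=False, name=None))
    btw = nx.betweenness_centrality(g, normalized=True)
    nodes = pd.DataFrame(
        {
            "category": [
                (categories or {}).get(v, "unknown") for v in names
            ],
            "degree": [g.degree(v) for v in names],
            "betweenness": [btw[v] for v in names],
        },
        index=pd.Index(names, name="variable"),
    )
    max_p = float(np.nanmax(edges["p"])) if len(edges) and p is not None else np.nan
    return VariableNetwork(
        cluster_id=cluster_id,
        nodes=nodes,
        edges=edges,
        fraction=fraction,
        threshold=threshold,
        max_edge_p=max_p,
    )


def centrality(network: VariableNetwork) -> pd.DataFrame:
    """Unweighted degree and normalized shortest-path betweenness per node."""
    g = network.to_graph()
    btw = nx.betweenness_centrality(g, normalized=True)
    return pd.DataFrame(
        {"degree": [g.degree(v) for v in g.nodes], "betweenness": [btw[v] for v in g.nodes]},
        index=pd.Index(list(g.nodes), name="variable"),
    )


def cluster_variables(
    degree_profiles: pd.DataFrame, n_flat: int | None = None
) -> tuple[np.ndarray, list[str], pd.Series | None]:
    """Complete-linkage hierarchical clustering of variables by their
    degree profiles across the subgroup networks (Euclidean distance).

    Returns the linkage matrix, the dendrogram leaf order, and optional
    flat cluster labels when ``n_flat`` is given.  A single variable
    yields a singleton tree.
    """
    names = list(degree_profiles.index)
    if len(names) == 1:
        return np.empty((0, 4)), names, (
            pd.Series([1], index=names) if n_flat else None
        )
    z = hierarchy.linkage(degree_profiles.to_numpy(dtype=float), method="complete")
    leaves = [names[i] for i in hierarchy.leaves_list(z)]
    flat = None
    if n_flat is not None:
        flat = pd.Series(
            hierarchy.fcluster(z, t=n_flat, criterion="maxclust"), index=names
        )
    return z, leaves, flat


def collinearity_summary(
    features: pd.DataFrame, threshold: float = 0.25
) -> tuple[float, pd.DataFrame]:
    """Fraction of variable pairs whose |PCC| is below ``threshold`` over
    the full cohort, plus the full correlation matrix for heatmaps."""
    x = features.loc[:, features.std(ddof=0) > 0]
    r = x.corr(method="pearson")
    iu, ju = np.triu_indices(len(r), k=1)
    vals = np.abs(r.to_numpy()[iu, ju])
    return float(np.mean(vals < threshold)), r


def group_variable_summary(
    features: pd.DataFrame, labels: pd.Series, reference: object
) -> pd.DataFrame:
    """Per-cluster variable means with a Kolmogorov-Smirnov p against the
    reference cluster's distribution (simple screening table)."""
    rows = []
    ref_rows = features.loc[labels.index[labels == reference]]
    for lev in sorted(labels.unique()):
        sub = features.loc[labels.index[labels == lev]]
        for var in features.columns:
            if lev == reference:
                p = 1.0
            else:
                p = float(stats.ks_2samp(sub[var], ref_rows[var]).pvalue)
            rows.append(
                {"cluster": lev, "variable": var, "mean": float(sub[var].mean()), "ks_p_vs_ref": p}
            )
    return pd.DataFrame(rows)
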