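"""Cluster-augmented parcellation graphs and node topology metrics.

Per subject, parcel-averaged time series are correlated (Pearson), the
correlation matrix is thresholded to a fixed density keeping only the
strongest positive edges, and six weighted node metrics are computed on the
resulting graph: strength, global efficiency, local efficiency, clustering
coefficient, betweenness centrality, and participation coefficient.
Path-based metrics use edge lengths 1/weight; clustering uses the
geometric-mean (Onnela) triangle coefficient with weights normalized by the
maximum retained weight; participation uses communities fixed a priori from
the parcellation (the seven canonical resting-state networks plus a single
shared "cluster" community for the variability clusters).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse.csgraph import dijkstra
from scipy.stats import spearmanr

from .cohort import SurfaceTimeSeries
from .dispersion import ClusterSet
from .inference import fdr_adjust

__all__ = [
    "Parcellation",
    "ParcelGraph",
    "METRICS",
    "augment_parcellation",
    "parcel_timeseries",
    "correlation_graph",
    "node_metrics",
    "metric_zprofile",
    "gradient_topology_association",
]

METRICS = (
    "strength",
    "global_efficiency",
    "local_efficiency",
    "clustering",
    "betweenness",
    "participation",
)

CLUSTER_COMMUNITY = "cluster"


@dataclass
class Parcellation:
    """Vertex labels, parcel membership, and community assignment."""

    labels: np.ndarray  # (V,) parcel index, -1 = unassigned
    parcel_names: list[str]
    communities: list[str]  # per parcel
    overlap: pd.DataFrame = field(default=None, repr=False)

    @property
    def n_parcels(self) -> int:
        return len(self.parcel_names)

    def vertices_of(self, parcel: int) -> np.ndarray:
        return np.flatnonzero(self.labels == parcel)


@dataclass
class ParcelGraph:
    """Density-thresholded positive-correlation graph over parcels."""

    weights: np.ndarray  # (N, N) symmetric, zero diagonal, entries in [0, 1]
    density: float
    communities: list[str]
    node_names: list[str]
    n_edges: int

    def __post_init__(self) -> None:
        w = self.weights
        if not np.allclose(w, w.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(w) != 0):
            raise ValueError("no self-loops allowed")
        if np.any(w < 0) or np.any(w > 1):
            raise ValueError("weights must lie in [0, 1]")

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]


def augment_parcellation(
    atlas: pd.DataFrame,
    clusters: ClusterSet,
    cluster_community: str = CLUSTER_COMMUNITY,
    one_community_per_cluster: bool = False,
) -> Parcellation:
    """Add variability clusters to an atlas, masking overlapped parcels.

    ``atlas`` needs columns ``vertex``, ``parcel``, ``network``. Cluster
    vertices are removed from their donor parcels; clusters are appended as
    new parcels assigned to a shared "cluster" community (or one community
    each when ``one_community_per_cluster``). Atlas parcels left empty are
    dropped. The per-(cluster, network) vertex overlap percentages are
    recorded before masking.
    """
    n_v = int(atlas["vertex"].max()) + 1
    if clusters.labels.shape[0] != n_v:
        raise ValueError("atlas and clusters cover different vertex spaces")
    parcel_of = np.full(n_v, -1, dtype=int)
    parcel_of[atlas["vertex"].to_numpy()] = atlas["parcel"].to_numpy()
    atlas_ids = sorted(atlas["parcel"].unique())
    net_of = dict(
        atlas.drop_duplicates("parcel")[["parcel", "network"]].itertuples(index=False)
    )

    overlap_rows = []
    for cl in clusters.clusters:
        nets = [net_of.get(parcel_of[v], None) for v in cl.vertices]
        if all(n is None for n in nets):
            raise ValueError(f"cluster {cl.id} covers no atlas vertex")
        counts = pd.Series([n for n in nets if n is not None]).value_counts()
        for net, cnt in counts.items():
            overlap_rows.append(
                {
                    "cluster": cl.id,
                    "network": net,
                    "pct_vertices": 100.0 * cnt / cl.vertices.size,
                }
            )
    overlap = pd.DataFrame(overlap_rows)

    labels = np.full(n_v, -1, dtype=int)
    names: list[str] = []
    communities: list[str] = []
    cluster_vertex = clusters.labels > 0
    idx = 0
    for pid in atlas_ids:
        verts = np.flatnonzero((parcel_of == pid) & ~cluster_vertex)
        if verts.size == 0:
            continue  # entirely masked by a cluster
        labels[verts] = idx
        names.append(f"parcel_{pid}")
        communities.append(net_of[pid])
        idx += 1
    for cl in clusters.clusters:
        labels[cl.vertices] = idx
        names.append(f"cluster_{cl.id}")
        communities.append(
            f"{cluster_community}_{cl.id}" if one_community_per_cluster else cluster_community
        )
        idx += 1
    return Parcellation(
        labels=labels, parcel_names=names, communities=communities, overlap=overlap
    )


def parcel_timeseries(ts: SurfaceTimeSeries, parc: Parcellation) -> np.ndarray:
    """Unweighted mean time series within each parcel (node x time)."""
    if ts.n_vertices != parc.labels.shape[0]:
        raise ValueError("vertex counts of time series and parcellation differ")
    out = np.empty((parc.n_parcels, ts.n_timepoints))
    for p in range(parc.n_parcels):
        verts = parc.vertices_of(p)
        if verts.size == 0:
            raise ValueError(f"parcel {p} is empty")
        out[p] = ts.data[verts].mean(axis=0)
    return out


def correlation_graph(
    node_ts: np.ndarray,
    density: float = 0.10,
    communities: list[str] | None = None,
    node_names: list[str] | None = None,
) -> ParcelGraph:
    """Pearson correlation graph thresholded to a fixed edge density.

    Keeps the ``floor(density * n(n-1)/2)`` largest strictly positive
    off-diagonal correlations (ties broken by lexicographic node pair);
    negative and zero correlations are never retained. If fewer positive
    edges exist than the density asks for, all of them are kept with a
    warning. Constant node series have undefined correlations, treated as 0
    with a warning.
    """
    if not 0 < density <= 1:
        raise ValueError("density must be in (0, 1]")
    node_ts = np.asarray(node_ts, dtype=float)
    n, t = node_ts.shape
    if t < 3:
        raise ValueError("need at least 3 timepoints")
    sd = node_ts.std(axis=1)
    if np.any(sd == 0):
        warnings.warn(
            f"{int((sd == 0).sum())} constant node series; correlations set to 0",
            RuntimeWarning,
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(node_ts)
    corr = np.nan_to_num(corr, nan=0.0)
    np.fill_diagonal(corr, 0.0)

    iu, ju = np.triu_indices(n, k=1)
    vals = corr[iu, ju]
    positive = vals > 0
    m_target = int(np.floor(density * n * (n - 1) / 2))
    cand = np.flatnonzero(positive)
    # sort by descending weight, then by (i, j) lexicographic for ties
    order = np.lexsort((ju[cand], iu[cand], -vals[cand]))
    keep = cand[order][:m_target]
    if cand.size < m_target:
        warnings.warn(
            f"only {cand.size} positive edges available for target {m_target}",
            RuntimeWarning,
            stacklevel=2,
        )
    weights = np.zeros((n, n))
    weights[iu[keep], ju[keep]] = vals[keep]
    weights = weights + weights.T
    return ParcelGraph(
        weights=weights,
        density=density,
        communities=list(communities) if communities else ["all"] * n,
        node_names=list(node_names) if node_names else [f"node_{i}" for i in range(n)],
        n_edges=int(keep.size),
    )


# ---------------------------------------------------------------------------
# node metrics

def _pairwise_distances(weights: np.ndarray) -> np.ndarray:
    """All-pairs shortest-path distances with edge length 1/weight."""
    with np.errstate(divide="ignore"):
        lengths = np.where(weights > 0, 1.0 / weights, 0.0)
    return dijkstra(lengths, directed=False)


def _graph_efficiency_per_node(weights: np.ndarray) -> np.ndarray:
    """Nodal global efficiency: mean inverse distance to every other node
    (unreachable pairs contribute 0)."""
    n = weights.shape[0]
    if n < 2:
        return np.zeros(n)
    d = _pairwise_distances(weights)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return inv.sum(axis=1) / (n - 1)


def _clustering_onnela(weights: np.ndarray) -> np.ndarray:
    """Weighted clustering coefficient (geometric-mean triangles), weights
    normalized by the maximum weight in the graph."""
    n = weights.shape[0]
    wmax = weights.max()
    if wmax == 0:
        return np.zeros(n)
    w_hat = (weights / wmax) ** (1.0 / 3.0)
    tri = np.diag(w_hat @ w_hat @ w_hat)  # 2x geometric-mean triangle count
    deg = (weights > 0).sum(axis=1)
    denom = deg * (deg - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(denom > 0, tri / denom, 0.0)
    return c


def node_metrics(g: ParcelGraph) -> pd.DataFrame:
    """The six weighted node metrics, one row per node.

    Isolated nodes get 0 for every metric by convention.
    """
    w = g.weights
    n = g.n_nodes
    if n == 0:
        raise ValueError("empty graph")
    strength = w.sum(axis=1)
    glob_eff = _graph_efficiency_per_node(w)
    clustering = _clustering_onnela(w)

    local_eff = np.zeros(n)
    for i in range(n):
        nbrs = np.flatnonzero(w[i] > 0)
        if nbrs.size < 2:
            continue
        sub = w[np.ix_(nbrs, nbrs)]
        local_eff[i] = _graph_efficiency_per_node(sub).mean()

    with np.errstate(divide="ignore"):
        lengths = np.where(w > 0, 1.0 / w, 0.0)
    G = nx.from_numpy_array(lengths)
    bc = nx.betweenness_centrality(G, weight="weight", normalized=False)
    betweenness = np.array([bc[i] for i in range(n)])

    comm = np.asarray(g.communities)
    participation = np.zeros(n)
    for i in range(n):
        k_i = strength[i]
        if k_i == 0:
            continue
        frac = np.array(
            [w[i, comm == m].sum() / k_i for m in np.unique(comm)]
        )
        participation[i] = 1.0 - np.sum(frac**2)

    return pd.DataFrame(
        {
            "strength": strength,
            "global_efficiency": glob_eff,
            "local_efficiency": local_eff,
            "clustering": clustering,
            "betweenness": betweenness,
            "participation": participation,
        },
        index=g.node_names,
    )


def metric_zprofile(
    metrics_per_subject: list[pd.DataFrame], target_nodes: list[str]
) -> pd.DataFrame:
    """Z-score each metric across nodes within subject, then average the
    target nodes' z-values across subjects.

    A metric constant across nodes in some subject is flagged (NaN for that
    subject) and excluded from the average.
    """
    if not metrics_per_subject:
        raise ValueError("need at least one subject")
    zs = []
    for df in metrics_per_subject:
        if df.shape[0] < 2:
            raise ValueError("need at least 2 nodes per subject")
        sd = df.std(ddof=1)
        z = (df - df.mean()) / sd.replace(0.0, np.nan)
        zs.append(z.loc[target_nodes])
    stacked = pd.concat(zs, keys=range(len(zs)))
    return stacked.groupby(level=1, sort=False).mean()


def gradient_topology_association(
    cluster_axis: np.ndarray, metrics: pd.DataFrame
) -> pd.DataFrame:
    """Spearman association between a cluster's gradient coordinate and each
    of its topology metrics across subjects, BH-adjusted across metrics.

    ``metrics`` has one row per subject and one column per metric.
    """
    x = np.asarray(cluster_axis, dtype=float)
    if x.size != metrics.shape[0]:
        raise ValueError("subject counts differ")
    if x.size < 5:
        raise ValueError("need at least 5 subjects")
    rows = []
    for col in metrics.columns:
        v = metrics[col].to_numpy(dtype=float)
        if np.std(v) == 0 or np.std(x) == 0:
            rows.append((col, np.nan, np.nan, True))
        else:
            rho, p = spearmanr(x, v)
            rows.append((col, float(rho), float(p), False))
    frame = pd.DataFrame(rows, columns=["metric", "rho", "p", "constant"])
    frame["q"] = np.nan
    ok = ~frame["constant"]
    if ok.any():
        frame.loc[ok, "q"] = fdr_adjust(frame.loc[ok, "p"].to_numpy())
    return frame
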