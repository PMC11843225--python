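"""Cross-subject dispersion in gradient space and cluster extraction.

For every vertex, subjects occupy K-dimensional gradient coordinates; the
dispersion statistic is the sum of squared Euclidean distances of the
subjects' coordinates from the group centroid (the arithmetic mean, which
minimizes that sum). Dispersion decomposes additively across gradient axes,
which lets total variability be attributed to individual functional
dimensions. Loci of maximal variability are extracted by thresholding the
total-dispersion map at a percentile and keeping connected suprathreshold
components above a minimum surface area.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components
from scipy.stats import spearmanr

from .embedding import GroupEmbedding, SubjectEmbedding
from .inference import fdr_adjust
from .mesh import MeshTopology

__all__ = [
    "DispersionMap",
    "Cluster",
    "ClusterSet",
    "vertex_dispersion",
    "axis_dispersion_correlation",
    "extract_clusters",
    "cluster_coordinates",
]


@dataclass
class DispersionMap:
    """Per-vertex dispersion: total, per-axis decomposition, and centroid."""

    total: np.ndarray  # (V,)
    per_axis: np.ndarray  # (V, K)
    centroids: np.ndarray  # (V, K)
    n_subjects: int
    normalized: bool = False

    def __post_init__(self) -> None:
        if np.any(self.total < -1e-12) or np.any(self.per_axis < -1e-12):
            raise ValueError("dispersion must be nonnegative")
        if not np.allclose(self.total, self.per_axis.sum(axis=1), atol=1e-8):
            raise ValueError("total must equal the per-axis sum")


@dataclass
class Cluster:
    id: int
    vertices: np.ndarray
    area_mm2: float
    tag: str | None = None


@dataclass
class ClusterSet:
    """Labeled suprathreshold clusters (label 0 = background)."""

    labels: np.ndarray
    clusters: list[Cluster]
    threshold_value: float

    def __len__(self) -> int:
        return len(self.clusters)


def vertex_dispersion(
    embeddings: list[SubjectEmbedding], normalize: bool = False
) -> DispersionMap:
    """Sum of squared distances of subjects from the per-vertex centroid.

    ``normalize`` divides by (n_subjects - 1), turning the raw scatter into
    a per-axis-summed sample variance for cross-cohort comparability.
    """
    if len(embeddings) < 2:
        raise ValueError("dispersion needs at least 2 subjects")
    coords = np.stack([e.coords for e in embeddings])  # (S, V, K)
    if any(e.coords.shape != coords[0].shape for e in embeddings):
        raise ValueError("all subject embeddings must share the same shape")
    centroids = coords.mean(axis=0)
    dev = coords - centroids[None]
    per_axis = (dev**2).sum(axis=0)  # (V, K)
    if normalize:
        per_axis = per_axis / (coords.shape[0] - 1)
    return DispersionMap(
        total=per_axis.sum(axis=1),
        per_axis=per_axis,
        centroids=centroids,
        n_subjects=coords.shape[0],
        normalized=normalize,
    )


def axis_dispersion_correlation(
    disp: DispersionMap, group: GroupEmbedding
) -> pd.DataFrame:
    """Spearman correlation of total dispersion with each axis' dispersion
    and with each group gradient map, FDR-adjusted across all rows.

    Constant inputs yield an undefined correlation, reported as NaN.
    """
    if disp.per_axis.shape[1] != group.k:
        raise ValueError("axis counts of dispersion map and embedding differ")
    rows = []
    for j in range(group.k):
        rows.append((f"axis_dispersion_{j + 1}",) + _safe_spearman(disp.total, disp.per_axis[:, j]))
    for j in range(group.k):
        rows.append((f"gradient_{j + 1}",) + _safe_spearman(disp.total, group.gradients[:, j]))
    frame = pd.DataFrame(rows, columns=["variable", "rho", "p"])
    valid = frame["p"].notna()
    frame["q"] = np.nan
    if valid.any():
        frame.loc[valid, "q"] = fdr_adjust(frame.loc[valid, "p"].to_numpy())
    return frame


def _safe_spearman(x, y):
    if np.std(x) == 0 or np.std(y) == 0:
        return (np.nan, np.nan)
    rho, p = spearmanr(x, y)
    return (float(rho), float(p))


def extract_clusters(
    disp: DispersionMap,
    mesh: MeshTopology,
    percentile: float = 95.0,
    min_area_mm2: float = 200.0,
) -> ClusterSet:
    """Threshold the total-dispersion map and extract connected clusters.

    The threshold is the given percentile (linear interpolation) of total
    dispersion over all vertices; vertices strictly above it are grouped
    into connected components under mesh edge adjacency, components with
    summed vertex area below ``min_area_mm2`` are discarded, and surviving
    clusters are labeled 1..C in order of descending area.

    An empty result (no suprathreshold vertices, or none surviving the
    area filter) is returned as an empty ClusterSet, not an error.
    """
    if not 0 < percentile < 100:
        raise ValueError("percentile must be in (0, 100)")
    if min_area_mm2 < 0:
        raise ValueError("min_area_mm2 must be >= 0")
    if disp.total.shape[0] != mesh.n_vertices:
        raise ValueError("dispersion map and mesh vertex counts differ")

    threshold = float(np.percentile(disp.total, percentile))
    above = np.flatnonzero(disp.total > threshold)
    labels = np.zeros(mesh.n_vertices, dtype=int)
    if above.size == 0:
        return ClusterSet(labels=labels, clusters=[], threshold_value=threshold)

    sub = mesh.adjacency[above][:, above]
    n_comp, comp = connected_components(sub, directed=False)
    candidates = []
    for c in range(n_comp):
        verts = above[comp == c]
        area = float(mesh.vertex_area[verts].sum())
        if area >= min_area_mm2:
            candidates.append((area, verts))
    # descending area; ties broken by smallest vertex index for determinism
    candidates.sort(key=lambda t: (-t[0], int(t[1][0])))
    clusters = []
    for cid, (area, verts) in enumerate(candidates, start=1):
        labels[verts] = cid
        clusters.append(Cluster(id=cid, vertices=verts, area_mm2=area))
    return ClusterSet(labels=labels, clusters=clusters, threshold_value=threshold)


def cluster_coordinates(
    embeddings: list[SubjectEmbedding], clusters: ClusterSet
) -> pd.DataFrame:
    """Per-subject mean gradient coordinates within each cluster.

    Returns a DataFrame indexed by subject id with one column per
    (cluster, axis) pair, named ``c<id>_g<axis>``.
    """
    if not clusters.clusters:
        raise ValueError("cluster set is empty")
    data = {}
    for cl in clusters.clusters:
        if cl.vertices.size == 0:
            raise ValueError(f"cluster {cl.id} has no vertices")
        for j in range(embeddings[0].coords.shape[1]):
            col = f"c{cl.id}_g{j + 1}"
            data[col] = [e.coords[cl.vertices, j].mean() for e in embeddings]
    frame = pd.DataFrame(data, index=[e.subject_id for e in embeddings])
    frame.index.name = "subject_id"
    if not np.isfinite(frame.to_numpy()).all():
        raise ValueError("cluster coordinates contain non-finite values")
    return frame
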