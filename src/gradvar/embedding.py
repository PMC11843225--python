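"""Two-step group embedding of multi-subject cortical time series.

The construction generalizes PCA across subjects (a generalized canonical
correlation scheme): each subject's normalized, concatenated vertex x time
matrix is reduced to its leading principal components, the per-subject
component matrices are concatenated column-wise and decomposed again with
an SVD, and the leading left singular vectors of that group decomposition
are the shared *functional gradients*. Each subject is then projected onto
the group gradients within their own component subspace, giving per-subject
vertex coordinates in a common K-dimensional gradient space.

Because the two-step scheme has no single explained-variance number, two
profiles are reported: the mean per-component fraction of subject-level
variance, and that fraction weighted by the cumulative group-level
explained-variance fraction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .cohort import SurfaceTimeSeries

__all__ = [
    "SubjectComponents",
    "GroupEmbedding",
    "SubjectEmbedding",
    "VarianceProfile",
    "normalize_concatenate",
    "subject_decomposition",
    "choose_rank",
    "group_decomposition",
    "project_subject",
    "align_signs",
    "variance_profile",
    "embed_cohort",
]


@dataclass
class SubjectComponents:
    """Leading principal components of one subject's time series.

    ``scores`` holds the r most informative spatial components as
    orthonormal columns (vertex x r); ``singular_values`` the matching
    nonincreasing singular values; ``variance_fractions`` the fraction of
    the subject's total variance carried by each component
    (sigma_i^2 / sum_j sigma_j^2 over *all* singular values).
    """

    subject_id: str
    scores: np.ndarray
    singular_values: np.ndarray
    variance_fractions: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.singular_values) > 1e-12):
            raise ValueError("singular values must be nonincreasing")
        if np.any(self.singular_values < 0):
            raise ValueError("singular values must be nonnegative")
        if self.variance_fractions.sum() > 1 + 1e-8:
            raise ValueError("variance fractions must sum to <= 1")

    @property
    def r(self) -> int:
        return self.scores.shape[1]


@dataclass
class GroupEmbedding:
    """Shared gradient space from the group-level SVD.

    ``gradients`` (vertex x K) are ordered by nonincreasing group singular
    value; ``all_singular_values`` keeps the full spectrum so cumulative
    explained-variance fractions can be formed.
    """

    gradients: np.ndarray
    group_singular_values: np.ndarray
    k: int
    all_singular_values: np.ndarray = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.gradients.shape[1] != self.k:
            raise ValueError("gradients must have k columns")
        if np.any(np.diff(self.group_singular_values) > 1e-12):
            raise ValueError("group singular values must be nonincreasing")
        if self.all_singular_values is None:
            self.all_singular_values = self.group_singular_values


@dataclass
class SubjectEmbedding:
    """One subject's coordinates in the common gradient space."""

    subject_id: str
    coords: np.ndarray  # vertex x K
    sign_flips: np.ndarray | None = None  # length K in {-1, +1}
    degenerate_axes: np.ndarray | None = None  # zero-variance columns


@dataclass
class VarianceProfile:
    """Per-component explained-variance metrics (mean over subjects)."""

    individual_fraction: np.ndarray
    weighted_fraction: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.weighted_fraction > self.individual_fraction + 1e-12):
            raise ValueError("weighted fraction cannot exceed individual fraction")


# ---------------------------------------------------------------------------

def normalize_concatenate(ts: SurfaceTimeSeries) -> SurfaceTimeSeries:
    """Z-score every vertex's series within each run, then concatenate runs.

    Constant series become all-zeros (rather than dropping the vertex), so
    vertex indexing stays aligned across subjects.
    """
    blocks = []
    for block in ts.runs():
        mean = block.mean(axis=1, keepdims=True)
        sd = block.std(axis=1, ddof=1, keepdims=True)
        out = np.zeros_like(block, dtype=float)
        ok = sd[:, 0] > 0
        out[ok] = (block[ok] - mean[ok]) / sd[ok]
        blocks.append(out)
    return SurfaceTimeSeries(
        subject_id=ts.subject_id,
        data=np.concatenate(blocks, axis=1),
        run_boundaries=list(ts.run_boundaries),
    )


def subject_decomposition(ts: SurfaceTimeSeries, r: int) -> SubjectComponents:
    """Top-r singular triplets of the (normalized) vertex x time matrix."""
    n_v, n_t = ts.data.shape
    if not 1 <= r <= min(n_v, n_t):
        raise ValueError(f"r={r} exceeds the rank bound min(vertices, timepoints)")
    u, s, _ = np.linalg.svd(ts.data, full_matrices=False)
    total = float((s**2).sum())
    if total == 0:
        raise ValueError("all-zero time series cannot be decomposed")
    return SubjectComponents(
        subject_id=ts.subject_id,
        scores=u[:, :r],
        singular_values=s[:r],
        variance_fractions=(s[:r] ** 2) / total,
    )


def choose_rank(
    ts: SurfaceTimeSeries, target_variance: float = 0.5, max_rank: int = 20
) -> int:
    """Smallest component count reaching ``target_variance`` of the
    subject's total variance, capped at ``max_rank``."""
    s = np.linalg.svd(ts.data, compute_uv=False)
    frac = np.cumsum(s**2) / (s**2).sum()
    r = int(np.searchsorted(frac, target_variance) + 1)
    return min(r, max_rank, len(s))


def group_decomposition(
    components: list[SubjectComponents],
    k: int,
    template: np.ndarray | None = None,
) -> GroupEmbedding:
    """SVD of the column-wise concatenation of subject component matrices.

    Each subject's scores enter weighted by their singular values and
    normalized to unit total (Frobenius) energy, so every subject
    contributes equally while the within-subject variance ordering of the
    components is preserved. The top-k left singular vectors, ordered by
    group singular value, are the group gradients.

    Sign convention: if a per-column ``template`` (vertex x k) is given,
    each gradient is flipped to correlate positively with it; otherwise the
    element of largest magnitude is made positive.
    """
    if not components:
        raise ValueError("need at least one subject")
    n_v = components[0].scores.shape[0]
    if any(c.scores.shape[0] != n_v for c in components):
        raise ValueError("all subjects must share the vertex count")
    if k > sum(c.r for c in components):
        raise ValueError("k exceeds the concatenated component count")

    blocks = []
    for c in components:
        w = c.scores * c.singular_values
        norm = np.linalg.norm(c.singular_values)
        if norm == 0:
            raise ValueError(f"subject {c.subject_id} has all-zero components")
        blocks.append(w / norm)
    concat = np.concatenate(blocks, axis=1)
    u, s, _ = np.linalg.svd(concat, full_matrices=False)
    gradients = u[:, :k].copy()

    for j in range(k):
        col = gradients[:, j]
        if template is not None and j < template.shape[1]:
            ref = template[:, j]
            flip = np.dot(col - col.mean(), ref - ref.mean()) < 0
        else:
            flip = col[np.argmax(np.abs(col))] < 0
        if flip:
            gradients[:, j] = -col
    return GroupEmbedding(
        gradients=gradients,
        group_singular_values=s[:k],
        k=k,
        all_singular_values=s,
    )


def project_subject(
    comp: SubjectComponents, group: GroupEmbedding
) -> SubjectEmbedding:
    """Least-squares representation of the group gradients within the
    subject's component subspace (coords = scores @ scores+ @ gradients),
    followed by sign alignment to the group gradients."""
    scores = comp.scores
    if scores.shape[0] != group.gradients.shape[0]:
        raise ValueError("vertex counts of subject and group differ")
    sv = np.linalg.svd(scores, compute_uv=False)
    if sv[-1] < 1e-10 * sv[0]:
        raise ValueError(f"subject {comp.subject_id} scores are rank deficient")
    coef, *_ = np.linalg.lstsq(scores, group.gradients, rcond=None)
    coords = scores @ coef
    emb = SubjectEmbedding(subject_id=comp.subject_id, coords=coords)
    return align_signs(emb, group)


def align_signs(emb: SubjectEmbedding, group: GroupEmbedding) -> SubjectEmbedding:
    """Flip each coords column whose correlation with the matching group
    gradient is negative; zero-variance columns are flagged and kept at +1."""
    coords = emb.coords
    if coords.shape != group.gradients.shape:
        raise ValueError("embedding and group gradient shapes differ")
    k = coords.shape[1]
    flips = np.ones(k, dtype=int)
    degenerate = np.zeros(k, dtype=bool)
    out = coords.copy()
    g_c = group.gradients - group.gradients.mean(axis=0)
    for j in range(k):
        col = coords[:, j]
        col_c = col - col.mean()
        denom = np.linalg.norm(col_c) * np.linalg.norm(g_c[:, j])
        if denom == 0:
            degenerate[j] = True
            warnings.warn(
                f"axis {j} of subject {emb.subject_id} has zero variance; "
                "sign left at +1",
                RuntimeWarning,
                stacklevel=2,
            )
            continue
        if np.dot(col_c, g_c[:, j]) / denom < 0:
            flips[j] = -1
            out[:, j] = -col
    return SubjectEmbedding(
        subject_id=emb.subject_id,
        coords=out,
        sign_flips=flips,
        degenerate_axes=degenerate,
    )


def variance_profile(
    components: list[SubjectComponents], group: GroupEmbedding
) -> VarianceProfile:
    """Mean subject-level variance fractions and their weighting by the
    cumulative group-level explained-variance fraction."""
    if not components:
        raise ValueError("need at least one subject")
    r = min(c.r for c in components)
    individual = np.mean([c.variance_fractions[:r] for c in components], axis=0)
    s2 = group.all_singular_values**2
    cum = np.cumsum(s2) / s2.sum()
    n = min(r, cum.size)
    weighted = individual[:n] * cum[:n]
    return VarianceProfile(
        individual_fraction=individual[:n], weighted_fraction=weighted
    )


def embed_cohort(
    subjects: list[SurfaceTimeSeries],
    k: int = 3,
    rank: int | str = "auto",
    target_variance: float = 0.5,
    max_rank: int = 20,
    template: np.ndarray | None = None,
):
    """Full embedding pass over a cohort.

    Normalizes and decomposes every subject, runs the group decomposition,
    and projects every subject into the common space.

    Returns ``(group, embeddings, components, profile)``.
    """
    components = []
    for ts in subjects:
        norm = normalize_concatenate(ts)
        r = choose_rank(norm, target_variance, max_rank) if rank == "auto" else int(rank)
        r = max(r, k)
        components.append(subject_decomposition(norm, r))
    group = group_decomposition(components, k, template=template)
    embeddings = [project_subject(c, group) for c in components]
    profile = variance_profile(components, group)
    return group, embeddings, components, profile
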