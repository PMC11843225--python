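import numpy as np
import pytest

from gradvar.cohort import SurfaceTimeSeries
from gradvar.embedding import (
    GroupEmbedding,
    SubjectEmbedding,
    align_signs,
    embed_cohort,
    group_decomposition,
    normalize_concatenate,
    project_subject,
    subject_decomposition,
    variance_profile,
)


def _ts(data, runs=None, sid="s0"):
    data = np.asarray(data, dtype=float)
    if runs is None:
        runs = [(0, data.shape[1])]
    return SurfaceTimeSeries(subject_id=sid, data=data, run_boundaries=runs)


# ---------------------------------------------------------------------------
# normalize_concatenate

def test_normalize_zscores_each_vertex():
    out = normalize_concatenate(_ts([[1.0, 2.0, 3.0]]))
    assert out.data.mean() == pytest.approx(0.0)
    assert out.data.std(ddof=1) == pytest.approx(1.0)


def test_normalize_constant_run_maps_to_zeros():
    out = normalize_concatenate(_ts([[5.0, 5.0, 5.0, 5.0]]))
    np.testing.assert_array_equal(out.data, np.zeros((1, 4)))


def test_normalize_concatenates_runs_with_per_run_means():
    data = np.arange(14, dtype=float).reshape(2, 7)
    out = normalize_concatenate(_ts(data, runs=[(0, 3), (3, 7)]))
    assert out.data.shape == (2, 7)
    assert out.data[:, :3].mean(axis=1) == pytest.approx([0.0, 0.0])
    assert out.data[:, 3:].mean(axis=1) == pytest.approx([0.0, 0.0])


# ---------------------------------------------------------------------------
# subject_decomposition

def test_rank_one_matrix_single_component_carries_all_variance(rng):
    u = rng.standard_normal((10, 1))
    v = rng.standard_normal((1, 20))
    comp = subject_decomposition(_ts(u @ v), r=1)
    assert comp.variance_fractions == pytest.approx([1.0])


def test_variance_fractions_nonincreasing(rng):
    comp = subject_decomposition(_ts(rng.standard_normal((15, 25))), r=10)
    assert np.all(np.diff(comp.variance_fractions) <= 1e-12)


def test_top_singular_values_match_eigendecomposition_oracle(rng):
    """Independent oracle: eigenvalues of the Gram matrix."""
    data = rng.standard_normal((30, 50))
    comp = subject_decomposition(_ts(data), r=5)
    eigvals = np.linalg.eigvalsh(data @ data.T)[::-1]
    np.testing.assert_allclose(comp.singular_values**2, eigvals[:5], atol=1e-8)


def test_rejects_r_beyond_rank_bound(rng):
    with pytest.raises(ValueError):
        subject_decomposition(_ts(rng.standard_normal((5, 9))), r=6)


# ---------------------------------------------------------------------------
# group_decomposition

def test_identical_subjects_group_spans_subject_subspace(rng):
    u = np.linalg.qr(rng.standard_normal((40, 3)))[0]
    data = u @ np.diag([5.0, 3.0, 2.0]) @ rng.standard_normal((3, 60))
    comps = [subject_decomposition(_ts(data, sid=f"s{i}"), r=3) for i in range(4)]
    group = group_decomposition(comps, k=3)
    # principal angles between group gradients and the subject subspace ~ 0
    sv = np.linalg.svd(u.T @ group.gradients, compute_uv=False)
    np.testing.assert_allclose(sv, 1.0, atol=1e-8)


def test_group_embedding_shape_and_ordering(rng):
    comps = [
        subject_decomposition(_ts(rng.standard_normal((20, 30)), sid=f"s{i}"), r=4)
        for i in range(5)
    ]
    group = group_decomposition(comps, k=3)
    assert group.gradients.shape == (20, 3)
    assert np.all(np.diff(group.group_singular_values) <= 1e-12)


def test_group_rejects_mismatched_vertex_counts(rng):
    a = subject_decomposition(_ts(rng.standard_normal((20, 30)), sid="a"), r=2)
    b = subject_decomposition(_ts(rng.standard_normal((21, 30)), sid="b"), r=2)
    with pytest.raises(ValueError):
        group_decomposition([a, b], k=2)


def test_group_gradient_columns_pairwise_orthogonal(rng):
    comps = [
        subject_decomposition(_ts(rng.standard_normal((25, 40)), sid=f"s{i}"), r=5)
        for i in range(6)
    ]
    g = group_decomposition(comps, k=3).gradients
    off = g.T @ g - np.diag(np.diag(g.T @ g))
    assert np.abs(off).max() < 1e-8


def test_subject_permutation_leaves_group_unchanged_up_to_sign(rng):
    comps = [
        subject_decomposition(_ts(rng.standard_normal((25, 40)), sid=f"s{i}"), r=4)
        for i in range(6)
    ]
    g1 = group_decomposition(comps, k=3).gradients
    g2 = group_decomposition(comps[::-1], k=3).gradients
    for j in range(3):
        c = abs(np.dot(g1[:, j], g2[:, j]))
        assert c == pytest.approx(1.0, abs=1e-8)


def test_scaling_one_subject_changes_nothing(rng):
    datas = [rng.standard_normal((25, 40)) for _ in range(5)]
    comps = [subject_decomposition(_ts(d, sid=f"s{i}"), r=4) for i, d in enumerate(datas)]
    datas_scaled = [d.copy() for d in datas]
    datas_scaled[2] *= 7.5
    comps_scaled = [
        subject_decomposition(_ts(d, sid=f"s{i}"), r=4) for i, d in enumerate(datas_scaled)
    ]
    np.testing.assert_allclose(
        np.abs(comps[2].scores), np.abs(comps_scaled[2].scores), atol=1e-10
    )
    g1 = group_decomposition(comps, k=3).gradients
    g2 = group_decomposition(comps_scaled, k=3).gradients
    np.testing.assert_allclose(np.abs(g1), np.abs(g2), atol=1e-8)


# ---------------------------------------------------------------------------
# project_subject / align_signs

def test_self_projection_reproduces_group_gradients(rng):
    q = np.linalg.qr(rng.standard_normal((30, 3)))[0]
    group = GroupEmbedding(
        gradients=q, group_singular_values=np.array([3.0, 2.0, 1.0]), k=3
    )
    comp = subject_decomposition(_ts(q @ np.diag([3, 2, 1]) @ rng.standard_normal((3, 40))), r=3)
    emb = project_subject(comp, group)
    for j in range(3):
        c = np.corrcoef(emb.coords[:, j], q[:, j])[0, 1]
        assert c == pytest.approx(1.0, abs=1e-8)


def test_projection_of_orthogonal_gradient_is_zero(rng):
    q = np.linalg.qr(rng.standard_normal((30, 4)))[0]
    group = GroupEmbedding(
        gradients=q[:, 2:4], group_singular_values=np.array([2.0, 1.0]), k=2
    )
    comp = subject_decomposition(
        _ts(q[:, 0:2] @ np.diag([2, 1]) @ rng.standard_normal((2, 40))), r=2
    )
    emb = project_subject(comp, group)
    np.testing.assert_allclose(emb.coords, 0.0, atol=1e-8)


def test_projection_matches_normal_equations_oracle(rng):
    scores = np.linalg.qr(rng.standard_normal((30, 5)))[0]
    grads = np.linalg.qr(rng.standard_normal((30, 3)))[0]
    group = GroupEmbedding(
        gradients=grads, group_singular_values=np.array([3.0, 2.0, 1.0]), k=3
    )
    from gradvar.embedding import SubjectComponents

    comp = SubjectComponents(
        subject_id="s",
        scores=scores,
        singular_values=np.linspace(5, 1, 5),
        variance_fractions=np.full(5, 0.1),
    )
    emb = project_subject(comp, group)
    # brute-force normal equations per gradient column
    for j in range(3):
        coef = np.linalg.solve(scores.T @ scores, scores.T @ grads[:, j])
        expect = scores @ coef
        flip = emb.sign_flips[j]
        np.testing.assert_allclose(emb.coords[:, j], flip * expect, atol=1e-8)


def test_align_signs_flips_negated_and_keeps_matching(rng):
    g = np.linalg.qr(rng.standard_normal((20, 2)))[0]
    group = GroupEmbedding(gradients=g, group_singular_values=np.array([2.0, 1.0]), k=2)
    coords = np.column_stack([-g[:, 0], g[:, 1]])
    out = align_signs(SubjectEmbedding("s", coords), group)
    assert out.sign_flips.tolist() == [-1, 1]
    assert np.corrcoef(out.coords[:, 0], g[:, 0])[0, 1] == pytest.approx(1.0)


def test_align_signs_flags_zero_variance_column(rng):
    g = np.linalg.qr(rng.standard_normal((20, 2)))[0]
    group = GroupEmbedding(gradients=g, group_singular_values=np.array([2.0, 1.0]), k=2)
    coords = np.column_stack([np.zeros(20), g[:, 1]])
    with pytest.warns(RuntimeWarning):
        out = align_signs(SubjectEmbedding("s", coords), group)
    assert out.sign_flips[0] == 1
    assert out.degenerate_axes[0]


# ---------------------------------------------------------------------------
# variance_profile

def test_single_rank_one_subject_full_variance(rng):
    u = rng.standard_normal((10, 1))
    comp = subject_decomposition(_ts(u @ rng.standard_normal((1, 15))), r=1)
    group = group_decomposition([comp], k=1)
    prof = variance_profile([comp], group)
    assert prof.individual_fraction == pytest.approx([1.0])
    assert prof.weighted_fraction == pytest.approx([1.0])


def test_individual_fraction_is_subject_mean():
    from gradvar.embedding import SubjectComponents

    def comp(vf):
        return SubjectComponents(
            subject_id="x",
            scores=np.eye(4)[:, :2],
            singular_values=np.sqrt(np.asarray(vf)),
            variance_fractions=np.asarray(vf),
        )

    group = GroupEmbedding(
        gradients=np.eye(4)[:, :2],
        group_singular_values=np.array([1.0, 1.0]),
        k=2,
        all_singular_values=np.array([1.0, 1.0]),
    )
    prof = variance_profile([comp([0.6, 0.4]), comp([0.8, 0.2])], group)
    assert prof.individual_fraction == pytest.approx([0.7, 0.3])


def test_weighted_never_exceeds_individual(rng):
    comps = [
        subject_decomposition(_ts(rng.standard_normal((20, 30)), sid=f"s{i}"), r=5)
        for i in range(4)
    ]
    group = group_decomposition(comps, k=3)
    prof = variance_profile(comps, group)
    assert np.all(prof.weighted_fraction <= prof.individual_fraction + 1e-12)


# ---------------------------------------------------------------------------
# end-to-end invariant

def test_noise_free_cohort_subject_embeddings_fully_correlated(mesh_small):
    """With no noise, every pair of projected subjects shares the same
    k-dimensional subspace: all canonical correlations equal 1."""
    from gradvar.cohort import CohortConfig, simulate_cohort

    cfg = CohortConfig(
        n_subjects=5,
        runs=(30, 30),
        noise_sd=0.0,
        dispersion_profile=np.zeros(mesh_small.n_vertices),
        behavior_effect=0.0,
        seed=3,
    )
    subjects, _, _ = simulate_cohort(mesh_small, cfg)
    _, embeddings, _, _ = embed_cohort(subjects, k=3, rank=3)
    for a in embeddings[1:]:
        qa = np.linalg.qr(embeddings[0].coords)[0]
        qb = np.linalg.qr(a.coords)[0]
        canon = np.linalg.svd(qa.T @ qb, compute_uv=False)
        np.testing.assert_allclose(canon, 1.0, atol=1e-6)
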