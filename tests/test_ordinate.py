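import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp
from scipy.spatial.distance import pdist, squareform

from domchar.ordinate import bray_curtis, bray_curtis_matrix, envfit, envfit_table, pcoa

nonneg_vectors = hnp.arrays(
    dtype=float,
    shape=st.integers(2, 20),
    elements=st.floats(0, 1e3, allow_nan=False, allow_infinity=False),
)


# --------------------------------------------------------------- Bray-Curtis


@pytest.mark.parametrize(
    "x, y, expected",
    [
        ([1, 2, 3], [1, 2, 3], 0.0),
        ([1, 1, 0], [0, 0, 2], 1.0),       # disjoint supports
        ([1, 1, 0], [0, 1, 1], 0.5),       # (1+0+1)/(1+2+1)
    ],
)
def test_bray_curtis_examples(x, y, expected):
    assert bray_curtis(np.array(x, float), np.array(y, float)) == pytest.approx(expected)


def test_bray_curtis_rejects_degenerate_input():
    with pytest.raises(ValueError):
        bray_curtis(np.zeros(3), np.zeros(3))
    with pytest.raises(ValueError):
        bray_curtis(np.array([-1.0, 1.0]), np.array([1.0, 1.0]))


@given(nonneg_vectors.flatmap(
    lambda x: st.tuples(st.just(x), hnp.arrays(float, x.shape,
        elements=st.floats(0, 1e3, allow_nan=False, allow_infinity=False)))
))
@settings(max_examples=200, derandomize=True)
def test_bray_curtis_symmetry_identity_bounds(xy):
    x, y = xy
    if x.sum() == 0 or y.sum() == 0:
        return
    d = bray_curtis(x, y)
    assert 0.0 <= d <= 1.0
    assert d == pytest.approx(bray_curtis(y, x))
    assert bray_curtis(x, x) == 0.0


def test_bray_curtis_matrix_agrees_with_scipy(rng):
    table = pd.DataFrame(rng.uniform(0, 1, (30, 5)), columns=list("abcde"))
    ours = bray_curtis_matrix(table).to_numpy()
    ref = squareform(pdist(table.to_numpy().T, metric="braycurtis"))
    np.testing.assert_allclose(ours, ref, atol=1e-12)


# ----------------------------------------------------------------------- PCoA


def test_pcoa_equidistant_triplet_has_two_equal_eigenvalues():
    d = np.full((3, 3), 0.8)
    np.fill_diagonal(d, 0.0)
    res = pcoa(d)
    pos = res.eigenvalues[res.eigenvalues > 1e-10]
    assert len(pos) == 2
    assert pos[0] == pytest.approx(pos[1])
    assert res.proportion_explained == pytest.approx([0.5, 0.5])


def test_pcoa_recovers_points_on_a_line():
    x = np.array([0.0, 1.0, 3.0, 7.0])
    d = np.abs(x[:, None] - x[None, :])
    res = pcoa(d)
    assert res.proportion_explained[0] == pytest.approx(1.0, abs=1e-10)
    recovered = res.scores.iloc[:, 0].to_numpy()
    gaps = np.abs(np.diff(np.sort(recovered)))
    np.testing.assert_allclose(gaps, [1.0, 2.0, 4.0], atol=1e-10)


def test_pcoa_preserves_euclidean_distances(rng):
    pts = rng.normal(size=(4, 3))
    d = squareform(pdist(pts))
    res = pcoa(d)
    rec = squareform(pdist(res.scores.to_numpy()))
    np.testing.assert_allclose(rec, d, atol=1e-8)


def test_pcoa_matches_pca_on_euclidean_distances(rng):
    """Classical scaling of Euclidean distances equals PCA scores up to sign."""
    pts = rng.normal(size=(8, 3))
    d = squareform(pdist(pts))
    res = pcoa(d)
    centered = pts - pts.mean(axis=0)
    u, sv, _ = np.linalg.svd(centered, full_matrices=False)
    pca_scores = u * sv
    ours = res.scores.to_numpy()[:, :3]
    assert ours.shape == pca_scores.shape
    np.testing.assert_allclose(np.abs(sv**2), np.abs(res.eigenvalues[:3]), rtol=1e-8)
    for k in range(3):
        match = min(
            np.abs(ours[:, k] - pca_scores[:, k]).max(),
            np.abs(ours[:, k] + pca_scores[:, k]).max(),
        )
        assert match < 1e-8


def test_pcoa_matches_scikit_bio_oracle(rng):
    skbio_pcoa = pytest.importorskip("skbio.stats.ordination").pcoa
    table = pd.DataFrame(rng.uniform(0, 1, (40, 6)))
    d = bray_curtis_matrix(table).to_numpy()
    ours = pcoa(d)
    ref = skbio_pcoa(d)
    np.testing.assert_allclose(
        np.sort(ours.eigenvalues)[::-1][:5],
        np.sort(ref.eigvals.to_numpy())[::-1][:5],
        atol=1e-10,
    )
    k = ours.n_axes
    np.testing.assert_allclose(
        np.abs(ours.scores.to_numpy()),
        np.abs(ref.samples.to_numpy()[:, :k]),
        atol=1e-8,
    )


def test_pcoa_rejects_asymmetric_matrix():
    with pytest.raises(ValueError):
        pcoa(np.array([[0.0, 1.0], [0.5, 0.0]]))


# --------------------------------------------------------------------- envfit


def _toy_ordination(rng, n=12):
    pts = rng.normal(size=(n, 3))
    return pcoa(squareform(pdist(pts)))


def test_envfit_perfect_fit_along_first_axis(rng):
    res = _toy_ordination(rng)
    y = res.scores["PC1"]
    fit = envfit(res, y, n_perm=999, rng=0)
    assert fit.r2 == pytest.approx(1.0, abs=1e-10)
    assert abs(fit.direction[0]) == pytest.approx(1.0, abs=1e-8)
    assert fit.direction[1] == pytest.approx(0.0, abs=1e-8)
    assert fit.p_value == pytest.approx(1.0 / 1000.0)


def test_envfit_power_on_noisy_axis_descriptor(rng):
    res = _toy_ordination(rng)
    y = res.scores["PC1"] + rng.normal(0, 0.05 * res.scores["PC1"].std(), 12)
    fit = envfit(res, y, n_perm=10_000, rng=1)
    assert fit.p_value <= 0.01


def test_envfit_p_invariant_to_affine_descriptor_transform(rng):
    res = _toy_ordination(rng)
    y = rng.normal(size=12)
    f1 = envfit(res, y, n_perm=2000, rng=7)
    f2 = envfit(res, 5.0 * y - 3.0, n_perm=2000, rng=7)
    assert f1.p_value == f2.p_value
    assert f1.r2 == pytest.approx(f2.r2, abs=1e-12)


def test_envfit_deterministic_under_fixed_seed(rng):
    res = _toy_ordination(rng)
    y = rng.normal(size=12)
    p1 = envfit(res, y, n_perm=2000, rng=42).p_value
    p2 = envfit(res, y, n_perm=2000, rng=42).p_value
    assert p1 == p2


def test_envfit_constant_descriptor_flagged(rng):
    res = _toy_ordination(rng)
    fit = envfit(res, np.full(12, 3.0), n_perm=99, rng=0)
    assert fit.degenerate
    assert not fit.significant
    assert np.isnan(fit.r2)


def test_envfit_table_runs_all_descriptors(rng):
    res = _toy_ordination(rng)
    desc = pd.DataFrame(
        {"a": res.scores["PC1"], "b": rng.normal(size=12)}, index=res.scores.index
    )
    out = envfit_table(res, desc, n_perm=499, alpha=0.1, seed=3)
    assert list(out.index) == ["a", "b"]
    assert out.loc["a", "r2"] == pytest.approx(1.0, abs=1e-10)
    assert {"dx", "dy", "p", "significant"} <= set(out.columns)
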