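import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.distance import braycurtis, pdist, squareform

from betashift.dissimilarity import (
    abc,
    decompose_matrix,
    decompose_pair,
    gower_center,
    pcoa,
    percentage_difference,
    sqrt_embed,
)
from tests.conftest import random_table

vectors = st.lists(st.floats(0, 50, allow_nan=False), min_size=1, max_size=12)


@pytest.mark.parametrize(
    "y1, y2, expected",
    [
        ([4, 1, 0], [1, 1, 3], (2, 3, 3)),
        ([2, 2], [2, 2], (4, 0, 0)),
        ([5, 2], [0, 0], (0, 7, 0)),
    ],
)
def test_abc_min_sums(y1, y2, expected):
    comp = abc(y1, y2)
    assert (comp.A, comp.B, comp.C) == expected


@pytest.mark.parametrize(
    "y1, y2, d, repl, diff",
    [
        ([4, 1, 0], [1, 1, 3], 0.6, 0.6, 0.0),
        ([2, 0], [0, 1], 1.0, 2 / 3, 1 / 3),
        ([5, 2], [0, 0], 1.0, 0.0, 1.0),
        ([3, 3], [3, 3], 0.0, 0.0, 0.0),
        ([0, 0], [0, 0], 0.0, 0.0, 0.0),  # both-empty convention
    ],
)
def test_pairwise_decomposition_worked_examples(y1, y2, d, repl, diff):
    assert percentage_difference(y1, y2) == pytest.approx(d, abs=1e-15)
    r, f = decompose_pair(y1, y2)
    assert (r, f) == (pytest.approx(repl, abs=1e-15), pytest.approx(diff, abs=1e-15))


def test_length_mismatch_rejected():
    with pytest.raises(ValueError, match="length"):
        abc([1, 2], [1, 2, 3])


@settings(max_examples=200, deadline=None, derandomize=True)
@given(vectors, st.data())
def test_additivity_and_oracle_equivalence(y1, data):
    """repl + diff == d exactly, and d matches Σ|y1−y2|/Σ(y1+y2)."""
    y2 = data.draw(st.lists(st.floats(0, 50), min_size=len(y1), max_size=len(y1)))
    d = percentage_difference(y1, y2)
    repl, diff = decompose_pair(y1, y2)
    assert abs(repl + diff - d) <= 1e-12
    a1, a2 = np.asarray(y1), np.asarray(y2)
    if (a1 + a2).sum() > 0:
        assert d == pytest.approx(np.abs(a1 - a2).sum() / (a1 + a2).sum(), abs=1e-12)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_scale_and_species_permutation_invariance(seed):
    rng = np.random.default_rng(seed)
    y1, y2 = rng.gamma(1, 2, 8), rng.gamma(1, 2, 8)
    k = rng.uniform(0.1, 10)
    assert percentage_difference(k * y1, k * y2) == pytest.approx(
        percentage_difference(y1, y2), abs=1e-12
    )
    perm = rng.permutation(8)
    assert decompose_pair(y1[perm], y2[perm]) == pytest.approx(
        decompose_pair(y1, y2), abs=1e-12
    )


def test_matrix_decomposition_matches_pair_oracle(toy_table):
    dec = decompose_matrix(toy_table)
    iu = np.triu_indices(3, 1)
    np.testing.assert_allclose(dec.d_total[iu], [0.6, 1.0, 0.25], atol=1e-12)
    assert np.allclose(dec.d_total, dec.d_total.T)
    assert np.allclose(np.diag(dec.d_total), 0)
    np.testing.assert_allclose(dec.d_total, dec.d_repl + dec.d_diff, atol=1e-12)


def test_matrix_against_scipy_braycurtis():
    rng = np.random.default_rng(42)
    table = random_table(rng, 10, 6)
    dec = decompose_matrix(table)
    X = table.matrix()
    expected = squareform([braycurtis(X[i], X[j])
                           for i in range(10) for j in range(i + 1, 10)])
    np.testing.assert_allclose(dec.d_total, expected, atol=1e-12)


def test_sqrt_embedding_is_euclidean():
    """Gower-centered −½·(√d)² must be PSD up to −1e−8 for biomass tables."""
    rng = np.random.default_rng(7)
    for _ in range(20):
        table = random_table(rng, 15, 8)
        d = sqrt_embed(decompose_matrix(table).d_total)
        g = gower_center(-0.5 * d**2)
        assert np.linalg.eigvalsh(g).min() >= -1e-8


def test_pcoa_reconstructs_distances(toy_table):
    d = sqrt_embed(decompose_matrix(toy_table).d_total)
    res = pcoa(d)
    rec = squareform(pdist(res.coordinates))
    np.testing.assert_allclose(rec, d, atol=1e-10)
    # eigenvalue sum equals the trace of the centered matrix
    assert res.eigenvalues.sum() + res.negative_eigenvalues.sum() == pytest.approx(
        res.trace, abs=1e-10
    )


def test_pcoa_two_points():
    d = np.array([[0.0, np.sqrt(0.6)], [np.sqrt(0.6), 0.0]])
    res = pcoa(d)
    assert res.coordinates.shape[1] == 1
    assert abs(res.coordinates[0, 0] - res.coordinates[1, 0]) == pytest.approx(
        np.sqrt(0.6), abs=1e-12
    )


def test_pcoa_agrees_with_skbio(toy_table):
    skbio = pytest.importorskip("skbio")
    from skbio.stats.ordination import pcoa as sk_pcoa

    d = sqrt_embed(decompose_matrix(toy_table).d_total)
    ours = pcoa(d)
    theirs = sk_pcoa(skbio.DistanceMatrix(d, ids=list("abc")))
    np.testing.assert_allclose(
        np.sort(ours.eigenvalues)[::-1],
        np.sort(np.asarray(theirs.eigvals))[::-1][: len(ours.eigenvalues)],
        atol=1e-10,
    )


def test_pcoa_warns_on_non_euclidean_input(toy_table):
    raw = decompose_matrix(toy_table).d_total  # raw percentage difference
    with pytest.warns(UserWarning, match="not fully Euclidean"):
        pcoa(raw)
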