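import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

from betashift.dissimilarity import decompose_matrix, sqrt_embed
from betashift.spacetime import RDA, embed_for_tests, rda, two_way_crossed_anova


def _blocks(rng, n_per=5, p=4, shift=0.0):
    a = rng.normal(0, 1, (n_per, p))
    b = rng.normal(shift, 1, (n_per, p))
    return np.vstack([a, b]), np.array([0] * n_per + [1] * n_per)


def test_rda_perfect_separation():
    y = np.vstack([np.tile([1.0, 0.0], (4, 1)), np.tile([0.0, 2.0], (4, 1))])
    labels = [0] * 4 + [1] * 4
    res = rda(y, labels)
    assert res.r2 == pytest.approx(1.0)


def test_rda_matches_centroid_projection_oracle():
    rng = np.random.default_rng(0)
    y, labels = _blocks(rng, shift=1.0)
    res = rda(y, labels)
    yc = y - y.mean(axis=0)
    fitted = np.vstack(
        [np.tile(yc[labels == g].mean(axis=0), (sum(labels == g), 1)) for g in (0, 1)]
    )
    assert res.r2 == pytest.approx((fitted**2).sum() / (yc**2).sum(), abs=1e-12)


def test_rda_null_r2_prior_and_uniform_p():
    """Unrelated factor: E[R²] ≈ (k−1)/(n−1); p roughly uniform."""
    rng = np.random.default_rng(1)
    r2s, ps = [], []
    for i in range(100):
        y, labels = _blocks(rng, n_per=8, shift=0.0)
        res = rda(y, rng.permutation(labels), n_perm=49, seed=i)
        r2s.append(res.r2)
        ps.append(res.p)
    assert np.mean(r2s) == pytest.approx(1 / 15, abs=0.02)
    assert 0.3 <= np.mean(ps) <= 0.7
    assert (np.asarray(ps) <= 0.05).mean() <= 0.12


def test_species_score_signs_track_direction():
    rng = np.random.default_rng(2)
    n = 20
    labels = np.array([0] * n + [1] * n)
    up = np.concatenate([np.full(n, 1.0), np.full(n, 3.0)])
    down = np.concatenate([np.full(n, 5.0), np.full(n, 2.0)])
    noise = rng.normal(0, 0.1, (2 * n, 2))
    y = np.column_stack([up, down]) + noise
    res = rda(y, labels)
    assert res.species_scores[0] > 0 and res.species_scores[1] < 0
    assert res.species_share.sum() == pytest.approx(1.0, abs=1e-12)


def test_rda_errors():
    with pytest.raises(ValueError, match="constant"):
        rda(np.ones((6, 2)), [0, 0, 0, 1, 1, 1])
    with pytest.raises(ValueError, match="levels"):
        rda(np.random.default_rng(0).normal(size=(4, 2)), [0, 0, 0, 0])


def _crossed(rng, a=3, b=4, r=2, p=5, site_eff=0.0, time_eff=0.0, int_eff=0.0):
    site = np.repeat(np.arange(a), b * r)
    time = np.tile(np.repeat(np.arange(b), r), a)
    y = rng.normal(0, 1, (a * b * r, p))
    y += site_eff * rng.normal(0, 1, (a, p))[site]
    y += time_eff * rng.normal(0, 1, (b, p))[time]
    y += int_eff * rng.normal(0, 1, (a * b, p))[site * b + time]
    return y, site, time


def test_two_way_partition_is_orthogonal():
    rng = np.random.default_rng(3)
    y, site, time = _crossed(rng, site_eff=1.0, time_eff=0.5, int_eff=0.5)
    res = two_way_crossed_anova(y, site, time, n_perm=0)
    terms = res.terms.set_index("term")["SS"]
    yc = y - y.mean(axis=0)
    assert terms.sum() == pytest.approx((yc**2).sum(), abs=1e-10)


def test_two_way_detects_injected_interaction():
    rng = np.random.default_rng(4)
    y, site, time = _crossed(rng, int_eff=1.5)
    res = two_way_crossed_anova(y, site, time, n_perm=199, seed=0)
    assert res.p <= 0.005 * 199 / 199 + 1 / 200 + 1e-9  # permutation floor


def test_two_way_unbalanced_rejected():
    rng = np.random.default_rng(5)
    y, site, time = _crossed(rng)
    with pytest.raises(ValueError, match="unbalanced"):
        two_way_crossed_anova(y[:-1], site[:-1], time[:-1], n_perm=0)


def test_two_way_interaction_type_i_error():
    """No-effect null: interaction rejection rate at alpha=0.05 stays within
    the binomial envelope."""
    rng = np.random.default_rng(6)
    rejections = 0
    n_sims = 100
    for i in range(n_sims):
        y, site, time = _crossed(rng, p=3)
        res = two_way_crossed_anova(y, site, time, n_perm=99, seed=i)
        rejections += res.p <= 0.05
    rate = rejections / n_sims
    se = np.sqrt(0.05 * 0.95 / n_sims)
    assert rate <= 0.05 + 3 * se


def test_embedding_reproduces_sqrt_distances(toy_table):
    dec = decompose_matrix(toy_table)
    coords = embed_for_tests(dec)
    np.testing.assert_allclose(
        squareform(pdist(coords)), sqrt_embed(dec.d_total), atol=1e-10
    )


def test_rda_invariant_to_rotation_of_coordinates(toy_table):
    rng = np.random.default_rng(7)
    dec = decompose_matrix(toy_table)
    coords = embed_for_tests(dec)
    q, _ = np.linalg.qr(rng.normal(size=(coords.shape[1],) * 2))
    labels = [0, 0, 1]
    assert rda(coords @ q, labels).r2 == pytest.approx(rda(coords, labels).r2, abs=1e-10)


def test_estimator_params_roundtrip():
    est = RDA(n_perm=9, seed=3)
    assert RDA(**est.get_params()).get_params() == est.get_params()
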