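import numpy as np
import pandas as pd
import pytest

from betashift.mrt import MultivariateRegressionTree, chronological_split, mrt_fit
from betashift.spacetime import rda


def test_two_blocks_split_on_site():
    y = np.vstack([np.tile([1.0, 0.0], (6, 1)), np.tile([0.0, 1.0], (6, 1))])
    preds = pd.DataFrame({"site": ["A", "B", "C"] * 2 + ["D", "E", "F"] * 2})
    tree = mrt_fit(y, preds, max_leaves=2, n_perm=0)
    assert tree.n_leaves == 2
    assert tree.r2 == pytest.approx(1.0)
    left = tree.root.rule[1]
    assert left in (frozenset("ABC"), frozenset("DEF"))


def test_homogeneous_response_stays_single_leaf():
    rng = np.random.default_rng(0)
    single_leaf = 0
    for i in range(30):
        y = rng.normal(size=(24, 3))
        preds = pd.DataFrame({"time": np.repeat(np.arange(8.0), 3)})
        tree = mrt_fit(y, preds, max_leaves=4, alpha=0.05, n_perm=99, seed=i)
        single_leaf += tree.n_leaves == 1
    assert single_leaf >= 24  # ≥~90 % of null runs


def test_tree_on_time_equals_chronological_split():
    rng = np.random.default_rng(1)
    t = np.repeat(np.arange(6.0), 3)
    y = rng.normal(size=(18, 4)) + (t >= 3)[:, None] * 2.0
    tree = mrt_fit(y, pd.DataFrame({"time": t}), max_leaves=2, n_perm=0)
    cs = chronological_split(y, t, n_perm=0)
    assert tree.root.rule[1] == pytest.approx(cs.boundary)
    assert tree.r2 == pytest.approx(cs.r2, abs=1e-12)


def test_chronological_split_recovers_changepoint_and_r2_identity():
    rng = np.random.default_rng(2)
    t = np.repeat([2007.0, 2007.5, 2008.0, 2008.5, 2009.0, 2009.5], 3)
    hits = 0
    for _ in range(50):
        y = rng.normal(size=(18, 5)) + (t >= 2009.0)[:, None] * np.array([2, -2, 1, 0, 0])
        cs = chronological_split(y, t, n_perm=0)
        hits += cs.boundary == pytest.approx((2008.5 + 2009.0) / 2)
    assert hits >= 48  # ≥95 %
    # cross-module identity: split R² equals the RDA R² of the induced factor
    cs = chronological_split(y, t, n_perm=0)
    assert cs.r2 == pytest.approx(rda(y, cs.labels).r2, abs=1e-12)


def test_chronological_null_calibration():
    rng = np.random.default_rng(3)
    nonsig = 0
    for i in range(30):
        y = rng.normal(size=(20, 3))
        cs = chronological_split(y, np.repeat(np.arange(5.0), 4), n_perm=99, seed=i)
        nonsig += cs.p > 0.05
    assert nonsig >= 24  # ≥~90 %


def test_two_distinct_times_trivial_split():
    y = np.vstack([np.tile([1.0, 0.0], (3, 1)), np.tile([0.0, 1.0], (3, 1))])
    cs = chronological_split(y, [0.0] * 3 + [1.0] * 3, n_perm=0)
    assert cs.r2 == pytest.approx(1.0)
    np.testing.assert_array_equal(cs.labels, [0, 0, 0, 1, 1, 1])
    with pytest.raises(ValueError, match="distinct"):
        chronological_split(y, [1.0] * 6, n_perm=0)


def test_block_by_epoch_recovery_four_leaves():
    """NE/W site contrast plus within-block temporal shifts → 4 leaves that
    match the generating blocks."""
    rng = np.random.default_rng(4)
    sites = [f"S{i}" for i in range(6)]
    t = np.tile(np.repeat(np.arange(8.0), 2), 6)
    site = np.repeat(sites, 16)
    block = np.isin(site, sites[:4])  # 4 "NE" + 2 "W" sites
    epoch_ne = (t >= 4) & block
    epoch_w = (t >= 6) & ~block
    y = rng.normal(0, 0.3, (96, 6))
    y[block] += [3, 0, 0, 0, 0, 0]
    y[epoch_ne] += [0, 0, 2.5, 0, 0, 0]
    y[epoch_w] += [0, 0, 0, 2.5, 0, 0]
    tree = mrt_fit(y, pd.DataFrame({"site": site, "time": t}),
                   max_leaves=4, n_perm=99, seed=0)
    assert tree.n_leaves == 4
    truth = block.astype(int) * 2 + np.where(block, epoch_ne, epoch_w)
    # leaf labels must induce exactly the generating 4-group partition
    frame = pd.DataFrame({"leaf": tree.labels, "truth": truth})
    assert frame.groupby("leaf")["truth"].nunique().max() == 1
    assert frame.groupby("truth")["leaf"].nunique().max() == 1


def test_r2_path_monotone_and_children_ss_bounded():
    rng = np.random.default_rng(5)
    y = rng.normal(size=(40, 3)) + (np.arange(40) >= 20)[:, None]
    preds = pd.DataFrame({"time": np.repeat(np.arange(10.0), 4),
                          "site": np.tile(["A", "B"], 20)})
    tree = mrt_fit(y, preds, max_leaves=4, n_perm=0)
    assert all(b >= a - 1e-12 for a, b in zip(tree.r2_path, tree.r2_path[1:]))

    def check(node):
        if node.left is not None:
            assert node.left.ss + node.right.ss <= node.ss + 1e-9
            check(node.left)
            check(node.right)
    check(tree.root)


def test_estimator_api():
    est = MultivariateRegressionTree(max_leaves=2, n_perm=0)
    y = np.vstack([np.zeros((4, 2)), np.ones((4, 2))])
    est.fit(y, pd.DataFrame({"time": np.repeat([0.0, 1.0], 4)}))
    assert est.r2_ == pytest.approx(1.0)
    assert len(np.unique(est.labels_)) == 2
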