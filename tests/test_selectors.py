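"""Selector contracts: rank-sum oracle, lasso path, PSODT swarm, RF
importance, and the uniform dispatch front end."""

from itertools import permutations

import numpy as np
import pytest
from scipy import stats

from nbselect import LabeledCountMatrix, baseline_config, simulate_dataset
from nbselect import selectors as sel

GROUPS_20_20 = np.r_[np.ones(20, int), np.zeros(20, int)]


# ---------------------------------------------------------------------------
# rank-sum

def _permutation_rank_sum_p(case, ctrl):
    """Brute-force oracle: distribution of the case rank sum over all
    permutations of the pooled midranks."""
    pooled = np.concatenate([case, ctrl])
    ranks = stats.rankdata(pooled)
    n1 = len(case)
    mu = n1 * (len(pooled) + 1) / 2.0
    d_obs = abs(ranks[:n1].sum() - mu)
    hits = total = 0
    for perm in permutations(ranks):
        total += 1
        hits += abs(sum(perm[:n1]) - mu) >= d_obs - 1e-9
    return hits / total


@pytest.mark.parametrize("case,ctrl", [
    ([1, 2, 3], [4, 5, 6]),
    ([5, 5, 9], [2, 5, 7]),          # ties across and within groups
    ([10, 2, 8, 4], [3, 3, 7]),
    ([0, 0, 1, 1], [1, 2, 2]),       # heavy ties
    ([12, 7], [7, 7, 9, 1]),
])
def test_exact_rank_sum_matches_permutation_oracle(case, ctrl):
    ours = sel._exact_rank_sum_p(np.array(case, float), np.array(ctrl, float))
    oracle = _permutation_rank_sum_p(np.array(case, float), np.array(ctrl, float))
    assert ours == pytest.approx(oracle, abs=1e-10)


def test_exact_rank_sum_textbook_case():
    """{1,2,3} vs {4,5,6}: the two extreme arrangements out of C(6,3)=20."""
    counts = np.array([[4, 5, 6, 1, 2, 3]])
    groups = np.array([1, 1, 1, 0, 0, 0])
    res = sel.rank_sum_select(counts, groups)
    assert res.scores[0] == pytest.approx(0.1)


def test_rank_sum_full_separation_small_p(rng):
    case = rng.integers(100, 200, (1, 20))
    ctrl = rng.integers(0, 50, (1, 20))
    res = sel.rank_sum_select(np.hstack([case, ctrl]), GROUPS_20_20)
    assert res.scores[0] < 1e-7
    assert res.selected[0]


def test_rank_sum_constant_feature_p_one():
    counts = np.vstack([np.full(12, 7), np.arange(12)])
    groups = np.r_[np.ones(6, int), np.zeros(6, int)]
    res = sel.rank_sum_select(counts, groups)
    assert res.scores[0] == 1.0


def test_rank_sum_null_rejection_near_alpha():
    cfg = baseline_config(seed=31, mu_sig_case=5.0)
    rates = [
        (sel.rank_sum_select(simulate_dataset(cfg, rep).counts, GROUPS_20_20)
         .scores < 0.05).mean()
        for rep in range(10)
    ]
    assert 0.03 <= np.mean(rates) <= 0.07


def test_rank_sum_monotone_transform_invariance(baseline_data):
    counts = baseline_data.counts[:50]
    base = sel.rank_sum_select(counts, baseline_data.labels).scores
    squared = sel.rank_sum_select(counts.astype(float) ** 2, baseline_data.labels).scores
    logged = sel.rank_sum_select(np.log1p(counts), baseline_data.labels).scores
    assert np.allclose(base, squared, atol=1e-12)
    assert np.allclose(base, logged, atol=1e-12)


def test_rank_sum_bonferroni_rule(baseline_data):
    res = sel.rank_sum_select(baseline_data.counts, baseline_data.labels,
                              bonferroni=True)
    assert res.rule == "p<0.0001"
    assert np.array_equal(res.selected, res.scores < 0.05 / 500)


# ---------------------------------------------------------------------------
# lasso

def test_lasso_selects_signal_with_high_specificity(baseline_data):
    cfg = baseline_config(seed=32, mu_sig_case=30.0)
    d = simulate_dataset(cfg, 0)
    res = sel.lasso_select(d.counts, d.labels, rng=1)
    assert res.selected[d.truth].sum() >= 1
    assert (~res.selected[~d.truth]).mean() >= 0.95


def test_lasso_null_selects_few(null_data):
    res = sel.lasso_select(null_data.counts, null_data.labels, rng=2)
    assert res.selected.sum() <= 0.05 * null_data.n_features


def test_lasso_huge_penalty_empty_selection(baseline_data):
    with pytest.warns(UserWarning):
        res = sel.lasso_select(baseline_data.counts, baseline_data.labels,
                               rng=1, C=1e-8)
    assert res.selected.sum() == 0


@pytest.mark.filterwarnings("ignore:lasso path fully shrunk")
def test_lasso_penalty_path_nesting(baseline_data):
    """Along a decreasing-C (increasing penalty) path the selection count
    never grows."""
    sizes = [
        sel.lasso_select(baseline_data.counts, baseline_data.labels, rng=7, C=C)
        .selected.sum()
        for C in (10.0, 1.0, 0.1, 0.02, 0.001)
    ]
    assert all(a >= b for a, b in zip(sizes, sizes[1:]))


# ---------------------------------------------------------------------------
# PSODT

def _small_noise_data(rng, n_features=20):
    counts = rng.poisson(8.0, (n_features, 16))
    groups = np.r_[np.ones(8, int), np.zeros(8, int)]
    return counts, groups


def test_psodt_deterministic(rng):
    counts, groups = _small_noise_data(rng)
    a = sel.psodt_select(counts, groups, swarm_size=6, n_iters=4, rng=42, n_restarts=2)
    b = sel.psodt_select(counts, groups, swarm_size=6, n_iters=4, rng=42, n_restarts=2)
    assert np.array_equal(a.scores, b.scores)
    assert np.array_equal(a.selected, b.selected)


def test_psodt_zero_iterations_empty(rng):
    counts, groups = _small_noise_data(rng)
    res = sel.psodt_select(counts, groups, swarm_size=6, n_iters=0, rng=0)
    assert res.scores.sum() == 0 and res.selected.sum() == 0


def test_psodt_score_conservation(rng):
    counts, groups = _small_noise_data(rng)
    swarm, iters, restarts = 6, 5, 2
    res = sel.psodt_select(counts, groups, swarm_size=swarm, n_iters=iters,
                           rng=3, n_restarts=restarts)
    assert res.scores.sum() <= restarts * iters * swarm * counts.shape[0]


def test_psodt_null_scores_exchangeable(rng):
    """On pure noise no feature's score should be a systematic outlier:
    the top score stays within the spread of a label permutation."""
    counts, groups = _small_noise_data(rng)
    res = sel.psodt_select(counts, groups, swarm_size=8, n_iters=6, rng=5,
                           n_restarts=2)
    perm_tops = [
        sel.psodt_select(counts, rng.permutation(groups), swarm_size=8,
                         n_iters=6, rng=100 + k, n_restarts=2).scores.max()
        for k in range(5)
    ]
    assert res.scores.max() <= 2.0 * max(max(perm_tops), 1.0)


# ---------------------------------------------------------------------------
# random forest

def test_rf_deterministic(baseline_data):
    a = sel.rf_select(baseline_data.counts[:60], baseline_data.labels,
                      n_trees=100, rng=9)
    b = sel.rf_select(baseline_data.counts[:60], baseline_data.labels,
                      n_trees=100, rng=9)
    assert np.array_equal(a.scores, b.scores)


def test_rf_null_importance_centred(rng):
    counts = rng.poisson(8.0, (40, 30))
    groups = np.r_[np.ones(15, int), np.zeros(15, int)]
    res = sel.rf_select(counts, groups, n_trees=200, rng=4)
    assert abs(np.mean(res.scores)) < 0.02
    assert res.selected.sum() <= 4


def test_rf_duplicated_feature_keeps_specificity(rng):
    """Duplicating a signal feature dilutes its importance but noise stays
    excluded at >= 0.9 specificity."""
    signal = np.r_[rng.poisson(40.0, 15), rng.poisson(5.0, 15)]
    noise = rng.poisson(5.0, (40, 30))
    counts = np.vstack([np.tile(signal, (5, 1)), noise])
    groups = np.r_[np.ones(15, int), np.zeros(15, int)]
    res = sel.rf_select(counts, groups, n_trees=300, rng=6)
    assert (~res.selected[5:]).mean() >= 0.9


def test_rf_selects_signal_on_baseline(baseline_data):
    res = sel.rf_select(baseline_data.counts, baseline_data.labels, rng=1)
    truth = baseline_data.truth
    assert res.selected[truth].mean() > 0.2
    assert (~res.selected[~truth]).mean() >= 0.93


# ---------------------------------------------------------------------------
# dispatch

def test_select_features_dispatch_rules(baseline_data):
    res = sel.select_features("edger", baseline_data, alpha=0.05)
    assert res.method_tag == "edger" and res.rule == "p<0.05"
    res_b = sel.select_features("ranksum", baseline_data, bonferroni=True)
    assert res_b.rule == "p<0.0001"


def test_select_features_unknown_method(baseline_data):
    with pytest.raises(ValueError, match="unknown selector"):
        sel.select_features("anova", baseline_data)


def test_fsresult_validation():
    with pytest.raises(ValueError):
        sel.FSResult("x", np.zeros(3), np.zeros(4, bool), "p<0.05")
    with pytest.raises(ValueError):
        sel.FSResult("x", np.zeros(3), np.zeros(3, bool), "")
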