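"""NB machinery: normalisation, dispersion estimation, exact test and the
empirical-Bayes posterior, each checked against independent oracles."""

import warnings
from dataclasses import replace

import numpy as np
import pytest
from scipy import stats

from nbselect import baseline_config, nb_sample, simulate_dataset
from nbselect import nbmethods as m

GROUPS_20_20 = np.r_[np.ones(20, int), np.zeros(20, int)]


# ---------------------------------------------------------------------------
# size factors

def test_size_factors_identity():
    col = np.array([3, 8, 15, 40, 7])
    counts = np.tile(col[:, None], (1, 6))
    assert np.allclose(m.size_factors(counts), 1.0)


def test_size_factors_doubled_column():
    counts = np.array([[2, 4], [6, 12], [10, 20], [1, 2]])
    expected = np.array([1 / np.sqrt(2), np.sqrt(2)])
    assert np.allclose(m.size_factors(counts), expected)


def test_size_factors_near_one_on_simulated_data(baseline_data):
    """The generator draws equal expected library sizes, so factors sit
    near 1; the median-of-ratios estimator on mean-5 overdispersed counts
    carries sampling noise of roughly +/-0.1, hence the 0.3 band."""
    factors = m.size_factors(baseline_data.counts)
    assert np.all(np.abs(factors - 1.0) < 0.3)
    assert np.isclose(np.exp(np.mean(np.log(factors))), 1.0)


def test_size_factors_all_zero_matrix_errors():
    with pytest.raises(ValueError):
        m.size_factors(np.zeros((4, 3)))


# ---------------------------------------------------------------------------
# dispersion estimation

@pytest.mark.parametrize("phi", [0.125, 0.5, 1.0, 2.0, 8.0])
def test_common_dispersion_recovery(phi, rng):
    """500 features at n=20/20 recover the generating dispersion within 25%."""
    counts = nb_sample(5.0, phi, 0, rng, size=(500, 40))
    est = m.estimate_common_dispersion(counts, GROUPS_20_20)
    assert abs(est - phi) / phi < 0.25


def test_common_dispersion_poisson_boundary(rng):
    counts = rng.poisson(5.0, (500, 40))
    assert m.estimate_common_dispersion(counts, GROUPS_20_20) <= 0.05


def test_common_dispersion_single_feature_large_n(rng):
    counts = nb_sample(20.0, 4.0, 0, rng, size=(1, 400))
    groups = np.r_[np.ones(200, int), np.zeros(200, int)]
    est = m.estimate_common_dispersion(counts, groups)
    assert 3.0 <= est <= 5.0


def test_tagwise_limits(baseline_data):
    counts = baseline_data.counts[:60]
    groups = baseline_data.labels
    common = m.estimate_common_dispersion(counts, groups)
    # alpha -> large: everything collapses onto the common estimate
    big = m.estimate_tagwise_dispersion(counts, groups, alpha_weight=1e6)
    assert np.all(np.abs(big.tagwise_phi - common) < 0.05 * max(common, 1.0))
    # alpha = 0: per-feature conditional ML, so spread out
    solo = m.estimate_tagwise_dispersion(counts, groups, alpha_weight=0.0)
    assert solo.tagwise_phi.std() > big.tagwise_phi.std()


def test_tagwise_orders_mixed_dispersions(rng):
    lo = nb_sample(10.0, 0.5, 0, rng, size=(100, 40))
    hi = nb_sample(10.0, 2.0, 0, rng, size=(100, 40))
    counts = np.vstack([lo, hi])
    fit = m.estimate_tagwise_dispersion(counts, GROUPS_20_20)
    assert fit.tagwise_phi[:100].mean() < fit.tagwise_phi[100:].mean()


# ---------------------------------------------------------------------------
# pooled mean-variance regression

def test_mean_variance_recovers_phi1(rng):
    """Features spanning a range of means at phi=1: fitted raw variance at
    mu=20 close to phi*mu^2 = 400."""
    means = rng.uniform(2.0, 50.0, size=400)
    counts = np.vstack([nb_sample(mu, 1.0, 0, rng, size=(1, 40)) for mu in means])
    fn = m.fit_mean_variance(counts, GROUPS_20_20)
    assert 300.0 <= float(fn(np.array([20.0]))[0]) <= 500.0


def test_mean_variance_poisson_near_zero(rng):
    counts = rng.poisson(8.0, (300, 40))
    fn = m.fit_mean_variance(counts, GROUPS_20_20)
    assert float(fn(np.array([8.0]))[0]) <= 0.10 * 8.0**2 * 0.05 + 1.0


def test_mean_variance_never_negative(rng):
    counts = rng.poisson(3.0, (100, 20))
    groups = np.r_[np.ones(10, int), np.zeros(10, int)]
    fn = m.fit_mean_variance(counts, groups)
    grid = np.linspace(0.5, 20.0, 50)
    assert np.all(fn(grid) >= 0.0)


def test_mean_variance_needs_features():
    with pytest.raises(ValueError):
        m.fit_mean_variance(np.ones((3, 10)), np.r_[np.ones(5, int), np.zeros(5, int)])


# ---------------------------------------------------------------------------
# the conditional exact test

def _oracle_conditional_p(sum_case, sum_control, n_case, n_control, mu, phi):
    """Independent route: conditional distribution of the case total from
    scipy NB pmfs of per-sample counts convolved into group-sum pmfs."""
    T = sum_case + sum_control
    support = np.arange(T + 1)
    if phi == 0:
        one = stats.poisson.pmf(support, mu)
    else:
        r = 1.0 / phi
        one = stats.nbinom.pmf(support, r, r / (r + mu))

    def group_pmf(n):
        pmf = one.copy()
        for _ in range(n - 1):
            pmf = np.convolve(pmf, one)[: T + 1]
        return pmf

    p1, p2 = group_pmf(n_case), group_pmf(n_control)
    joint = p1 * p2[::-1]
    joint = joint / joint.sum()
    obs = joint[sum_case]
    return joint[joint <= obs * (1 + 1e-9)].sum()


@pytest.mark.parametrize("s1,s2,n1,n2,phi", [
    (10, 3, 2, 2, 0.5), (0, 12, 1, 3, 1.0), (15, 15, 3, 3, 2.0),
    (7, 20, 2, 3, 0.25), (30, 0, 3, 2, 1.5), (4, 4, 1, 1, 0.0),
    (18, 9, 3, 3, 0.0),
])
def test_exact_test_against_convolution_oracle(s1, s2, n1, n2, phi):
    mu = (s1 + s2) / (n1 + n2)
    ours = m.nb_exact_test(s1, s2, n1, n2, mu, phi)
    oracle = _oracle_conditional_p(s1, s2, n1, n2, mu, phi)
    assert ours == pytest.approx(oracle, abs=1e-10)


def test_exact_test_mode_split_gives_one():
    assert m.nb_exact_test(50, 50, 5, 5, 10.0, 0.5) == 1.0


def test_exact_test_poisson_extreme_split():
    """Poisson 1-vs-1, total 10 observed (10, 0): two-tailed binomial mass
    of the extreme split is 2/1024."""
    assert m.nb_exact_test(10, 0, 1, 1, 5.0, 0.0) == pytest.approx(2 / 1024)


def test_exact_test_group_swap_symmetry(rng):
    for _ in range(20):
        s1, s2 = int(rng.integers(0, 200)), int(rng.integers(0, 200))
        n1, n2 = int(rng.integers(1, 8)), int(rng.integers(1, 8))
        phi = float(rng.uniform(0, 3))
        mu = max((s1 + s2) / (n1 + n2), 0.1)
        a = m.nb_exact_test(s1, s2, n1, n2, mu, phi)
        b = m.nb_exact_test(s2, s1, n2, n1, mu, phi)
        assert 0.0 <= a <= 1.0
        assert a == pytest.approx(b, abs=1e-12)


def test_exact_test_zero_total():
    assert m.nb_exact_test(0, 0, 3, 3, 1.0, 1.0) == 1.0


def test_exact_test_window_matches_full_enumeration(monkeypatch):
    """Forcing the +/-12-sd window reproduces full enumeration."""
    args = (6000, 4500, 20, 20, 262.5, 1.0)
    full = m.nb_exact_test(*args)
    monkeypatch.setattr(m, "_ENUM_CUTOFF", 1000)
    windowed = m.nb_exact_test(*args)
    assert windowed == pytest.approx(full, abs=1e-12)


# ---------------------------------------------------------------------------
# method pipelines

def test_edger_like_null_rejection_rate():
    cfg = baseline_config(seed=21, mu_sig_case=5.0)
    rates = []
    for rep in range(10):
        d = simulate_dataset(cfg, rep)
        res = m.edger_like_test(d.counts, d.labels)
        rates.append((res.p_values < 0.05).mean())
    assert 0.03 <= np.mean(rates) <= 0.08


def test_edger_like_power_saturates_at_b5():
    cfg = baseline_config(seed=22, mu_sig_case=30.0)
    d = simulate_dataset(cfg, 0)
    res = m.edger_like_test(d.counts, d.labels)
    assert (res.p_values[d.truth] < 0.05).mean() >= 0.95


def test_edger_like_sample_permutation_invariance(baseline_data):
    d = baseline_data
    res = m.edger_like_test(d.counts[:80], d.labels)
    perm = np.random.default_rng(0).permutation(d.n_samples)
    res_p = m.edger_like_test(d.counts[:80][:, perm], d.labels[perm])
    assert np.allclose(res.p_values, res_p.p_values, atol=1e-12)


def test_deseq_like_power_saturates_at_b5():
    cfg = baseline_config(seed=23, mu_sig_case=30.0)
    d = simulate_dataset(cfg, 0)
    res = m.deseq_like_test(d.counts, d.labels)
    assert (res.p_values[d.truth] < 0.05).mean() >= 0.95


def test_deseq_like_null_calibrated_or_conservative():
    cfg = baseline_config(seed=24, mu_sig_case=5.0)
    rates = []
    for rep in range(10):
        d = simulate_dataset(cfg, rep)
        res = m.deseq_like_test(d.counts, d.labels)
        rates.append((res.p_values < 0.05).mean())
    assert np.mean(rates) <= 0.07


def test_deseq_like_runs_with_one_sample_per_group(rng):
    counts = nb_sample(5.0, 1.0, 0, rng, size=(60, 2))
    res = m.deseq_like_test(counts, np.array([1, 0]))
    assert np.all((res.p_values >= 0) & (res.p_values <= 1))


def test_group_swap_symmetry_of_pipelines(baseline_data):
    d = baseline_data
    counts = d.counts[:60]
    swapped = 1 - d.labels
    for test in (m.edger_like_test, m.deseq_like_test):
        a = test(counts, d.labels).p_values
        b = test(counts, swapped).p_values
        assert np.allclose(a, b, atol=1e-10)


# ---------------------------------------------------------------------------
# empirical-Bayes posterior

def test_bayseq_posterior_normalised(baseline_data):
    d = baseline_data
    res = m.bayseq_like_posterior(d.counts, d.labels, rng=np.random.default_rng(3))
    assert np.allclose(res.p_values + res.posterior, 1.0)
    assert np.all((res.posterior >= 0) & (res.posterior <= 1))


def test_bayseq_self_consistency(baseline_data):
    """At the fixed point the mean posterior equals the estimated DE model
    proportion."""
    d = baseline_data
    res = m.bayseq_like_posterior(d.counts, d.labels, rng=np.random.default_rng(4))
    assert abs(res.posterior.mean() - res.de_proportion) < 0.05


def test_bayseq_power_on_baseline(baseline_data):
    d = baseline_data
    res = m.bayseq_like_posterior(d.counts, d.labels, rng=np.random.default_rng(4))
    assert (res.p_values[d.truth] < 0.05).mean() >= 0.6
    assert (res.p_values[~d.truth] < 0.05).mean() <= 0.05


def test_bayseq_null_rejects_few():
    cfg = baseline_config(seed=25, mu_sig_case=5.0)
    d = simulate_dataset(cfg, 0)
    res = m.bayseq_like_posterior(d.counts, d.labels, rng=np.random.default_rng(5))
    assert (res.p_values < 0.05).mean() <= 0.05


def test_deresult_validates_range():
    with pytest.raises(ValueError):
        m.DEResult(p_values=np.array([0.5, 1.2]), statistic_tag="x")
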