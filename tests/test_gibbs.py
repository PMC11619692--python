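"""The data-augmentation Gibbs sampler and its convergence diagnostics."""

import numpy as np
import pytest
from scipy import stats

import lcmgof as m
from lcmgof.gibbs import _diagnose, truncated_beta
from lcmgof.simulate import PATTERNS

from conftest import REDUCED


def test_fit_is_deterministic_given_seed():
    s = m.scenario_from_codes("HHHH", "HHHH", n_obs=500)
    d = m.simulate_dataset(s, 3)
    tiny = m.McmcSettings(n_chains=2, n_burnin=100, n_iter=200)
    f1 = m.gibbs_fit(d, tiny, rng=5)
    f2 = m.gibbs_fit(d, tiny, rng=5)
    np.testing.assert_array_equal(f1.draws, f2.draws)


def test_empty_counts_rejected():
    with pytest.raises(ValueError):
        m.gibbs_fit(np.zeros(16, dtype=int))


def test_settings_validation():
    with pytest.raises(ValueError):
        m.McmcSettings(n_chains=0)
    with pytest.raises(ValueError):
        m.McmcSettings(rhat_threshold=0.9)


def test_constraint_holds_for_every_draw():
    """Se_i + Sp_i >= 1 for all retained draws: no mirror-mode excursions."""
    s = m.scenario_from_codes("LLHH", "HHLL", n_obs=500)
    d = m.simulate_dataset(s, 4)
    fit = m.gibbs_fit(d, m.McmcSettings(n_burnin=200, n_iter=500), rng=6)
    se = fit.sensitivity_draws
    sp = fit.specificity_draws
    assert (se + sp >= 1.0).all()
    assert (fit.draws > 0).all() and (fit.draws < 1).all()


def test_truncated_beta_matches_analytic_quantiles():
    """Inverse-CDF truncated Beta draws reproduce the analytic truncated
    distribution, including the untruncated special case."""
    rng = np.random.default_rng(0)
    n = 200_000
    for a, b, lo in [(30.0, 10.0, 0.0), (30.0, 10.0, 0.75), (5.0, 5.0, 0.6)]:
        x = truncated_beta(rng, np.full(n, a), np.full(n, b), np.full(n, lo))
        assert (x >= lo).all()
        f_lo = stats.beta.cdf(lo, a, b)
        for q in (0.1, 0.5, 0.9):
            expected = stats.beta.ppf(f_lo + q * (1 - f_lo), a, b)
            assert np.quantile(x, q) == pytest.approx(expected, abs=3e-3)


def test_collapsed_single_class_posterior_is_analytic_beta():
    """When every subject is allocated to the diseased class, the sampler's
    Se full conditional is Beta(1 + positives, 1 + negatives) (the constraint
    bound sits at zero); its draws must match the analytic Beta quantiles."""
    rng = np.random.default_rng(1)
    counts = np.zeros(16, dtype=np.int64)
    counts[0b1111] = 70  # test 1 positive in 70 + 12 of 100 subjects
    counts[0b1000] = 12
    counts[0b0000] = 18
    positives = counts[PATTERNS[:, 0] == 1].sum()
    n = counts.sum()
    draws = truncated_beta(
        rng,
        np.full(50_000, 1.0 + positives),
        np.full(50_000, 1.0 + n - positives),
        np.zeros(50_000),
    )
    for q in (0.05, 0.25, 0.5, 0.75, 0.95):
        assert np.quantile(draws, q) == pytest.approx(
            stats.beta.ppf(q, 1 + positives, 1 + n - positives), abs=2e-3
        )


def test_posterior_matches_importance_sampling_oracle():
    """Full-posterior cross-check on a small data set: quantiles from the
    Gibbs sampler agree with a constrained-prior importance-sampling
    estimate of the same posterior."""
    s = m.ScenarioConfig(0.4, (0.8, 0.7, 0.9, 0.85), (0.75, 0.8, 0.9, 0.7), 0.0, 40)
    d = m.simulate_dataset(s, 11)

    rng = np.random.default_rng(5)
    n_prop = 2_000_000
    pi = rng.random(n_prop)
    se = rng.random((n_prop, 4))
    sp = rng.random((n_prop, 4))
    flip = se + sp < 1
    se = np.where(flip, 1 - se, se)
    sp = np.where(flip, 1 - sp, sp)
    loglik = np.zeros(n_prop)
    for start in range(0, n_prop, 500_000):
        sl = slice(start, start + 500_000)
        p1 = np.ones((500_000, 16))
        p0 = np.ones((500_000, 16))
        for i in range(4):
            pos = PATTERNS[None, :, i] == 1
            p1 *= np.where(pos, se[sl][:, i, None], 1 - se[sl][:, i, None])
            p0 *= np.where(pos, 1 - sp[sl][:, i, None], sp[sl][:, i, None])
        cell = pi[sl][:, None] * p1 + (1 - pi[sl][:, None]) * p0
        loglik[sl] = (d.counts[None, :] * np.log(cell)).sum(axis=1)
    w = np.exp(loglik - loglik.max())
    ess = w.sum() ** 2 / (w**2).sum()
    assert ess > 150  # enough weight mass for quantile comparison

    def weighted_quantile(x, q):
        order = np.argsort(x)
        cw = np.cumsum(w[order])
        return np.interp(q, cw / cw[-1], x[order])

    fit = m.gibbs_fit(d, m.McmcSettings(n_burnin=2000, n_iter=10000), rng=3)
    pooled = fit.pooled
    for idx, ref in [(0, pi), (1, se[:, 0]), (5, sp[:, 0])]:
        for q in (0.25, 0.5, 0.75):
            assert np.quantile(pooled[:, idx], q) == pytest.approx(
                weighted_quantile(ref, q), abs=0.04
            )


def test_parameter_recovery_on_conditionally_independent_data():
    """CInd-generated data, n_obs = 5000: posterior medians land within 3
    posterior SDs of the generating parameters."""
    s = m.scenario_from_codes("HHHH", "HHHH", prevalence=0.5, omega=0.0, n_obs=5000)
    d = m.simulate_dataset(s, 21)
    fit = m.gibbs_fit(d, REDUCED, rng=22)
    assert fit.converged
    pooled = fit.pooled
    medians = np.median(pooled, axis=0)
    sds = pooled.std(axis=0)
    truth = np.asarray(s.params)
    assert (np.abs(medians - truth) < 3 * sds).all()


def test_rhat_near_one_for_well_mixed_and_large_for_separated_chains():
    rng = np.random.default_rng(2)
    good = rng.normal(size=(3, 10000))
    assert abs(m.compute_rhat(good) - 1.0) < 0.01
    bad = np.stack([rng.normal(0, 1, 5000), rng.normal(10, 1, 5000)])
    assert m.compute_rhat(bad) > 1.5


def test_rhat_constant_chains_fall_back_to_one():
    with pytest.warns(UserWarning):
        assert m.compute_rhat(np.ones((3, 100))) == 1.0
    assert m.compute_neff(np.ones((3, 100))) == 0.0


def test_diagnostics_reject_single_chain():
    with pytest.raises(ValueError):
        m.compute_rhat(np.zeros((1, 100)))
    with pytest.raises(ValueError):
        m.compute_neff(np.zeros((1, 100)))


def test_neff_iid_and_autocorrelated():
    rng = np.random.default_rng(3)
    iid = rng.normal(size=(3, 10000))
    assert m.compute_neff(iid) == pytest.approx(30000, rel=0.2)
    phi = 0.6
    n = 20000
    ar = np.empty((3, n))
    for c in range(3):
        eps = rng.normal(size=n)
        v = np.empty(n)
        v[0] = eps[0]
        for t in range(1, n):
            v[t] = phi * v[t - 1] + eps[t]
        ar[c] = v
    theory = 3 * n * (1 - phi) / (1 + phi)
    assert m.compute_neff(ar) == pytest.approx(theory, rel=0.25)


def test_exclusion_rule_reproduces_thresholds():
    """converged is false iff any parameter fails the R-hat or ESS screen."""
    rng = np.random.default_rng(4)
    settings = m.McmcSettings(n_burnin=1, n_iter=5000)
    good = rng.normal(0.5, 0.01, size=(3, 5000, 9))
    _, _, ok = _diagnose(good, settings)
    assert ok
    split = good.copy()
    split[0, :, 2] += 1.0  # one chain of one parameter far away -> R-hat blows up
    rhat, _, ok = _diagnose(split, settings)
    assert rhat[2] > settings.rhat_threshold and not ok
    sticky = good.copy()
    walk = np.cumsum(rng.normal(size=(3, 5000)), axis=1) * 0.05  # strong autocorrelation
    sticky[:, :, 7] = walk
    _, neff, ok = _diagnose(sticky, settings)
    assert neff[7] < settings.neff_threshold and not ok


def test_summarize_posterior_quantiles():
    draws = np.full((2, 50, 9), 0.3)
    pd_ = m.PosteriorDraws(draws=draws, rhat=np.ones(9), n_eff=np.full(9, 1e4), converged=True)
    s = m.summarize_posterior(pd_)
    np.testing.assert_allclose(s.medians, 0.3)
    np.testing.assert_allclose(s.cri_low, 0.3)
    np.testing.assert_allclose(s.cri_high, 0.3)
    assert (s.cri_low <= s.medians).all() and (s.medians <= s.cri_high).all()


def test_batch_fit_matches_shapes_and_accounting():
    s = m.scenario_from_codes("HHHH", "HHHH", n_obs=500)
    counts = np.stack([m.simulate_dataset(s, i).counts for i in range(4)])
    tiny = m.McmcSettings(n_chains=2, n_burnin=100, n_iter=150)
    fits = m.gibbs_fit_batch(counts, tiny, rng=9)
    assert len(fits) == 4
    for f in fits:
        assert f.draws.shape == (2, 150, 9)
        frame = f.to_frame()
        assert set(frame.columns) == {"chain", "iteration", *m.PARAM_NAMES}
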