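"""Residual correlations, chi-squared / G-squared statistics, agreement."""

import numpy as np
import pytest

import lcmgof as m
from lcmgof.gof import _fitted_corr_draws, collapse_pair

HHHH = (0.5, 0.9, 0.9, 0.9, 0.9, 0.9, 0.9, 0.9, 0.9)


def counts_from_table(n11, n10, n01, n00, pair=(0, 1)):
    """Spread a 2x2 table of tests (i, j) over 16 cells (others at zero)."""
    i, j = pair
    counts = np.zeros(16, dtype=np.int64)
    for val, (ti, tj) in zip((n11, n10, n01, n00), ((1, 1), (1, 0), (0, 1), (0, 0))):
        k = (ti << (3 - i)) | (tj << (3 - j))
        counts[k] += val
    return counts


def test_observed_phi_examples():
    perfect = counts_from_table(50, 0, 0, 50)
    assert m.observed_marginal_correlation(perfect, (0, 1)) == pytest.approx(1.0)
    independent = counts_from_table(25, 25, 25, 25)
    assert m.observed_marginal_correlation(independent, (0, 1)) == pytest.approx(0.0)
    assert m.observed_marginal_correlation(counts_from_table(40, 10, 10, 40), (0, 1)) == pytest.approx(0.6)


def test_degenerate_margin_raises():
    all_pos = counts_from_table(100, 0, 0, 0)
    with pytest.raises(m.DegenerateMarginError):
        m.observed_marginal_correlation(all_pos, (0, 1))


def test_fitted_correlation_limits():
    # nearly single-class population: conditional independence within the
    # class leaves no marginal association
    nearly_one_class = (1e-9, 0.9, 0.8, 0.9, 0.8, 0.7, 0.9, 0.7, 0.9)
    assert m.fitted_marginal_correlation(nearly_one_class, (0, 1)) == pytest.approx(0.0, abs=1e-6)
    # an uninformative test (Se = 1 - Sp) is independent of disease status
    uninformative = (0.5, 0.3, 0.9, 0.9, 0.9, 0.7, 0.9, 0.9, 0.9)
    assert m.fitted_marginal_correlation(uninformative, (0, 1)) == pytest.approx(0.0, abs=1e-12)


def test_fitted_correlation_dual_route():
    """16-cell route equals the closed-form moment route and a brute-force
    phi of the exact model 2x2 table."""
    params = np.array([0.35, 0.85, 0.7, 0.9, 0.6, 0.8, 0.75, 0.95, 0.65])
    closed = _fitted_corr_draws(params[None, :])[0]
    for p, pair in enumerate(m.PAIRS):
        cell16 = m.cind_pattern_probs(params[0], params[1:5], params[5:9])
        table = collapse_pair(cell16, pair)
        pi_, pj_ = table[0] + table[1], table[0] + table[2]
        phi = (table[0] - pi_ * pj_) / np.sqrt(pi_ * (1 - pi_) * pj_ * (1 - pj_))
        assert m.fitted_marginal_correlation(params, pair) == pytest.approx(phi, abs=1e-12)
        assert closed[p] == pytest.approx(phi, abs=1e-12)


def test_residual_zero_when_draws_equal_generating_parameters():
    """Exact expected counts assessed at the generating parameters leave no
    residual correlation, and intervals collapse onto zero."""
    probs = m.cind_pattern_probs(HHHH[0], HHHH[1:5], HHHH[5:9])
    exact_counts = probs * 10000  # exact expected frequencies as 'observations'
    draws = np.broadcast_to(np.asarray(HHHH), (2, 100, 9)).copy()
    fit = m.PosteriorDraws(draws=draws, rhat=np.ones(9), n_eff=np.full(9, 1e4), converged=True)
    med, cri = m.residual_correlations(exact_counts, fit)
    np.testing.assert_allclose(med, 0.0, atol=1e-12)
    np.testing.assert_allclose(cri, 0.0, atol=1e-12)


def test_expected_frequencies():
    uniform = (0.5, 0.5, 0.5, 0.5, 0.5, 0.5, 0.5, 0.5, 0.5)
    np.testing.assert_allclose(m.expected_frequencies(uniform, 1600), np.full(16, 100.0))
    e = m.expected_frequencies(HHHH, 2000)
    assert e.sum() == pytest.approx(2000)
    assert e[0b1111] == pytest.approx(2000 * (0.5 * 0.9**4 + 0.5 * 0.1**4))


def test_gof_statistics_toy_values():
    assert m.gof_statistics(np.array([7.0, 3.0]), np.array([7.0, 3.0])) == (0.0, 0.0)
    chi2, g2 = m.gof_statistics(np.array([10.0, 20.0]), np.array([15.0, 15.0]))
    assert chi2 == pytest.approx(10.0 / 3.0)
    assert g2 == pytest.approx(2 * (10 * np.log(10 / 15) + 20 * np.log(20 / 15)))
    # empty observed cell: 0*log(0) convention
    chi2, g2 = m.gof_statistics(np.array([0.0, 30.0]), np.array([10.0, 20.0]))
    assert np.isfinite(g2) and g2 == pytest.approx(2 * 30 * np.log(30 / 20))


def test_gof_statistics_input_guards():
    with pytest.raises(ValueError):
        m.gof_statistics(np.array([10.0, 20.0]), np.array([20.0, 20.0]))
    with pytest.raises(ValueError):
        m.gof_statistics(np.array([10.0, 0.0]), np.array([10.0, 0.0]))


def test_chi2_g2_agree_near_the_null():
    """First-order equivalence: chi2 / G2 ratio tends to 1 as O -> E."""
    e = m.expected_frequencies(HHHH, 5000)
    rng = np.random.default_rng(0)
    ratios = []
    for scale in (1.0, 0.1, 0.01):
        perturbation = rng.normal(size=16) * scale
        perturbation -= perturbation.mean()
        chi2, g2 = m.gof_statistics(e + perturbation, e)
        ratios.append(chi2 / g2)
    assert abs(ratios[-1] - 1.0) < 1e-4
    assert abs(ratios[-1] - 1.0) < abs(ratios[0] - 1.0) + 1e-12


def test_overall_gof_flags_and_df():
    assert m.DF_OVERALL == 6
    probs = m.cind_pattern_probs(HHHH[0], HHHH[1:5], HHHH[5:9])
    exact = probs * 2000
    chi2, g2, f1, f2 = m.overall_gof(exact, HHHH)
    assert chi2 == pytest.approx(0.0, abs=1e-20) and g2 == pytest.approx(0.0, abs=1e-10)
    assert not f1 and not f2


def test_pairwise_collapse_consistency():
    s = m.scenario_from_codes("LLHH", "LLHH")
    d = m.simulate_dataset(s, 5)
    e16 = m.expected_frequencies(HHHH, d.n_obs)
    for pair in m.PAIRS:
        collapsed = collapse_pair(e16, pair)
        assert collapsed.sum() == pytest.approx(d.n_obs)
        # agreement from the collapsed table equals agreement from 16 cells
        agree16 = m.agreement_probabilities(e16)[m.PAIRS.index(pair)]
        assert (collapsed[0] + collapsed[3]) / d.n_obs == pytest.approx(agree16)


def test_pairwise_flag_threshold_behaviour():
    """A 2x2 statistic just above / below the df = 1 critical value flips
    the flag (critical value from the chi-squared quantile function)."""
    n = 4000
    e = np.full(4, n / 4)

    def chi2_of(delta):
        o = e + np.array([delta, -delta, -delta, delta])
        return m.gof_statistics(o, e)[0]

    # solve for deltas bracketing the critical value
    crit = m.CHI2_CRIT_PAIRWISE
    delta_hi = np.sqrt((crit + 0.05) * n / 16) + 1e-9
    delta_lo = np.sqrt((crit - 0.05) * n / 16) - 1e-9
    assert chi2_of(delta_hi) > crit
    assert chi2_of(delta_lo) < crit


def test_assess_fit_structure(llhh_fit):
    scenario, dataset, fit = llhh_fit
    a = m.assess_fit(dataset, fit)
    assert a.residual_corr_median.shape == (6,)
    assert a.residual_corr_cri.shape == (6, 2)
    assert (a.residual_corr_cri[:, 0] <= a.residual_corr_median).all()
    assert (a.residual_corr_median <= a.residual_corr_cri[:, 1]).all()
    assert a.overall_chi2 >= 0 and a.overall_g2 >= 0
    assert ((0 <= a.agreement_observed) & (a.agreement_observed <= 1)).all()
    # flags match interval / critical-value definitions
    np.testing.assert_array_equal(
        a.pairwise_flags, (a.residual_corr_cri[:, 0] > 0) | (a.residual_corr_cri[:, 1] < 0)
    )
    np.testing.assert_array_equal(a.pairwise_chi2_flags, a.pairwise_chi2 > m.CHI2_CRIT_PAIRWISE)
    row = a.to_row()
    assert row["res_any_flag"] == a.pairwise_flags.any()
    assert "res_median_T1xT2" in row and "est_pi" in row


def test_dependence_is_detected_in_the_favourable_scenario(llhh_fit):
    """In the LLHH-LLHH scenario the residual plot flags the truly dependent
    pair T1xT2 and the fitted model reproduces the T3xT4 agreement."""
    scenario, dataset, fit = llhh_fit
    a = m.assess_fit(dataset, fit)
    assert a.pairwise_flags[0]  # T1xT2
    assert abs(a.agreement_fitted[5] - a.agreement_observed[5]) < 0.03
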