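"""Goodness-of-fit assessment of a fitted conditional-independence model.

Three families of tools, all operating on one data set (16 pattern counts)
and one fitted posterior:

* residual correlations: the observed marginal (phi) correlation of each
  test pair minus the model-fitted marginal correlation, evaluated at every
  MCMC draw; a pair is flagged when the equal-tailed 95% credible interval
  of the residual excludes zero, and the "residual plot" flags lack of
  overall fit when any pair is flagged;
* overall chi-squared and G-squared statistics over the 16 cells, evaluated
  at the posterior medians and referred to the 95% critical value of a
  chi-squared distribution with 2^4 - 9 - 1 = 6 degrees of freedom;
* pairwise chi-squared and G-squared statistics on the collapsed 2x2 table
  of each test pair, referred to the df = 1 critical value.

Pairwise agreement probabilities P(T_i = T_j) — observed and at the fitted
posterior medians — are computed alongside, since they explain *why* the
tools flag the pairs they do.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .gibbs import PosteriorDraws, PosteriorSummary, summarize_posterior
from .simulate import PAIRS, PATTERNS, CountsLike, agreement_probabilities, as_counts_array, cind_pattern_probs

__all__ = [
    "DF_OVERALL",
    "CHI2_CRIT_PAIRWISE",
    "CHI2_CRIT_OVERALL",
    "DegenerateMarginError",
    "FitAssessment",
    "observed_marginal_correlation",
    "fitted_marginal_correlation",
    "residual_correlations",
    "expected_frequencies",
    "gof_statistics",
    "overall_gof",
    "pairwise_gof",
    "assess_fit",
]

#: Overall-test degrees of freedom: 2^4 cells - 9 parameters - 1.
DF_OVERALL = 2**4 - 9 - 1

#: 95% critical values from the chi-squared quantile function.
CHI2_CRIT_PAIRWISE = float(stats.chi2.ppf(0.95, 1))
CHI2_CRIT_OVERALL = float(stats.chi2.ppf(0.95, DF_OVERALL))


class DegenerateMarginError(ValueError):
    """A test is all-positive or all-negative in the sample, so the observed
    marginal correlation is undefined."""


def _unpack_params(params: Sequence[float]) -> tuple[float, np.ndarray, np.ndarray]:
    p = np.asarray(params, dtype=float)
    if p.shape != (9,):
        raise ValueError(f"expected 9 parameters (pi, se1..4, sp1..4), got shape {p.shape}")
    return float(p[0]), p[1:5], p[5:9]


def collapse_pair(vec: np.ndarray, pair: tuple[int, int]) -> np.ndarray:
    """Collapse 16 cells to the 2x2 table of (T_i, T_j): [n11, n10, n01, n00]."""
    i, j = pair
    ti, tj = PATTERNS[:, i], PATTERNS[:, j]
    return np.array(
        [
            vec[(ti == 1) & (tj == 1)].sum(),
            vec[(ti == 1) & (tj == 0)].sum(),
            vec[(ti == 0) & (tj == 1)].sum(),
            vec[(ti == 0) & (tj == 0)].sum(),
        ]
    )


def _phi_from_table(n11: float, n10: float, n01: float, n00: float) -> float:
    n = n11 + n10 + n01 + n00
    p11 = n11 / n
    pi_ = (n11 + n10) / n
    pj_ = (n11 + n01) / n
    denom2 = pi_ * (1 - pi_) * pj_ * (1 - pj_)
    if denom2 <= 0.0:
        raise DegenerateMarginError(
            "a test margin is all-positive or all-negative; phi coefficient undefined"
        )
    return (p11 - pi_ * pj_) / np.sqrt(denom2)


def observed_marginal_correlation(counts: CountsLike, pair: tuple[int, int]) -> float:
    """Observed phi coefficient of the 2x2 table for the given test pair.

    Raises :class:`DegenerateMarginError` when either test has zero observed
    variance in the sample.
    """
    table = collapse_pair(as_counts_array(counts).astype(float), pair)
    return _phi_from_table(*table)


def fitted_marginal_correlation(params: Sequence[float], pair: tuple[int, int]) -> float:
    """Model-fitted marginal correlation of a test pair under the CInd model.

    Computed from the fitted 16-cell pattern probabilities, so it is the phi
    coefficient of the model-implied 2x2 table.
    """
    pi, se, sp = _unpack_params(params)
    probs = cind_pattern_probs(pi, se, sp)
    table = collapse_pair(probs, pair)
    return _phi_from_table(*table)


def _fitted_corr_draws(draws: np.ndarray) -> np.ndarray:
    """Fitted marginal correlation per draw for all 6 pairs, shape (n, 6).

    Uses the closed form of the model-implied moments,
    P(T_i=1) = pi Se_i + (1-pi)(1-Sp_i) and
    P(T_i=1, T_j=1) = pi Se_i Se_j + (1-pi)(1-Sp_i)(1-Sp_j),
    which equals the 16-cell route (cross-checked in the test suite).
    """
    pi = draws[:, 0:1]
    se = draws[:, 1:5]
    fp = 1.0 - draws[:, 5:9]  # P(T=1 | D=0)
    p1 = pi * se + (1.0 - pi) * fp
    out = np.empty((draws.shape[0], 6))
    for p, (i, j) in enumerate(PAIRS):
        p11 = pi[:, 0] * se[:, i] * se[:, j] + (1.0 - pi[:, 0]) * fp[:, i] * fp[:, j]
        denom = np.sqrt(p1[:, i] * (1 - p1[:, i]) * p1[:, j] * (1 - p1[:, j]))
        out[:, p] = (p11 - p1[:, i] * p1[:, j]) / denom
    return out


def residual_correlations(
    counts: CountsLike, draws: PosteriorDraws
) -> tuple[np.ndarray, np.ndarray]:
    """Posterior medians and 95% CrIs of the six residual correlations.

    For every retained draw, residual = observed phi - fitted phi; the
    observed term is constant across draws. Returns ``(medians, cris)`` with
    shapes (6,) and (6, 2).
    """
    observed = np.array([observed_marginal_correlation(counts, pair) for pair in PAIRS])
    fitted = _fitted_corr_draws(draws.pooled)
    residual = observed[None, :] - fitted
    q = np.quantile(residual, [0.025, 0.5, 0.975], axis=0)
    return q[1], np.stack([q[0], q[2]], axis=1)


def expected_frequencies(params: Sequence[float], n_obs: int) -> np.ndarray:
    """Fitted frequencies E_k = n_obs * CInd pattern probability, 16 cells."""
    pi, se, sp = _unpack_params(params)
    if n_obs <= 0:
        raise ValueError("n_obs must be positive")
    return n_obs * cind_pattern_probs(pi, se, sp)


def gof_statistics(observed: np.ndarray, expected: np.ndarray) -> tuple[float, float]:
    """Pearson chi-squared and likelihood-ratio G-squared over matched cells.

    chi2 = sum (O_k - E_k)^2 / E_k ;  G2 = 2 sum O_k log(O_k / E_k)
    with the 0*log(0) = 0 convention for empty observed cells.
    """
    obs = np.asarray(observed, dtype=float)
    exp = np.asarray(expected, dtype=float)
    if obs.shape != exp.shape:
        raise ValueError("observed and expected must have matching shapes")
    tiny = 1e-12
    bad = np.where(exp <= tiny)[0]
    if bad.size:
        raise ValueError(f"expected frequency is numerically zero in cell {int(bad[0])}")
    if not np.isclose(obs.sum(), exp.sum(), rtol=1e-6, atol=1e-6):
        raise ValueError("expected frequencies must sum to the observed total")
    chi2 = float(((obs - exp) ** 2 / exp).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(obs > 0, obs * np.log(np.where(obs > 0, obs, 1.0) / exp), 0.0)
    g2 = float(2.0 * terms.sum())
    return chi2, g2


def overall_gof(
    counts: CountsLike, params: Sequence[float]
) -> tuple[float, float, bool, bool]:
    """Overall chi2 and G2 over the 16 cells, with df = 6 critical-value flags."""
    obs = as_counts_array(counts).astype(float)
    exp = expected_frequencies(params, int(obs.sum()))
    chi2, g2 = gof_statistics(obs, exp)
    return chi2, g2, chi2 > CHI2_CRIT_OVERALL, g2 > CHI2_CRIT_OVERALL


def pairwise_gof(
    counts: CountsLike, params: Sequence[float], pair: tuple[int, int]
) -> tuple[float, float, bool, bool]:
    """Pairwise chi2 and G2 on the collapsed 2x2 table, df = 1 flags."""
    obs16 = as_counts_array(counts).astype(float)
    exp16 = expected_frequencies(params, int(obs16.sum()))
    obs = collapse_pair(obs16, pair)
    exp = collapse_pair(exp16, pair)
    chi2, g2 = gof_statistics(obs, exp)
    return chi2, g2, chi2 > CHI2_CRIT_PAIRWISE, g2 > CHI2_CRIT_PAIRWISE


@dataclass
class FitAssessment:
    """All goodness-of-fit quantities for one fitted data set.

    Pair-indexed arrays follow the order (1,2), (1,3), (1,4), (2,3), (2,4),
    (3,4). ``pairwise_flags`` marks residual-correlation CrIs that exclude
    zero (strictly); the chi2/G2 flags mark statistics above their 95%
    critical values.
    """

    residual_corr_median: np.ndarray
    residual_corr_cri: np.ndarray
    pairwise_flags: np.ndarray
    overall_chi2: float
    overall_g2: float
    overall_chi2_flag: bool
    overall_g2_flag: bool
    pairwise_chi2: np.ndarray
    pairwise_g2: np.ndarray
    pairwise_chi2_flags: np.ndarray
    pairwise_g2_flags: np.ndarray
    agreement_observed: np.ndarray
    agreement_fitted: np.ndarray
    summary: PosteriorSummary

    @property
    def any_residual_flag(self) -> bool:
        """Residual-plot verdict on overall fit: any pair's CrI excludes zero."""
        return bool(self.pairwise_flags.any())

    def to_row(self) -> dict:
        """Flatten into one replicate-level record."""
        row: dict = {
            "overall_chi2": self.overall_chi2,
            "overall_g2": self.overall_g2,
            "overall_chi2_flag": self.overall_chi2_flag,
            "overall_g2_flag": self.overall_g2_flag,
            "res_any_flag": self.any_residual_flag,
        }
        from .simulate import PAIR_LABELS

        for p, lab in enumerate(PAIR_LABELS):
            row[f"res_median_{lab}"] = float(self.residual_corr_median[p])
            row[f"res_lo_{lab}"] = float(self.residual_corr_cri[p, 0])
            row[f"res_hi_{lab}"] = float(self.residual_corr_cri[p, 1])
            row[f"res_flag_{lab}"] = bool(self.pairwise_flags[p])
            row[f"chi2_flag_{lab}"] = bool(self.pairwise_chi2_flags[p])
            row[f"g2_flag_{lab}"] = bool(self.pairwise_g2_flags[p])
            row[f"agree_obs_{lab}"] = float(self.agreement_observed[p])
            row[f"agree_fit_{lab}"] = float(self.agreement_fitted[p])
        row.update(self.summary.to_dict())
        return row


def assess_fit(
    counts: CountsLike,
    draws: PosteriorDraws,
    summary: Optional[PosteriorSummary] = None,
) -> FitAssessment:
    """Full goodness-of-fit assessment of one fitted data set.

    Raises :class:`DegenerateMarginError` when a test has zero observed
    variance (residual correlations undefined); callers running simulation
    studies should catch it and record the replicate as degenerate.
    """
    summary = summary or summarize_posterior(draws)
    medians9 = summary.medians
    res_med, res_cri = residual_correlations(counts, draws)
    flags = (res_cri[:, 0] > 0.0) | (res_cri[:, 1] < 0.0)

    chi2, g2, chi2_flag, g2_flag = overall_gof(counts, medians9)
    pw = [pairwise_gof(counts, medians9, pair) for pair in PAIRS]
    pw_chi2 = np.array([t[0] for t in pw])
    pw_g2 = np.array([t[1] for t in pw])
    pw_chi2_flags = np.array([t[2] for t in pw])
    pw_g2_flags = np.array([t[3] for t in pw])

    arr = as_counts_array(counts)
    pi, se, sp = _unpack_params(medians9)
    agree_obs = agreement_probabilities(arr.astype(float))
    agree_fit = agreement_probabilities(cind_pattern_probs(pi, se, sp))

    return FitAssessment(
        residual_corr_median=res_med,
        residual_corr_cri=res_cri,
        pairwise_flags=flags,
        overall_chi2=chi2,
        overall_g2=g2,
        overall_chi2_flag=bool(chi2_flag),
        overall_g2_flag=bool(g2_flag),
        pairwise_chi2=pw_chi2,
        pairwise_g2=pw_g2,
        pairwise_chi2_flags=pw_chi2_flags,
        pairwise_g2_flags=pw_g2_flags,
        agreement_observed=agree_obs,
        agreement_fitted=agree_fit,
        summary=summary,
    )
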