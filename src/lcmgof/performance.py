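"""ADEMP performance measures with Monte Carlo uncertainty.

Per-replicate assessments (one row per simulated data set) are aggregated
into the study's performance measures:

* detection rates — how often each tool (residual correlation plot, overall
  and pairwise G2 / chi2) flags lack of fit, overall and per test pair,
  among *converged* replicates, with exact Clopper-Pearson 95% Monte Carlo
  confidence intervals;
* bias — posterior-median estimate minus truth per parameter, summarised
  both as a mean with an MCSE-based interval and as a median with 2.5th /
  97.5th percentiles (the mean of |bias| is also reported, since "average
  absolute bias" admits both readings);
* coverage — fraction of replicates whose 95% credible interval contains
  the truth, with Clopper-Pearson intervals.

Non-converged replicates are excluded from every denominator; replicates
with a degenerate observed margin (a test all-positive or all-negative)
are excluded from the residual-correlation denominators and counted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .gibbs import PARAM_NAMES
from .scenarios import ScenarioConfig
from .simulate import PAIR_LABELS

__all__ = [
    "Z_975",
    "TOOLS",
    "ScenarioPerformance",
    "required_simulations",
    "clopper_pearson",
    "mc_interval_mean",
    "aggregate_scenario",
    "aggregate_across_scenarios",
]

#: 97.5% standard-normal quantile used throughout the Monte Carlo intervals.
Z_975 = float(stats.norm.ppf(0.975))

#: Tool identifiers: residual correlation plot, likelihood-ratio, Pearson.
TOOLS = ("residual", "g2", "chi2")

_OVERALL_FLAG = {"residual": "res_any_flag", "g2": "overall_g2_flag", "chi2": "overall_chi2_flag"}
_PAIR_FLAG = {"residual": "res_flag", "g2": "g2_flag", "chi2": "chi2_flag"}


def required_simulations(p: float, length: float) -> int:
    """Number of simulation replicates for a 95% Monte Carlo CI of given length.

    n_req = (z_0.975 * sqrt(p (1-p)) / (L/2))^2, rounded to the nearest
    integer; ``p`` is the anticipated detection proportion and ``length``
    the maximum acceptable CI length.
    """
    if not 0.0 < p < 1.0:
        raise ValueError(f"p must lie in (0, 1), got {p}")
    if length <= 0.0:
        raise ValueError(f"length must be positive, got {length}")
    return int(round((Z_975 * np.sqrt(p * (1.0 - p)) / (length / 2.0)) ** 2))


def clopper_pearson(successes: int, trials: int) -> tuple[float, float]:
    """Exact 95% binomial confidence interval (Beta quantiles)."""
    if trials <= 0:
        raise ValueError("trials must be positive")
    if not 0 <= successes <= trials:
        raise ValueError("successes must lie in [0, trials]")
    ci = stats.binomtest(successes, trials).proportion_ci(confidence_level=0.95, method="exact")
    return float(ci.low), float(ci.high)


def mc_interval_mean(values: Sequence[float]) -> tuple[float, tuple[float, float]]:
    """Mean with the MCSE-based 95% Monte Carlo interval, mean +/- z * sd/sqrt(n)."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("need at least 2 values for a Monte Carlo interval")
    m = float(arr.mean())
    mcse = float(arr.std(ddof=1) / np.sqrt(arr.size))
    return m, (m - Z_975 * mcse, m + Z_975 * mcse)


def _rate_record(flags: np.ndarray) -> dict:
    n = int(flags.size)
    k = int(flags.sum())
    lo, hi = clopper_pearson(k, n)
    return {"pct": 100.0 * k / n, "lo": 100.0 * lo, "hi": 100.0 * hi, "n": n}


@dataclass
class ScenarioPerformance:
    """Performance measures for one scenario of the study."""

    scenario: ScenarioConfig
    n_sim: int
    n_converged: int
    n_excluded: int
    n_degenerate: int
    #: tool -> {pct, lo, hi, n} for lack-of-overall-fit detection
    detect_overall: dict = field(default_factory=dict)
    #: tool -> {pair label -> {pct, lo, hi, n}}
    detect_pairwise: dict = field(default_factory=dict)
    #: parameter -> {mean, mean_lo, mean_hi, median, p2_5, p97_5, mean_abs}
    bias: dict = field(default_factory=dict)
    #: parameter -> {pct, lo, hi, n}
    coverage: dict = field(default_factory=dict)

    def to_row(self) -> dict:
        s = self.scenario
        row = {
            "label": s.label,
            "pi": s.prevalence,
            "omega": s.omega,
            "n_obs": s.n_obs,
            "n_sim": self.n_sim,
            "n_converged": self.n_converged,
            "n_excluded": self.n_excluded,
            "n_degenerate": self.n_degenerate,
        }
        for tool in TOOLS:
            rec = self.detect_overall[tool]
            row[f"overall_{tool}_pct"] = rec["pct"]
            row[f"overall_{tool}_lo"] = rec["lo"]
            row[f"overall_{tool}_hi"] = rec["hi"]
            for lab in PAIR_LABELS:
                prec = self.detect_pairwise[tool][lab]
                row[f"{tool}_{lab}_pct"] = prec["pct"]
                row[f"{tool}_{lab}_lo"] = prec["lo"]
                row[f"{tool}_{lab}_hi"] = prec["hi"]
        for name in PARAM_NAMES:
            b = self.bias[name]
            row[f"bias_mean_{name}"] = b["mean"]
            row[f"bias_median_{name}"] = b["median"]
            row[f"bias_mean_abs_{name}"] = b["mean_abs"]
            row[f"coverage_{name}"] = self.coverage[name]["pct"]
        return row


def aggregate_scenario(frame: pd.DataFrame, scenario: ScenarioConfig) -> ScenarioPerformance:
    """Aggregate one scenario's replicate-level table into performance measures.

    ``frame`` must carry the columns produced by the study runner: a
    ``converged`` flag, a ``degenerate`` flag, the tool flags, the 9
    ``est_*`` posterior medians and ``lo_*`` / ``hi_*`` CrI bounds.
    """
    n_sim = len(frame)
    conv = frame[frame["converged"].astype(bool)]
    n_converged = len(conv)
    n_excluded = n_sim - n_converged
    usable = conv[~conv["degenerate"].astype(bool)]
    n_degenerate = len(conv) - len(usable)
    if len(usable) == 0:
        raise ValueError(
            f"no converged, non-degenerate replicates for scenario {scenario.key}; "
            "no performance estimate is possible"
        )

    detect_overall: dict = {}
    detect_pairwise: dict = {}
    for tool in TOOLS:
        detect_overall[tool] = _rate_record(usable[_OVERALL_FLAG[tool]].to_numpy(bool))
        detect_pairwise[tool] = {
            lab: _rate_record(usable[f"{_PAIR_FLAG[tool]}_{lab}"].to_numpy(bool))
            for lab in PAIR_LABELS
        }

    truth = dict(zip(PARAM_NAMES, scenario.params))
    bias: dict = {}
    coverage: dict = {}
    for name in PARAM_NAMES:
        b = usable[f"est_{name}"].to_numpy(float) - truth[name]
        mean, (mlo, mhi) = mc_interval_mean(b)
        bias[name] = {
            "mean": mean,
            "mean_lo": mlo,
            "mean_hi": mhi,
            "median": float(np.median(b)),
            "p2_5": float(np.quantile(b, 0.025)),
            "p97_5": float(np.quantile(b, 0.975)),
            "mean_abs": float(np.abs(b).mean()),
        }
        covered = (usable[f"lo_{name}"].to_numpy(float) <= truth[name]) & (
            truth[name] <= usable[f"hi_{name}"].to_numpy(float)
        )
        coverage[name] = _rate_record(covered)

    return ScenarioPerformance(
        scenario=scenario,
        n_sim=n_sim,
        n_converged=n_converged,
        n_excluded=n_excluded,
        n_degenerate=n_degenerate,
        detect_overall=detect_overall,
        detect_pairwise=detect_pairwise,
        bias=bias,
        coverage=coverage,
    )


_GROUPERS = {"all": None, "pi": "pi_true", "omega": "omega", "n_obs": "n_obs"}


def aggregate_across_scenarios(
    frame: pd.DataFrame, grouping: str = "all"
) -> pd.DataFrame:
    """Pool replicate-level results across scenarios.

    ``grouping`` is one of ``"all"``, ``"pi"``, ``"omega"``, ``"n_obs"``.
    Pooling operates on the flat replicate table restricted to converged,
    non-degenerate replicates ("across all converged data sets"), not on
    scenario-level summaries. Returns one row per group with detection
    percentages (Clopper-Pearson CIs) and bias medians with 2.5th / 97.5th
    percentiles per parameter. Bias columns require the replicate table to
    carry ``bias_*`` columns (truth-dependent, added by the study runner).
    """
    if grouping not in _GROUPERS:
        raise ValueError(f"grouping must be one of {sorted(_GROUPERS)}, got {grouping!r}")
    usable = frame[frame["converged"].astype(bool) & ~frame["degenerate"].astype(bool)]
    if len(usable) == 0:
        raise ValueError("no converged, non-degenerate replicates to pool")

    if grouping == "all":
        groups = [("all", usable)]
    else:
        col = _GROUPERS[grouping]
        groups = [(f"{grouping}={key:g}", sub) for key, sub in usable.groupby(col)]

    rows = []
    for name, sub in groups:
        row: dict = {"group": name, "n_replicates": len(sub)}
        for tool in TOOLS:
            rec = _rate_record(sub[_OVERALL_FLAG[tool]].to_numpy(bool))
            row[f"overall_{tool}_pct"] = rec["pct"]
            row[f"overall_{tool}_lo"] = rec["lo"]
            row[f"overall_{tool}_hi"] = rec["hi"]
            for lab in PAIR_LABELS:
                prec = _rate_record(sub[f"{_PAIR_FLAG[tool]}_{lab}"].to_numpy(bool))
                row[f"{tool}_{lab}_pct"] = prec["pct"]
                row[f"{tool}_{lab}_lo"] = prec["lo"]
                row[f"{tool}_{lab}_hi"] = prec["hi"]
        for pname in PARAM_NAMES:
            col = f"bias_{pname}"
            if col in sub.columns:
                b = sub[col].to_numpy(float)
                row[f"bias_median_{pname}"] = float(np.median(b))
                row[f"bias_p2_5_{pname}"] = float(np.quantile(b, 0.025))
                row[f"bias_p97_5_{pname}"] = float(np.quantile(b, 0.975))
        rows.append(row)
    return pd.DataFrame(rows)
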