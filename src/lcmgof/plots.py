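"""Diagnostic figures: residual correlation plots and bias jitter plots."""

from __future__ import annotations

from typing import Optional, Sequence

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .gibbs import PARAM_NAMES
from .gof import FitAssessment
from .simulate import PAIR_LABELS

__all__ = ["residual_correlation_plot", "bias_jitter_plot"]


def residual_correlation_plot(assessment: FitAssessment, ax: Optional[plt.Axes] = None) -> plt.Axes:
    """Six posterior-median residual correlations with 95% CrIs and a zero line.

    Pairs whose interval excludes zero are drawn filled; this is the visual
    the 'residual plot' lack-of-fit tool formalizes.
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    x = np.arange(6)
    med = assessment.residual_corr_median
    lo = med - assessment.residual_corr_cri[:, 0]
    hi = assessment.residual_corr_cri[:, 1] - med
    ax.axhline(0.0, color="grey", lw=1, ls="--")
    for k in range(6):
        flagged = bool(assessment.pairwise_flags[k])
        ax.errorbar(
            x[k], med[k], yerr=[[lo[k]], [hi[k]]],
            fmt="o", color="C3" if flagged else "C0",
            mfc="C3" if flagged else "white", capsize=3,
        )
    ax.set_xticks(x, PAIR_LABELS)
    ax.set_ylabel("residual correlation")
    ax.set_xlabel("test pair")
    return ax


def bias_jitter_plot(
    frame: pd.DataFrame,
    params: Sequence[str] = PARAM_NAMES,
    ax: Optional[plt.Axes] = None,
    seed: int = 0,
) -> plt.Axes:
    """Per-parameter bias of each replicate as jittered points.

    Grey markers give the median with 2.5th-97.5th percentile bars. The
    ``frame`` is a replicate table carrying ``bias_*`` columns, restricted
    to converged replicates by the caller if desired.
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4))
    rng = np.random.default_rng(seed)
    for k, name in enumerate(params):
        col = f"bias_{name}"
        if col not in frame.columns:
            raise ValueError(f"frame lacks column {col!r}")
        b = frame[col].to_numpy(float)
        jitter = rng.uniform(-0.25, 0.25, b.size)
        ax.plot(k + jitter, b, ".", ms=3, alpha=0.4,
                color={"pi": "C0"}.get(name, "C2" if name.startswith("sp") else "C6"))
        med = np.median(b)
        qlo, qhi = np.quantile(b, [0.025, 0.975])
        ax.errorbar(k, med, yerr=[[med - qlo], [qhi - med]], fmt="o", color="grey", capsize=3)
    ax.axhline(0.0, color="k", lw=0.8)
    ax.set_xticks(range(len(params)), params)
    ax.set_ylabel("bias (posterior median - truth)")
    return ax
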