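"""Exact pattern probabilities and multinomial simulation.

Four binary diagnostic tests on each subject give 2**4 = 16 possible result
patterns. A pattern ``(t1, t2, t3, t4)`` is stored at index
``k = 8*t1 + 4*t2 + 2*t3 + t4`` (test 1 most significant); this convention
is shared by every module downstream.

Two latent-class models over these patterns:

* the conditional-independence (CInd) model — tests mutually independent
  given true disease status D, parameters (pi, Se1..4, Sp1..4);
* the conditional-dependence (CDep) data-generating model — identical except
  for one positive covariance ``covse12`` between tests 1 and 2 within the
  diseased class, added when t1 == t2 and subtracted when t1 != t2.

Data sets are a single multinomial draw of size ``n_obs`` over the 16
pattern probabilities, kept as the 16-cell count vector (the sufficient
statistic for everything downstream).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence, Union

import numpy as np

from .scenarios import ScenarioConfig, max_covariance

__all__ = [
    "PATTERNS",
    "PAIRS",
    "PAIR_LABELS",
    "PatternCounts",
    "cind_pattern_probs",
    "cdep_pattern_probs",
    "implied_correlation",
    "simulate_dataset",
    "agreement_probabilities",
]

#: PATTERNS[k, i] = t_{i+1} for pattern index k = 8 t1 + 4 t2 + 2 t3 + t4.
PATTERNS = np.array(
    [[(k >> 3) & 1, (k >> 2) & 1, (k >> 1) & 1, k & 1] for k in range(16)], dtype=np.int64
)

#: Test pairs in reporting order (0-based indices).
PAIRS = ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3))
PAIR_LABELS = tuple(f"T{i + 1}xT{j + 1}" for i, j in PAIRS)


@dataclass
class PatternCounts:
    """Counts of the 16 test-result patterns for one simulated data set."""

    counts: np.ndarray
    seed_info: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (16,):
            raise ValueError(f"counts must have shape (16,), got {self.counts.shape}")
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")

    @property
    def n_obs(self) -> int:
        return int(self.counts.sum())


CountsLike = Union[PatternCounts, Sequence[int], np.ndarray]


def as_counts_array(counts: CountsLike) -> np.ndarray:
    arr = counts.counts if isinstance(counts, PatternCounts) else np.asarray(counts)
    if arr.shape != (16,):
        raise ValueError(f"expected 16 pattern counts, got shape {arr.shape}")
    return arr


def _class_products(values: np.ndarray, tests: Sequence[int]) -> np.ndarray:
    """prod_i v_i^t_i (1-v_i)^(1-t_i) over the given tests, for all 16 patterns."""
    out = np.ones(16)
    for i in tests:
        out *= np.where(PATTERNS[:, i] == 1, values[i], 1.0 - values[i])
    return out


def cind_pattern_probs(
    prevalence: float,
    sensitivities: Sequence[float],
    specificities: Sequence[float],
) -> np.ndarray:
    """Pattern probabilities under the conditional-independence model.

    P(t) = pi * prod Se_i^t_i (1-Se_i)^(1-t_i)
         + (1-pi) * prod Sp_i^(1-t_i) (1-Sp_i)^t_i
    """
    se = np.asarray(sensitivities, dtype=float)
    sp = np.asarray(specificities, dtype=float)
    if not 0.0 < prevalence < 1.0:
        raise ValueError(f"prevalence must be in (0, 1), got {prevalence}")
    if se.shape != (4,) or sp.shape != (4,):
        raise ValueError("sensitivities and specificities must each have length 4")
    if not ((0 < se) & (se < 1)).all() or not ((0 < sp) & (sp < 1)).all():
        raise ValueError("all sensitivities and specificities must lie in (0, 1)")
    diseased = _class_products(se, range(4))
    healthy = _class_products(1.0 - sp, range(4))  # P(T_i=1 | D=0) = 1 - Sp_i
    return prevalence * diseased + (1.0 - prevalence) * healthy


def cdep_pattern_probs(scenario: ScenarioConfig) -> np.ndarray:
    """Pattern probabilities under the conditional-dependence model.

    Within the diseased class the product over tests 1-2 is shifted by
    ``(-1)^(t1 - t2) * covse12``: the covariance is added when the first two
    tests agree and subtracted when they disagree. Tests 3-4 and the whole
    disease-free class stay conditionally independent.
    """
    se = np.asarray(scenario.sensitivities, dtype=float)
    sp = np.asarray(scenario.specificities, dtype=float)
    pi = scenario.prevalence
    cov = scenario.covse12
    if cov > max_covariance(se[0], se[1]) + 1e-12:
        raise ValueError("covse12 exceeds the admissible covariance bound")

    sign = np.where(PATTERNS[:, 0] == PATTERNS[:, 1], 1.0, -1.0)
    dep12 = _class_products(se, (0, 1)) + sign * cov
    diseased = dep12 * _class_products(se, (2, 3))
    healthy = _class_products(1.0 - sp, range(4))
    probs = pi * diseased + (1.0 - pi) * healthy

    bad = np.where(probs < -1e-12)[0]
    if bad.size:
        k = int(bad[0])
        raise ValueError(
            f"negative probability for pattern {tuple(PATTERNS[k])} (index {k}); "
            "the covariance bound is violated"
        )
    return np.clip(probs, 0.0, 1.0)


def implied_correlation(scenario: ScenarioConfig) -> float:
    """Conditional Pearson correlation between T1 and T2 given D=1.

    covse12 / sqrt(Se1 (1-Se1) Se2 (1-Se2)); equals ``omega`` whenever
    Se1 == Se2.
    """
    se1, se2 = scenario.sensitivities[:2]
    return scenario.covse12 / np.sqrt(se1 * (1 - se1) * se2 * (1 - se2))


def simulate_dataset(
    scenario: ScenarioConfig,
    rng: Union[np.random.Generator, int, np.random.SeedSequence],
) -> PatternCounts:
    """One multinomial draw of size ``n_obs`` over the CDep pattern probabilities."""
    seed_info: dict = {}
    if not isinstance(rng, np.random.Generator):
        seed_info["seed"] = repr(rng)
        rng = np.random.default_rng(rng)
    probs = cdep_pattern_probs(scenario)
    counts = rng.multinomial(scenario.n_obs, probs)
    seed_info["scenario"] = scenario.key
    return PatternCounts(counts, seed_info=seed_info)


def agreement_probabilities(source: CountsLike) -> np.ndarray:
    """P(T_i = T_j) for the six test pairs.

    ``source`` is either a vector of 16 pattern probabilities or pattern
    counts (counts are normalized to proportions). For each pair the eight
    patterns with t_i == t_j are summed.
    """
    if isinstance(source, PatternCounts):
        vec = source.counts / source.n_obs
    else:
        vec = np.asarray(source, dtype=float)
        if vec.shape != (16,):
            raise ValueError(f"expected 16 entries, got shape {vec.shape}")
        total = vec.sum()
        if total <= 0:
            raise ValueError("source must have positive total mass")
        if not np.isclose(total, 1.0):
            vec = vec / total  # counts given as a plain array
    out = np.empty(6)
    for p, (i, j) in enumerate(PAIRS):
        out[p] = vec[PATTERNS[:, i] == PATTERNS[:, j]].sum()
    return out
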