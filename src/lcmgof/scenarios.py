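"""Scenario grid for the conditional-dependence simulation study.

A scenario is one point of the data-generating design: prevalence ``pi``,
four sensitivities, four specificities, the dependence fraction ``omega``
(the fraction of the maximum admissible covariance between tests 1 and 2
within the diseased class), and the sample size ``n_obs``.

Sensitivities and specificities take two levels, High (0.9) and Low (0.6),
combined according to the study design: six sensitivity patterns (tests 1
and 2 always jointly high or jointly low) crossed with seven specificity
patterns. Together with three sample sizes, two prevalences and two values
of ``omega`` this yields the full 504-scenario grid.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "LEVELS",
    "SE_CODES",
    "SP_CODES",
    "PREVALENCES",
    "OMEGAS",
    "SAMPLE_SIZES",
    "ScenarioConfig",
    "max_covariance",
    "scenario_from_codes",
    "build_full_grid",
    "grid_to_frame",
]

#: Accuracy levels used by the study design.
LEVELS = {"H": 0.9, "L": 0.6}

#: Sensitivity patterns (Se1 Se2 Se3 Se4); tests 1 and 2 are jointly H or L.
SE_CODES = ("HHLL", "HHHL", "HHHH", "LLLL", "LLHL", "LLHH")

#: Specificity patterns (Sp1 Sp2 Sp3 Sp4); all combinations used in the study.
SP_CODES = ("HHLL", "HHHL", "HHHH", "LLLL", "LLHL", "LLHH", "LHLH")

PREVALENCES = (0.2, 0.5)
OMEGAS = (0.5, 0.9)
SAMPLE_SIZES = (500, 2000, 5000)


def max_covariance(se1: float, se2: float) -> float:
    """Upper bound of the within-diseased covariance between tests 1 and 2.

    The covariance term is bounded so that every test-result-pattern
    probability stays in [0, 1], giving ``min(se1, se2) - se1*se2``.
    """
    for name, v in (("se1", se1), ("se2", se2)):
        if not 0.0 < v < 1.0:
            raise ValueError(f"{name} must lie strictly in (0, 1), got {v}")
    return min(se1, se2) - se1 * se2


def _code_for(values: tuple[float, ...]) -> str:
    inv = {v: k for k, v in LEVELS.items()}
    try:
        return "".join(inv[v] for v in values)
    except KeyError:
        return "x" * len(values)


@dataclass(frozen=True)
class ScenarioConfig:
    """One point of the data-generating grid.

    Parameters
    ----------
    prevalence
        P(D=1), strictly in (0, 1).
    sensitivities, specificities
        Per-test P(T_i=1 | D=1) and P(T_i=0 | D=0), each strictly in (0, 1).
    omega
        Fraction of the maximum admissible covariance between tests 1 and 2
        within the diseased class, in [0, 1). When Se1 == Se2 it equals the
        conditional Pearson correlation between T1 and T2 given D=1.
    n_obs
        Number of study subjects.
    """

    prevalence: float
    sensitivities: tuple[float, float, float, float]
    specificities: tuple[float, float, float, float]
    omega: float
    n_obs: int
    label: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError(f"prevalence must be in (0, 1), got {self.prevalence}")
        object.__setattr__(self, "sensitivities", tuple(float(v) for v in self.sensitivities))
        object.__setattr__(self, "specificities", tuple(float(v) for v in self.specificities))
        for name, vec in (("sensitivities", self.sensitivities), ("specificities", self.specificities)):
            if len(vec) != 4:
                raise ValueError(f"{name} must have length 4")
            if not all(0.0 < v < 1.0 for v in vec):
                raise ValueError(f"all {name} must lie strictly in (0, 1), got {vec}")
        if not 0.0 <= self.omega < 1.0:
            raise ValueError(f"omega must lie in [0, 1), got {self.omega}")
        if self.n_obs < 1:
            raise ValueError(f"n_obs must be positive, got {self.n_obs}")
        if not self.label:
            code = f"{_code_for(self.sensitivities)}-{_code_for(self.specificities)}"
            object.__setattr__(self, "label", code)

    @property
    def covse12(self) -> float:
        """Within-diseased covariance between tests 1 and 2: omega x its bound."""
        se1, se2 = self.sensitivities[:2]
        return self.omega * max_covariance(se1, se2)

    @property
    def key(self) -> str:
        """File-system-safe unique identifier for the scenario."""
        return f"{self.label}_pi{self.prevalence:g}_om{self.omega:g}_n{self.n_obs}"

    @property
    def params(self) -> tuple[float, ...]:
        """The 9 conditional-independence parameters (pi, Se1..4, Sp1..4)."""
        return (self.prevalence, *self.sensitivities, *self.specificities)

    def with_omega(self, omega: float) -> "ScenarioConfig":
        return ScenarioConfig(self.prevalence, self.sensitivities, self.specificities, omega, self.n_obs)


def scenario_from_codes(
    se_code: str,
    sp_code: str,
    prevalence: float = 0.5,
    omega: float = 0.5,
    n_obs: int = 2000,
) -> ScenarioConfig:
    """Build a scenario from H/L letter codes, e.g. ``("HHHH", "HHLL")``."""
    for code in (se_code, sp_code):
        if len(code) != 4 or any(c not in LEVELS for c in code):
            raise ValueError(f"codes must be 4 letters from {sorted(LEVELS)}, got {code!r}")
    se = tuple(LEVELS[c] for c in se_code)
    sp = tuple(LEVELS[c] for c in sp_code)
    return ScenarioConfig(prevalence, se, sp, omega, n_obs)


def build_full_grid() -> list[ScenarioConfig]:
    """Enumerate the full study design: 3 x 2 x 6 x 7 x 2 = 504 scenarios."""
    grid = []
    for n_obs, pi, se_code, sp_code, omega in itertools.product(
        SAMPLE_SIZES, PREVALENCES, SE_CODES, SP_CODES, OMEGAS
    ):
        grid.append(scenario_from_codes(se_code, sp_code, pi, omega, n_obs))
    return grid


def grid_to_frame(scenarios: list[ScenarioConfig]) -> pd.DataFrame:
    """Flatten scenarios into one row each (exportable as CSV)."""
    rows = []
    for s in scenarios:
        row = {"label": s.label, "pi": s.prevalence}
        row.update({f"se{i + 1}": v for i, v in enumerate(s.sensitivities)})
        row.update({f"sp{i + 1}": v for i, v in enumerate(s.specificities)})
        row.update({"omega": s.omega, "covse12": s.covse12, "n_obs": s.n_obs})
        rows.append(row)
    return pd.DataFrame(rows)
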