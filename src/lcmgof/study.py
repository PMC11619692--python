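"""End-to-end study orchestration: simulate -> fit -> assess -> aggregate.

A run is fully determined by a :class:`StudyConfig` (scenario list,
replicates per scenario, MCMC settings, root seed). Every source of
randomness derives from the root seed through ``numpy.random.SeedSequence``
keyed by (scenario index, replicate index) for data simulation and by
(scenario index, chunk index) for the batched Gibbs fits, so reruns are
byte-identical and completed scenarios can be skipped on resume.

Replicates are fitted in chunks: the chains of ``chunk_size`` data sets are
advanced together as one vectorized sampler state. Replicate accounting
distinguishes ``converged`` (passed the R-hat / effective-sample-size
screen), ``excluded`` (failed it) and ``degenerate`` (a test with zero
observed variance, making residual correlations undefined).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .gibbs import PARAM_NAMES, McmcSettings, PosteriorDraws, gibbs_fit_batch, summarize_posterior
from .gof import DegenerateMarginError, assess_fit
from .performance import ScenarioPerformance, aggregate_scenario
from .scenarios import ScenarioConfig, build_full_grid, grid_to_frame, scenario_from_codes
from .simulate import PAIR_LABELS, agreement_probabilities, cdep_pattern_probs, cind_pattern_probs, simulate_dataset

__all__ = [
    "StudyConfig",
    "PRESETS",
    "preset_scenario",
    "run_scenario",
    "run_study",
    "run_agreement_table",
]

logger = logging.getLogger("lcmgof")

#: Named desk-scale scenarios matching rows of the study's result tables
#: (all at pi = 0.5, omega = 0.5, n_obs = 2000).
PRESETS = {
    "table6-LLHH-LLHH": ("LLHH", "LLHH"),
    "table6-HHHH-HHHH": ("HHHH", "HHHH"),
    "table4-HHHH-HHLL": ("HHHH", "HHLL"),
}


def preset_scenario(name: str) -> ScenarioConfig:
    """Resolve a named preset to its scenario."""
    try:
        se_code, sp_code = PRESETS[name]
    except KeyError:
        raise ValueError(f"unknown preset {name!r}; available: {sorted(PRESETS)}") from None
    return scenario_from_codes(se_code, sp_code, prevalence=0.5, omega=0.5, n_obs=2000)


@dataclass
class StudyConfig:
    """Configuration of one simulation-study run."""

    scenarios: list[ScenarioConfig]
    n_sim: int = 1000
    mcmc: McmcSettings = field(default_factory=McmcSettings)
    root_seed: int = 0
    output_dir: Optional[Path] = None
    chunk_size: int = 50

    def __post_init__(self) -> None:
        if self.n_sim < 1:
            raise ValueError("n_sim must be at least 1")
        if self.chunk_size < 1:
            raise ValueError("chunk_size must be at least 1")
        if not self.scenarios:
            raise ValueError("at least one scenario is required")
        if self.output_dir is not None:
            self.output_dir = Path(self.output_dir)

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "StudyConfig":
        """Load a config; scenarios given as preset names, H/L code pairs or
        'full-grid'."""
        raw = yaml.safe_load(Path(path).read_text())
        scenarios: list[ScenarioConfig] = []
        spec = raw.get("scenarios", "full-grid")
        if spec == "full-grid":
            scenarios = build_full_grid()
        else:
            for item in spec:
                if isinstance(item, str):
                    scenarios.append(preset_scenario(item))
                else:
                    scenarios.append(
                        scenario_from_codes(
                            item["se"],
                            item["sp"],
                            prevalence=item.get("pi", 0.5),
                            omega=item.get("omega", 0.5),
                            n_obs=item.get("n_obs", 2000),
                        )
                    )
        mcmc = McmcSettings(**raw.get("mcmc", {}))
        return cls(
            scenarios=scenarios,
            n_sim=raw.get("n_sim", 1000),
            mcmc=mcmc,
            root_seed=raw.get("root_seed", 0),
            output_dir=raw.get("output_dir"),
            chunk_size=raw.get("chunk_size", 50),
        )


def _sim_rng(root_seed: int, scen_index: int, rep: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((root_seed, scen_index, rep, 0)))


def _fit_rng(root_seed: int, scen_index: int, chunk: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((root_seed, scen_index, chunk, 1)))


def _replicate_row(
    scenario: ScenarioConfig,
    rep: int,
    fit: PosteriorDraws,
) -> dict:
    """One flat replicate record: identifiers, diagnostics, estimates, flags."""
    row: dict = {
        "label": scenario.label,
        "key": scenario.key,
        "pi_true": scenario.prevalence,
        "omega": scenario.omega,
        "n_obs": scenario.n_obs,
        "rep": rep,
        "converged": fit.converged,
        "rhat_max": float(fit.rhat.max()),
        "neff_min": float(fit.n_eff.min()),
        "degenerate": False,
    }
    return row


def run_scenario(
    scenario: ScenarioConfig,
    n_sim: int,
    mcmc: Optional[McmcSettings] = None,
    root_seed: int = 0,
    scen_index: int = 0,
    chunk_size: int = 50,
) -> pd.DataFrame:
    """Simulate, fit and assess ``n_sim`` replicates of one scenario.

    Returns the replicate-level table (one row per simulated data set) with
    convergence diagnostics, posterior summaries, per-parameter bias and
    CrI-coverage indicators, and all tool flags.
    """
    mcmc = mcmc or McmcSettings()
    truth = dict(zip(PARAM_NAMES, scenario.params))
    rows: list[dict] = []
    for start in range(0, n_sim, chunk_size):
        reps = range(start, min(start + chunk_size, n_sim))
        datasets = [simulate_dataset(scenario, _sim_rng(root_seed, scen_index, r)) for r in reps]
        counts_mat = np.stack([d.counts for d in datasets])
        fits = gibbs_fit_batch(counts_mat, mcmc, _fit_rng(root_seed, scen_index, start // chunk_size))
        for d, rep, fit in zip(datasets, reps, fits):
            row = _replicate_row(scenario, rep, fit)
            summary = summarize_posterior(fit)
            try:
                assessment = assess_fit(d, fit, summary=summary)
                row.update(assessment.to_row())
            except DegenerateMarginError:
                row["degenerate"] = True
                row.update(summary.to_dict())
            for name in PARAM_NAMES:
                if f"est_{name}" in row:
                    row[f"bias_{name}"] = row[f"est_{name}"] - truth[name]
                    row[f"cover_{name}"] = row[f"lo_{name}"] <= truth[name] <= row[f"hi_{name}"]
            rows.append(row)
        logger.info("%s: %d/%d replicates done", scenario.key, reps.stop, n_sim)
    frame = pd.DataFrame(rows)
    n_excl = int((~frame["converged"]).sum())
    n_degen = int(frame["degenerate"].sum())
    if n_excl or n_degen:
        logger.info("%s: %d excluded (convergence), %d degenerate", scenario.key, n_excl, n_degen)
    return frame


def run_study(config: StudyConfig) -> tuple[pd.DataFrame, list[ScenarioPerformance]]:
    """Run every scenario of a config; optionally persist and resume.

    With ``output_dir`` set, writes ``grid.csv``, one
    ``replicates_<key>.csv`` per scenario (skipped and reloaded when already
    present with the expected row count — resumability), a pooled
    ``replicates.csv``, ``scenario_summary.csv`` and ``config.json``.
    Returns the pooled replicate table and per-scenario performance.
    """
    out = config.output_dir
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        grid_to_frame(config.scenarios).to_csv(out / "grid.csv", index=False)
        (out / "config.json").write_text(
            json.dumps(
                {
                    "n_sim": config.n_sim,
                    "root_seed": config.root_seed,
                    "chunk_size": config.chunk_size,
                    "mcmc": config.mcmc.__dict__,
                    "scenarios": [s.key for s in config.scenarios],
                },
                indent=2,
            )
        )

    frames = []
    performances = []
    for idx, scenario in enumerate(config.scenarios):
        path = None if out is None else out / f"replicates_{scenario.key}.csv"
        if path is not None and path.exists():
            frame = pd.read_csv(path)
            if len(frame) == config.n_sim:
                logger.info("%s: resuming from %s", scenario.key, path)
                frames.append(frame)
                performances.append(aggregate_scenario(frame, scenario))
                continue
        frame = run_scenario(
            scenario,
            config.n_sim,
            mcmc=config.mcmc,
            root_seed=config.root_seed,
            scen_index=idx,
            chunk_size=config.chunk_size,
        )
        if path is not None:
            frame.to_csv(path, index=False)
        frames.append(frame)
        performances.append(aggregate_scenario(frame, scenario))

    pooled = pd.concat(frames, ignore_index=True)
    if out is not None:
        pooled.to_csv(out / "replicates.csv", index=False)
        pd.DataFrame([p.to_row() for p in performances]).to_csv(
            out / "scenario_summary.csv", index=False
        )
    return pooled, performances


def run_agreement_table(
    scenarios: Sequence[ScenarioConfig],
    fitted_params: Optional[dict] = None,
) -> pd.DataFrame:
    """Analytic pairwise agreement probabilities per scenario.

    For each scenario: the 'observed' row (exact agreement under the
    conditional-dependence generating model) and the 'true CInd' row (the
    same parameters with the covariance removed). When ``fitted_params``
    maps a scenario key to a 9-vector of posterior medians, a 'fitted' row
    is added.
    """
    rows = []
    for s in scenarios:
        obs = agreement_probabilities(cdep_pattern_probs(s))
        cind = agreement_probabilities(
            cind_pattern_probs(s.prevalence, s.sensitivities, s.specificities)
        )
        for kind, vals in (("observed", obs), ("true_cind", cind)):
            rows.append({"key": s.key, "label": s.label, "kind": kind,
                         **{lab: v for lab, v in zip(PAIR_LABELS, vals)}})
        if fitted_params and s.key in fitted_params:
            p = np.asarray(fitted_params[s.key], dtype=float)
            fit = agreement_probabilities(cind_pattern_probs(p[0], p[1:5], p[5:9]))
            rows.append({"key": s.key, "label": s.label, "kind": "fitted",
                         **{lab: v for lab, v in zip(PAIR_LABELS, fit)}})
    return pd.DataFrame(rows)
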