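"""Internal glue: evaluate a full config through dose weighting, the cohort
engine and the CEA comparison."""

from __future__ import annotations

from .cea import CEAComparison, compare
from .config import AnalysisConfig
from .dose import resolve_strategy
from .engine import CohortTrajectory, StrategyResult, run_cohort

__all__ = ["evaluate_config", "run_strategies"]


def run_strategies(
    config: AnalysisConfig,
) -> dict[str, tuple[CohortTrajectory, StrategyResult]]:
    """Resolve and simulate every strategy in the config."""
    out = {}
    for strat in config.strategies:
        resolved = resolve_strategy(config, strat)
        out[strat.name] = run_cohort(resolved, config.economics)
    return out


def evaluate_config(config: AnalysisConfig) -> CEAComparison:
    """Full pipeline: dose weighting -> cohort engine -> CEA comparison."""
    runs = run_strategies(config)
    return compare([(name, res) for name, (_, res) in runs.items()], config.economics)
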