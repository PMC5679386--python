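"""Model/Results facade over the analysis pipeline.

:class:`CostEffectivenessAnalysis` wraps a validated configuration;
``fit()`` evaluates it — dose weighting, cohort simulation per strategy,
CEA comparison — and returns a :class:`CEAResults` carrying per-strategy
trajectories and totals, the comparison table and a text ``summary()``.
Sensitivity analyses (one-way sweeps, tornado, thresholds) hang off the
results object since they re-run the same pipeline around the fitted
baseline.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd

from .cea import CEAComparison
from .config import AnalysisConfig, load_config, loads_config
from .engine import CohortTrajectory, StrategyResult
from .pipeline import evaluate_config, run_strategies
from .sensitivity import (
    ParamPath,
    SensitivityRange,
    ThresholdResult,
    TornadoEntry,
    find_threshold,
    one_way_sweep,
    tornado,
)

__all__ = ["CostEffectivenessAnalysis", "CEAResults"]


class CostEffectivenessAnalysis:
    """A configured multi-strategy cost-effectiveness model.

    Parameters
    ----------
    config
        Validated :class:`AnalysisConfig` (see :func:`radcea.load_config`).
    """

    def __init__(self, config: AnalysisConfig):
        self.config = config

    @classmethod
    def from_file(cls, path: str | Path) -> "CostEffectivenessAnalysis":
        """Build from a JSON or YAML config file."""
        return cls(load_config(path))

    @classmethod
    def from_yaml(cls, text: str) -> "CostEffectivenessAnalysis":
        """Build from a YAML config string."""
        return cls(loads_config(text))

    def fit(self) -> "CEAResults":
        """Evaluate the model: simulate every strategy and compare them."""
        runs = run_strategies(self.config)
        comparison = evaluate_config(self.config)
        return CEAResults(self, runs, comparison)


class CEAResults:
    """Fitted results: trajectories, lifetime totals and the comparison."""

    def __init__(
        self,
        model: CostEffectivenessAnalysis,
        runs: dict[str, tuple[CohortTrajectory, StrategyResult]],
        comparison: CEAComparison,
    ):
        self.model = model
        self.trajectories: dict[str, CohortTrajectory] = {k: t for k, (t, _) in runs.items()}
        self.strategy_results: dict[str, StrategyResult] = {k: r for k, (_, r) in runs.items()}
        self.comparison = comparison

    # -- tabular views -------------------------------------------------------

    def to_frame(self, rounded: bool = False) -> pd.DataFrame:
        return self.comparison.to_frame(rounded=rounded)

    def summary(self) -> str:
        """Plain-text summary in the style of a results table."""
        econ = self.model.config.economics
        frame = self.to_frame(rounded=True)
        lines = [
            "Cost-effectiveness comparison",
            "=" * 64,
            f"willingness to pay: ${econ.wtp:,.0f}/QALY   horizon: {econ.horizon} years",
            f"discount rates: costs {econ.discount_rate_cost:.1%}/yr, "
            f"utilities {econ.discount_rate_utility:.1%}/yr",
            "-" * 64,
            frame.to_string(index=False),
            "-" * 64,
            f"classification ({self.comparison.names[0]} vs {self.comparison.names[1]}): "
            f"{self.comparison.classification}",
            f"preferred by NMB: {self.comparison.preferred_by_nmb}",
        ]
        if self.comparison.icer is not None:
            lines.append(f"ICER: ${self.comparison.icer:,.0f}/QALY")
        lines.append(
            "display rounding: dollars to nearest $1, QALYs to 2 dp; "
            "internal arithmetic is full precision"
        )
        return "\n".join(lines)

    # -- sensitivity ---------------------------------------------------------

    def one_way(self, rng: SensitivityRange) -> list[tuple[float, dict[str, float]]]:
        return one_way_sweep(self.model.config, rng)

    def tornado(self, ranges: Sequence[SensitivityRange]) -> list[TornadoEntry]:
        return tornado(self.model.config, ranges)

    def threshold(
        self,
        param_path: ParamPath,
        bounds: tuple[float, float],
        tolerance: float | None = None,
    ) -> ThresholdResult:
        return find_threshold(self.model.config, param_path, bounds, tolerance)

    # -- plotting ------------------------------------------------------------

    def plot_tornado(self, entries: Sequence[TornadoEntry], path: str | Path):
        """Horizontal-bar tornado diagram saved to ``path``."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        entries = list(entries)[::-1]  # widest bar on top
        base = self.comparison.table[self.comparison.preferred_by_nmb]["nmb"]
        fig, ax = plt.subplots(figsize=(8, 0.6 * len(entries) + 1.5))
        for i, e in enumerate(entries):
            lo, hi = sorted((e.nmb_at_low, e.nmb_at_high))
            ax.barh(i, hi - lo, left=lo, color="#4878d0", edgecolor="black")
        ax.axvline(base, color="black", lw=1, ls="--")
        ax.set_yticks(range(len(entries)))
        ax.set_yticklabels([e.label for e in entries])
        ax.set_xlabel(f"NMB of {self.comparison.preferred_by_nmb} (USD)")
        ax.set_title("One-way sensitivity (tornado)")
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)
        return Path(path)
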