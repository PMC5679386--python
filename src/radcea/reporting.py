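"""Report assembly and budget-impact arithmetic.

``run_analysis`` writes the full report bundle for a config: the
results-table-shaped comparison (CSV and Markdown), per-strategy trajectory
CSVs, tornado and threshold tables, a budget-impact summary and a run log
(config hash, seed, package version).  ``budget_impact`` is the national
budget projection: annual cases x per-patient saving.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from .config import AnalysisConfig, config_digest
from .model import CEAResults, CostEffectivenessAnalysis
from .sensitivity import SensitivityRange, ThresholdResult

logger = logging.getLogger("radcea")

__all__ = ["BudgetImpactInputs", "budget_impact", "run_analysis", "ReportBundle"]

ROUNDING_FOOTER = (
    "Display rounding: dollars to the nearest $1, QALYs to 2 decimal places; "
    "all arithmetic is carried at full precision, so displayed NMB may differ "
    "from WTP x displayed QALYs - displayed cost by a few dollars."
)


class BudgetImpactInputs(BaseModel):
    """National annual caseload and per-patient cost deltas."""

    model_config = ConfigDict(extra="forbid")

    annual_cases: float = Field(ge=0)
    per_patient_saving: float = Field(default=0.0, ge=0)
    per_patient_indirect_delta: float = Field(default=0.0, ge=0)


def budget_impact(inputs: BudgetImpactInputs) -> dict[str, float]:
    """Annual system-wide totals: cases x per-patient direct / indirect delta."""
    return {
        "direct_total": inputs.annual_cases * inputs.per_patient_saving,
        "indirect_total": inputs.annual_cases * inputs.per_patient_indirect_delta,
    }


def _markdown_table(frame: pd.DataFrame) -> str:
    cols = list(frame.columns)
    lines = ["| " + " | ".join(cols) + " |", "| " + " | ".join("---" for _ in cols) + " |"]
    for _, row in frame.iterrows():
        lines.append("| " + " | ".join(str(row[c]) for c in cols) + " |")
    return "\n".join(lines)


@dataclass(frozen=True)
class ReportBundle:
    """Paths of everything run_analysis wrote."""

    output_dir: Path
    comparison_csv: Path
    comparison_md: Path
    trajectory_csvs: dict[str, Path]
    tornado_csv: Optional[Path]
    threshold_csv: Optional[Path]
    budget_json: Optional[Path]
    log_path: Path
    results: CEAResults


def run_analysis(
    config: AnalysisConfig | str | Path,
    output_dir: str | Path,
    *,
    tornado_ranges: Sequence[SensitivityRange] | None = None,
    thresholds: Sequence[tuple[SensitivityRange, ThresholdResult]] | None = None,
    budget: BudgetImpactInputs | None = None,
    seed: int | None = None,
) -> ReportBundle:
    """Evaluate a config and write the report bundle into ``output_dir``."""
    if not isinstance(config, AnalysisConfig):
        model = CostEffectivenessAnalysis.from_file(config)
    else:
        model = CostEffectivenessAnalysis(config)
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)

    results = model.fit()
    raw = results.to_frame(rounded=False)
    disp = results.to_frame(rounded=True)

    comparison_csv = out / "comparison.csv"
    raw.to_csv(comparison_csv, index=False)
    comparison_md = out / "comparison.md"
    md = [
        "# Cost-effectiveness comparison",
        "",
        _markdown_table(disp),
        "",
        f"Classification: **{results.comparison.classification}** "
        f"({results.comparison.names[0]} vs {results.comparison.names[1]}); "
        f"preferred by NMB: **{results.comparison.preferred_by_nmb}**.",
        "",
        ROUNDING_FOOTER,
    ]
    comparison_md.write_text("\n".join(md))

    trajectory_csvs = {}
    for name, traj in results.trajectories.items():
        p = out / f"trajectory_{name}.csv"
        traj.to_frame().to_csv(p, index=False)
        trajectory_csvs[name] = p

    tornado_csv = None
    if tornado_ranges:
        entries = results.tornado(tornado_ranges)
        frame = pd.DataFrame(
            [
                {
                    "parameter": e.label,
                    "nmb_at_low": e.nmb_at_low,
                    "nmb_at_high": e.nmb_at_high,
                    "spread": e.spread,
                }
                for e in entries
            ]
        )
        tornado_csv = out / "tornado.csv"
        frame.to_csv(tornado_csv, index=False)
        (out / "tornado.md").write_text(
            "# Tornado (one-way NMB spreads)\n\n" + _markdown_table(frame) + "\n\n" + ROUNDING_FOOTER
        )

    threshold_csv = None
    if thresholds:
        frame = pd.DataFrame(
            [
                {
                    "parameter": rng.name,
                    "baseline": res.baseline_value,
                    "threshold": res.threshold if res.found else "none in range",
                    "preferred_below": res.preferred_below,
                    "preferred_above": res.preferred_above,
                    "tolerance": res.tolerance,
                }
                for rng, res in thresholds
            ]
        )
        threshold_csv = out / "thresholds.csv"
        frame.to_csv(threshold_csv, index=False)
        (out / "thresholds.md").write_text(
            "# NMB crossover thresholds\n\n" + _markdown_table(frame) + "\n\n" + ROUNDING_FOOTER
        )

    budget_json = None
    if budget is not None:
        budget_json = out / "budget_impact.json"
        budget_json.write_text(
            json.dumps({"inputs": budget.model_dump(), "totals": budget_impact(budget)}, indent=2)
        )

    from . import __version__

    log_path = out / "run_log.json"
    log_path.write_text(
        json.dumps(
            {
                "package": "radcea",
                "version": __version__,
                "config_sha256": config_digest(model.config),
                "seed": seed,
                "strategies": list(results.comparison.names),
                "preferred_by_nmb": results.comparison.preferred_by_nmb,
            },
            indent=2,
        )
    )
    logger.info("report bundle written to %s", out)
    return ReportBundle(
        output_dir=out,
        comparison_csv=comparison_csv,
        comparison_md=comparison_md,
        trajectory_csvs=trajectory_csvs,
        tornado_csv=tornado_csv,
        threshold_csv=threshold_csv,
        budget_json=budget_json,
        log_path=log_path,
        results=results,
    )
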