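"""Comparative cost-effectiveness outputs.

Turns per-strategy lifetime totals into the decision quantities: dominance
classification (a strategy dominates when it is at least as cheap and at
least as effective, strictly better on one axis), cost per QALY, the
incremental cost-effectiveness ratio (ICER, reported only for genuine
trade-off pairs), and net monetary benefit
NMB = total QALYs x willingness-to-pay - total cost.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .config import EconomicSettings
from .engine import StrategyResult
from .exceptions import ConfigReferenceError

__all__ = [
    "nmb",
    "cost_per_qaly",
    "classify_dominance",
    "compare",
    "CEAComparison",
]


def nmb(total_cost: float, total_qalys: float, wtp: float) -> float:
    """Net monetary benefit: total_qalys x wtp - total_cost (may be negative)."""
    return total_qalys * wtp - total_cost


def cost_per_qaly(total_cost: float, total_qalys: float) -> float:
    """Average cost per QALY gained; undefined at zero QALYs."""
    if total_qalys <= 0:
        raise ValueError(f"cost per QALY undefined for total_qalys={total_qalys}")
    return total_cost / total_qalys


def classify_dominance(a: StrategyResult, b: StrategyResult) -> str:
    """Classify a against b: 'dominant', 'dominated', 'tradeoff' or 'tie'.

    a dominates when it is no more costly and no less effective, with strict
    improvement on at least one axis (weak equality on one axis plus strict
    improvement on the other counts as dominance).
    """
    dc = a.total_cost - b.total_cost
    dq = a.total_qalys - b.total_qalys
    if dc == 0 and dq == 0:
        return "tie"
    if dc <= 0 and dq >= 0:
        return "dominant"
    if dc >= 0 and dq <= 0:
        return "dominated"
    return "tradeoff"


@dataclass(frozen=True)
class CEAComparison:
    """Full comparison across strategies at one willingness-to-pay.

    ``table`` holds per-strategy total_cost, total_qalys, cost_per_qaly and
    nmb at full precision.  Incremental quantities are second-listed minus
    first-listed strategy; the ICER is defined only for trade-off pairs.
    """

    wtp: float
    names: tuple[str, ...]
    table: dict[str, dict[str, float]]
    classification: str              # first-listed strategy vs second
    incremental_cost: float
    incremental_qalys: float
    icer: Optional[float]
    preferred_by_nmb: str

    def to_frame(self, rounded: bool = False) -> pd.DataFrame:
        """Results-table-shaped frame: Alternative, Direct cost, QALYs, Cost/QALY, NMB.

        With ``rounded=True`` dollars round to the nearest integer and QALYs
        to 2 decimal places (display convention; internal arithmetic is full
        precision).
        """
        rows = []
        for name in self.names:
            r = self.table[name]
            if rounded:
                rows.append(
                    {
                        "Alternative": name,
                        "Direct cost": round(r["total_cost"]),
                        "QALYs": round(r["total_qalys"], 2),
                        "Cost/QALY": round(r["cost_per_qaly"]),
                        "NMB": round(r["nmb"]),
                    }
                )
            else:
                rows.append(
                    {
                        "Alternative": name,
                        "Direct cost": r["total_cost"],
                        "QALYs": r["total_qalys"],
                        "Cost/QALY": r["cost_per_qaly"],
                        "NMB": r["nmb"],
                    }
                )
        return pd.DataFrame(rows)


def compare(
    results: Sequence[tuple[str, StrategyResult]] | Sequence[StrategyResult],
    econ: EconomicSettings,
) -> CEAComparison:
    """Compare two or more strategies at the configured willingness to pay.

    The pairwise classification and increments refer to the first two listed
    strategies; ``preferred_by_nmb`` is the NMB argmax over all of them.
    """
    pairs: list[tuple[str, StrategyResult]] = []
    for item in results:
        if isinstance(item, StrategyResult):
            pairs.append((item.name, item))
        else:
            pairs.append(item)
    if len(pairs) < 2:
        raise ValueError("compare requires at least two strategies")
    names = [n for n, _ in pairs]
    if len(set(names)) != len(names):
        raise ConfigReferenceError(f"duplicate strategy names in comparison: {names}")

    table = {
        name: {
            "total_cost": r.total_cost,
            "total_qalys": r.total_qalys,
            "cost_per_qaly": cost_per_qaly(r.total_cost, r.total_qalys),
            "nmb": nmb(r.total_cost, r.total_qalys, econ.wtp),
        }
        for name, r in pairs
    }
    (name_a, a), (name_b, b) = pairs[0], pairs[1]
    classification = classify_dominance(a, b)
    dc = b.total_cost - a.total_cost
    dq = b.total_qalys - a.total_qalys
    icer = dc / dq if classification == "tradeoff" and dq != 0 else None
    preferred = max(names, key=lambda n: table[n]["nmb"])
    return CEAComparison(
        wtp=econ.wtp,
        names=tuple(names),
        table=table,
        classification=classification,
        incremental_cost=dc,
        incremental_qalys=dq,
        icer=icer,
        preferred_by_nmb=preferred,
    )
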