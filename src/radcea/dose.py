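"""Radiation-dose weighting of long-term complications.

Organ doses (Gy to the heart, ipsilateral lung and contralateral breast) map
linearly — no threshold — onto excess probabilities of the three late
complications considered: major coronary events (MCE), lung cancer and
contralateral breast cancer.  The three complications are pooled into a
single long-term-complication health state whose life expectancy and costs
are incidence-weighted averages of the per-complication components; the
pooled total probability drives the transition into that state during the
late (>10-year) window.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .config import (
    AnalysisConfig,
    ComplicationComponent,
    ComplicationSettings,
    DoseProfile,
    HealthState,
    RiskCoefficients,
    StrategyModel,
    TransitionRule,
)
from .exceptions import ConfigReferenceError, ConfigValidationError, DegenerateWeightsError

__all__ = [
    "COMPLICATIONS",
    "ComplicationRisk",
    "complication_probabilities",
    "weighted_value",
    "pooled_complication_state",
    "resolve_strategy",
]

#: Canonical complication names, in (heart, lung, contralateral breast) order.
COMPLICATIONS = ("mce", "lung_cancer", "contralateral_breast_cancer")


@dataclass(frozen=True)
class ComplicationRisk:
    """Per-complication excess probabilities over the late window, plus total."""

    per_complication: dict[str, float]
    total: float


def complication_probabilities(
    dose: DoseProfile, coeff: RiskCoefficients, scale: float = 1.0
) -> ComplicationRisk:
    """Linear dose-to-risk mapping, clamped to [0, 1].

    probability_i = min(1, scale * coeff_i * dose_i); the total is the
    clamped sum.  ``scale`` is a sensitivity-analysis multiplier (default 1).
    """
    if scale < 0:
        raise ConfigValidationError(f"complication risk scale must be >= 0, got {scale}")
    raw = {
        "mce": coeff.mce_per_gy * dose.heart_gy,
        "lung_cancer": coeff.lung_cancer_per_gy * dose.ipsilateral_lung_gy,
        "contralateral_breast_cancer": coeff.contralateral_breast_cancer_per_gy
        * dose.contralateral_breast_gy,
    }
    per = {k: min(1.0, scale * v) for k, v in raw.items()}
    return ComplicationRisk(per_complication=per, total=min(1.0, sum(per.values())))


def weighted_value(components: Iterable[tuple[float, float]]) -> float:
    """Incidence-weighted mean: sum(value*weight) / sum(weight).

    Raises :class:`DegenerateWeightsError` when all weights are zero and
    :class:`ConfigValidationError` on a negative weight.
    """
    num = 0.0
    den = 0.0
    for value, weight in components:
        if weight < 0:
            raise ConfigValidationError(f"negative weight {weight} in weighted average")
        num += value * weight
        den += weight
    if den == 0.0:
        raise DegenerateWeightsError("all weights are zero; weighted mean undefined")
    return num / den


def pooled_complication_state(
    components: Sequence[ComplicationComponent],
    probabilities: Mapping[str, float],
    *,
    name: str = "long_term_complication",
    utility: float = 1.0,
    on_dwell_exit: str = "dead",
) -> HealthState:
    """Pool per-complication components into one dwell-limited health state.

    The state's dwell is the incidence-weighted life expectancy, its entry
    cost the weighted initial cost, its annual cost the weighted ongoing
    cost, and its exit cost the weighted last-year-of-life cost (charged to
    the mass leaving at the end of the dwell).
    """
    comp_names = {c.name for c in components}
    if comp_names != set(probabilities):
        raise ConfigReferenceError(
            f"complication sets differ: components {sorted(comp_names)} vs "
            f"probabilities {sorted(probabilities)}"
        )
    pairs = [(c, probabilities[c.name]) for c in components]
    dwell = weighted_value((c.life_expectancy, w) for c, w in pairs)
    return HealthState(
        name=name,
        utility=utility,
        annual_cost=weighted_value((c.ongoing_annual_cost, w) for c, w in pairs),
        entry_cost=weighted_value((c.initial_cost, w) for c, w in pairs),
        exit_cost=weighted_value((c.last_year_cost, w) for c, w in pairs),
        max_dwell=dwell,
        on_dwell_exit=on_dwell_exit,
    )


def resolve_strategy(config: AnalysisConfig, strategy: StrategyModel) -> StrategyModel:
    """Materialize a strategy for the cohort engine.

    Expands the event-risk block into explicit cumulative transition rules
    and, when the dose profile yields a positive pooled complication
    probability, injects the pooled long-term-complication state together
    with the cumulative transition into it over the late window.  The
    returned strategy has explicit states and transitions only.
    """
    states = list(strategy.states)
    transitions = list(strategy.transitions)
    if strategy.event_risk is not None:
        transitions.extend(strategy.event_risk.to_rules(strategy.initial_state))

    risk = complication_probabilities(
        strategy.dose, config.risk_coefficients, strategy.complication_risk_scale
    )
    if risk.total > 0.0:
        cs: ComplicationSettings = config.complication
        if not config.complication_components:
            raise ConfigValidationError(
                f"strategy {strategy.name!r}: dose implies complication risk "
                f"{risk.total:.4g} but no complication_components are configured"
            )
        dead = strategy.dead_state().name
        ltc = pooled_complication_state(
            config.complication_components,
            risk.per_complication,
            name=cs.state_name,
            utility=cs.utility,
            on_dwell_exit=dead,
        )
        window_end = cs.window_end if cs.window_end is not None else float(config.economics.horizon)
        states.append(ltc)
        # A cumulative probability of 1 (possible under extreme sensitivity
        # scaling) has no finite annual hazard; cap just below 1.
        transitions.append(
            TransitionRule(
                from_state=strategy.initial_state,
                to_state=cs.state_name,
                mode="cumulative_over_window",
                value=min(risk.total, 1.0 - 1e-12),
                window_start=cs.window_start,
                window_end=window_end,
            )
        )
    return StrategyModel(
        name=strategy.name,
        initial_state=strategy.initial_state,
        acute=strategy.acute,
        dose=strategy.dose,
        states=states,
        transitions=transitions,
        event_risk=None,
        complication_risk_scale=1.0,
    )
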