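"""Model configuration: schema, validation, reading and writing.

A single config document parameterizes one analysis: economic settings
(willingness to pay, discount rates, horizon), shared radiation-risk inputs
(per-Gy excess-risk coefficients and the late-complication cost/life-expectancy
components), and two or more treatment strategies.  Each strategy carries an
acute phase (procedure cost, acute complication burden), a set of health states
with annual/entry/exit costs, utilities and optional dwell limits, explicit
transition rules, an optional "event risk" block (a cumulative probability of
recurrence-or-death spread over a window and split across destination states),
and an organ radiation dose profile.

Both JSON and YAML are accepted on read; YAML is canonical on write.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from .exceptions import (
    ConfigFormatError,
    ConfigReferenceError,
    ConfigValidationError,
)

__all__ = [
    "EconomicSettings",
    "HealthState",
    "TransitionRule",
    "EventRisk",
    "AcutePhase",
    "DoseProfile",
    "RiskCoefficients",
    "ComplicationComponent",
    "ComplicationSettings",
    "StrategyModel",
    "AnalysisConfig",
    "load_config",
    "loads_config",
    "write_config",
    "dumps_config",
    "validate_model",
]


class _Base(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class EconomicSettings(_Base):
    """Willingness to pay, discounting and simulation horizon.

    ``wtp`` is in USD per QALY (default $50,000/QALY).  Discount rates are
    annual fractions; costs and utilities may be discounted at different
    rates.  ``horizon`` is the number of annual cycles simulated.
    """

    wtp: float = 50_000.0
    discount_rate_cost: float = 0.03
    discount_rate_utility: float = 0.03
    horizon: int = Field(default=23, ge=1)
    half_cycle_correction: bool = False

    @model_validator(mode="after")
    def _check(self) -> "EconomicSettings":
        if self.wtp < 0:
            raise ValueError("wtp must be >= 0")
        for name in ("discount_rate_cost", "discount_rate_utility"):
            r = getattr(self, name)
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {r}")
        return self


class HealthState(_Base):
    """One Markov health state.

    ``max_dwell`` bounds the number of years a patient may remain in the
    state (fractional values allowed, e.g. a 5.625-year metastatic life
    expectancy); when bounded, ``on_dwell_exit`` names the successor state
    (typically the dead state).  ``exit_cost`` is a one-time cost charged to
    the mass leaving through the dwell exit — it carries last-year-of-life
    costs.
    """

    name: str
    utility: float = Field(ge=0.0, le=1.0)
    annual_cost: float = Field(default=0.0, ge=0.0)
    entry_cost: float = Field(default=0.0, ge=0.0)
    exit_cost: float = Field(default=0.0, ge=0.0)
    max_dwell: Optional[float] = None
    on_dwell_exit: Optional[str] = None

    @model_validator(mode="after")
    def _check(self) -> "HealthState":
        if self.max_dwell is not None:
            if not self.max_dwell > 0:
                raise ValueError(f"state {self.name!r}: max_dwell must be > 0 when bounded")
            if self.on_dwell_exit is None:
                raise ValueError(f"state {self.name!r}: on_dwell_exit required when max_dwell is bounded")
        elif self.on_dwell_exit is not None:
            raise ValueError(f"state {self.name!r}: on_dwell_exit given without max_dwell")
        return self


class TransitionRule(_Base):
    """A transition out of ``from_state``.

    ``annual_probability`` applies ``value`` each cycle the rule is active;
    ``cumulative_over_window`` spreads a cumulative probability ``value``
    uniformly on the hazard scale over ``[window_start, window_end)`` via
    p_annual = 1 - (1 - value)^(1/width).  Rules are active for cycles t with
    window_start <= t < window_end (window_end ``None`` means open-ended).
    """

    from_state: str
    to_state: str
    mode: Literal["annual_probability", "cumulative_over_window"] = "annual_probability"
    value: float = Field(ge=0.0, le=1.0)
    window_start: float = Field(default=0.0, ge=0.0)
    window_end: Optional[float] = None

    @model_validator(mode="after")
    def _check(self) -> "TransitionRule":
        if self.window_end is not None and not self.window_end > self.window_start:
            raise ValueError(
                f"transition {self.from_state}->{self.to_state}: window_end must exceed window_start"
            )
        if self.mode == "cumulative_over_window":
            if self.window_end is None:
                raise ValueError(
                    f"transition {self.from_state}->{self.to_state}: cumulative mode requires window_end"
                )
            if self.value >= 1.0:
                raise ValueError(
                    f"transition {self.from_state}->{self.to_state}: cumulative probability 1 implies "
                    "infinite hazard"
                )
        return self

    @property
    def window_width(self) -> float:
        assert self.window_end is not None
        return self.window_end - self.window_start


class EventRisk(_Base):
    """Cumulative recurrence-or-death risk out of the initial (well) state.

    ``cumulative`` is the probability of any event over the window (e.g. the
    10-year cumulative probability of local/other cancer and death).
    ``destinations`` maps destination state names to shares (summing to 1).
    The shares split the log-survival (hazard) so that the combined cumulative
    exit probability over the window equals ``cumulative`` exactly.
    """

    cumulative: float = Field(ge=0.0, lt=1.0)
    window_start: float = Field(default=0.0, ge=0.0)
    window_end: float = 10.0
    destinations: dict[str, float]

    @model_validator(mode="after")
    def _check(self) -> "EventRisk":
        if not self.window_end > self.window_start:
            raise ValueError("event_risk: window_end must exceed window_start")
        if not self.destinations:
            raise ValueError("event_risk: at least one destination required")
        total = sum(self.destinations.values())
        if any(v < 0 for v in self.destinations.values()):
            raise ValueError("event_risk: destination shares must be >= 0")
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"event_risk: destination shares must sum to 1, got {total}")
        return self

    def to_rules(self, from_state: str) -> list[TransitionRule]:
        """Expand into per-destination cumulative transition rules.

        Destination shares partition the log-survival: each destination d with
        share f_d gets cumulative value 1 - (1 - C)^f_d, so the annualized
        per-cycle survival factors multiply back to (1 - C)^(1/width).
        """
        rules = []
        for dest, share in self.destinations.items():
            if share == 0.0:
                continue
            value = 1.0 - (1.0 - self.cumulative) ** share
            rules.append(
                TransitionRule(
                    from_state=from_state,
                    to_state=dest,
                    mode="cumulative_over_window",
                    value=value,
                    window_start=self.window_start,
                    window_end=self.window_end,
                )
            )
        return rules


class AcutePhase(_Base):
    """Treatment-year costs and acute complication burden.

    The acute complication enters as an expected one-time cost
    (probability x cost) and an expected one-time QALY decrement
    (probability x disutility) applied at cycle 0.
    """

    procedure_cost: float = Field(default=0.0, ge=0.0)
    complication_probability: float = Field(default=0.0, ge=0.0, le=1.0)
    complication_cost: float = Field(default=0.0, ge=0.0)
    complication_disutility: float = Field(default=0.0, ge=0.0)


class DoseProfile(_Base):
    """Mean organ radiation doses in gray (Gy)."""

    heart_gy: float = Field(default=0.0, ge=0.0)
    ipsilateral_lung_gy: float = Field(default=0.0, ge=0.0)
    contralateral_breast_gy: float = Field(default=0.0, ge=0.0)


class RiskCoefficients(_Base):
    """Excess long-term complication probability per Gy, by complication.

    Linear no-threshold dose-risk mapping: the excess probability of each
    late complication over the late window is coefficient x organ dose,
    clamped to [0, 1].  MCE (major coronary event) risk scales with heart
    dose, lung cancer with ipsilateral lung dose, contralateral breast
    cancer with contralateral breast dose.
    """

    mce_per_gy: float = Field(default=0.0, ge=0.0)
    lung_cancer_per_gy: float = Field(default=0.0, ge=0.0)
    contralateral_breast_cancer_per_gy: float = Field(default=0.0, ge=0.0)


class ComplicationComponent(_Base):
    """Life expectancy and cost profile of one late-complication type."""

    name: str
    life_expectancy: float = Field(gt=0.0)
    initial_cost: float = Field(default=0.0, ge=0.0)
    ongoing_annual_cost: float = Field(default=0.0, ge=0.0)
    last_year_cost: float = Field(default=0.0, ge=0.0)


class ComplicationSettings(_Base):
    """Shared settings for the pooled long-term-complication state.

    The pooled state's incidence applies as a cumulative probability over
    ``[window_start, window_end)`` while in the initial state; ``window_end``
    ``None`` defaults to the economic horizon at build time.
    """

    state_name: str = "long_term_complication"
    utility: float = Field(default=1.0, ge=0.0, le=1.0)
    window_start: float = Field(default=10.0, ge=0.0)
    window_end: Optional[float] = None


class StrategyModel(_Base):
    """One treatment arm: acute phase, states, transitions, dose profile."""

    name: str
    initial_state: str
    acute: AcutePhase = Field(default_factory=AcutePhase)
    dose: DoseProfile = Field(default_factory=DoseProfile)
    states: list[HealthState]
    transitions: list[TransitionRule] = Field(default_factory=list)
    event_risk: Optional[EventRisk] = None
    complication_risk_scale: float = Field(default=1.0, ge=0.0)

    @property
    def state_names(self) -> list[str]:
        return [s.name for s in self.states]

    def state(self, name: str) -> HealthState:
        for s in self.states:
            if s.name == name:
                return s
        raise ConfigReferenceError(f"strategy {self.name!r}: unknown state {name!r}")

    def dead_state(self) -> HealthState:
        """The unique absorbing dead state (utility 0, cost 0, no exits)."""
        dead = [s for s in self.states if _is_dead_candidate(self, s)]
        if len(dead) != 1:
            raise ConfigValidationError(
                f"strategy {self.name!r}: expected exactly one absorbing dead state, found "
                f"{[s.name for s in dead]}"
            )
        return dead[0]


class AnalysisConfig(_Base):
    """Top-level config: economics, shared risk inputs, strategies."""

    economics: EconomicSettings = Field(default_factory=EconomicSettings)
    risk_coefficients: RiskCoefficients = Field(default_factory=RiskCoefficients)
    complication_components: list[ComplicationComponent] = Field(default_factory=list)
    complication: ComplicationSettings = Field(default_factory=ComplicationSettings)
    strategies: list[StrategyModel]

    @model_validator(mode="after")
    def _check(self) -> "AnalysisConfig":
        names = [s.name for s in self.strategies]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate strategy names: {names}")
        comp = [c.name for c in self.complication_components]
        if len(set(comp)) != len(comp):
            raise ValueError(f"duplicate complication component names: {comp}")
        return self

    def strategy(self, name: str) -> StrategyModel:
        for s in self.strategies:
            if s.name == name:
                return s
        raise ConfigReferenceError(f"unknown strategy {name!r}")


def _is_dead_candidate(strategy: StrategyModel, state: HealthState) -> bool:
    """Absorbing dead state: no dwell limit, no outgoing mass, utility 0, cost 0."""
    has_exit = any(r.from_state == state.name and r.value > 0 for r in strategy.transitions)
    if strategy.event_risk is not None and strategy.initial_state == state.name:
        has_exit = has_exit or strategy.event_risk.cumulative > 0
    return (
        state.max_dwell is None
        and not has_exit
        and state.utility == 0.0
        and state.annual_cost == 0.0
        and state.entry_cost == 0.0
    )


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def _annualized(rule: TransitionRule) -> float:
    if rule.mode == "annual_probability":
        return rule.value
    return 1.0 - (1.0 - rule.value) ** (1.0 / rule.window_width)


def validate_model(strategy: StrategyModel, horizon: int | None = None) -> list[str]:
    """Check structural invariants; return human-readable violations.

    An empty list means the strategy is valid.  Violations are returned, not
    raised, so callers can report all of them at once.
    """
    v: list[str] = []
    names = set(strategy.state_names)
    if len(names) != len(strategy.states):
        v.append(f"strategy {strategy.name!r}: duplicate state names")
    if strategy.initial_state not in names:
        v.append(f"strategy {strategy.name!r}: initial_state {strategy.initial_state!r} not a state")

    for r in strategy.transitions:
        for endpoint in (r.from_state, r.to_state):
            if endpoint not in names:
                v.append(
                    f"strategy {strategy.name!r}: transition {r.from_state!r}->{r.to_state!r} "
                    f"references unknown state {endpoint!r}"
                )
    if strategy.event_risk is not None:
        for dest in strategy.event_risk.destinations:
            if dest not in names:
                v.append(f"strategy {strategy.name!r}: event_risk destination {dest!r} not a state")

    for s in strategy.states:
        if s.on_dwell_exit is not None and s.on_dwell_exit not in names:
            v.append(
                f"strategy {strategy.name!r}: state {s.name!r} dwell exit {s.on_dwell_exit!r} "
                "not a state"
            )

    # exactly one absorbing dead state
    dead = [s.name for s in strategy.states if _is_dead_candidate(strategy, s)]
    if len(dead) != 1:
        v.append(
            f"strategy {strategy.name!r}: expected exactly one absorbing dead state "
            f"(utility 0, cost 0, no exits), found {dead}"
        )

    # probability mass: annualized exit probabilities from any state must not
    # exceed 1 in any cycle.  Checked at every window breakpoint.
    rules = list(strategy.transitions)
    if strategy.event_risk is not None:
        rules += strategy.event_risk.to_rules(strategy.initial_state)
    breakpoints = {0.0}
    for r in rules:
        breakpoints.add(r.window_start)
        if r.window_end is not None:
            breakpoints.add(r.window_end)
    if horizon is not None:
        breakpoints.add(float(horizon - 1))
    for s in strategy.states:
        out = [r for r in rules if r.from_state == s.name]
        if not out:
            continue
        for t in sorted(breakpoints):
            mass = sum(_annualized(r) for r in out if _active(r, t))
            if mass > 1.0 + 1e-9:
                v.append(
                    f"strategy {strategy.name!r}: state {s.name!r} annualized exit probability "
                    f"mass {mass:.6g} exceeds 1 at cycle {t:g}"
                )
                break
    return v


def _active(rule: TransitionRule, t: float) -> bool:
    if t < rule.window_start:
        return False
    return rule.window_end is None or t < rule.window_end


def _validate_config(config: AnalysisConfig) -> None:
    violations: list[str] = []
    for s in config.strategies:
        violations.extend(validate_model(s, horizon=config.economics.horizon))
    if violations:
        if any("unknown" in x or "not a state" in x for x in violations):
            raise ConfigReferenceError("; ".join(violations))
        raise ConfigValidationError("; ".join(violations))


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def loads_config(text: str, fmt: str = "yaml") -> AnalysisConfig:
    """Parse and fully validate a config document from a string."""
    try:
        if fmt == "json":
            data = json.loads(text)
        else:
            data = yaml.safe_load(text)
    except json.JSONDecodeError as exc:
        raise ConfigFormatError(f"JSON parse failure at line {exc.lineno}: {exc.msg}") from exc
    except yaml.YAMLError as exc:
        mark = getattr(exc, "problem_mark", None)
        line = mark.line + 1 if mark is not None else "?"
        raise ConfigFormatError(f"YAML parse failure at line {line}: {exc}") from exc
    if not isinstance(data, dict):
        raise ConfigFormatError("config document must be a mapping")
    try:
        config = AnalysisConfig.model_validate(data)
    except ValidationError as exc:
        details = "; ".join(
            f"{'.'.join(str(p) for p in err['loc'])}: {err['msg']}" for err in exc.errors()
        )
        raise ConfigValidationError(details) from exc
    _validate_config(config)
    return config


def load_config(path: str | Path) -> AnalysisConfig:
    """Read a JSON or YAML config file; apply defaults; check all invariants.

    Returns the validated :class:`AnalysisConfig` whose ``economics`` and
    ``strategies`` attributes carry the settings and strategy list.
    """
    path = Path(path)
    fmt = "json" if path.suffix.lower() == ".json" else "yaml"
    return loads_config(path.read_text(), fmt=fmt)


def dumps_config(config: AnalysisConfig) -> str:
    """Serialize to canonical YAML (stable field order, no aliasing)."""
    data = config.model_dump(mode="json", exclude_none=True)
    return yaml.safe_dump(data, sort_keys=False, default_flow_style=False)


def write_config(config: AnalysisConfig, path: str | Path) -> Path:
    """Write canonical YAML; round-trips field-for-field through load_config."""
    path = Path(path)
    path.write_text(dumps_config(config))
    return path


def config_digest(config: AnalysisConfig) -> str:
    """Stable SHA-256 hash of the canonical YAML serialization."""
    import hashlib

    return hashlib.sha256(dumps_config(config).encode()).hexdigest()
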