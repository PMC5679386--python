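"""Annual-cycle Markov cohort engine.

The cohort starts fully in the strategy's initial state.  Each cycle the
fraction occupying a state accrues that state's utility (QALY stream) and
annual cost, each discounted at its own rate; transitions are applied at
cycle end.  Dwell-limited states are expanded into tunnel-state chains so a
condition's life expectancy is enforced exactly, including fractional years
(the final tunnel copy carries the fractional reward weight).  Cycle 0
additionally applies the acute phase: procedure cost, expected acute
complication cost and an expected one-time QALY decrement.

Rewards accrue to state membership at cycle start and transitions happen at
cycle end (no half-cycle correction by default; the
``half_cycle_correction`` flag switches rewards to the average of start- and
end-of-cycle occupancy).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import EconomicSettings, StrategyModel, TransitionRule
from .exceptions import ModelStructureError, RuntimeModelError

__all__ = [
    "discount_factor",
    "cumulative_to_annual",
    "expand_tunnels",
    "run_cohort",
    "CohortTrajectory",
    "StrategyResult",
]

_MASS_TOL = 1e-9

# Dwell durations within this distance of an integer are treated as integer:
# a derived dwell (e.g. an incidence-weighted life expectancy) that lands on
# 16 +- 1e-15 must not oscillate between 16 and 17 tunnel copies.
_DWELL_SNAP = 1e-9


def _snap_integer(x: float) -> float:
    r = round(x)
    return float(r) if abs(x - r) < _DWELL_SNAP else x


def discount_factor(rate: float, t: int) -> float:
    """Present-value factor 1/(1+rate)^t for year index t (t=0 undiscounted)."""
    if rate < 0:
        raise ValueError(f"discount rate must be >= 0, got {rate}")
    if t < 0:
        raise ValueError(f"year index must be >= 0, got {t}")
    return 1.0 / (1.0 + rate) ** t


def cumulative_to_annual(p_cum: float, window_years: float) -> float:
    """Spread a cumulative probability uniformly on the hazard scale.

    Returns the constant annual probability p with
    1 - (1 - p)^window_years = p_cum.
    """
    if not 0.0 <= p_cum < 1.0:
        raise ValueError(f"cumulative probability must lie in [0, 1), got {p_cum}")
    if window_years <= 0:
        raise ValueError(f"window must be positive, got {window_years}")
    return 1.0 - (1.0 - p_cum) ** (1.0 / window_years)


# ---------------------------------------------------------------------------
# tunnel expansion
# ---------------------------------------------------------------------------


@dataclass
class ExpandedModel:
    """Internal tunnel-expanded representation of a strategy."""

    strategy: StrategyModel
    origin: list[str]                 # original state name per expanded index
    copy_index: list[int]             # tunnel copy number per expanded index
    entry_index: dict[str, int]       # original state name -> entry copy index
    utility: np.ndarray
    annual_cost: np.ndarray
    reward_weight: np.ndarray         # fractional dwell weight (1 elsewhere)
    alive: np.ndarray                 # bool mask, False only for the dead state
    dead_index: int
    _rules_by_state: dict[str, list[TransitionRule]] = field(default_factory=dict)
    _matrix_cache: dict[tuple, tuple[np.ndarray, np.ndarray, np.ndarray]] = field(
        default_factory=dict
    )

    @property
    def n(self) -> int:
        return len(self.origin)

    def aggregate(self, expanded: np.ndarray) -> np.ndarray:
        """Sum expanded-state columns back to original states."""
        out = np.zeros(expanded.shape[:-1] + (len(self.strategy.states),))
        for j, name in enumerate(self.origin):
            out[..., self._orig_pos[name]] += expanded[..., j]
        return out

    def __post_init__(self) -> None:
        self._orig_pos = {s.name: i for i, s in enumerate(self.strategy.states)}

    # -- transition matrices -------------------------------------------------

    def matrices(self, t: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(transition matrix, entry-cost vector, exit-cost vector) for cycle t.

        The entry-cost vector e satisfies occ @ e = sum of entry costs charged
        this cycle (inflow into a state's entry copy from a different state);
        the exit-cost vector likewise carries last-year-of-life costs on the
        dwell-exit flow.  Matrices are cached by the set of active rules.
        """
        key = tuple(
            _rule_active(r, t)
            for rules in self._rules_by_state.values()
            for r in rules
        )
        cached = self._matrix_cache.get(key)
        if cached is not None:
            return cached

        n = self.n
        M = np.zeros((n, n))
        entry_vec = np.zeros(n)
        exit_vec = np.zeros(n)
        states = {s.name: s for s in self.strategy.states}
        for i in range(n):
            name = self.origin[i]
            state = states[name]
            rules = [r for r in self._rules_by_state.get(name, []) if _rule_active(r, t)]
            mass = 0.0
            for r in rules:
                p = _annual_probability(r)
                j = self.entry_index[r.to_state]
                if r.to_state == name:
                    M[i, i] += p  # self-loop: stay, no entry cost
                else:
                    M[i, j] += p
                    entry_vec[i] += p * states[r.to_state].entry_cost
                mass += p
            if mass > 1.0 + _MASS_TOL:
                raise RuntimeModelError(
                    f"strategy {self.strategy.name!r}: state {name!r} exit probability "
                    f"mass {mass:.6g} exceeds 1 at cycle {t}"
                )
            remainder = max(0.0, 1.0 - mass)
            if state.max_dwell is None:
                M[i, i] += remainder
            else:
                n_copies = math.ceil(_snap_integer(state.max_dwell))
                if self.copy_index[i] < n_copies - 1:
                    M[i, i + 1] += remainder  # advance along the tunnel
                else:
                    j = self.entry_index[state.on_dwell_exit]
                    M[i, j] += remainder
                    entry_vec[i] += remainder * states[state.on_dwell_exit].entry_cost
                    exit_vec[i] += remainder * state.exit_cost
        self._matrix_cache[key] = (M, entry_vec, exit_vec)
        return M, entry_vec, exit_vec


def _rule_active(rule: TransitionRule, t: float) -> bool:
    if t < rule.window_start:
        return False
    return rule.window_end is None or t < rule.window_end


def _annual_probability(rule: TransitionRule) -> float:
    if rule.mode == "annual_probability":
        return rule.value
    return cumulative_to_annual(rule.value, rule.window_width)


def expand_tunnels(strategy: StrategyModel) -> ExpandedModel:
    """Replace every dwell-limited state by a chain of tunnel copies.

    A state with max_dwell D becomes ceil(D) copies feeding ``on_dwell_exit``;
    for non-integer D the final copy's utility, annual cost and life-year
    contribution carry weight frac(D), so the expected dwell of an entrant is
    exactly D.  Requires a resolved strategy (no event-risk sugar).
    """
    if strategy.event_risk is not None:
        raise ModelStructureError(
            f"strategy {strategy.name!r}: expand event_risk (resolve_strategy) before the engine"
        )
    # cyclic dwell-exit chains make the dwell semantics ill-defined
    succ = {s.name: s.on_dwell_exit for s in strategy.states if s.max_dwell is not None}
    for start in succ:
        seen = {start}
        cur = succ.get(start)
        while cur is not None:
            if cur in seen:
                raise ModelStructureError(
                    f"strategy {strategy.name!r}: cyclic dwell-exit chain through {cur!r}"
                )
            seen.add(cur)
            cur = succ.get(cur)

    origin: list[str] = []
    copy_index: list[int] = []
    entry_index: dict[str, int] = {}
    utility: list[float] = []
    annual_cost: list[float] = []
    weight: list[float] = []
    alive: list[bool] = []
    dead_name = strategy.dead_state().name
    for s in strategy.states:
        entry_index[s.name] = len(origin)
        if s.max_dwell is None:
            n_copies, frac = 1, 1.0
        else:
            d = _snap_integer(s.max_dwell)
            n_copies = math.ceil(d)
            frac = d - math.floor(d)
            if frac == 0.0:
                frac = 1.0
        for k in range(n_copies):
            origin.append(s.name)
            copy_index.append(k)
            utility.append(s.utility)
            annual_cost.append(s.annual_cost)
            weight.append(frac if k == n_copies - 1 and s.max_dwell is not None else 1.0)
            alive.append(s.name != dead_name)

    em = ExpandedModel(
        strategy=strategy,
        origin=origin,
        copy_index=copy_index,
        entry_index=entry_index,
        utility=np.asarray(utility),
        annual_cost=np.asarray(annual_cost),
        reward_weight=np.asarray(weight),
        alive=np.asarray(alive, dtype=bool),
        dead_index=entry_index[dead_name],
    )
    em._rules_by_state = {}
    for r in strategy.transitions:
        em._rules_by_state.setdefault(r.from_state, []).append(r)
    return em


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------


@dataclass
class CohortTrajectory:
    """Per-cycle occupancy and discounted reward streams for one strategy.

    ``occupancy`` has horizon+1 rows (start of each cycle plus the final
    post-transition distribution) over the original (unexpanded) states.
    ``cost_by_state``/``qaly_by_state`` attribute each cycle's discounted
    accruals to states; one-time flow costs (entry and dwell-exit/last-year
    costs) are attributed to the state the flow leaves, and the acute phase
    to the initial state at cycle 0.
    """

    strategy_name: str
    state_names: list[str]
    occupancy: np.ndarray          # (H+1, n_states), original-state fractions
    cost_by_state: np.ndarray      # (H, n_states), discounted USD
    qaly_by_state: np.ndarray      # (H, n_states), discounted QALY increments
    expanded_final: np.ndarray     # internal: expanded occupancy after last cycle

    @property
    def cycle_costs(self) -> np.ndarray:
        return self.cost_by_state.sum(axis=1)

    @property
    def cycle_qalys(self) -> np.ndarray:
        return self.qaly_by_state.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        """Long-format export: cycle, state, occupancy, discounted cost/QALY."""
        h = self.cost_by_state.shape[0]
        rows = []
        for t in range(h):
            for j, name in enumerate(self.state_names):
                rows.append(
                    {
                        "cycle": t,
                        "state": name,
                        "occupancy": self.occupancy[t, j],
                        "discounted_cost": self.cost_by_state[t, j],
                        "discounted_qaly": self.qaly_by_state[t, j],
                    }
                )
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class StrategyResult:
    """Lifetime totals for one strategy.

    ``total_cost`` and ``total_qalys`` are discounted at the configured
    rates; ``life_years`` is the undiscounted expected number of years alive.
    """

    name: str
    total_cost: float
    total_qalys: float
    life_years: float
    undiscounted_cost: float
    undiscounted_qalys: float


def run_cohort(
    strategy: StrategyModel,
    econ: EconomicSettings,
    *,
    cycles: int | None = None,
    start_cycle: int = 0,
    initial_occupancy: np.ndarray | None = None,
    apply_acute: bool | None = None,
) -> tuple[CohortTrajectory, StrategyResult]:
    """Simulate the cohort for ``cycles`` annual cycles (default: horizon).

    ``start_cycle``/``initial_occupancy`` allow resuming a run from an
    intermediate expanded occupancy with correctly shifted discount indices;
    the acute phase is applied only on a fresh run from cycle 0.
    """
    em = expand_tunnels(strategy)
    h = econ.horizon if cycles is None else cycles
    if apply_acute is None:
        apply_acute = start_cycle == 0 and initial_occupancy is None

    occ = np.zeros(em.n)
    if initial_occupancy is None:
        occ[em.entry_index[strategy.initial_state]] = 1.0
    else:
        occ[:] = initial_occupancy

    occupancy = np.zeros((h + 1, em.n))
    cost_by_state = np.zeros((h, em.n))
    qaly_by_state = np.zeros((h, em.n))
    undisc_cost = 0.0
    undisc_qalys = 0.0
    life_years = 0.0
    w_util = em.utility * em.reward_weight
    w_cost = em.annual_cost * em.reward_weight
    w_alive = em.alive * em.reward_weight

    for k in range(h):
        t = start_cycle + k
        occupancy[k] = occ
        total = occ.sum()
        if abs(total - 1.0) > 1e-9:
            raise RuntimeModelError(
                f"strategy {strategy.name!r}: occupancy mass {total!r} at cycle {t}"
            )
        M, entry_vec, exit_vec = em.matrices(t)
        nxt = occ @ M
        occ_reward = 0.5 * (occ + nxt) if econ.half_cycle_correction else occ
        dfc = discount_factor(econ.discount_rate_cost, t)
        dfu = discount_factor(econ.discount_rate_utility, t)
        q = occ_reward * w_util
        c = occ_reward * w_cost + occ * (entry_vec + exit_vec)
        qaly_by_state[k] = dfu * q
        cost_by_state[k] = dfc * c
        undisc_qalys += float(q.sum())
        undisc_cost += float(c.sum())
        life_years += float(occ_reward @ w_alive)
        occ = nxt
    occupancy[h] = occ

    if apply_acute:
        a = strategy.acute
        acute_cost = a.procedure_cost + a.complication_probability * a.complication_cost
        acute_decrement = a.complication_probability * a.complication_disutility
        i0 = em.entry_index[strategy.initial_state]
        cost_by_state[0, i0] += acute_cost  # cycle 0: undiscounted by construction
        undisc_cost += acute_cost
        qaly_by_state[0, i0] -= acute_decrement
        undisc_qalys -= acute_decrement

    trajectory = CohortTrajectory(
        strategy_name=strategy.name,
        state_names=[s.name for s in strategy.states],
        occupancy=em.aggregate(occupancy),
        cost_by_state=em.aggregate(cost_by_state),
        qaly_by_state=em.aggregate(qaly_by_state),
        expanded_final=occ,
    )
    result = StrategyResult(
        name=strategy.name,
        total_cost=float(cost_by_state.sum()),
        total_qalys=float(qaly_by_state.sum()),
        life_years=life_years,
        undiscounted_cost=undisc_cost,
        undiscounted_qalys=undisc_qalys,
    )
    return trajectory, result
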