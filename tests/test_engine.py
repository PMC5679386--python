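"""Cohort engine: discounting, probability conversion, tunnel expansion and
cohort simulation against independent oracles."""

import numpy as np
import pytest

from radcea import (
    EconomicSettings,
    HealthState,
    StrategyModel,
    TransitionRule,
    cumulative_to_annual,
    discount_factor,
    expand_tunnels,
    run_cohort,
)
from radcea.dose import resolve_strategy
from radcea.exceptions import ModelStructureError, RuntimeModelError
from radcea.synthetic import closed_form_toy, random_model


class TestDiscountFactor:
    @pytest.mark.parametrize(
        "rate,t,expected",
        [(0.03, 0, 1.0), (0.0, 10, 1.0), (0.03, 1, 0.970874)],
    )
    def test_examples(self, rate, t, expected):
        assert discount_factor(rate, t) == pytest.approx(expected, abs=5e-7)

    def test_negative_year_rejected(self):
        with pytest.raises(ValueError):
            discount_factor(0.03, -1)


class TestCumulativeToAnnual:
    def test_zero_risk(self):
        assert cumulative_to_annual(0.0, 10) == 0.0

    @pytest.mark.parametrize("p_cum", [0.254, 0.23, 0.0031, 0.9])
    def test_recompounds_to_cumulative(self, p_cum):
        p = cumulative_to_annual(p_cum, 10)
        assert 1.0 - (1.0 - p) ** 10 == pytest.approx(p_cum, abs=1e-12)

    def test_certain_event_has_infinite_hazard(self):
        with pytest.raises(ValueError):
            cumulative_to_annual(1.0, 10)


def _chain(*states, transitions=()):
    return StrategyModel(
        name="toy", initial_state=states[0].name, states=list(states),
        transitions=list(transitions),
    )


ALIVE = HealthState(name="alive", utility=1.0)
DEAD = HealthState(name="dead", utility=0.0)


class TestExpandTunnels:
    def test_unbounded_model_unchanged(self):
        em = expand_tunnels(_chain(ALIVE, DEAD))
        assert em.n == 2

    def test_integer_dwell_copies(self):
        s = HealthState(name="met", utility=0.5, max_dwell=6.0, on_dwell_exit="dead")
        em = expand_tunnels(_chain(s, DEAD))
        assert em.origin.count("met") == 6
        assert np.all(em.reward_weight[:6] == 1.0)

    def test_fractional_dwell_weight_and_expected_dwell(self):
        # summation oracle: expected dwell = sum of per-copy reward weights
        s = HealthState(name="met", utility=0.5, max_dwell=5.625, on_dwell_exit="dead")
        em = expand_tunnels(_chain(s, DEAD))
        weights = em.reward_weight[np.array(em.origin) == "met"]
        assert len(weights) == 6
        assert weights[-1] == pytest.approx(0.625)
        assert weights.sum() == pytest.approx(5.625, abs=1e-12)

    def test_cyclic_dwell_exit_chain_rejected(self):
        a = HealthState(name="a", utility=0.5, max_dwell=2.0, on_dwell_exit="b")
        b = HealthState(name="b", utility=0.5, max_dwell=2.0, on_dwell_exit="a")
        with pytest.raises(ModelStructureError, match="cyclic"):
            expand_tunnels(_chain(a, b, DEAD))


class TestRunCohort:
    def test_immortal_cohort_accrues_horizon_qalys(self):
        strat = _chain(ALIVE, DEAD)
        econ = EconomicSettings(
            discount_rate_cost=0.0, discount_rate_utility=0.0, horizon=23
        )
        _, res = run_cohort(strat, econ)
        assert res.total_qalys == 23.0
        assert res.life_years == 23.0

    @pytest.mark.parametrize("i", range(50))
    def test_geometric_closed_form_oracle(self, i):
        rng = np.random.default_rng(1000 + i)
        p = float(rng.uniform(0.0, 0.9))
        u = float(rng.uniform(0.1, 1.0))
        r = float(rng.choice([0.0, 0.015, 0.03, 0.05, 0.1]))
        h = int(rng.integers(1, 60))
        strat, econ, expected = closed_form_toy(p, u, r, h)
        _, res = run_cohort(strat, econ)
        assert res.total_qalys == pytest.approx(expected, abs=1e-10)

    @pytest.mark.parametrize("seed", range(20))
    def test_matrix_power_oracle_equivalence(self, seed):
        """Totals match an independent matrix-power summation for 2-4 state models."""
        strat = random_model(seed, n_states=2 + seed % 3)
        econ = EconomicSettings(horizon=25)
        _, res = run_cohort(strat, econ)
        oracle_cost, oracle_qaly = _matrix_power_oracle(strat, econ)
        assert res.total_qalys == pytest.approx(oracle_qaly, abs=1e-10)
        assert res.total_cost == pytest.approx(oracle_cost, abs=1e-8)

    @pytest.mark.parametrize("seed", range(20))
    def test_occupancy_conserved_every_cycle(self, seed):
        strat = random_model(seed, n_states=3 + seed % 4)
        traj, res = run_cohort(strat, EconomicSettings(horizon=30))
        sums = traj.occupancy.sum(axis=1)
        assert np.all(np.abs(sums - 1.0) < 1e-12)
        assert np.all(traj.occupancy >= -1e-15) and np.all(traj.occupancy <= 1 + 1e-12)
        assert res.total_qalys <= res.life_years <= 30

    def test_discounting_never_increases_totals(self):
        strat = random_model(7, n_states=4)
        disc = EconomicSettings(horizon=20)
        zero = EconomicSettings(
            horizon=20, discount_rate_cost=0.0, discount_rate_utility=0.0
        )
        _, r_disc = run_cohort(strat, disc)
        _, r_zero = run_cohort(strat, zero)
        assert r_disc.total_cost < r_disc.undiscounted_cost
        assert r_disc.total_qalys < r_disc.undiscounted_qalys
        assert r_zero.total_cost == pytest.approx(r_zero.undiscounted_cost, rel=1e-14)
        assert r_zero.total_qalys == pytest.approx(r_zero.undiscounted_qalys, rel=1e-14)

    def test_mass_violation_names_cycle_and_state(self):
        strat = _chain(
            ALIVE,
            DEAD,
            transitions=[
                TransitionRule(from_state="alive", to_state="dead", value=0.7),
                TransitionRule(from_state="alive", to_state="dead", value=0.6),
            ],
        )
        with pytest.raises(RuntimeModelError, match="alive"):
            run_cohort(strat, EconomicSettings(horizon=5))

    def test_horizon_additivity(self, study_config):
        """Running H cycles equals running H1 then H-H1 from the intermediate state."""
        strat = resolve_strategy(study_config, study_config.strategy("EBRT"))
        econ = study_config.economics
        traj_full, res_full = run_cohort(strat, econ, cycles=30)
        traj1, res1 = run_cohort(strat, econ, cycles=12)
        traj2, res2 = run_cohort(
            strat, econ, cycles=18, start_cycle=12,
            initial_occupancy=traj1.expanded_final,
        )
        assert res1.total_cost + res2.total_cost == pytest.approx(res_full.total_cost, abs=1e-8)
        assert res1.total_qalys + res2.total_qalys == pytest.approx(
            res_full.total_qalys, abs=1e-10
        )
        assert res1.life_years + res2.life_years == pytest.approx(res_full.life_years, abs=1e-10)

    def test_half_cycle_correction_matches_direct_average(self):
        p, u, r, h = 0.2, 0.8, 0.03, 10
        strat, econ, _ = closed_form_toy(p, u, r, h)
        econ = econ.model_copy(update={"half_cycle_correction": True})
        _, res = run_cohort(strat, econ)
        expected = sum(
            u * 0.5 * ((1 - p) ** t + (1 - p) ** (t + 1)) / (1 + r) ** t for t in range(h)
        )
        assert res.total_qalys == pytest.approx(expected, abs=1e-12)


def test_raising_utility_or_cost_is_monotone(study_config):
    from radcea.pipeline import evaluate_config
    from radcea.sensitivity import perturbed

    base = evaluate_config(study_config).table["IORT"]
    up_u = evaluate_config(
        perturbed(study_config, "strategies.IORT.states.local_regional.utility", 0.9)
    ).table["IORT"]
    up_c = evaluate_config(
        perturbed(study_config, "strategies.IORT.states.well.annual_cost", 5_000.0)
    ).table["IORT"]
    assert up_u["total_qalys"] > base["total_qalys"]
    assert up_c["total_cost"] > base["total_cost"]


def _matrix_power_oracle(strategy, econ):
    """Independent summation using numpy matrix powers (constant probabilities)."""
    names = [s.name for s in strategy.states]
    idx = {n: i for i, n in enumerate(names)}
    n = len(names)
    M = np.zeros((n, n))
    for s in strategy.states:
        out = [r for r in strategy.transitions if r.from_state == s.name]
        i = idx[s.name]
        for r in out:
            M[i, idx[r.to_state]] += r.value
        M[i, i] += 1.0 - sum(r.value for r in out)
    u = np.array([s.utility for s in strategy.states])
    c = np.array([s.annual_cost for s in strategy.states])
    entry = np.array([s.entry_cost for s in strategy.states])
    occ0 = np.zeros(n)
    occ0[idx[strategy.initial_state]] = 1.0
    off = M * (1 - np.eye(n))
    cost = qaly = 0.0
    for t in range(econ.horizon):
        occ = occ0 @ np.linalg.matrix_power(M, t)
        dfu = 1.0 / (1.0 + econ.discount_rate_utility) ** t
        dfc = 1.0 / (1.0 + econ.discount_rate_cost) ** t
        qaly += dfu * float(occ @ u)
        cost += dfc * (float(occ @ c) + float((occ @ off) @ entry))
    return cost, qaly
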