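"""Cohort engines: determinism, closed forms, Monte Carlo vs exact
expectation, initialization, and monotonicity."""

import numpy as np
import pytest

import cemocsim as cs
from cemocsim.natural_history import HealthState
from cemocsim.synthetic_fixtures import _zeroed


def test_run_config_validation():
    with pytest.raises(ValueError):
        cs.RunConfig(n_women=0)
    with pytest.raises(ValueError):
        cs.RunConfig(horizon_cycles=0)


def test_zero_fertility_cohort_earns_full_qalys(params, prior_table):
    """Nobody pregnant, nobody dies: QALYs equal the horizon exactly and
    costs are zero, in both engines."""
    p0 = _zeroed(params)
    strat = cs.Strategy(id="any", target_cs_rate=0.5, access=1.0, hist_cs=0.0)
    cfg = cs.RunConfig(n_women=500, horizon_cycles=35, seed=3)
    for engine in (cs.expected_value, cs.run_cohort):
        res = engine(cfg, p0, strat, prior_table)
        assert res.mean_qaly == pytest.approx(35.0, abs=1e-12)
        assert res.mean_cost == 0.0


def test_monte_carlo_is_bitwise_reproducible(params, strategies, prior_table):
    cfg = cs.RunConfig(n_women=400, horizon_cycles=6, seed=99)
    r1 = cs.run_cohort(cfg, params, strategies["A_national"], prior_table)
    r2 = cs.run_cohort(cfg, params, strategies["A_national"], prior_table)
    assert r1.tally_totals == r2.tally_totals
    assert (r1.mean_cost, r1.mean_qaly) == (r2.mean_cost, r2.mean_qaly)
    r3 = cs.run_cohort(
        cs.RunConfig(n_women=400, horizon_cycles=6, seed=100),
        params, strategies["A_national"], prior_table,
    )
    assert r3.tally_totals != r1.tally_totals


@pytest.mark.parametrize("horizon", [1, 2, 3])
def test_monte_carlo_agrees_with_exact_expectation(horizon, strategies, prior_table):
    """Oracle equivalence: Monte Carlo means fall within 4 standard errors
    of the exact per-cycle expectation, across randomized parameter
    tables and short horizons."""
    for seed in range(7):
        reg = cs.random_registry(100 + seed)
        p = cs.baseline_set(reg).with_overrides(p_pregnancy=0.3)
        strat = list(strategies.values())[seed % 3]
        cfg = cs.RunConfig(n_women=1500, horizon_cycles=horizon, seed=seed)
        ev = cs.expected_value(cfg, p, strat, prior_table)
        mc = cs.run_cohort(cfg, p, strat, prior_table)
        assert mc.mean_qaly <= horizon + 1e-12
        assert abs(mc.mean_cost - ev.mean_cost) <= 4 * max(mc.se_cost, 1e-9)
        assert abs(mc.mean_qaly - ev.mean_qaly) <= 4 * max(mc.se_qaly, 1e-9)


def test_cohort_tally_conservation(params, strategies, prior_table):
    cfg = cs.RunConfig(n_women=2000, horizon_cycles=10, seed=5)
    res = cs.run_cohort(cfg, params, strategies["C_urban"], prior_table)
    t = res.tally_totals
    assert t.vaginal_deliveries + t.cesarean_sections == t.pregnancies_to_term
    assert t.live_births + t.neonatal_deaths == t.pregnancies_to_term
    assert t.maternal_deaths <= cfg.n_women
    assert 0 <= res.mean_qaly <= cfg.horizon_cycles


def test_initialize_woman_prevalences(params, strategies):
    """Entrants start at age 14 with the strategy's prior-CS prevalence and
    the published hysterectomy-history prevalence."""
    rng = np.random.default_rng(42)
    n = 10_000
    women = [cs.initialize_woman(params, strategies["C_urban"], rng) for _ in range(n)]
    frac_cs = np.mean([w.prior_cs_count for w in women if w.state is HealthState.NON_PREGNANT])
    frac_hyst = np.mean([w.state is HealthState.POST_HYSTERECTOMY for w in women])
    assert abs(frac_cs - 0.282) < 0.015
    assert abs(frac_hyst - 0.017) < 0.005
    assert all(w.age == 14 and w.tally.pregnancies_to_term == 0 for w in women)
    p0 = params.with_overrides(p_hist_hysterectomy=0.0)
    strat0 = cs.Strategy(id="z", target_cs_rate=0.1, access=0.5, hist_cs=0.0)
    women0 = [cs.initialize_woman(p0, strat0, rng) for _ in range(100)]
    assert all(w.state is HealthState.NON_PREGNANT and w.prior_cs_count == 0 for w in women0)


def test_mean_cost_is_monotone_in_cs_cost(params, calibrated, base_config, prior_table):
    """Raising the CS cost strictly raises every strategy's expected cost
    (exact evaluator, positive CS volume)."""
    strat = calibrated["C_urban"].strategy
    costs = []
    for c in (373.0, 745.66, 1491.0):
        p = params.with_overrides(cost_cs=c)
        costs.append(cs.expected_value(base_config, p, strat, prior_table).mean_cost)
    assert costs[0] < costs[1] < costs[2]


def test_fistulae_decrease_with_access(params, prior_table):
    """Fistulae arise only without access to CEmOC, so raising access
    lowers their expected count (exact evaluator)."""
    cfg = cs.RunConfig(n_women=10_000, horizon_cycles=35, seed=0)
    counts = []
    for a in (0.3, 0.5, 0.7):
        strat = cs.Strategy(id=f"a{a}", target_cs_rate=0.2, access=a, hist_cs=0.172)
        counts.append(
            cs.expected_value(cfg, params, strat, prior_table).tally_totals.fistula
        )
    assert counts[0] > counts[1] > counts[2]


def test_expected_value_state_space_bound(params, strategies, prior_table):
    cfg = cs.RunConfig(n_women=10, horizon_cycles=2, seed=0)
    with pytest.raises(ValueError, match="prior_cs_cap"):
        cs.expected_value(cfg, params, strategies["A_national"], prior_table, prior_cs_cap=40)


def test_certain_death_first_delivery_half_cycle(params, prior_table):
    """All women die during their first delivery: lifetime QALYs equal half
    the pregnancy utility under the half-cycle convention, and nothing
    accrues after death."""
    p = _zeroed(params).with_overrides(
        p_pregnancy=1.0, p_antepartum_indication=1.0, p_death_antepartum_indication=1.0
    )
    strat = cs.Strategy(id="fatal", target_cs_rate=0.5, access=1.0, hist_cs=0.0)
    cfg = cs.RunConfig(n_women=200, horizon_cycles=35, seed=8)
    for engine in (cs.expected_value, cs.run_cohort):
        res = engine(cfg, p, strat, prior_table)
        assert res.mean_qaly == pytest.approx(0.5 * 0.99, abs=1e-12)
        assert res.tally_totals.maternal_deaths == pytest.approx(cfg.n_women)


def test_discounting_reduces_totals(params, calibrated, prior_table):
    strat = calibrated["A_national"].strategy
    cfg0 = cs.RunConfig(n_women=1, horizon_cycles=35, seed=0)
    cfg3 = cs.RunConfig(
        n_women=1, horizon_cycles=35, seed=0,
        discount_rate_costs=0.03, discount_rate_qalys=0.03,
    )
    ev0 = cs.expected_value(cfg0, params, strat, prior_table)
    ev3 = cs.expected_value(cfg3, params, strat, prior_table)
    assert ev3.mean_cost < ev0.mean_cost
    assert ev3.mean_qaly < ev0.mean_qaly
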