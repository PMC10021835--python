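"""Delivery-episode trees: leaf-probability conservation, forced paths,
state rules, and outcome invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import cemocsim as cs
from cemocsim.natural_history import (
    HealthState,
    RngChooser,
    WomanState,
    enumerate_leaves,
    walk_episode,
)
from cemocsim.parameters import PriorCsRow, PriorCsTable
from cemocsim.synthetic_fixtures import ZERO_PRIOR_TABLE, _zeroed


def leaf_sum(params, strategy, prior_cs, table):
    leaves = enumerate_leaves(
        lambda ch: walk_episode(ch, params, strategy, prior_cs, table)
    )
    return sum(pr for pr, _ in leaves), leaves


@pytest.mark.parametrize("seed", range(20))
def test_leaf_probabilities_conserve_on_random_tables(seed, strategies, prior_table):
    """Exhaustive enumeration of the episode tree sums to probability one
    for randomized-but-valid parameter tables, at every prior-CS count."""
    reg = cs.random_registry(seed)
    p = cs.baseline_set(reg)
    strat = list(strategies.values())[seed % 3]
    for prior in (0, 1, 4):
        total, _ = leaf_sum(p, strat, prior, prior_table)
        assert total == pytest.approx(1.0, abs=1e-9)


def test_null_path_costs_exactly_vaginal_delivery(params):
    """With every complication and indication switched off and full access,
    the only leaf is an uncomplicated facility vaginal delivery."""
    p0 = _zeroed(params)
    strat = cs.Strategy(
        id="clean", target_cs_rate=0.5, access=1.0, hist_cs=0.0,
        p_nonind_antepartum=0.0, p_nonind_intrapartum=0.0,
    )
    leaves = enumerate_leaves(
        lambda ch: walk_episode(ch, p0, strat, 0, ZERO_PRIOR_TABLE)
    )
    assert len(leaves) == 1
    prob, leaf = leaves[0]
    assert prob == pytest.approx(1.0)
    assert leaf.mode == "vaginal"
    assert leaf.episode_cost == pytest.approx(153.70)
    assert leaf.events.get("live_births") == 1
    assert not leaf.maternal_died and not leaf.neonate_died


def test_forced_accreta_path_cost_is_sum_of_component_costs(params):
    """Accreta -> PPH -> hysterectomy -> ICU accumulates the CS, PPH,
    hysterectomy and ICU costs: 745.66 + 79.89 + 2241.42 + 1172.50."""
    table = PriorCsTable({0: PriorCsRow(0.0, 1.0, 0.0)})
    p = _zeroed(params).with_overrides(
        p_pph_accreta=1.0, p_hyst_accreta=1.0, p_icu_hysterectomy=1.0
    )
    strat = cs.Strategy(id="forced", target_cs_rate=0.5, access=1.0, hist_cs=0.0)
    leaves = enumerate_leaves(lambda ch: walk_episode(ch, p, strat, 0, table))
    assert len(leaves) == 1
    _, leaf = leaves[0]
    assert leaf.episode_cost == pytest.approx(745.66 + 79.89 + 2241.42 + 1172.50)
    for key in ("accreta", "pph_transfusion", "peripartum_hysterectomy", "icu_admissions"):
        assert leaf.events.get(key) == 1
    assert leaf.hysterectomy_performed


def test_no_access_tree_has_no_surgical_care(params, prior_table):
    """Without access every leaf is a vaginal delivery costed at the
    vaginal-delivery price only; hysterectomy, ICU and transfusion costs
    are unreachable, and an absolute indication kills the neonate."""
    strat = cs.Strategy(id="none", target_cs_rate=0.0, access=0.0, hist_cs=0.0)
    for prior in (0, 2):
        leaves = enumerate_leaves(
            lambda ch: walk_episode(ch, params, strat, prior, prior_table)
        )
        assert sum(pr for pr, _ in leaves) == pytest.approx(1.0, abs=1e-9)
        for pr, leaf in leaves:
            assert leaf.mode == "vaginal"
            assert leaf.episode_cost == pytest.approx(params["cost_vaginal"])
            assert not leaf.hysterectomy_performed
            assert leaf.events.get("peripartum_hysterectomy", 0) == 0
            assert leaf.events.get("icu_admissions", 0) == 0
    # forced indication -> neonatal death, and fistula only without access
    p_forced = _zeroed(params).with_overrides(
        p_intrapartum_indication=1.0, p_fistula=1.0
    )
    leaves = enumerate_leaves(
        lambda ch: walk_episode(ch, p_forced, strat, 0, ZERO_PRIOR_TABLE)
    )
    assert len(leaves) == 1
    _, leaf = leaves[0]
    assert leaf.neonate_died
    assert leaf.events.get("fistula") == 1
    assert leaf.events.get("neonatal_deaths") == 1


def test_neonatal_survival_is_certain_with_access(params, prior_table):
    strat = cs.Strategy(id="full", target_cs_rate=0.5, access=1.0, hist_cs=0.0)
    for prior in (0, 1, 3):
        leaves = enumerate_leaves(
            lambda ch: walk_episode(ch, params, strat, prior, prior_table)
        )
        assert all(not leaf.neonate_died for _, leaf in leaves)


def test_failed_tolac_increments_prior_cs(params, prior_table):
    """TOLAC ending in intrapartum CS (probability forced to one) yields a
    cesarean and one more prior CS."""
    p = _zeroed(params).with_overrides(p_intrapartum_cs_tolac=1.0)
    strat = cs.Strategy(
        id="tolac", target_cs_rate=0.5, access=1.0, hist_cs=1.0,
        p_nonind_antepartum=0.0, p_nonind_intrapartum=0.0,
    )
    table = PriorCsTable({0: PriorCsRow(0.0, 0.0, 0.0)})  # TOLAC for everyone
    leaves = enumerate_leaves(lambda ch: walk_episode(ch, p, strat, 1, table))
    assert len(leaves) == 1
    _, leaf = leaves[0]
    assert leaf.mode == "cesarean"
    assert leaf.next_prior_cs == 2
    assert leaf.events.get("tolac") == 1


def test_dead_state_is_absorbing(params, strategies, prior_table):
    w = WomanState(age=20, state=HealthState.DEAD, cum_qaly=3.0, cum_cost=10.0)
    rng = np.random.default_rng(0)
    out = cs.cycle_transition(w, params, strategies["A_national"], rng, prior_table)
    assert out.state is HealthState.DEAD
    assert out.cum_qaly == 3.0 and out.cum_cost == 10.0 and out.age == 20


def test_post_hysterectomy_never_pregnant_and_earns_its_utility(params, strategies, prior_table):
    p = params.with_overrides(p_pregnancy=1.0)
    w = WomanState(age=20, state=HealthState.POST_HYSTERECTOMY, had_hysterectomy=True)
    rng = np.random.default_rng(0)
    for _ in range(5):
        cs.cycle_transition(w, p, strategies["A_national"], rng, prior_table)
    assert w.state is HealthState.POST_HYSTERECTOMY
    assert w.tally.pregnancies_to_term == 0
    assert w.cum_qaly == pytest.approx(5 * 0.94)


def test_branch_overflow_renormalizes(caplog):
    """A node whose explicit branches sum above one is renormalized
    proportionally rather than producing an invalid draw."""
    ch = RngChooser(np.random.default_rng(0))
    with caplog.at_level("WARNING"):
        draws = [ch.choice((0.8, 0.6), label="overflow-test") for _ in range(200)]
    assert set(draws) <= {0, 1}  # complement has zero renormalized mass
    assert abs(np.mean([d == 0 for d in draws]) - 0.8 / 1.4) < 0.1


@settings(derandomize=True, max_examples=60, deadline=None)
@given(seed=st.integers(0, 10_000), prior=st.integers(0, 8))
def test_episode_outcome_invariants(seed, prior):
    """Any sampled episode is internally consistent: the delivery mode
    matches the prior-CS increment, exactly one neonatal outcome occurs,
    and a performed hysterectomy is costed."""
    reg = cs.default_registry()
    p = cs.baseline_set(reg)
    table = cs.default_prior_cs_table()
    strat = cs.builtin_strategies()["C_urban"]
    out = walk_episode(RngChooser(np.random.default_rng(seed)), p, strat, prior, table)
    assert out.mode in ("vaginal", "cesarean")
    assert out.next_prior_cs == prior + (1 if out.mode == "cesarean" else 0)
    assert out.events.get("live_births", 0) + out.events.get("neonatal_deaths", 0) == 1
    assert all(v >= 0 for v in out.events.values())
    if out.hysterectomy_performed:
        assert out.episode_cost >= p["cost_hysterectomy"]
    if out.maternal_died:
        assert out.events.get("maternal_deaths") == 1
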