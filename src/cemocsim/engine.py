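"""Cohort simulation engines.

Two interchangeable evaluators produce a :class:`CohortResult` for a
(strategy, parameter set) pair:

``run_cohort``
    First-order Monte Carlo: each of ``n_women`` women walks the
    state-transition model individually for ``horizon_cycles`` annual
    cycles, with one RNG substream per (seed, woman, cycle) so results are
    reproducible and strategies can be compared with common random numbers.

``expected_value``
    Exact expectation by per-cycle dynamic programming over the small
    (health state x prior-CS count) space, with the delivery-episode tree
    enumerated analytically.  It is the verification oracle for the Monte
    Carlo engine and the deterministic evaluator used by calibration and
    the sensitivity sweeps.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .natural_history import (
    EVENT_KEYS,
    EventTally,
    HealthState,
    RngChooser,
    WomanState,
    cycle_transition,
    enumerate_leaves,
    walk_episode,
)
from .parameters import ParameterSet, PriorCsTable, default_prior_cs_table

#: Prior-CS counts above this reuse the top row of the prior-CS table and
#: collapse to one state in the exact evaluator.
PRIOR_CS_CAP = 5


@dataclass(frozen=True)
class RunConfig:
    """Run settings for one cohort evaluation."""

    n_women: int = 10_000
    horizon_cycles: int = 35
    cycle_length_years: float = 1.0
    seed: int = 0
    strategy_id: str | None = None
    half_cycle_correction: bool = True
    discount_rate_costs: float = 0.0
    discount_rate_qalys: float = 0.0

    def __post_init__(self) -> None:
        if self.n_women < 1:
            raise ValueError("n_women must be >= 1")
        if self.horizon_cycles < 1:
            raise ValueError("horizon_cycles must be >= 1")
        if self.discount_rate_costs < 0 or self.discount_rate_qalys < 0:
            raise ValueError("discount rates must be >= 0")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        return cls(**data)


@dataclass(frozen=True)
class CohortResult:
    """Per-strategy mean cost/QALY with Monte Carlo error and event totals."""

    mean_cost: float
    mean_qaly: float
    se_cost: float
    se_qaly: float
    tally_totals: EventTally
    n_women: int
    seed: int
    strategy_id: str | None = None
    method: str = "monte_carlo"

    def to_json_dict(self) -> dict:
        return {
            "strategy_id": self.strategy_id,
            "method": self.method,
            "n_women": self.n_women,
            "seed": self.seed,
            "mean_cost": self.mean_cost,
            "mean_qaly": self.mean_qaly,
            "se_cost": self.se_cost,
            "se_qaly": self.se_qaly,
            "tally_totals": self.tally_totals.to_dict(),
        }


def initialize_woman(params: ParameterSet, strategy, rng) -> WomanState:
    """Draw a 14-year-old entrant: post-hysterectomy history with
    probability 0.017, otherwise non-pregnant; one prior CS with the
    strategy's history-of-CS prevalence."""
    ch = rng if hasattr(rng, "bernoulli") else RngChooser(rng)
    if ch.bernoulli(params["p_hist_hysterectomy"], "hist_hysterectomy"):
        return WomanState(age=14, state=HealthState.POST_HYSTERECTOMY, had_hysterectomy=True)
    prior = 1 if ch.bernoulli(strategy.hist_cs_value(params), "hist_cs") else 0
    return WomanState(age=14, state=HealthState.NON_PREGNANT, prior_cs_count=prior)


def run_cohort(
    config: RunConfig,
    params: ParameterSet,
    strategy,
    prior_table: PriorCsTable | None = None,
) -> CohortResult:
    """First-order Monte Carlo simulation of ``config.n_women`` women."""
    prior_table = prior_table or default_prior_cs_table()
    totals = EventTally()
    sum_c = sum_c2 = sum_q = sum_q2 = 0.0
    seed = config.seed
    hcc = config.half_cycle_correction
    rc, rq = config.discount_rate_costs, config.discount_rate_qalys
    for widx in range(config.n_women):
        rng0 = np.random.default_rng((seed, widx, 0))
        w = initialize_woman(params, strategy, rng0)
        for cyc in range(1, config.horizon_cycles + 1):
            if w.state is HealthState.DEAD:
                break
            cw = (1.0 + rc) ** -(cyc - 1) if rc else 1.0
            qw = (1.0 + rq) ** -(cyc - 1) if rq else 1.0
            rng = np.random.default_rng((seed, widx, cyc))
            cycle_transition(
                w,
                params,
                strategy,
                rng,
                prior_table=prior_table,
                half_cycle_correction=hcc,
                cost_weight=cw,
                qaly_weight=qw,
            )
        totals.merge(w.tally)
        sum_c += w.cum_cost
        sum_c2 += w.cum_cost**2
        sum_q += w.cum_qaly
        sum_q2 += w.cum_qaly**2
    n = config.n_women
    mean_c, mean_q = sum_c / n, sum_q / n
    var_c = max(sum_c2 / n - mean_c**2, 0.0)
    var_q = max(sum_q2 / n - mean_q**2, 0.0)
    return CohortResult(
        mean_cost=mean_c,
        mean_qaly=mean_q,
        se_cost=math.sqrt(var_c / n),
        se_qaly=math.sqrt(var_q / n),
        tally_totals=totals,
        n_women=n,
        seed=seed,
        strategy_id=getattr(strategy, "id", None) or config.strategy_id,
        method="monte_carlo",
    )


class _EpisodeSummary:
    """Leaf-aggregated view of the delivery tree for one prior-CS count:
    expected cost/events and the exact transition kernel of the episode."""

    __slots__ = ("cost", "events", "utility_hcc", "utility_raw", "trans")

    def __init__(self, leaves, params, prior_cs_cap):
        u_preg = params["u_pregnant"]
        u_np = params["u_nonpregnant"]
        u_ph = params["u_hysterectomy"]
        u_dead = params["u_dead"]
        self.cost = 0.0
        self.events = {k: 0.0 for k in EVENT_KEYS}
        self.utility_hcc = 0.0
        self.utility_raw = u_preg  # entry-state utility, no half-cycle averaging
        self.trans: dict[tuple[str, int], float] = {}
        total = 0.0
        for prob, leaf in leaves:
            total += prob
            self.cost += prob * leaf.episode_cost
            for k, v in leaf.events.items():
                self.events[k] += prob * v
            if leaf.maternal_died:
                dest, u_exit = ("DEAD", 0), u_dead
            elif leaf.hysterectomy_performed:
                dest, u_exit = ("PH", 0), u_ph
            else:
                dest = ("NP", min(leaf.next_prior_cs, prior_cs_cap))
                u_exit = u_np
            self.utility_hcc += prob * 0.5 * (u_preg + u_exit)
            self.trans[dest] = self.trans.get(dest, 0.0) + prob
        if abs(total - 1.0) > 1e-9:
            raise AssertionError(
                f"episode leaf probabilities sum to {total!r}, expected 1"
            )


def expected_value(
    config: RunConfig,
    params: ParameterSet,
    strategy,
    prior_table: PriorCsTable | None = None,
    prior_cs_cap: int = PRIOR_CS_CAP,
) -> CohortResult:
    """Exact expected cost, QALYs and event counts for one strategy.

    Enumerates every delivery-tree leaf analytically for each prior-CS
    count, then propagates the cohort distribution over
    ``{non-pregnant x prior-CS count, post-hysterectomy, dead}`` cycle by
    cycle.  Standard errors are zero; ``tally_totals`` are expected counts
    scaled to ``config.n_women`` women.
    """
    prior_table = prior_table or default_prior_cs_table()
    if prior_cs_cap < 1 or prior_cs_cap > 12:
        raise ValueError("prior_cs_cap must be within [1, 12] (state-space bound)")
    episodes = {
        c: _EpisodeSummary(
            enumerate_leaves(
                lambda ch, c=c: walk_episode(ch, params, strategy, c, prior_table)
            ),
            params,
            prior_cs_cap,
        )
        for c in range(prior_cs_cap + 1)
    }
    p_preg = params["p_pregnancy"]
    u_np = params["u_nonpregnant"]
    u_ph = params["u_hysterectomy"]
    hcc = config.half_cycle_correction
    rc, rq = config.discount_rate_costs, config.discount_rate_qalys

    # initial distribution
    p_hh = params["p_hist_hysterectomy"]
    p_hcs = strategy.hist_cs_value(params)
    mass: dict[tuple[str, int], float] = {("PH", 0): p_hh, ("DEAD", 0): 0.0}
    for c in range(prior_cs_cap + 1):
        mass[("NP", c)] = 0.0
    mass[("NP", 1)] = (1 - p_hh) * p_hcs
    mass[("NP", 0)] = (1 - p_hh) * (1 - p_hcs)

    exp_cost = exp_qaly = 0.0
    exp_events = {k: 0.0 for k in EVENT_KEYS}
    for cyc in range(1, config.horizon_cycles + 1):
        cw = (1.0 + rc) ** -(cyc - 1) if rc else 1.0
        qw = (1.0 + rq) ** -(cyc - 1) if rq else 1.0
        nxt = {k: 0.0 for k in mass}
        exp_qaly += qw * mass[("PH", 0)] * u_ph
        nxt[("PH", 0)] += mass[("PH", 0)]
        nxt[("DEAD", 0)] += mass[("DEAD", 0)]
        for c in range(prior_cs_cap + 1):
            m = mass[("NP", c)]
            if m <= 0.0:
                continue
            stay = m * (1 - p_preg)
            exp_qaly += qw * stay * u_np
            nxt[("NP", c)] += stay
            preg = m * p_preg
            if preg <= 0.0:
                continue
            ep = episodes[c]
            exp_cost += cw * preg * ep.cost
            exp_qaly += qw * preg * (ep.utility_hcc if hcc else ep.utility_raw)
            for k, v in ep.events.items():
                if v:
                    exp_events[k] += preg * v
            for dest, tp in ep.trans.items():
                nxt[dest] += preg * tp
        mass = nxt

    n = config.n_women
    totals = EventTally({k: v * n for k, v in exp_events.items()})
    return CohortResult(
        mean_cost=exp_cost,
        mean_qaly=exp_qaly,
        se_cost=0.0,
        se_qaly=0.0,
        tally_totals=totals,
        n_women=n,
        seed=config.seed,
        strategy_id=getattr(strategy, "id", None) or config.strategy_id,
        method="expected_value",
    )
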