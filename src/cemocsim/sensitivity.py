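"""Deterministic one-way sweeps, the two-way access x CS-rate surface, and
probabilistic sensitivity analysis (PSA).

One-way and two-way analyses are evaluated on the exact expected-value
engine, so sweeps are smooth in the swept parameter (no Monte Carlo
jitter) and trivially satisfy common random numbers.  PSA resamples every
registered parameter jointly from its distribution; strategies are
evaluated per draw and the optimal strategy at the willingness-to-pay
threshold is recorded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calibration import Strategy, calibrate
from .cea import CEAConfig, build_frontier, select_optimal
from .engine import RunConfig, expected_value, run_cohort
from .parameters import (
    ParameterRegistry,
    PriorCsTable,
    baseline_set,
    default_prior_cs_table,
    sample_set,
)

logger = logging.getLogger(__name__)

#: Parameters examined one-way in the published analysis.
DEFAULT_ONE_WAY_PARAMETERS = (
    "p_pph_vaginal",
    "p_pph_previa",
    "p_pph_accreta",
    "p_pph_rupture",
    "p_intrapartum_cs_tolac",
    "p_rupture_tolac",
    "p_icu_hysterectomy",
    "p_hyst_accreta",
    "p_hyst_rupture",
    "p_death_pph_vaginal",
    "p_death_antepartum_indication",
    "p_death_intrapartum_indication",
    "p_death_icu",
    "cost_icu",
    "cost_cs",
    "cost_vaginal",
)


@dataclass(frozen=True)
class SweepSpec:
    parameter_id: str
    low: float
    high: float
    n_points: int = 11
    metric: str = "optimal_strategy"

    def __post_init__(self) -> None:
        if self.low >= self.high:
            raise ValueError("low must be < high")
        if self.n_points < 2:
            raise ValueError("n_points must be >= 2")


def default_sweep(registry: ParameterRegistry, pid: str, n_points: int = 11) -> SweepSpec:
    """+/-50% of baseline, clipped to the units-legal range."""
    spec = registry[pid]
    lo, hi = 0.5 * spec.baseline, 1.5 * spec.baseline
    if spec.units in ("probability", "utility"):
        hi = min(hi, 1.0)
    return SweepSpec(pid, lo, hi, n_points)


def _legal_bounds(units: str) -> tuple[float, float]:
    if units in ("probability", "utility"):
        return 0.0, 1.0
    return 0.0, float("inf")


def _evaluate_strategies(strategies, params, config, prior_table, evaluator="expected"):
    fn = expected_value if evaluator == "expected" else run_cohort
    return [fn(config, params, s, prior_table) for s in strategies]


def one_way(
    spec: SweepSpec,
    registry: ParameterRegistry,
    strategies: list[Strategy],
    config: RunConfig,
    cea_config: CEAConfig | None = None,
    prior_table: PriorCsTable | None = None,
) -> pd.DataFrame:
    """Sweep one parameter; at each grid value rebuild the parameter set
    with the single substitution and recompute the frontier.

    Returns a long-format table: value, strategy_id, mean_cost, mean_qaly,
    status, optimal_strategy.
    """
    if spec.parameter_id not in registry:
        raise KeyError(spec.parameter_id)
    cea_config = cea_config or CEAConfig()
    prior_table = prior_table or default_prior_cs_table()
    lo_leg, hi_leg = _legal_bounds(registry[spec.parameter_id].units)
    lo, hi = spec.low, spec.high
    if lo < lo_leg or hi > hi_leg:
        logger.warning(
            "sweep range [%g, %g] for %s clipped to legal bounds", lo, hi, spec.parameter_id
        )
        lo, hi = max(lo, lo_leg), min(hi, hi_leg)
    base = baseline_set(registry)
    rows = []
    for value in np.linspace(lo, hi, spec.n_points):
        params = base.with_overrides(**{spec.parameter_id: float(value)})
        results = _evaluate_strategies(strategies, params, config, prior_table)
        entries = build_frontier(
            [(r.strategy_id, r.mean_cost, r.mean_qaly) for r in results]
        )
        optimal = select_optimal(entries, cea_config)
        for e in entries:
            rows.append(
                {
                    "parameter_id": spec.parameter_id,
                    "value": float(value),
                    "strategy_id": e.strategy_id,
                    "mean_cost": e.mean_cost,
                    "mean_qaly": e.mean_qaly,
                    "status": e.dominated,
                    "optimal_strategy": optimal,
                }
            )
    return pd.DataFrame(rows)


def two_way(
    access_range: tuple[float, float],
    cs_rate_range: tuple[float, float],
    n_points: int,
    registry: ParameterRegistry,
    config: RunConfig,
    prior_table: PriorCsTable | None = None,
    hist_cs: float = 0.172,
    grid_step: float = 0.001,
    tolerance: float = 0.005,
) -> pd.DataFrame:
    """Decision surface over the (access to CEmOC, CS rate) plane.

    Each cell defines a custom strategy calibrated to its CS rate; cells
    whose target lies below the medically indicated floor are labelled
    ``floor_constrained`` rather than dropped.  Returns one row per cell
    with cost, QALY and the calibration certificate.
    """
    for lo, hi in (access_range, cs_rate_range):
        if not (0.0 <= lo < hi <= 1.0):
            raise ValueError("ranges must lie within [0, 1] with low < high")
    prior_table = prior_table or default_prior_cs_table()
    params = baseline_set(registry)
    rows = []
    for access in np.linspace(*access_range, n_points):
        for cs_rate in np.linspace(*cs_rate_range, n_points):
            strat = Strategy(
                id=f"cell_a{access:.3f}_c{cs_rate:.3f}",
                target_cs_rate=float(cs_rate),
                access=float(access),
                hist_cs=hist_cs,
            )
            cal = calibrate(
                strat,
                params,
                config,
                grid_step=grid_step,
                tolerance=tolerance,
                prior_table=prior_table,
            )
            res = expected_value(config, params, cal.strategy, prior_table)
            rows.append(
                {
                    "access": float(access),
                    "cs_rate": float(cs_rate),
                    "achieved_cs_rate": cal.achieved_rate,
                    "calibrated": cal.success,
                    "floor_constrained": cal.floor_constrained,
                    "mean_cost": res.mean_cost,
                    "mean_qaly": res.mean_qaly,
                }
            )
    return pd.DataFrame(rows)


def qaly_gradients(surface: pd.DataFrame, access0: float, cs_rate0: float) -> tuple[float, float]:
    """Central/one-sided finite-difference |dQALY/daccess| and
    |dQALY/dCS-rate| at the grid cell nearest (access0, cs_rate0)."""
    acc = np.sort(surface["access"].unique())
    cs = np.sort(surface["cs_rate"].unique())
    ia = int(np.argmin(np.abs(acc - access0)))
    ic = int(np.argmin(np.abs(cs - cs_rate0)))

    def q(a, c):
        row = surface[(surface["access"] == a) & (surface["cs_rate"] == c)]
        return float(row["mean_qaly"].iloc[0])

    ia0, ia1 = max(ia - 1, 0), min(ia + 1, len(acc) - 1)
    ic0, ic1 = max(ic - 1, 0), min(ic + 1, len(cs) - 1)
    d_access = (q(acc[ia1], cs[ic]) - q(acc[ia0], cs[ic])) / (acc[ia1] - acc[ia0])
    d_cs = (q(acc[ia], cs[ic1]) - q(acc[ia], cs[ic0])) / (cs[ic1] - cs[ic0])
    return abs(d_access), abs(d_cs)


@dataclass(frozen=True)
class PsaResult:
    draws: pd.DataFrame  # columns: draw, strategy_id, mean_cost, mean_qaly, optimal
    n_draws: int
    seed: int
    optimal_freq: dict[str, float]


def run_psa(
    n_draws: int,
    registry: ParameterRegistry,
    strategies: list[Strategy],
    config: RunConfig,
    cea_config: CEAConfig | None = None,
    seed: int = 0,
    evaluator: str = "monte_carlo",
    prior_table: PriorCsTable | None = None,
) -> PsaResult:
    """Joint resampling of all parameters; per draw every strategy is
    evaluated (with common random numbers under the Monte Carlo evaluator,
    via the shared per-(woman, cycle) streams) and the optimal strategy at
    the WTP threshold recorded.  Calibrated non-indicated CS probabilities
    are held at their baseline-calibrated values across draws.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    cea_config = cea_config or CEAConfig()
    prior_table = prior_table or default_prior_cs_table()
    rows = []
    counts: dict[str, int] = {s.id: 0 for s in strategies}
    for d in range(n_draws):
        draw_seed = int(np.random.SeedSequence((seed, d)).generate_state(1)[0] % (2**31))
        params = sample_set(registry, draw_seed)
        results = _evaluate_strategies(
            strategies, params, config, prior_table, evaluator=evaluator
        )
        entries = build_frontier(
            [(r.strategy_id, r.mean_cost, r.mean_qaly) for r in results]
        )
        optimal = select_optimal(entries, cea_config)
        counts[optimal] += 1
        for r in results:
            rows.append(
                {
                    "draw": d,
                    "strategy_id": r.strategy_id,
                    "mean_cost": r.mean_cost,
                    "mean_qaly": r.mean_qaly,
                    "optimal": optimal,
                }
            )
    freq = {k: v / n_draws for k, v in counts.items()}
    return PsaResult(draws=pd.DataFrame(rows), n_draws=n_draws, seed=seed, optimal_freq=freq)
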