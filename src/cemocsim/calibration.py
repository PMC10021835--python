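"""Strategies and grid calibration of the non-indicated CS probabilities.

The non-indicated antepartum/intrapartum CS probabilities are not directly
observed; they are estimated by sweeping them over a regular grid — holding
their baseline ratio (0.0094 : 0.018) fixed — until the simulated overall
CS rate (cesarean deliveries per full-term pregnancy) matches the
strategy's observed target rate.  The sweep is evaluated on the exact
expected-value engine by default, so grid selection is free of Monte Carlo
jitter; a rural-style target at or below the rate implied by medically
indicated CS alone forces both probabilities to zero.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from importlib import resources

import pandas as pd

from .engine import CohortResult, RunConfig, expected_value, run_cohort
from .parameters import ParameterSet, PriorCsTable, default_prior_cs_table

#: Printed baseline ratio between the two calibrated probabilities.
NONIND_BASELINES = (0.0094, 0.018)


@dataclass(frozen=True)
class Strategy:
    """An (access to CEmOC, target CS rate) policy arm.

    ``access_param``/``hist_cs_param`` name registry parameters so PSA draws
    propagate into the strategy; fixed numeric overrides are also accepted.
    """

    id: str
    target_cs_rate: float
    access: float | None = None
    access_param: str | None = None
    hist_cs: float | None = None
    hist_cs_param: str | None = None
    p_nonind_antepartum: float = NONIND_BASELINES[0]
    p_nonind_intrapartum: float = NONIND_BASELINES[1]
    calibrated: bool = False

    def __post_init__(self) -> None:
        for name in ("target_cs_rate", "p_nonind_antepartum", "p_nonind_intrapartum"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{self.id}: {name}={v} outside [0, 1]")
        if self.access is None and self.access_param is None:
            raise ValueError(f"{self.id}: need access or access_param")

    def access_value(self, params: ParameterSet) -> float:
        if self.access is not None:
            return self.access
        return params[self.access_param]

    def hist_cs_value(self, params: ParameterSet) -> float:
        if self.hist_cs is not None:
            return self.hist_cs
        if self.hist_cs_param is not None:
            return params[self.hist_cs_param]
        return 0.0


def load_strategies(path) -> dict[str, Strategy]:
    df = pd.read_csv(path)
    out = {}
    for _, r in df.iterrows():
        s = Strategy(
            id=str(r["id"]),
            target_cs_rate=float(r["target_cs_rate"]),
            access_param=str(r["access_param"]) if pd.notna(r.get("access_param")) else None,
            access=float(r["access"]) if "access" in df.columns and pd.notna(r.get("access")) else None,
            hist_cs_param=str(r["hist_cs_param"]) if pd.notna(r.get("hist_cs_param")) else None,
        )
        out[s.id] = s
    return out


def builtin_strategies() -> dict[str, Strategy]:
    """The three published policy arms: A (national average), B (rural),
    C (urban)."""
    with resources.as_file(
        resources.files("cemocsim.data").joinpath("strategies.csv")
    ) as path:
        return load_strategies(path)


def achieved_cs_rate(result: CohortResult) -> float:
    """Cesarean sections per full-term pregnancy."""
    preg = result.tally_totals.pregnancies_to_term
    if preg <= 0:
        raise ValueError("undefined CS rate: no full-term pregnancies")
    return result.tally_totals.cesarean_sections / preg


@dataclass(frozen=True)
class CalibrationResult:
    strategy: Strategy
    grid: list[tuple[float, float, float]]  # (p_antepartum, p_intrapartum, achieved)
    selected: tuple[float, float]
    achieved_rate: float
    target_rate: float
    tolerance: float
    seed: int
    success: bool
    floor_rate: float
    floor_constrained: bool = False

    def grid_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.grid, columns=["p_nonind_antepartum", "p_nonind_intrapartum", "achieved_cs_rate"]
        )


def _evaluate(strategy, params, config, prior_table, evaluator):
    if evaluator == "expected":
        return expected_value(config, params, strategy, prior_table)
    return run_cohort(config, params, strategy, prior_table)


def calibrate(
    strategy: Strategy,
    params: ParameterSet,
    config: RunConfig,
    grid_step: float = 0.001,
    tolerance: float = 0.005,
    ratio: tuple[float, float] = NONIND_BASELINES,
    evaluator: str = "expected",
    prior_table: PriorCsTable | None = None,
) -> CalibrationResult:
    """Grid-search the non-indicated CS probabilities to hit the target rate.

    Sweeps ``p_nonind_antepartum`` over a regular grid (a coarse pass at
    10x ``grid_step`` followed by a fine pass at ``grid_step`` around the
    coarse optimum — equivalent to the full fine grid because the achieved
    rate is monotone in the swept probability) with
    ``p_nonind_intrapartum`` locked to the printed ratio.  Returns the grid
    point minimizing ``|achieved - target|`` and a recalibrated strategy.
    """
    if grid_step <= 0:
        raise ValueError("grid_step must be > 0")
    prior_table = prior_table or default_prior_cs_table()
    target = strategy.target_cs_rate
    scale = ratio[1] / ratio[0]

    def rate_at(p_ante: float) -> float:
        trial = replace(
            strategy,
            p_nonind_antepartum=p_ante,
            p_nonind_intrapartum=min(p_ante * scale, 1.0),
            calibrated=False,
        )
        return achieved_cs_rate(_evaluate(trial, params, config, prior_table, evaluator))

    grid: list[tuple[float, float, float]] = []

    def record(p_ante: float) -> float:
        r = rate_at(p_ante)
        grid.append((p_ante, min(p_ante * scale, 1.0), r))
        return r

    floor = record(0.0)
    if target <= floor:
        # No CS are performed without indication when the observed rate is
        # already at or below the medically indicated rate.
        achieved = floor
        selected = (0.0, 0.0)
        success = abs(achieved - target) <= tolerance
        cal = replace(
            strategy,
            p_nonind_antepartum=0.0,
            p_nonind_intrapartum=0.0,
            calibrated=success,
        )
        return CalibrationResult(
            strategy=cal,
            grid=grid,
            selected=selected,
            achieved_rate=achieved,
            target_rate=target,
            tolerance=tolerance,
            seed=config.seed,
            success=success,
            floor_rate=floor,
            floor_constrained=True,
        )

    p_max = min(0.95, 0.95 / scale)
    coarse = 10.0 * grid_step
    best_p, best_err = 0.0, abs(floor - target)
    p = coarse
    while p <= p_max + 1e-12:
        r = record(p)
        err = abs(r - target)
        if err < best_err:
            best_p, best_err = p, err
        if r > target + coarse:  # monotone: no need to sweep further
            break
        p += coarse
    lo = max(0.0, best_p - coarse)
    hi = min(p_max, best_p + coarse)
    p = lo
    while p <= hi + 1e-12:
        r = record(p)
        err = abs(r - target)
        if err < best_err - 1e-15:
            best_p, best_err = p, err
        p += grid_step

    achieved = rate_at(best_p)
    success = abs(achieved - target) <= tolerance
    cal = replace(
        strategy,
        p_nonind_antepartum=best_p,
        p_nonind_intrapartum=min(best_p * scale, 1.0),
        calibrated=success,
    )
    return CalibrationResult(
        strategy=cal,
        grid=grid,
        selected=(cal.p_nonind_antepartum, cal.p_nonind_intrapartum),
        achieved_rate=achieved,
        target_rate=target,
        tolerance=tolerance,
        seed=config.seed,
        success=success,
        floor_rate=floor,
        floor_constrained=False,
    )
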