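"""Synthetic inputs with the statistical structure the pipeline assumes.

Two generators back the test suite and let every stage run without any
external data: :func:`random_parameter_table` emits randomized-but-valid
parameter tables in the registry CSV dialect (so the real I/O path is
exercised), and :func:`degenerate_scenarios` builds parameter sets whose
outcomes have closed forms, usable as exact oracles for both the Monte
Carlo and expected-value engines.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .calibration import Strategy
from .parameters import (
    ParameterRegistry,
    ParameterSet,
    PriorCsRow,
    PriorCsTable,
    baseline_set,
    default_prior_cs_table,
    default_registry,
    load_registry,
)

#: Prior-CS table with placentation risks switched off, for closed forms.
ZERO_PRIOR_TABLE = PriorCsTable({0: PriorCsRow(0.0, 0.0, 0.0)})

#: Concentration of the beta distributions attached to randomized
#: probability rows (mean = drawn baseline).
_KAPPA = 50.0


def random_parameter_table(seed: int, out_path=None) -> pd.DataFrame:
    """Randomized registry table: probabilities in (0, 1) with node-sum
    feasibility at every decision node, costs log-uniform in [10, 5000],
    utilities in [0.5, 1].  Always passes :func:`load_registry`."""
    rng = np.random.default_rng(seed)
    base = default_registry()
    rows = []
    # trial-of-labor node: three explicit siblings must leave room for VBAC
    tolac_node = {"p_rupture_tolac", "p_intrapartum_cs_tolac", "p_nonind_intrapartum_tolac"}
    tolac_draw = rng.dirichlet((1.0, 1.0, 1.0, 1.0))[:3] * rng.uniform(0.3, 0.95)
    tolac_vals = dict(zip(sorted(tolac_node), np.sort(tolac_draw)[::-1]))
    # antepartum node: previa/accreta come from the prior-CS table (small);
    # keep the in-registry sibling comfortably below 1
    for spec in base:
        if spec.units == "probability":
            if spec.id in tolac_node:
                v = float(tolac_vals[spec.id])
            elif spec.id == "p_antepartum_indication":
                v = float(rng.uniform(0.005, 0.4))
            else:
                v = float(rng.uniform(0.0005, 0.6))
            a, b = max(v * _KAPPA, 1e-3), max((1 - v) * _KAPPA, 1e-3)
            rows.append((spec.id, v, "beta", f"{a!r};{b!r}", "probability"))
        elif spec.units == "usd_2016":
            v = float(np.exp(rng.uniform(np.log(10.0), np.log(5000.0))))
            rows.append((spec.id, v, "gamma", f"16.0;{v / 16.0!r}", "usd_2016"))
        else:  # utility
            if spec.id == "u_dead":
                rows.append((spec.id, 0.0, "point", "0.0", "utility"))
                continue
            v = float(rng.uniform(0.5, 1.0))
            lo, hi = max(0.5, v - 0.02), min(1.0, v + 0.02)
            rows.append((spec.id, v, "uniform", f"{lo!r};{hi!r}", "utility"))
    df = pd.DataFrame(
        rows, columns=["id", "baseline", "family", "params", "units"]
    )
    df["description"] = "synthetic"
    df["source"] = f"random_parameter_table(seed={seed})"
    if out_path is not None:
        df.to_csv(Path(out_path), index=False)
    return df


def random_registry(seed: int) -> ParameterRegistry:
    """Randomized table parsed back through the real loader."""
    import io

    buf = io.StringIO()
    random_parameter_table(seed).to_csv(buf, index=False)
    buf.seek(0)
    return load_registry(buf)


@dataclass(frozen=True)
class ScenarioFixture:
    """A parameter set + strategy whose outcomes have stated closed forms.

    ``expected``: metric name -> (value or None for 'undefined', provenance
    in {closed_form, enumeration}).  ``tolerance`` applies to the Monte
    Carlo engine; the expected-value engine must match exactly (1e-9).
    """

    name: str
    params: ParameterSet
    strategy: Strategy
    horizon_cycles: int
    expected: dict[str, tuple[float | None, str]]
    tolerance: float
    prior_table: PriorCsTable | None = None


def _zeroed(params: ParameterSet, *, keep: set[str] = frozenset()) -> ParameterSet:
    overrides = {
        pid: 0.0
        for pid in params.values
        if pid.startswith("p_") and pid not in keep
    }
    return params.with_overrides(**overrides)


def degenerate_scenarios() -> list[ScenarioFixture]:
    """Boundary scenarios with closed-form outcomes.

    (i)   zero fertility: nobody is ever pregnant, QALY = horizon exactly;
    (ii)  certain pregnancy, no complications, full access, one cycle:
          cost is the two-leaf form p*cost_cs + (1-p)*cost_vaginal;
    (iii) no access, certain absolute indication: every pregnancy ends in
          a neonatal death, live births = 0, mortality rates undefined;
    (iv)  certain pregnancy, certain antepartum indication, certain
          mortality: every woman dies in her first delivery, so lifetime
          QALY is half the pregnancy utility (half-cycle convention).
    """
    base = baseline_set(default_registry())
    default_table = default_prior_cs_table()
    scenarios = []

    p0 = _zeroed(base)
    scenarios.append(
        ScenarioFixture(
            name="zero_fertility",
            params=p0,
            strategy=Strategy(id="any", target_cs_rate=0.5, access=1.0, hist_cs=0.0),
            horizon_cycles=35,
            expected={
                "mean_qaly": (35.0, "closed_form"),
                "mean_cost": (0.0, "closed_form"),
            },
            tolerance=0.0,
            prior_table=default_table,
        )
    )

    p_nonind = 0.0094
    p2 = _zeroed(base).with_overrides(p_pregnancy=1.0)
    cost2 = p_nonind * base["cost_cs"] + (1 - p_nonind) * base["cost_vaginal"]
    scenarios.append(
        ScenarioFixture(
            name="certain_pregnancy_no_complications",
            params=p2,
            strategy=Strategy(
                id="full_access",
                target_cs_rate=0.5,
                access=1.0,
                hist_cs=0.0,
                p_nonind_antepartum=p_nonind,
                p_nonind_intrapartum=0.0,
            ),
            horizon_cycles=1,
            expected={
                "mean_cost": (cost2, "closed_form"),
                "neonatal_deaths_per_woman": (0.0, "closed_form"),
            },
            tolerance=25.0,  # USD; Monte Carlo noise at moderate cohort sizes
            prior_table=ZERO_PRIOR_TABLE,  # closed form excludes placentation
        )
    )

    p3 = _zeroed(base).with_overrides(p_pregnancy=1.0, p_antepartum_indication=1.0)
    scenarios.append(
        ScenarioFixture(
            name="no_access_certain_indication",
            params=p3,
            strategy=Strategy(id="no_access", target_cs_rate=0.0, access=0.0, hist_cs=0.0),
            horizon_cycles=2,
            expected={
                "neonatal_deaths_equal_pregnancies": (1.0, "closed_form"),
                "live_births_per_woman": (0.0, "closed_form"),
                "nmr_per_1000": (None, "closed_form"),  # undefined denominator
            },
            tolerance=0.0,
            prior_table=default_table,
        )
    )

    p4 = _zeroed(base).with_overrides(
        p_pregnancy=1.0,
        p_antepartum_indication=1.0,
        p_death_antepartum_indication=1.0,
    )
    scenarios.append(
        ScenarioFixture(
            name="certain_first_delivery_death",
            params=p4,
            strategy=Strategy(id="full_access", target_cs_rate=0.5, access=1.0, hist_cs=0.0),
            horizon_cycles=35,
            expected={
                "mean_qaly": (0.5 * base["u_pregnant"], "closed_form"),
                "maternal_deaths_per_woman": (1.0, "closed_form"),
            },
            tolerance=0.0,
            prior_table=default_table,
        )
    )
    return scenarios


def write_fixtures(out_dir) -> list[Path]:
    """Emit fixture tables as CSV files in the registry/strategy dialects."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for seed in (0, 1, 2):
        path = out_dir / f"random_parameters_seed{seed}.csv"
        random_parameter_table(seed, path)
        written.append(path)
    for sc in degenerate_scenarios():
        df = pd.DataFrame(
            [{"id": k, "value": v} for k, v in sc.params.values.items()]
        )
        path = out_dir / f"scenario_{sc.name}.csv"
        df.to_csv(path, index=False)
        written.append(path)
    return written
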