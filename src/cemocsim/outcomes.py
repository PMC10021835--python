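"""Reporting units: events per 10,000 women per year, national
extrapolation, and maternal/neonatal mortality rates.

The published event tables are annual rates: events per 10,000 women of
reproductive age per year, extrapolated to India's 2018 female population
of reproductive age.  :func:`summarize` therefore divides lifetime cohort
tallies by the simulated horizon; the raw lifetime per-10,000-women view is
kept alongside.  Mortality ratios use live births as denominator and are
undefined (``None``) when there are none.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .engine import CohortResult
from .natural_history import EVENT_KEYS

#: India's 2018 female population of reproductive age.  Recovered from the
#: published (per-10k, national) pairs: national / per_10k * 10,000 ~ 3.25e8.
DEFAULT_POPULATION = 325_000_000


@dataclass(frozen=True)
class OutcomeReport:
    strategy_id: str | None
    per_10k: dict[str, float]  # events per 10,000 women per year
    per_10k_lifetime: dict[str, float]  # events per 10,000 women over horizon
    national: dict[str, float]  # annual events in the reference population
    mmr_per_100k: float | None  # maternal deaths per 100,000 live births
    nmr_per_1000: float | None  # neonatal deaths per 1,000 live births
    population_reference: int
    horizon_years: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "event": k,
                    "per_10k_per_year": self.per_10k[k],
                    "per_10k_lifetime": self.per_10k_lifetime[k],
                    "national_per_year": self.national[k],
                }
                for k in EVENT_KEYS
            ]
        )


def summarize(
    result: CohortResult,
    population_reference: int = DEFAULT_POPULATION,
    horizon_years: float | None = None,
) -> OutcomeReport:
    """Convert cohort tallies to the published reporting units."""
    if result.n_women <= 0:
        raise ValueError("empty cohort")
    if horizon_years is None or horizon_years <= 0:
        raise ValueError("horizon_years (the simulated horizon) is required")
    tall = result.tally_totals.to_dict()
    lifetime = {k: v * 10_000 / result.n_women for k, v in tall.items()}
    annual = {k: v / horizon_years for k, v in lifetime.items()}
    national = {k: v * population_reference / 10_000 for k, v in annual.items()}
    lb = tall["live_births"]
    mmr = tall["maternal_deaths"] * 100_000 / lb if lb > 0 else None
    nmr = tall["neonatal_deaths"] * 1_000 / lb if lb > 0 else None
    return OutcomeReport(
        strategy_id=result.strategy_id,
        per_10k=annual,
        per_10k_lifetime=lifetime,
        national=national,
        mmr_per_100k=mmr,
        nmr_per_1000=nmr,
        population_reference=population_reference,
        horizon_years=horizon_years,
    )


def difference_table(base: OutcomeReport, alt: OutcomeReport) -> dict[str, tuple[float, float]]:
    """Signed per-event differences ``alt - base`` (per-10k/year, national).

    Positive numbers mean more events under ``alt``.
    """
    if base.population_reference != alt.population_reference:
        raise ValueError("reports use different reference populations")
    missing = set(base.per_10k) ^ set(alt.per_10k)
    if missing:
        raise ValueError(f"mismatched event keys: {sorted(missing)}")
    return {
        k: (alt.per_10k[k] - base.per_10k[k], alt.national[k] - base.national[k])
        for k in base.per_10k
    }


def difference_frame(base: OutcomeReport, alt: OutcomeReport) -> pd.DataFrame:
    diff = difference_table(base, alt)
    return pd.DataFrame(
        [
            {"event": k, "delta_per_10k_per_year": d10, "delta_national_per_year": dn}
            for k, (d10, dn) in diff.items()
        ]
    )
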