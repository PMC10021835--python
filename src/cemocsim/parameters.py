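"""Model parameters: registry, distributions, baseline and PSA realizations.

Every probability, cost (2016 USD) and health-state utility that drives the
microsimulation lives in a :class:`ParameterRegistry`, normally loaded from
the packaged CSV table (``data/parameters.csv``).  Each parameter carries a
baseline value and a sampling distribution (beta for probabilities, gamma
for costs, uniform for utilities, point for constants) used by the
probabilistic sensitivity analysis.  Placentation and delivery-mode risks
that depend on the number of previous cesarean sections are held separately
in a :class:`PriorCsTable`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

FAMILIES = ("beta", "gamma", "dirichlet", "uniform", "point")
UNITS = ("probability", "usd_2016", "utility")

#: Sibling branch probabilities drawn jointly at one decision node.  The
#: trial-of-labor node is the one standardized (Dirichlet) node whose three
#: explicit branches (uterine rupture, intrapartum CS, non-indicated
#: intrapartum CS) plus the VBAC complement must sum to one.
DEFAULT_DIRICHLET_GROUPS: tuple[tuple[str, ...], ...] = (
    ("p_rupture_tolac", "p_intrapartum_cs_tolac", "p_nonind_intrapartum_tolac"),
)


class RegistryError(ValueError):
    """Malformed parameter table (duplicate id, range violation, bad spec)."""


@dataclass(frozen=True)
class DistributionSpec:
    """Sampling distribution of a single parameter.

    ``params`` ordering: beta ``(alpha, beta)``; gamma ``(shape, scale)``;
    dirichlet ``(c1, ..., ck)`` (the parameter is the first component);
    uniform ``(low, high)``; point ``(value,)``.
    """

    family: str
    params: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise RegistryError(f"unknown distribution family {self.family!r}")
        p = self.params
        if self.family == "beta":
            if len(p) != 2 or p[0] <= 0 or p[1] <= 0:
                raise RegistryError(f"beta requires two positive params, got {p}")
        elif self.family == "gamma":
            if len(p) != 2 or p[0] <= 0 or p[1] <= 0:
                raise RegistryError(f"gamma requires two positive params, got {p}")
        elif self.family == "dirichlet":
            if len(p) < 2 or any(c <= 0 for c in p):
                raise RegistryError(f"dirichlet requires >=2 positive params, got {p}")
        elif self.family == "uniform":
            if len(p) != 2 or p[0] > p[1]:
                raise RegistryError(f"uniform requires low <= high, got {p}")
        elif self.family == "point":
            if len(p) != 1:
                raise RegistryError(f"point requires one param, got {p}")

    def mean(self) -> float:
        a = self.params
        if self.family == "beta":
            return a[0] / (a[0] + a[1])
        if self.family == "gamma":
            return a[0] * a[1]
        if self.family == "dirichlet":
            return a[0] / sum(a)
        if self.family == "uniform":
            return 0.5 * (a[0] + a[1])
        return a[0]

    def sample(self, rng: np.random.Generator) -> float:
        a = self.params
        if self.family == "beta":
            return float(rng.beta(a[0], a[1]))
        if self.family == "gamma":
            return float(rng.gamma(a[0], a[1]))
        if self.family == "dirichlet":
            return float(rng.dirichlet(a)[0])
        if self.family == "uniform":
            return float(rng.uniform(a[0], a[1]))
        return a[0]


@dataclass(frozen=True)
class ParameterSpec:
    id: str
    baseline: float
    distribution: DistributionSpec
    units: str
    description: str = ""
    source: str = ""

    def __post_init__(self) -> None:
        if self.units not in UNITS:
            raise RegistryError(f"{self.id}: unknown units {self.units!r}")
        if self.units in ("probability", "utility") and not 0.0 <= self.baseline <= 1.0:
            raise RegistryError(
                f"{self.id}: baseline {self.baseline} outside [0, 1] for {self.units}"
            )
        if self.units == "usd_2016" and self.baseline < 0:
            raise RegistryError(f"{self.id}: negative cost baseline {self.baseline}")


class ParameterRegistry:
    """Validated collection of :class:`ParameterSpec`, keyed by id."""

    def __init__(
        self,
        specs: Iterable[ParameterSpec],
        dirichlet_groups: Iterable[tuple[str, ...]] = DEFAULT_DIRICHLET_GROUPS,
    ) -> None:
        self._specs: dict[str, ParameterSpec] = {}
        for spec in specs:
            if spec.id in self._specs:
                raise RegistryError(f"duplicate parameter id {spec.id!r}")
            self._specs[spec.id] = spec
        self.dirichlet_groups = tuple(
            tuple(g) for g in dirichlet_groups if all(m in self._specs for m in g)
        )

    def __contains__(self, pid: str) -> bool:
        return pid in self._specs

    def __iter__(self):
        return iter(self._specs.values())

    def __len__(self) -> int:
        return len(self._specs)

    def __getitem__(self, pid: str) -> ParameterSpec:
        return self._specs[pid]

    def ids(self) -> tuple[str, ...]:
        return tuple(self._specs)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "id": s.id,
                "baseline": s.baseline,
                "family": s.distribution.family,
                "params": ";".join(repr(float(x)) for x in s.distribution.params),
                "units": s.units,
                "description": s.description,
                "source": s.source,
            }
            for s in self
        ]
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class ParameterSet:
    """One realized assignment of every registered parameter.

    Complement branch probabilities (e.g. successful TOLAC, no history of
    CS) are never stored: they are recomputed as ``1 - sum(siblings)`` at
    every decision node when the episode tree is walked, so each node's
    branches sum to one by construction.
    """

    values: Mapping[str, float]
    provenance: str = "baseline"
    seed_used: int | None = None

    def __getitem__(self, pid: str) -> float:
        return self.values[pid]

    def get(self, pid: str, default: float | None = None) -> float | None:
        return self.values.get(pid, default)

    def with_overrides(self, **overrides: float) -> "ParameterSet":
        vals = dict(self.values)
        vals.update(overrides)
        return replace(self, values=vals)


def _parse_params(raw: str) -> tuple[float, ...]:
    return tuple(float(tok) for tok in str(raw).split(";") if tok.strip() != "")


def load_registry(table_path) -> ParameterRegistry:
    """Load and validate a parameter table CSV.

    Expected header: ``id,baseline,family,params,units,description,source``
    with ``params`` a semicolon-separated numeric list.  Raises
    :class:`RegistryError` naming the offending row on any violation.
    """
    df = pd.read_csv(table_path, dtype={"id": str, "params": str})
    required = {"id", "baseline", "family", "params", "units"}
    missing = required - set(df.columns)
    if missing:
        raise RegistryError(f"parameter table missing columns {sorted(missing)}")
    specs = []
    for _, row in df.iterrows():
        try:
            dist = DistributionSpec(str(row["family"]), _parse_params(row["params"]))
            spec = ParameterSpec(
                id=str(row["id"]),
                baseline=float(row["baseline"]),
                distribution=dist,
                units=str(row["units"]),
                description=str(row.get("description", "") or ""),
                source=str(row.get("source", "") or ""),
            )
        except RegistryError as err:
            raise RegistryError(f"row {row['id']!r}: {err}") from err
        specs.append(spec)
    return ParameterRegistry(specs)


def default_registry() -> ParameterRegistry:
    """Registry reproducing the published input-parameter table."""
    with resources.as_file(
        resources.files("cemocsim.data").joinpath("parameters.csv")
    ) as path:
        return load_registry(path)


def baseline_set(registry: ParameterRegistry) -> ParameterSet:
    """Realize every parameter at its printed baseline value."""
    return ParameterSet(
        values={s.id: s.baseline for s in registry}, provenance="baseline"
    )


def _renormalize_group(values: dict[str, float], group: tuple[str, ...]) -> None:
    total = sum(values[m] for m in group)
    if total > 1.0:
        logger.warning(
            "sampled branch probabilities at node %s sum to %.4f > 1; "
            "renormalizing proportionally",
            group,
            total,
        )
        for m in group:
            values[m] /= total


def sample_set(registry: ParameterRegistry, seed: int) -> ParameterSet:
    """Draw one joint PSA realization of all parameters.

    Parameters are drawn independently from their distributions, except the
    standardized (Dirichlet) node groups which are drawn jointly so that the
    branch probabilities of the node remain a proper simplex.  Dirichlet
    concentrations are the branch baselines scaled to the smallest effective
    sample size (alpha + beta) among the sibling beta distributions.  Any
    remaining node whose independently drawn siblings sum above one is
    renormalized proportionally (with a warning).
    """
    rng = np.random.default_rng(seed)
    grouped = {m for g in registry.dirichlet_groups for m in g}
    values: dict[str, float] = {}
    for spec in registry:
        if spec.id in grouped:
            continue
        values[spec.id] = spec.distribution.sample(rng)
    for group in registry.dirichlet_groups:
        members = [registry[m] for m in group]
        ess = min(sum(m.distribution.params) for m in members)
        base = [m.baseline for m in members]
        comp = max(1.0 - sum(base), 1e-9)
        conc = [max(b, 1e-9) * ess for b in base] + [comp * ess]
        draw = rng.dirichlet(conc)
        for m, v in zip(group, draw[:-1]):
            values[m] = float(v)
    for group in registry.dirichlet_groups:
        _renormalize_group(values, group)
    # clip utilities/probabilities into their legal range (uniform specs are
    # constructed inside [0, 1] but guard against user-supplied tables)
    for spec in registry:
        if spec.units in ("probability", "utility"):
            values[spec.id] = min(max(values[spec.id], 0.0), 1.0)
    return ParameterSet(values=values, provenance="psa_sample", seed_used=seed)


# ---------------------------------------------------------------------------
# Prior-CS-dependent risks


@dataclass(frozen=True)
class PriorCsRow:
    p_previa: float
    p_accreta: float
    p_elective_repeat: float


class PriorCsTable:
    """Placenta previa/accreta and elective-repeat-CS probabilities keyed by
    the number of previous cesarean sections (rows 0, 1, 2, 3+; counts above
    the last row reuse it)."""

    def __init__(self, rows: Mapping[int, PriorCsRow]) -> None:
        counts = sorted(rows)
        if not counts or counts[0] != 0:
            raise RegistryError("prior-CS table must start at count 0")
        prev_previa = prev_accreta = -1.0
        for c in counts:
            r = rows[c]
            for name, v in (
                ("p_previa", r.p_previa),
                ("p_accreta", r.p_accreta),
                ("p_elective_repeat", r.p_elective_repeat),
            ):
                if not 0.0 <= v <= 1.0:
                    raise RegistryError(f"prior-CS row {c}: {name}={v} outside [0,1]")
            if r.p_previa < prev_previa or r.p_accreta < prev_accreta:
                raise RegistryError(
                    "previa/accreta probabilities must be non-decreasing in CS count"
                )
            prev_previa, prev_accreta = r.p_previa, r.p_accreta
        self._rows = dict(rows)
        self._max = counts[-1]

    def row(self, prior_cs_count: int) -> PriorCsRow:
        return self._rows[min(int(prior_cs_count), self._max)]

    def counts(self) -> tuple[int, ...]:
        return tuple(sorted(self._rows))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "prior_cs_count": c,
                    "p_previa": r.p_previa,
                    "p_accreta": r.p_accreta,
                    "p_elective_repeat": r.p_elective_repeat,
                }
                for c, r in sorted(self._rows.items())
            ]
        )


def load_prior_cs_table(path) -> PriorCsTable:
    df = pd.read_csv(path)
    required = {"prior_cs_count", "p_previa", "p_accreta", "p_elective_repeat"}
    missing = required - set(df.columns)
    if missing:
        raise RegistryError(f"prior-CS table missing columns {sorted(missing)}")
    rows = {
        int(r["prior_cs_count"]): PriorCsRow(
            float(r["p_previa"]), float(r["p_accreta"]), float(r["p_elective_repeat"])
        )
        for _, r in df.iterrows()
    }
    return PriorCsTable(rows)


def default_prior_cs_table() -> PriorCsTable:
    """Shipped default table (documented in the methods note): previa and
    accreta risk rise with each prior CS, anchored so the count-weighted
    averages reproduce the published marginal previa/accreta event rates."""
    with resources.as_file(
        resources.files("cemocsim.data").joinpath("prior_cs.csv")
    ) as path:
        return load_prior_cs_table(path)
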