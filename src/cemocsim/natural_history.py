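"""Markov health states and per-pregnancy delivery-episode decision trees.

The model has four health states — non-pregnant (utility 1), pregnant
(0.99), post-hysterectomy (0.94) and dead (0) — advanced on a one-year
cycle.  A pregnancy resolves within its cycle through one of two decision
trees: the *with-access* tree (the woman reaches a facility providing
comprehensive emergency obstetric care: cesarean section, transfusion,
hysterectomy, ICU) or the *no-access* tree (vaginal delivery only; an unmet
absolute indication for CS is fatal to the neonate and exposes the mother
to obstructed-labor sequelae).

Both Monte Carlo simulation and exact expectation share a single tree
implementation, written against an abstract :class:`Chooser`:
:class:`RngChooser` resolves each branch by drawing a uniform, while
:func:`enumerate_leaves` re-executes the walk to enumerate every leaf with
its exact path probability.  This guarantees the simulated and enumerated
trees can never drift apart.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Callable, Sequence

import numpy as np

from .parameters import ParameterSet, PriorCsTable, default_prior_cs_table

logger = logging.getLogger(__name__)

EVENT_KEYS: tuple[str, ...] = (
    "pregnancies_to_term",
    "vaginal_deliveries",
    "cesarean_sections",
    "vbac",
    "tolac",
    "previa",
    "accreta",
    "pph_transfusion",
    "peripartum_hysterectomy",
    "icu_admissions",
    "uterine_rupture",
    "fistula",
    "incontinence",
    "stroke",
    "live_births",
    "neonatal_deaths",
    "maternal_deaths",
)


class HealthState(Enum):
    NON_PREGNANT = "non_pregnant"
    PREGNANT = "pregnant"
    POST_HYSTERECTOMY = "post_hysterectomy"
    DEAD = "dead"


class EventTally:
    """Counters for every tracked obstetric event (one per EVENT_KEYS)."""

    __slots__ = ("counts",)

    def __init__(self, counts: dict[str, float] | None = None) -> None:
        self.counts = {k: 0 for k in EVENT_KEYS}
        if counts:
            for k, v in counts.items():
                if k not in self.counts:
                    raise KeyError(f"unknown event key {k!r}")
                self.counts[k] = v

    def __getattr__(self, key: str):
        try:
            return self.counts[key]
        except KeyError:  # pragma: no cover - attribute errors
            raise AttributeError(key) from None

    def add(self, key: str, n: float = 1) -> None:
        self.counts[key] += n

    def merge(self, other: "EventTally | dict[str, float]") -> None:
        src = other.counts if isinstance(other, EventTally) else other
        for k, v in src.items():
            self.counts[k] += v

    def to_dict(self) -> dict[str, float]:
        return dict(self.counts)

    def __eq__(self, other) -> bool:
        return isinstance(other, EventTally) and self.counts == other.counts


@dataclass
class WomanState:
    age: float
    state: HealthState
    prior_cs_count: int = 0
    had_hysterectomy: bool = False
    cum_cost: float = 0.0
    cum_qaly: float = 0.0
    tally: EventTally = field(default_factory=EventTally)


@dataclass(frozen=True)
class DeliveryOutcome:
    """Resolved delivery episode: mode, tallied events, cost, and fate."""

    mode: str  # "vaginal" | "cesarean"
    events: dict[str, int]
    episode_cost: float
    maternal_died: bool
    neonate_died: bool
    hysterectomy_performed: bool
    next_prior_cs: int


# ---------------------------------------------------------------------------
# Choosers


class _NeedChoice(Exception):
    def __init__(self, probs: tuple[float, ...]):
        self.probs = probs


_warned_nodes: set[str] = set()


def _guard(probs: Sequence[float], label: str = "") -> tuple[float, ...]:
    """Branch probabilities of one node (complement implicit).  If the
    explicit branches sum above one (possible after an adverse joint PSA
    draw or an aggressive calibration point) they are renormalized
    proportionally, keeping the node a proper simplex."""
    total = float(sum(probs))
    if total > 1.0 + 1e-12:
        if label not in _warned_nodes:
            _warned_nodes.add(label)
            logger.warning(
                "branch probabilities at node %r sum to %.4f > 1; renormalizing",
                label,
                total,
            )
        return tuple(p / total for p in probs)
    return tuple(float(p) for p in probs)


class RngChooser:
    """Resolves branches by consuming one uniform per decision, in fixed
    tree order, from a dedicated per-(woman, cycle) stream — the basis of
    common-random-number comparisons across strategies."""

    __slots__ = ("rng",)

    def __init__(self, rng: np.random.Generator) -> None:
        self.rng = rng

    def choice(self, probs: Sequence[float], label: str = "") -> int:
        probs = _guard(probs, label)
        u = self.rng.random()
        acc = 0.0
        for i, p in enumerate(probs):
            acc += p
            if u < acc:
                return i
        return len(probs)

    def bernoulli(self, p: float, label: str = "") -> bool:
        return self.choice((p,), label) == 0


class _EnumChooser:
    """Replays a fixed prefix of branch indices, accumulating the path
    probability; raises :class:`_NeedChoice` at the first unresolved node."""

    __slots__ = ("prefix", "pos", "prob")

    def __init__(self, prefix: Sequence[int]) -> None:
        self.prefix = prefix
        self.pos = 0
        self.prob = 1.0

    def choice(self, probs: Sequence[float], label: str = "") -> int:
        probs = _guard(probs, label)
        full = probs + (1.0 - sum(probs),)
        if self.pos >= len(self.prefix):
            raise _NeedChoice(full)
        i = self.prefix[self.pos]
        self.pos += 1
        self.prob *= full[i]
        return i

    def bernoulli(self, p: float, label: str = "") -> bool:
        return self.choice((p,), label) == 0


def enumerate_leaves(walk: Callable[["_EnumChooser"], object]):
    """Exhaustively enumerate ``walk``'s decision tree.

    Returns a list of ``(probability, leaf)`` pairs covering every path with
    nonzero probability; the probabilities sum to one whenever every node's
    branch probabilities do.
    """
    out: list[tuple[float, object]] = []

    def rec(prefix: list[int]) -> None:
        ch = _EnumChooser(prefix)
        try:
            leaf = walk(ch)
        except _NeedChoice as need:
            for i, p in enumerate(need.probs):
                if p > 0.0:
                    rec(prefix + [i])
            return
        out.append((ch.prob, leaf))

    rec([])
    return out


# ---------------------------------------------------------------------------
# Delivery-episode trees


def _hysterectomy_chain(ch, p: ParameterSet, ev, cost: float, died: bool):
    """Peripartum hysterectomy -> possible ICU admission -> possible death.
    Only reachable with access to care."""
    ev["peripartum_hysterectomy"] = ev.get("peripartum_hysterectomy", 0) + 1
    cost += p["cost_hysterectomy"]
    if ch.bernoulli(p["p_icu_hysterectomy"], "icu_after_hysterectomy"):
        ev["icu_admissions"] = ev.get("icu_admissions", 0) + 1
        cost += p["cost_icu"]
        if ch.bernoulli(p["p_death_icu"], "death_in_icu"):
            died = True
    return cost, died


def _with_access(ch, p: ParameterSet, strategy, row, ev, has_prior_cs):
    """Decision tree for a woman delivering with access to CEmOC care.

    Wiring order (antepartum absolute indication -> non-indicated antepartum
    CS -> labor) with antepartum and intrapartum indications mutually
    exclusive.  Every CS may be complicated by emergency hysterectomy; every
    hysterectomy may lead to ICU admission and ICU death.  Returns
    (mode, cost, died, hysterectomy_performed); neonatal survival is 100%
    with access.
    """
    cost = 0.0
    died = False
    hyst = False
    ante = ch.choice(
        (row.p_previa, row.p_accreta, p["p_antepartum_indication"]),
        "antepartum_indication",
    )
    if ante == 0:  # placenta previa -> antepartum CS
        ev["previa"] = 1
        mode = "cesarean"
        cost += p["cost_cs"]
        if ch.bernoulli(p["p_pph_previa"], "pph_previa"):
            ev["pph_transfusion"] = 1
            cost += p["cost_pph"]
        if ch.bernoulli(p["p_emergency_hyst_cs"], "emergency_hyst"):
            hyst = True
            cost, died = _hysterectomy_chain(ch, p, ev, cost, died)
        if not died and ch.bernoulli(
            p["p_death_antepartum_indication"], "death_antepartum"
        ):
            died = True
    elif ante == 1:  # placenta accreta -> antepartum CS
        ev["accreta"] = 1
        mode = "cesarean"
        cost += p["cost_cs"]
        if ch.bernoulli(p["p_pph_accreta"], "pph_accreta"):
            ev["pph_transfusion"] = 1
            cost += p["cost_pph"]
        if ch.bernoulli(p["p_hyst_accreta"], "hyst_accreta"):
            hyst = True
            cost, died = _hysterectomy_chain(ch, p, ev, cost, died)
        if not died and ch.bernoulli(
            p["p_death_antepartum_indication"], "death_antepartum"
        ):
            died = True
    elif ante == 2:  # other absolute antepartum indication -> CS
        mode = "cesarean"
        cost += p["cost_cs"]
        if ch.bernoulli(p["p_emergency_hyst_cs"], "emergency_hyst"):
            hyst = True
            cost, died = _hysterectomy_chain(ch, p, ev, cost, died)
        if not died and ch.bernoulli(
            p["p_death_antepartum_indication"], "death_antepartum"
        ):
            died = True
    elif ch.bernoulli(strategy.p_nonind_antepartum, "nonind_antepartum"):
        mode = "cesarean"  # non-indicated antepartum CS
        cost += p["cost_cs"]
        if ch.bernoulli(p["p_emergency_hyst_cs"], "emergency_hyst"):
            hyst = True
            cost, died = _hysterectomy_chain(ch, p, ev, cost, died)
    else:  # labor
        if has_prior_cs and ch.bernoulli(
            row.p_elective_repeat, "elective_repeat"
        ):
            mode = "cesarean"  # elective repeat CS instead of TOLAC
            cost += p["cost_cs"]
            if ch.bernoulli(p["p_emergency_hyst_cs"], "emergency_hyst"):
                hyst = True
                cost, died = _hysterectomy_chain(ch, p, ev, cost, died)
        elif has_prior_cs:
            # trial of labor after cesarean
            ev["tolac"] = 1
            branch = ch.choice(
                (
                    p["p_rupture_tolac"],
                    p["p_intrapartum_cs_tolac"],
                    strategy.p_nonind_intrapartum,
                ),
                "tolac",
            )
            if branch == 0:  # uterine rupture -> emergency laparotomy
                ev["uterine_rupture"] = 1
                mode = "cesarean"  # rupture surgery costed as a CS
                cost += p["cost_cs"]
                if ch.bernoulli(p["p_pph_rupture"], "pph_rupture"):
                    ev["pph_transfusion"] = 1
                    cost += p["cost_pph"]
                if ch.bernoulli(p["p_hyst_rupture"], "hyst_rupture"):
                    hyst = True
                    cost, died = _hysterectomy_chain(ch, p, ev, cost, died)
                if not died and ch.bernoulli(
                    p["p_death_intrapartum_indication"], "death_intrapartum"
                ):
                    died = True
            elif branch == 1:  # failed TOLAC -> intrapartum CS
                mode = "cesarean"
                cost += p["cost_cs"]
                if ch.bernoulli(p["p_emergency_hyst_cs"], "emergency_hyst"):
                    hyst = True
                    cost, died = _hysterectomy_chain(ch, p, ev, cost, died)
            elif branch == 2:  # non-indicated intrapartum CS during TOLAC
                mode = "cesarean"
                cost += p["cost_cs"]
                if ch.bernoulli(p["p_emergency_hyst_cs"], "emergency_hyst"):
                    hyst = True
                    cost, died = _hysterectomy_chain(ch, p, ev, cost, died)
            else:  # successful TOLAC -> VBAC
                ev["vbac"] = 1
                mode = "vaginal"
                cost += p["cost_vaginal"]
                if ch.bernoulli(p["p_pph_vaginal"], "pph_vaginal"):
                    ev["pph_transfusion"] = 1
                    cost += p["cost_pph"]
                    if not died and ch.bernoulli(
                        p["p_death_pph_vaginal"], "death_pph"
                    ):
                        died = True
                if ch.bernoulli(p["p_hyst_vaginal"], "hyst_vaginal"):
                    hyst = True
                    cost, died = _hysterectomy_chain(ch, p, ev, cost, died)
        elif ch.bernoulli(p["p_intrapartum_indication"], "intrapartum_indication"):
            mode = "cesarean"  # absolute intrapartum indication -> CS
            cost += p["cost_cs"]
            if ch.bernoulli(p["p_emergency_hyst_cs"], "emergency_hyst"):
                hyst = True
                cost, died = _hysterectomy_chain(ch, p, ev, cost, died)
            if not died and ch.bernoulli(
                p["p_death_intrapartum_indication"], "death_intrapartum"
            ):
                died = True
        elif ch.bernoulli(strategy.p_nonind_intrapartum, "nonind_intrapartum"):
            mode = "cesarean"  # non-indicated intrapartum CS
            cost += p["cost_cs"]
            if ch.bernoulli(p["p_emergency_hyst_cs"], "emergency_hyst"):
                hyst = True
                cost, died = _hysterectomy_chain(ch, p, ev, cost, died)
        else:  # uncomplicated labor -> vaginal delivery
            mode = "vaginal"
            cost += p["cost_vaginal"]
            if ch.bernoulli(p["p_pph_vaginal"], "pph_vaginal"):
                ev["pph_transfusion"] = 1
                cost += p["cost_pph"]
                if not died and ch.bernoulli(p["p_death_pph_vaginal"], "death_pph"):
                    died = True
            if ch.bernoulli(p["p_hyst_vaginal"], "hyst_vaginal"):
                hyst = True
                cost, died = _hysterectomy_chain(ch, p, ev, cost, died)
    return mode, cost, died, hyst


def _no_access(ch, p: ParameterSet, row, ev):
    """Decision tree for a woman delivering without access to CEmOC care.

    All deliveries are vaginal; there is no transfusion, hysterectomy or
    ICU.  An absolute indication for CS — antepartum (previa, accreta,
    other) or intrapartum (obstructed labor) — is fatal to the neonate.
    Obstructed labor additionally risks uterine rupture, fistula,
    incontinence and stroke.  PPH is tallied but cannot be treated; its
    mortality uses the without-access value.
    """
    cost = p["cost_vaginal"]
    died = False
    neo_died = False
    ante = ch.choice(
        (row.p_previa, row.p_accreta, p["p_antepartum_indication"]),
        "antepartum_indication",
    )
    if ante < 3:  # unmet absolute antepartum indication
        neo_died = True
        if ante == 0:
            ev["previa"] = 1
            if ch.bernoulli(p["p_pph_previa"], "pph_previa"):
                ev["pph_transfusion"] = 1
                if ch.bernoulli(p["p_death_pph_no_access"], "death_pph_no_access"):
                    died = True
        elif ante == 1:
            ev["accreta"] = 1
            if ch.bernoulli(p["p_pph_accreta"], "pph_accreta"):
                ev["pph_transfusion"] = 1
                if ch.bernoulli(p["p_death_pph_no_access"], "death_pph_no_access"):
                    died = True
        if not died and ch.bernoulli(
            p["p_death_antepartum_indication"], "death_antepartum"
        ):
            died = True
    elif ch.bernoulli(p["p_intrapartum_indication"], "intrapartum_indication"):
        # unmet absolute intrapartum indication (obstructed labor)
        neo_died = True
        if ch.bernoulli(p["p_rupture_tolac"], "rupture_no_access"):
            ev["uterine_rupture"] = 1
            if ch.bernoulli(p["p_pph_rupture"], "pph_rupture"):
                ev["pph_transfusion"] = 1
                if ch.bernoulli(p["p_death_pph_no_access"], "death_pph_no_access"):
                    died = True
        if ch.bernoulli(p["p_fistula"], "fistula"):
            ev["fistula"] = 1
        if ch.bernoulli(p["p_incontinence"], "incontinence"):
            ev["incontinence"] = 1
        if ch.bernoulli(p["p_stroke"], "stroke"):
            ev["stroke"] = 1
        if not died and ch.bernoulli(
            p["p_death_intrapartum_indication"], "death_intrapartum"
        ):
            died = True
    else:  # uncomplicated vaginal delivery
        if ch.bernoulli(p["p_pph_vaginal"], "pph_vaginal"):
            ev["pph_transfusion"] = 1
            if ch.bernoulli(p["p_death_pph_no_access"], "death_pph_no_access"):
                died = True
    return "vaginal", cost, died, neo_died


def walk_episode(
    ch,
    params: ParameterSet,
    strategy,
    prior_cs_count: int,
    prior_table: PriorCsTable,
) -> DeliveryOutcome:
    """One full-term pregnancy resolved through access draw + delivery tree."""
    row = prior_table.row(prior_cs_count)
    ev: dict[str, int] = {"pregnancies_to_term": 1}
    access = ch.bernoulli(strategy.access_value(params), "access")
    if access:
        mode, cost, died, hyst = _with_access(
            ch, params, strategy, row, ev, prior_cs_count > 0
        )
        neo_died = False  # with access to CS, neonatal survival is 100%
    else:
        mode, cost, died, neo_died = _no_access(ch, params, row, ev)
        hyst = False  # hysterectomy requires surgical access
    if mode == "cesarean":
        ev["cesarean_sections"] = 1
        next_cs = prior_cs_count + 1
    else:
        ev["vaginal_deliveries"] = 1
        next_cs = prior_cs_count
    if neo_died:
        ev["neonatal_deaths"] = 1
    else:
        ev["live_births"] = 1
    if died:
        ev["maternal_deaths"] = 1
    return DeliveryOutcome(
        mode=mode,
        events=ev,
        episode_cost=cost,
        maternal_died=died,
        neonate_died=neo_died,
        hysterectomy_performed=hyst,
        next_prior_cs=next_cs,
    )


def delivery_episode(
    w: WomanState,
    params: ParameterSet,
    strategy,
    rng,
    prior_table: PriorCsTable | None = None,
) -> DeliveryOutcome:
    """Resolve the delivery episode of a pregnant woman (Monte Carlo)."""
    if w.state is not HealthState.PREGNANT:
        raise ValueError("delivery_episode requires a pregnant woman")
    prior_table = prior_table or default_prior_cs_table()
    ch = rng if hasattr(rng, "bernoulli") else RngChooser(rng)
    return walk_episode(ch, params, strategy, w.prior_cs_count, prior_table)


def with_access_tree(w, params, strategy, rng, prior_table=None) -> DeliveryOutcome:
    """Delivery episode with the access draw forced to 'access granted'."""
    return _forced_access_episode(w, params, strategy, rng, prior_table, True)


def no_access_tree(w, params, strategy, rng, prior_table=None) -> DeliveryOutcome:
    """Delivery episode with the access draw forced to 'no access'."""
    return _forced_access_episode(w, params, strategy, rng, prior_table, False)


class _ForcedAccess:
    """Chooser wrapper that pins the first (access) decision."""

    def __init__(self, inner, access: bool) -> None:
        self.inner = inner
        self.access = access
        self._first = True

    def choice(self, probs, label=""):
        if self._first and label == "access":
            self._first = False
            return 0 if self.access else 1
        return self.inner.choice(probs, label)

    def bernoulli(self, p, label=""):
        return self.choice((p,), label) == 0


def _forced_access_episode(w, params, strategy, rng, prior_table, access):
    prior_table = prior_table or default_prior_cs_table()
    ch = rng if hasattr(rng, "bernoulli") else RngChooser(rng)
    return walk_episode(
        _ForcedAccess(ch, access), params, strategy, w.prior_cs_count, prior_table
    )


# ---------------------------------------------------------------------------
# Cycle transition


def cycle_transition(
    w: WomanState,
    params: ParameterSet,
    strategy,
    rng,
    prior_table: PriorCsTable | None = None,
    half_cycle_correction: bool = True,
    cost_weight: float = 1.0,
    qaly_weight: float = 1.0,
) -> WomanState:
    """Advance one woman by one annual cycle (in place), returning her state.

    Utility is credited with the half-cycle convention: each cycle earns the
    average of the utility of the state occupied during the cycle and the
    utility of the state at cycle exit, so a woman who dies mid-cycle earns
    half her entry-state utility and the dead state accrues nothing.
    ``cost_weight``/``qaly_weight`` carry any per-cycle discount factors.
    """
    if w.state is HealthState.DEAD:
        return w
    prior_table = prior_table or default_prior_cs_table()
    u_np = params["u_nonpregnant"]
    u_ph = params["u_hysterectomy"]
    if w.state is HealthState.POST_HYSTERECTOMY:
        w.cum_qaly += qaly_weight * u_ph
        w.age += 1
        return w
    # non-pregnant: may become pregnant and deliver within the cycle
    ch = rng if hasattr(rng, "bernoulli") else RngChooser(rng)
    if not ch.bernoulli(params["p_pregnancy"], "pregnancy"):
        w.cum_qaly += qaly_weight * u_np
        w.age += 1
        return w
    w.state = HealthState.PREGNANT
    out = walk_episode(ch, params, strategy, w.prior_cs_count, prior_table)
    w.tally.merge(out.events)
    w.cum_cost += cost_weight * out.episode_cost
    w.prior_cs_count = out.next_prior_cs
    u_entry = params["u_pregnant"]
    if out.maternal_died:
        w.state = HealthState.DEAD
        u_exit = params["u_dead"]
    elif out.hysterectomy_performed:
        w.state = HealthState.POST_HYSTERECTOMY
        w.had_hysterectomy = True
        u_exit = u_ph
    else:
        w.state = HealthState.NON_PREGNANT
        u_exit = u_np
    if half_cycle_correction:
        w.cum_qaly += qaly_weight * 0.5 * (u_entry + u_exit)
    else:
        w.cum_qaly += qaly_weight * u_entry
    w.age += 1
    return w


def tree_to_json(strategy, prior_cs_count: int = 0) -> dict:
    """Audit dump: node labels and branch parameter ids of both trees."""
    return {
        "access_node": {"parameter": strategy.access_param or "fixed", "branches": ["with_access", "no_access"]},
        "with_access": {
            "antepartum_indication": ["prior_cs_table.p_previa", "prior_cs_table.p_accreta", "p_antepartum_indication"],
            "nonind_antepartum": "strategy.p_nonind_antepartum",
            "labor_prior_cs": ["prior_cs_table.p_elective_repeat", "tolac"],
            "tolac": ["p_rupture_tolac", "p_intrapartum_cs_tolac", "strategy.p_nonind_intrapartum", "vbac"],
            "labor_no_prior_cs": ["p_intrapartum_indication", "strategy.p_nonind_intrapartum", "vaginal"],
            "per_cs": ["p_emergency_hyst_cs"],
            "per_hysterectomy": ["p_icu_hysterectomy", "p_death_icu"],
        },
        "no_access": {
            "antepartum_indication": ["prior_cs_table.p_previa", "prior_cs_table.p_accreta", "p_antepartum_indication"],
            "intrapartum_indication": ["p_intrapartum_indication"],
            "sequelae": ["p_rupture_tolac", "p_fistula", "p_incontinence", "p_stroke"],
            "mortality": ["p_death_antepartum_indication", "p_death_intrapartum_indication", "p_death_pph_no_access"],
        },
        "prior_cs_count": prior_cs_count,
    }
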