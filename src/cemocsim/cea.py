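"""Cost-effectiveness frontier, ICERs and optimal-strategy selection.

Strategies are sorted by mean cost; strictly dominated entries (costlier,
no more effective) are removed, then extended (weakly) dominated entries
are removed iteratively until incremental cost-effectiveness ratios are
strictly increasing along the frontier.  The optimal strategy at a
willingness-to-pay threshold is the highest-QALY frontier entry whose ICER
does not exceed the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

#: India's 2017 GDP per capita, the willingness-to-pay threshold (USD/QALY).
DEFAULT_WTP = 1939.61


@dataclass(frozen=True)
class CEAConfig:
    wtp_threshold: float = DEFAULT_WTP
    perspective: str = "societal"

    def __post_init__(self) -> None:
        if self.wtp_threshold <= 0:
            raise ValueError("wtp_threshold must be > 0")


@dataclass
class FrontierEntry:
    strategy_id: str
    mean_cost: float
    mean_qaly: float
    icer: float | None = None
    dominated: str = "none"  # none | strict | extended


def icer(lower: FrontierEntry, upper: FrontierEntry) -> float:
    """Incremental cost per incremental QALY of ``upper`` vs ``lower``."""
    dq = upper.mean_qaly - lower.mean_qaly
    dc = upper.mean_cost - lower.mean_cost
    if dq <= 0:
        raise ValueError("ICER undefined: no incremental QALY (dominated pair)")
    return dc / dq


def build_frontier(results) -> list[FrontierEntry]:
    """Label every strategy and compute frontier ICERs.

    ``results``: iterable of ``(strategy_id, mean_cost, mean_qaly)`` or
    objects with those attributes.  Returns one :class:`FrontierEntry` per
    input, sorted by cost (cost ties broken by descending QALY), with
    ``dominated`` set to ``strict``/``extended`` for removed entries and
    ``icer`` populated for non-dominated entries beyond the cheapest.
    """
    entries = []
    for r in results:
        if isinstance(r, tuple):
            sid, c, q = r
        else:
            sid, c, q = r.strategy_id, r.mean_cost, r.mean_qaly
        if not (pd.notna(c) and pd.notna(q)):
            raise ValueError(f"{sid}: non-finite cost/QALY")
        entries.append(FrontierEntry(sid, float(c), float(q)))
    if not entries:
        raise ValueError("no strategies supplied")
    entries.sort(key=lambda e: (e.mean_cost, -e.mean_qaly))

    # strict dominance: some cheaper (or tied) entry is at least as effective
    for i, e in enumerate(entries):
        for other in entries[:i]:
            if other.dominated == "none" and other.mean_qaly >= e.mean_qaly:
                e.dominated = "strict"
                break

    # extended dominance: remove until ICERs strictly increase
    changed = True
    while changed:
        changed = False
        active = [e for e in entries if e.dominated == "none"]
        for i in range(1, len(active) - 1):
            lo, mid, hi = active[i - 1], active[i], active[i + 1]
            if icer(lo, mid) >= icer(mid, hi):
                mid.dominated = "extended"
                changed = True
                break

    active = [e for e in entries if e.dominated == "none"]
    active[0].icer = None
    for lo, hi in zip(active, active[1:]):
        hi.icer = icer(lo, hi)
    return entries


def frontier_only(entries: list[FrontierEntry]) -> list[FrontierEntry]:
    return [e for e in entries if e.dominated == "none"]


def select_optimal(entries: list[FrontierEntry], cea_config: CEAConfig | None = None) -> str:
    """Highest-QALY frontier strategy whose ICER is within the WTP
    threshold (the cheapest frontier entry qualifies unconditionally)."""
    cea_config = cea_config or CEAConfig()
    active = frontier_only(entries)
    if not active:
        raise ValueError("empty frontier")
    best = active[0]
    for e in active[1:]:
        if e.icer is not None and e.icer <= cea_config.wtp_threshold:
            best = e
    return best.strategy_id


def frontier_frame(entries: list[FrontierEntry]) -> pd.DataFrame:
    """Frontier table with the published 2-decimal ICER formatting."""
    return pd.DataFrame(
        [
            {
                "strategy_id": e.strategy_id,
                "cost": round(e.mean_cost, 2),
                "qaly": round(e.mean_qaly, 4),
                "icer": None if e.icer is None else round(e.icer, 2),
                "status": "frontier" if e.dominated == "none" else f"dominated_{e.dominated}",
            }
            for e in entries
        ]
    )
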