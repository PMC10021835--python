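"""Frontier construction, dominance labelling, ICERs and WTP selection."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import cemocsim as cs
from cemocsim.cea import FrontierEntry, frontier_frame

from conftest import brute_force_frontier


def _by_id(entries):
    return {e.strategy_id: e for e in entries}


def test_strict_dominance_removed():
    entries = cs.build_frontier([("X", 100.0, 10.0), ("Y", 200.0, 9.0)])
    d = _by_id(entries)
    assert d["Y"].dominated == "strict"
    assert [e.strategy_id for e in cs.frontier_only(entries)] == ["X"]


def test_extended_dominance_removed_and_icer_recomputed():
    entries = cs.build_frontier([("X", 0.0, 0.0), ("Y", 10.0, 1.0), ("Z", 11.0, 3.0)])
    d = _by_id(entries)
    assert d["Y"].dominated == "extended"
    assert d["Z"].icer == pytest.approx(11.0 / 3.0)
    assert d["X"].icer is None


def test_cost_ties_ordered_by_qaly():
    entries = cs.build_frontier([("lo", 5.0, 1.0), ("hi", 5.0, 2.0)])
    d = _by_id(entries)
    assert d["lo"].dominated == "strict"
    assert d["hi"].dominated == "none"


def test_icer_arithmetic_and_errors():
    a = FrontierEntry("a", 0.0, 0.0)
    b = FrontierEntry("b", 100.0, 10.0)
    assert cs.icer(a, b) == 10.0
    assert cs.icer(a, FrontierEntry("c", 0.0, 1.0)) == 0.0
    with pytest.raises(ValueError):
        cs.icer(b, a)


def test_select_optimal_respects_wtp():
    entries = cs.build_frontier(
        [("base", 0.0, 10.0), ("mid", 52.0, 20.0), ("top", 406.9, 21.0)]
    )
    d = _by_id(entries)
    assert d["mid"].icer == pytest.approx(5.2)
    assert d["top"].icer == pytest.approx(354.9)
    assert cs.select_optimal(entries, cs.CEAConfig(wtp_threshold=1939.61)) == "top"
    assert cs.select_optimal(entries, cs.CEAConfig(wtp_threshold=100.0)) == "mid"
    assert cs.select_optimal(entries, cs.CEAConfig(wtp_threshold=1.0)) == "base"
    single = cs.build_frontier([("only", 3.0, 1.0)])
    assert cs.select_optimal(single) == "only"


def test_frontier_invariant_to_input_order(rng):
    pts = [(f"s{i}", float(c), float(q)) for i, (c, q) in
           enumerate(zip(rng.uniform(0, 100, 6), rng.uniform(0, 10, 6)))]
    f1 = {e.strategy_id for e in cs.frontier_only(cs.build_frontier(pts))}
    f2 = {e.strategy_id for e in cs.frontier_only(cs.build_frontier(pts[::-1]))}
    assert f1 == f2


@settings(derandomize=True, max_examples=200, deadline=None)
@given(
    n=st.integers(1, 6),
    seed=st.integers(0, 10_000),
)
def test_frontier_matches_brute_force_hull_oracle(n, seed):
    """The iteratively built frontier equals the independently computed
    upper-left convex hull of (QALY, cost) points."""
    rng = np.random.default_rng(seed)
    pts = [
        (f"s{i}", float(rng.uniform(0, 100)), float(rng.uniform(0, 10)))
        for i in range(n)
    ]
    entries = cs.build_frontier(pts)
    mine = {e.strategy_id for e in cs.frontier_only(entries)}
    assert mine == brute_force_frontier(pts)
    icers = [e.icer for e in cs.frontier_only(entries)][1:]
    assert all(b > a for a, b in zip(icers, icers[1:]))  # strictly increasing


def test_removed_entries_are_certified(rng):
    """Every removal has a witness: a cheaper no-worse point (strict) or a
    blending pair with lower interpolated cost (extended)."""
    pts = [(f"s{i}", float(c), float(q)) for i, (c, q) in
           enumerate(zip(rng.uniform(0, 100, 6), rng.uniform(0, 10, 6)))]
    entries = cs.build_frontier(pts)
    lookup = {sid: (c, q) for sid, c, q in pts}
    for e in entries:
        c, q = lookup[e.strategy_id]
        if e.dominated == "strict":
            assert any(
                c2 <= c and q2 >= q and (c2 < c or q2 > q)
                for sid2, (c2, q2) in lookup.items() if sid2 != e.strategy_id
            )
        elif e.dominated == "extended":
            found = False
            for sa, (ca, qa) in lookup.items():
                for sb, (cb, qb) in lookup.items():
                    if sa in (sb, e.strategy_id) or sb == e.strategy_id:
                        continue
                    if qa < q < qb:
                        w = (q - qa) / (qb - qa)
                        if ca + w * (cb - ca) < c:
                            found = True
            assert found


def test_frontier_frame_formatting():
    entries = cs.build_frontier([("X", 0.0, 0.0), ("Z", 10.123456, 3.0)])
    df = frontier_frame(entries)
    assert list(df.columns) == ["strategy_id", "cost", "qaly", "icer", "status"]
    assert df.loc[df.strategy_id == "Z", "icer"].iloc[0] == pytest.approx(3.37)
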