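import numpy as np
import pytest

import cemocsim as cs

SESSION_SEED = 20240917


@pytest.fixture(scope="session")
def registry():
    return cs.default_registry()


@pytest.fixture(scope="session")
def params(registry):
    return cs.baseline_set(registry)


@pytest.fixture(scope="session")
def prior_table():
    return cs.default_prior_cs_table()


@pytest.fixture(scope="session")
def strategies():
    return cs.builtin_strategies()


@pytest.fixture(scope="session")
def base_config():
    return cs.RunConfig(n_women=10_000, horizon_cycles=35, seed=SESSION_SEED)


@pytest.fixture(scope="session")
def calibrated(strategies, params, base_config, prior_table):
    """Grid-calibrated strategies (exact evaluator, full horizon)."""
    return {
        sid: cs.calibrate(s, params, base_config, prior_table=prior_table)
        for sid, s in strategies.items()
    }


@pytest.fixture(scope="session")
def ev_results(calibrated, params, base_config, prior_table):
    return {
        sid: cs.expected_value(base_config, params, c.strategy, prior_table)
        for sid, c in calibrated.items()
    }


@pytest.fixture(scope="session")
def mc_results(calibrated, params, base_config, prior_table):
    """10,000-woman Monte Carlo runs of the calibrated strategies."""
    return {
        sid: cs.run_cohort(base_config, params, c.strategy, prior_table)
        for sid, c in calibrated.items()
    }


def brute_force_frontier(points):
    """Independent frontier oracle: a strategy is on the cost-effectiveness
    frontier iff no other point (strict dominance) and no convex blend of
    two other points (extended dominance) offers at least its QALYs at
    lower cost.  O(n^3) by direct checking."""
    keep = []
    for sid, c, q in points:
        dominated = False
        for sid2, c2, q2 in points:
            if sid2 != sid and c2 <= c and q2 >= q and (c2 < c or q2 > q):
                dominated = True
                break
        if not dominated:
            for a in points:
                for b in points:
                    if a[0] in (sid, b[0]) or b[0] == sid:
                        continue
                    qa, qb = a[2], b[2]
                    if not (qa < q < qb):
                        continue
                    w = (q - qa) / (qb - qa)
                    blend_cost = a[1] + w * (b[1] - a[1])
                    if blend_cost < c:
                        dominated = True
                        break
                if dominated:
                    break
        if not dominated:
            keep.append(sid)
    return set(keep)


@pytest.fixture(scope="session")
def frontier_oracle():
    return brute_force_frontier


@pytest.fixture()
def rng():
    return np.random.default_rng(SESSION_SEED)
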