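"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from medadhere.adherence import Period
from medadhere.simulate import SimulationConfig, simulate_cohort


def stock_counter_pdc(events, period: Period, carry_in: int = 0) -> int:
    """Day-by-day pill-stock simulation: the independent PDC oracle.

    A stock counter is incremented by each dispense's supply on its date
    and decremented on every day it is positive; a day is covered iff the
    stock was positive on it.  Returns covered days within ``period``.
    """
    pairs = sorted((int(d), int(s)) for d, s in events)
    if not pairs:
        return 0
    start = min(pairs[0][0], period.start)
    by_day = {}
    for d, s in pairs:
        by_day[d] = by_day.get(d, 0) + s
    stock = carry_in if carry_in else 0
    covered = 0
    for day in range(start, period.end):
        stock += by_day.get(day, 0)
        if stock > 0:
            stock -= 1
            if period.start <= day:
                covered += 1
    return covered


def random_dispensing_pattern(rng) -> tuple[list, Period]:
    """One random stress pattern: dates in a 2-year span, 30/60/90 supplies,
    overlaps and gaps included, plus a random valid evaluation period."""
    n = int(rng.integers(1, 12))
    dates = np.sort(rng.integers(0, 730, size=n))
    supplies = rng.choice([30, 60, 90], size=n)
    events = list(zip(dates.tolist(), supplies.tolist()))
    end = int(rng.integers(30, 900))
    return events, Period(0, end)


@pytest.fixture(scope="session")
def small_cohort():
    """A 300-patient default cohort reused across pipeline tests."""
    cfg = SimulationConfig(n_patients=300)
    return cfg, simulate_cohort(cfg, 11)


def grad_check(loss_and_grads, params, eps=1e-6):
    """Central finite differences vs analytic gradients.

    Returns the worst relative error over all parameter arrays, where the
    relative error of a block is ||ga - gf|| / max(||ga|| + ||gf||, 1e-8).
    """
    loss, grads = loss_and_grads(params)
    worst = 0.0
    for key, arr in params.items():
        fd = np.zeros_like(arr)
        it = np.nditer(arr, flags=["multi_index"])
        for _ in it:
            ix = it.multi_index
            orig = arr[ix]
            arr[ix] = orig + eps
            lp, _ = loss_and_grads(params)
            arr[ix] = orig - eps
            lm, _ = loss_and_grads(params)
            arr[ix] = orig
            fd[ix] = (lp - lm) / (2 * eps)
        ga = grads[key]
        denom = max(np.linalg.norm(ga) + np.linalg.norm(fd), 1e-8)
        worst = max(worst, np.linalg.norm(ga - fd) / denom)
    return worst
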