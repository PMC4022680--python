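"""Compiled inner loop for whole-simulation runs.

This mirrors the model logic exposed by :mod:`fissim.movement` (the daily
movement pass) and :mod:`fissim.network` (transfer rewiring, the
irreversible-fission check), but runs the full day loop inside one
numba-compiled function so that parameter sweeps with thousands of
replicates finish in seconds.  The pure-Python operations remain the
readable reference; the test suite replays kernel traces through them to
confirm the two paths agree on the network dynamics.

The kernel uses numba's internal Mersenne-Twister stream, seeded once per
simulation, so results are reproducible run to run for a given seed.
"""

from __future__ import annotations

import numpy as np
from numba import njit

#: status codes returned by :func:`run_days`
STATUS_CENSORED = 0
STATUS_FISSION = 1
STATUS_ROUND_LIMIT = 2

#: preference schemes (see fissim.movement.draw_preferences)
PREF_HOMOGENEOUS = 0
PREF_UNIFORM = 1

#: day-process modes
MODE_SINGLE_PASS = 0
MODE_UNTIL_EMPTY = 1


@njit(cache=True)
def _draw_preferences(lam1_mean, lam2_mean, bound, pref_mode, lam1, lam2):
    """Fill per-individual intrinsic probabilities (one uniform split each)."""
    n = lam1.shape[0]
    for i in range(n):
        if pref_mode == PREF_HOMOGENEOUS:
            a = lam1_mean
            b = lam2_mean
        else:
            u = np.random.random()
            a = 2.0 * lam1_mean * u
            b = 2.0 * lam2_mean * (1.0 - u)
        tot = a + b
        if tot > bound and tot > 0.0:
            a *= bound / tot
            b *= bound / tot
        lam1[i] = a
        lam2[i] = b


@njit(cache=True)
def run_days(
    W: np.ndarray,
    C: float,
    lam1_mean: float,
    lam2_mean: float,
    q: float,
    max_days: int,
    threshold: float,
    min_subgroup: int,
    seed: int,
    stop_on_fission: bool,
    pref_mode: int,
    redraw_daily: bool,
    day_mode: int,
    round_limit: int,
    trace: np.ndarray,
):  # pragma: no cover - exercised via engine wrappers
    """Simulate up to ``max_days`` days, mutating ``W`` in place.

    ``q`` is the transfer fraction T/100.  ``trace`` is an
    ``(max_days, n)`` int8 array filled with each day's end-of-day areas
    (0 = stayed resting), or an empty array to disable recording.
    Returns ``(day, status)``.
    """
    np.random.seed(seed)
    n = W.shape[0]
    record = trace.shape[0] > 0
    bound = 1.0 - C * 100.0
    lam1 = np.empty(n)
    lam2 = np.empty(n)
    _draw_preferences(lam1_mean, lam2_mean, bound, pref_mode, lam1, lam2)
    areas = np.zeros(n, dtype=np.int8)
    order = np.empty(n, dtype=np.int64)
    sum1 = np.zeros(n)
    sum2 = np.zeros(n)

    for day in range(1, max_days + 1):
        if redraw_daily:
            _draw_preferences(lam1_mean, lam2_mean, bound, pref_mode, lam1, lam2)
        # --- daily movement out of the resting area
        for i in range(n):
            areas[i] = 0
            order[i] = i
            sum1[i] = 0.0
            sum2[i] = 0.0
        nrest = n
        rounds = 0
        while nrest > 0:
            rounds += 1
            if rounds > round_limit:
                return day, STATUS_ROUND_LIMIT
            # fresh random visiting order (Fisher-Yates)
            for j in range(n - 1, 0, -1):
                r = np.random.randint(0, j + 1)
                tmp = order[j]
                order[j] = order[r]
                order[r] = tmp
            for j in range(n):
                i = order[j]
                if areas[i] != 0:
                    continue
                p1 = lam1[i] + C * sum1[i]
                p2 = lam2[i] + C * sum2[i]
                x = np.random.random()
                if p1 >= x:
                    s = 1
                elif p1 + p2 >= x:
                    s = 2
                else:
                    continue
                areas[i] = s
                # departure is visible to every later draw
                if s == 1:
                    for k in range(n):
                        sum1[k] += W[k, i]
                else:
                    for k in range(n):
                        sum2[k] += W[k, i]
                nrest -= 1
            if day_mode == MODE_SINGLE_PASS:
                break  # everyone had their one opportunity today

        if record:
            for i in range(n):
                trace[day - 1, i] = areas[i]

        if nrest > 0:
            continue  # part of the group stayed at rest: network untouched
        n1 = 0
        for i in range(n):
            if areas[i] == 1:
                n1 += 1
        n2 = n - n1
        if n1 == 0 or n2 == 0:
            continue  # cohesive foraging day: no temporary fission

        # --- temporary fission: transfer q of each cross link onto companions
        for i in range(n):
            si = areas[i]
            n_same = (n1 if si == 1 else n2) - 1
            if n_same == 0:
                continue  # alone in its area: outgoing links frozen
            loss = 0.0
            for k in range(n):
                if k != i and areas[k] != si:
                    removed = W[i, k] * q
                    W[i, k] -= removed
                    loss += removed
            gain = loss / n_same
            for k in range(n):
                if k != i and areas[k] == si:
                    W[i, k] += gain

        # --- irreversible-fission check on the post-update network
        if stop_on_fission and n1 >= min_subgroup and n2 >= min_subgroup:
            split = True
            for i in range(n):
                si = areas[i]
                within = 0.0
                for k in range(n):
                    if k != i and areas[k] == si:
                        within += W[i, k]
                if within < threshold:
                    split = False
                    break
            if split:
                return day, STATUS_FISSION

    return max_days, STATUS_CENSORED
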