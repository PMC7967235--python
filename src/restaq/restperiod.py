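"""Longest rest period (LRP) detection.

The longest continuous rest period (LCRP) of a day is the maximal run of
REST intervals containing no ACTIVE or MISSING interval (earliest run wins
ties).  The LCRP is then extended outward: a nearby run of consecutive REST
intervals, separated from the current period by a gap of at most
``gap_search_intervals`` intervals, is annexed when

* every intervening interval is MISSING (a data gap, not evidence the rest
  ended), or
* exactly one intervening interval is ACTIVE — a brief mid-sleep
  awakening — and the candidate run has at least ``min_rescue_run``
  consecutive REST intervals.

A gap with two or more ACTIVE intervals blocks annexation on that side.
The scan restarts from the new period edge after every annexation and stops
when neither end can grow.
"""

from __future__ import annotations

from typing import Optional, Sequence

from .config import RunConfig
from .types import DayGrid, RestPeriod, State


def find_lcrp(states: Sequence[State]) -> Optional[tuple[int, int]]:
    """Longest run of REST intervals, inclusive index span.

    Ties are broken toward the earliest run; None if no REST interval.
    """
    best: Optional[tuple[int, int]] = None
    best_len = 0
    run_start: Optional[int] = None
    for i, s in enumerate(list(states) + [None]):  # sentinel flushes last run
        if s == State.REST:
            if run_start is None:
                run_start = i
        else:
            if run_start is not None:
                length = i - run_start
                if length > best_len:
                    best, best_len = (run_start, i - 1), length
                run_start = None
    return best


def _annex(
    states: Sequence[State], edge: int, step: int, cfg: RunConfig
) -> Optional[int]:
    """Try one annexation outward from ``edge`` in direction ``step``.

    Returns the new edge (the far end of the annexed run) or None.
    """
    n = len(states)
    block_at = 2 if cfg.two_active_blocks else 3
    gap = 0
    n_active = 0
    pos = edge + step
    while 0 <= pos < n and states[pos] != State.REST:
        gap += 1
        if gap > cfg.gap_search_intervals:
            return None
        if states[pos] == State.ACTIVE:
            n_active += 1
        pos += step
    if not (0 <= pos < n) or gap == 0:
        return None  # no rest run within reach (gap==0 cannot occur post-LCRP)
    if n_active >= block_at:
        return None
    run_end = pos
    while 0 <= run_end + step < n and states[run_end + step] == State.REST:
        run_end += step
    run_len = abs(run_end - pos) + 1
    if n_active == 0 or run_len >= cfg.min_rescue_run:
        return run_end
    return None


def extend_lrp(
    states: Sequence[State], lcrp: tuple[int, int], cfg: RunConfig
) -> tuple[int, int]:
    """Grow an all-REST span by the gap-bridging rules; returns the final
    inclusive span."""
    lo, hi = lcrp
    while True:
        grew = False
        new_hi = _annex(states, hi, +1, cfg)
        if new_hi is not None:
            hi, grew = new_hi, True
        new_lo = _annex(states, lo, -1, cfg)
        if new_lo is not None:
            lo, grew = new_lo, True
        if not grew or not cfg.iterative_extension:
            break
    return lo, hi


def rest_period_for_grid(grid: DayGrid, cfg: RunConfig) -> Optional[RestPeriod]:
    """LCRP + extension for one labeled day; None when the day has no REST."""
    states = grid.states
    lcrp = find_lcrp(states)
    if lcrp is None:
        return None
    lo, hi = extend_lrp(states, lcrp, cfg)
    rest_idx = [i for i in range(lo, hi + 1) if states[i] == State.REST]
    return RestPeriod(
        day_id=grid.day_id,
        span=(lo, hi),
        start_time=grid.intervals[lo].start,
        duration_min=(hi - lo + 1) * cfg.interval_minutes,
        rest_indices=rest_idx,
        n_bridged_missing=sum(
            1 for i in range(lo, hi + 1) if states[i] == State.MISSING
        ),
        n_bridged_active=sum(
            1 for i in range(lo, hi + 1) if states[i] == State.ACTIVE
        ),
    )


def daily_lrps(grids: list[DayGrid], cfg: RunConfig) -> dict:
    """At most one RestPeriod per day; days with no REST interval are absent."""
    out = {}
    for g in grids:
        rp = rest_period_for_grid(g, cfg)
        if rp is not None:
            out[g.day_id] = rp
    return out


def lrps_to_frame(lrps: dict, cfg: RunConfig):
    import pandas as pd

    rows = []
    for day in sorted(lrps):
        rp = lrps[day]
        rows.append(
            {
                "day": day.isoformat(),
                "lrp_start": rp.start_time.isoformat(),
                "lrp_end": (
                    rp.start_time + pd.Timedelta(minutes=rp.duration_min)
                ).isoformat(),
                "duration_min": rp.duration_min,
                "n_rest": len(rp.rest_indices),
                "n_bridged_missing": rp.n_bridged_missing,
                "n_bridged_active": rp.n_bridged_active,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "day",
            "lrp_start",
            "lrp_end",
            "duration_min",
            "n_rest",
            "n_bridged_missing",
            "n_bridged_active",
        ],
    )
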