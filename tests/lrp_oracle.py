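"""Independent rule-table oracle for rest-period detection.

Deliberately written with run-length encoding instead of index scanning so
it shares no code path with the package implementation.  The rules:

* LCRP: among all maximal runs of REST, the longest (earliest on ties).
* Extension, per side, repeated until no change: take the nearest REST run
  beyond the current span; if the gap to it exceeds 5 intervals, stop; count
  ACTIVE intervals in the gap — 0 annexes, 1 annexes only a run of >= 4,
  2 or more blocks.
"""

from __future__ import annotations

R, A, M = 0, 1, 2


def rle(states):
    """[(value, start, end_inclusive)] run-length encoding."""
    out = []
    i = 0
    n = len(states)
    while i < n:
        j = i
        while j + 1 < n and states[j + 1] == states[i]:
            j += 1
        out.append((states[i], i, j))
        i = j + 1
    return out


def oracle_lcrp_bruteforce(states):
    """Longest all-REST contiguous span by exhaustive span enumeration."""
    best = None
    n = len(states)
    for i in range(n):
        for j in range(i, n):
            if all(states[k] == R for k in range(i, j + 1)):
                if best is None or (j - i) > (best[1] - best[0]):
                    best = (i, j)
    return best


def oracle_lcrp(states):
    """Longest earliest REST run via run-length encoding."""
    best = None
    for val, s, e in rle(states):
        if val == R and (best is None or (e - s) > (best[1] - best[0])):
            best = (s, e)
    return best


def oracle_extend(states, span, gap_max=5, rescue_len=4, active_block=2):
    """Rule-table extension on run-length segments."""
    lo, hi = span
    segs = rle(states)

    def rest_runs():
        return [(s, e) for val, s, e in rle(states) if val == R]

    changed = True
    while changed:
        changed = False
        runs = rest_runs()
        # right side: nearest rest run starting after hi
        after = [(s, e) for s, e in runs if s > hi]
        if after:
            s, e = after[0]
            gap = s - hi - 1
            actives = sum(1 for k in range(hi + 1, s) if states[k] == A)
            if 0 < gap <= gap_max and actives < active_block:
                if actives == 0 or (e - s + 1) >= rescue_len:
                    hi = e
                    changed = True
        before = [(s, e) for s, e in runs if e < lo]
        if before:
            s, e = before[-1]
            gap = lo - e - 1
            actives = sum(1 for k in range(e + 1, lo) if states[k] == A)
            if 0 < gap <= gap_max and actives < active_block:
                if actives == 0 or (e - s + 1) >= rescue_len:
                    lo = s
                    changed = True
    return lo, hi


def oracle_lrp(states, gap_max=5, rescue_len=4, active_block=2):
    """Full day result: LCRP then extension; None without any REST."""
    lcrp = oracle_lcrp(states)
    if lcrp is None:
        return None
    return oracle_extend(states, lcrp, gap_max, rescue_len, active_block)
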