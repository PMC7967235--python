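"""LCRP detection and gap-bridging extension, checked against an
independent run-length oracle and on randomized sequences."""

import datetime as dt
import random

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from restaq.config import RunConfig
from restaq.restperiod import daily_lrps, extend_lrp, find_lcrp, rest_period_for_grid
from restaq.types import DayGrid, Interval15, State

from lrp_oracle import oracle_extend, oracle_lcrp, oracle_lcrp_bruteforce, oracle_lrp

R, A, M = State.REST, State.ACTIVE, State.MISSING


def seq(code: str):
    return [{"R": R, "A": A, "M": M}[c] for c in code]


class TestLCRP:
    @pytest.mark.parametrize(
        "code,expected",
        [
            ("RRRARR", (0, 2)),
            ("RRARR", (0, 1)),  # earliest of the tied 2-runs
            ("AAMM", None),
            ("R", (0, 0)),
            ("ARRRRA", (1, 4)),
        ],
    )
    def test_examples(self, code, expected):
        assert find_lcrp(seq(code)) == expected

    def test_matches_bruteforce_on_random_sequences(self):
        rng = random.Random(0)
        for _ in range(200):
            n = rng.randint(1, 50)
            states = [rng.choice([R, A, M]) for _ in range(n)]
            assert find_lcrp(states) == oracle_lcrp_bruteforce(states)


class TestExtension:
    @pytest.mark.parametrize(
        "code,lcrp,expected",
        [
            # all-missing gap is bridged
            ("RRRRRMMRR", (0, 4), (0, 8)),
            # one active: rescue requires a candidate run of >= 4
            ("RRRRRARRRR", (0, 4), (0, 9)),
            ("RRRRRARRR", (0, 4), (0, 4)),
            # two actives block annexation entirely
            ("RRRRRAARRRR", (0, 4), (0, 4)),
            # mixed missing+one-active gap still needs the 4-run rescue
            ("RRRRRMARRRR", (0, 4), (0, 10)),
            ("RRRRRMARRR", (0, 4), (0, 4)),
            # gap longer than 5 intervals is out of reach
            ("RRRRRMMMMMMRR", (0, 4), (0, 4)),
            ("RRRRRMMMMMRR", (0, 4), (0, 11)),
            # extension works symmetrically on the left
            ("RRMMRRRRR", (4, 8), (0, 8)),
            # iterative: annexation restarts the scan from the new edge
            ("RRRRRMMRRMMRR", (0, 4), (0, 12)),
        ],
    )
    def test_branch_battery(self, cfg, code, lcrp, expected):
        assert extend_lrp(seq(code), lcrp, cfg) == expected

    def test_idempotent(self, cfg):
        rng = random.Random(1)
        for _ in range(300):
            states = [rng.choice([R, A, M]) for _ in range(rng.randint(1, 40))]
            lcrp = find_lcrp(states)
            if lcrp is None:
                continue
            span = extend_lrp(states, lcrp, cfg)
            assert extend_lrp(states, span, cfg) == span

    def test_never_shrinks_and_contains_lcrp(self, cfg):
        rng = random.Random(2)
        for _ in range(300):
            states = [rng.choice([R, A, M]) for _ in range(rng.randint(1, 40))]
            lcrp = find_lcrp(states)
            if lcrp is None:
                continue
            lo, hi = extend_lrp(states, lcrp, cfg)
            assert lo <= lcrp[0] and hi >= lcrp[1]

    @settings(derandomize=True, max_examples=400, deadline=None)
    @given(
        st.lists(st.sampled_from([0, 1, 2]), min_size=1, max_size=24).map(
            lambda xs: [State(x) for x in xs]
        )
    )
    def test_agrees_with_rule_table_oracle(self, states):
        cfg = RunConfig()
        lcrp = find_lcrp(states)
        expected = oracle_lrp([int(s) for s in states])
        if lcrp is None:
            assert expected is None
        else:
            assert extend_lrp(states, lcrp, cfg) == expected

    @settings(derandomize=True, max_examples=300, deadline=None)
    @given(st.lists(st.sampled_from([0, 1, 2]), min_size=1, max_size=30))
    def test_annexation_never_crosses_two_active_gap(self, raw):
        """No bridged gap inside the final span contains >= 2 ACTIVE intervals."""
        cfg = RunConfig()
        states = [State(x) for x in raw]
        lcrp = find_lcrp(states)
        if lcrp is None:
            return
        lo, hi = extend_lrp(states, lcrp, cfg)
        # walk the span; every maximal non-REST gap must have < 2 actives
        i = lo
        while i <= hi:
            if states[i] != R:
                j = i
                while j <= hi and states[j] != R:
                    j += 1
                actives = sum(1 for k in range(i, j) if states[k] == A)
                assert actives < 2
                assert j - i <= cfg.gap_search_intervals
                i = j
            else:
                i += 1


def _grid_from_codes(code: str, day=dt.date(2021, 3, 1)) -> DayGrid:
    start = pd.Timestamp("2021-03-01T12:00:00")
    ivs = [
        Interval15(
            start=start + pd.Timedelta(minutes=15 * i),
            state=s,
            n_accel=15,
            n_ecg=3,
            pairing_overlap=False,
            rest_minute_fraction=1.0 if s == R else 0.0,
        )
        for i, s in enumerate(seq(code))
    ]
    return DayGrid(day_id=day, start=start, intervals=ivs)


class TestDailyLRPs:
    def test_day_without_rest_yields_none(self, cfg):
        assert daily_lrps([_grid_from_codes("AMAM" * 24)], cfg) == {}

    def test_all_rest_day_spans_full_day(self, cfg):
        lrps = daily_lrps([_grid_from_codes("R" * 96)], cfg)
        rp = lrps[dt.date(2021, 3, 1)]
        assert rp.duration_min == 1440
        assert rp.span == (0, 95)

    def test_duration_counts_bridged_intervals(self, cfg):
        rp = rest_period_for_grid(_grid_from_codes("RRRRRMMRR" + "A" * 87), cfg)
        assert rp.span == (0, 8)
        assert rp.duration_min == 9 * 15
        assert rp.n_bridged_missing == 2
        assert len(rp.rest_indices) == 7

    def test_simulated_days_overlap_planted_blocks(self, cfg, sim_result):
        result, truth = sim_result
        assert len(result.lrps) >= 8  # nearly every simulated day has an LRP
        for day, rp in result.lrps.items():
            b0, b1 = truth.rest_blocks[day]
            a0 = rp.start_time
            a1 = a0 + pd.Timedelta(minutes=rp.duration_min)
            assert a0 < b1 and b0 < a1  # detected period overlaps the truth
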