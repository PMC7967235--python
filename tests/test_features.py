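"""Rolling-window extraction, the four canonical features, and
agglomeration-based feature selection."""

import math

import numpy as np
import pandas as pd
import pytest

from restaq.config import RunConfig
from restaq.features import (
    SelectionError,
    candidate_registry,
    canonical_features,
    feat_accel_norm_mean,
    feat_ax_sd,
    feat_theta_mean,
    feat_yz_circ_dev,
    rolling_windows,
    select_features,
    window_count,
)
from restaq.intervals import partition_day

from conftest import hr_block, make_stream, minute_block

NOON = pd.Timestamp("2021-03-01T12:00:00")


def block(ax=(0, 0, 0), ay=(0, 0, 0), az=(1, 1, 1), theta=(0, 0, 0), steps=(0, 0, 0)):
    return {
        "ax": np.asarray(ax, float),
        "ay": np.asarray(ay, float),
        "az": np.asarray(az, float),
        "theta_deg": np.asarray(theta, float),
        "steps": np.asarray(steps, float),
    }


class TestCanonicalFeatures:
    @pytest.mark.parametrize(
        "ay,az,expected",
        [
            ((0, 0, 0), (1, 1, 1), 0.0),  # lying still on the unit circle
            ((0, 0, 0), (0, 0, 0), 1.0),  # upright, gravity on x
            ((0.8, 1.0, 1.4), (0, 0, 0), (0.2 + 0.0 + 0.4) / 3),
        ],
    )
    def test_yz_circular_deviation(self, ay, az, expected):
        assert feat_yz_circ_dev(block(ay=ay, az=az)) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "theta,expected", [((0, 0, 0), 0.0), ((10, 20, 30), 20.0), ((90, 90, 90), 90.0)]
    )
    def test_theta_mean(self, theta, expected):
        assert feat_theta_mean(block(theta=theta)) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "ax,ay,az,expected",
        [
            ((0, 0, 0), (0, 0, 0), (1, 1, 1), 1.0),
            ((1, 0, 0), (0, 1, 0), (0, 0, 1), 1.0),
            ((0, 0, 0), (0, 0, 0), (2, 1, 1), 4 / 3),
        ],
    )
    def test_accel_norm_mean(self, ax, ay, az, expected):
        assert feat_accel_norm_mean(block(ax=ax, ay=ay, az=az)) == pytest.approx(expected)

    def test_ax_sd_population_denominator(self):
        assert feat_ax_sd(block(ax=(0.1, 0.1, 0.1))) == pytest.approx(0.0, abs=1e-15)
        assert feat_ax_sd(block(ax=(-1, 0, 1))) == pytest.approx(math.sqrt(2 / 3))

    def test_ax_sd_homogeneous(self):
        base = feat_ax_sd(block(ax=(-0.3, 0.1, 0.4)))
        scaled = feat_ax_sd(block(ax=(-0.9, 0.3, 1.2)))
        assert scaled == pytest.approx(3 * base)

    def test_yz_rotation_invariance(self):
        """Rotating (a_y, a_z) jointly leaves circ-dev and norm unchanged."""
        rng = np.random.default_rng(0)
        ay, az = rng.normal(0, 1, 3), rng.normal(0, 1, 3)
        ang = 0.7
        ay2 = ay * np.cos(ang) - az * np.sin(ang)
        az2 = ay * np.sin(ang) + az * np.cos(ang)
        assert feat_yz_circ_dev(block(ay=ay, az=az)) == pytest.approx(
            feat_yz_circ_dev(block(ay=ay2, az=az2))
        )
        assert feat_accel_norm_mean(block(ay=ay, az=az)) == pytest.approx(
            feat_accel_norm_mean(block(ay=ay2, az=az2))
        )


class TestRollingWindows:
    @pytest.mark.parametrize("n,expected", [(15, 13), (3, 1), (2, 0), (16, 13)])
    def test_window_count_law(self, n, expected):
        assert window_count(min(n, 15), 3) == expected

    def _interval(self, cfg, present_minutes):
        rows = []
        for m in present_minutes:
            rows += minute_block(NOON + pd.Timedelta(minutes=m), 1)
        stream = make_stream(rows, hr_block(NOON, 15))
        grid = partition_day(stream, NOON, cfg)
        return grid.intervals[0], stream

    def test_full_interval_gives_13_windows(self, cfg):
        iv, stream = self._interval(cfg, range(15))
        assert len(rolling_windows(iv, stream.accel, cfg)) == 13

    def test_missing_minute_drops_overlapping_windows(self, cfg):
        # slot 7 empty: windows starting at 5, 6, 7 are dropped
        iv, stream = self._interval(cfg, [m for m in range(15) if m != 7])
        wins = rolling_windows(iv, stream.accel, cfg)
        assert len(wins) == 10
        assert [w.window_index for w in wins] == [0, 1, 2, 3, 4, 8, 9, 10, 11, 12]

    def test_contiguous_prefix(self, cfg):
        iv, stream = self._interval(cfg, range(12))
        assert len(rolling_windows(iv, stream.accel, cfg)) == 10

    def test_feature_vector_order_matches_registry(self, cfg):
        iv, stream = self._interval(cfg, range(15))
        w = rolling_windows(iv, stream.accel, cfg)[0]
        names = [d.name for d in canonical_features(cfg)]
        assert names == ["yz_circ_dev", "theta_mean", "accel_norm_mean", "ax_sd"]
        # stream is lying still (az=1): circ dev 0, theta 5, norm 1, sd 0
        np.testing.assert_allclose(w.feature_vector, [0.0, 5.0, 1.0, 0.0], atol=1e-12)


class TestSelection:
    def _defs(self, n):
        from restaq.features import FeatureDef

        return [FeatureDef(f"f{i}", lambda b: 0.0, "1", f"synthetic {i}") for i in range(n)]

    def test_duplicates_collapse_to_distinct_features(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=(200, 4))
        mats = []
        for _ in range(5):
            x = rng.normal(size=(200, 4))
            mats.append(np.hstack([x, x]))  # 4 distinct + 4 exact duplicates
        chosen = select_features(mats, self._defs(8), k=4)
        names = {d.name for d in chosen}
        assert len(names) == 4
        # one of each duplicated pair (i, i+4)
        for i in range(4):
            assert (f"f{i}" in names) != (f"f{i + 4}" in names)

    def test_k_equal_registry_size_is_identity(self):
        mats = [np.random.default_rng(1).normal(size=(50, 3))]
        chosen = select_features(mats, self._defs(3), k=3)
        assert [d.name for d in chosen] == ["f0", "f1", "f2"]

    def test_correlated_pair_yields_single_representative(self):
        rng = np.random.default_rng(2)
        mats = []
        for _ in range(6):
            a = rng.normal(size=300)
            b = a + 0.05 * rng.normal(size=300)  # rho ~ 0.999
            rest = rng.normal(size=(300, 3))
            mats.append(np.column_stack([a, b, rest]))
        chosen = select_features(mats, self._defs(5), k=4)
        names = {d.name for d in chosen}
        assert len(names & {"f0", "f1"}) == 1
        assert {"f2", "f3", "f4"} <= names

    def test_degenerate_registry_raises(self):
        mats = [np.zeros((50, 4))]
        with pytest.raises(SelectionError):
            select_features(mats, self._defs(4), k=4)

    def test_registry_has_documented_candidates(self, cfg):
        defs = candidate_registry(cfg)
        assert len(defs) >= 30
        assert len({d.name for d in defs}) == len(defs)
        canon = [d for d in defs if d.canonical]
        assert len(canon) == 4
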