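"""Z-score standardisation, composite score, ingestion metrics, and
outlier coincidence matching."""

import datetime as dt
import logging

import numpy as np
import pandas as pd
import pytest

from restaq.config import RunConfig
from restaq.scores import (
    composite_rest,
    ingestion_rate,
    ingestion_time_z,
    ingestion_times,
    outlier_coincidences,
    zscore_series,
)

from conftest import make_stream, minute_block


def _days(n, start="2021-03-01"):
    d0 = dt.date.fromisoformat(start)
    return [d0 + dt.timedelta(days=i) for i in range(n)]


class TestZScores:
    def test_hand_example(self):
        z = zscore_series(pd.Series([10.0, 20.0, 30.0], index=_days(3)))
        np.testing.assert_allclose(z.to_numpy(), [-1.0, 0.0, 1.0])

    def test_constant_series_zero_with_warning(self, caplog):
        with caplog.at_level(logging.WARNING, logger="restaq.scores"):
            z = zscore_series(pd.Series([5.0, 5.0, 5.0], index=_days(3)))
        assert z.tolist() == [0.0, 0.0, 0.0]
        assert "constant" in caplog.text

    def test_standardization_identity(self):
        rng = np.random.default_rng(0)
        z = zscore_series(pd.Series(rng.normal(50, 7, 30), index=_days(30)))
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std(ddof=1) == pytest.approx(1.0, rel=1e-12)

    def test_too_few_days_gives_nan(self):
        z = zscore_series(pd.Series([1.0], index=_days(1)))
        assert z.isna().all()

    def test_missing_days_excluded_from_moments(self):
        vals = pd.Series([10.0, np.nan, 30.0], index=_days(3))
        z = zscore_series(vals)
        assert np.isnan(z.iloc[1])
        np.testing.assert_allclose(z.dropna().to_numpy(), [-np.sqrt(0.5), np.sqrt(0.5)])

    def test_translation_invariance(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(600, 40, 20)
        z1 = zscore_series(pd.Series(vals, index=_days(20)))
        z2 = zscore_series(pd.Series(vals + 123.0, index=_days(20)))
        np.testing.assert_allclose(z1.to_numpy(), z2.to_numpy(), atol=1e-9)


class TestComposite:
    @pytest.mark.parametrize(
        "q,s,d,expected",
        [(0, 0, 0, 0.0), (1, -1, 2, 4.0), (-0.5, 0.25, 0, 0.75)],
    )
    def test_absolute_sum(self, q, s, d, expected):
        assert composite_rest(q, s, d) == pytest.approx(expected)

    def test_dominates_each_component(self):
        rng = np.random.default_rng(2)
        for q, s, d in rng.normal(size=(50, 3)):
            assert composite_rest(q, s, d) >= max(abs(q), abs(s), abs(d)) - 1e-12


def _stream_with_ingestions(patch_days, ingestion_stamps):
    rows = []
    for d in patch_days:
        rows += minute_block(pd.Timestamp(d) + pd.Timedelta(hours=12), 5)
    return make_stream(rows, ingestion_times=ingestion_stamps)


class TestIngestionRate:
    def test_full_adherence(self):
        days = [f"2021-03-{d:02d}" for d in range(1, 8)]
        s = _stream_with_ingestions(days, [f"{d}T09:00:00" for d in days])
        assert ingestion_rate(s) == pytest.approx(1.0)

    def test_printed_definition(self):
        # doses on 5 days; first patch day 03-01, last ingestion 03-10 -> 5/10
        patch = [f"2021-03-{d:02d}" for d in range(1, 11)]
        dosed = ["2021-03-01", "2021-03-03", "2021-03-05", "2021-03-07", "2021-03-10"]
        s = _stream_with_ingestions(patch, [f"{d}T09:00:00" for d in dosed])
        assert ingestion_rate(s) == pytest.approx(0.5)

    def test_duplicate_doses_count_once(self):
        patch = ["2021-03-01", "2021-03-02"]
        s = _stream_with_ingestions(
            patch, ["2021-03-01T09:00:00", "2021-03-01T21:00:00", "2021-03-02T09:00:00"]
        )
        assert ingestion_rate(s) == pytest.approx(1.0)

    def test_no_ingestions_rate_zero(self):
        s = _stream_with_ingestions(["2021-03-01"], [])
        assert ingestion_rate(s) == 0.0


class TestIngestionTimes:
    def test_daily_clock_times_z(self):
        s = _stream_with_ingestions(
            ["2021-03-01", "2021-03-02", "2021-03-03"],
            ["2021-03-01T08:00:00", "2021-03-02T09:00:00", "2021-03-03T10:00:00"],
        )
        times = ingestion_times(s)
        assert times.tolist() == [480.0, 540.0, 600.0]
        np.testing.assert_allclose(ingestion_time_z(s).to_numpy(), [-1.0, 0.0, 1.0])

    def test_constant_dose_time_all_zero(self):
        days = [f"2021-03-{d:02d}" for d in range(1, 6)]
        s = _stream_with_ingestions(days, [f"{d}T09:00:00" for d in days])
        assert ingestion_time_z(s).tolist() == [0.0] * 5

    def test_shifted_day_has_max_magnitude(self):
        days = [f"2021-03-{d:02d}" for d in range(1, 8)]
        stamps = [f"{d}T09:00:00" for d in days[:-1]] + ["2021-03-07T13:00:00"]
        z = ingestion_time_z(_stream_with_ingestions(days, stamps))
        assert z.abs().idxmax() == dt.date(2021, 3, 7)


class TestCoincidences:
    def _series(self, vals, start="2021-03-01"):
        return pd.Series(vals, index=_days(len(vals), start), dtype=float)

    def test_no_outliers_empty(self, cfg):
        comp = self._series([0.1] * 10)
        ingz = self._series([0.0] * 10)
        assert outlier_coincidences(comp, ingz, cfg) == []

    def test_same_day_pair_found(self, cfg):
        comp = self._series([1.0] * 20)
        ingz = self._series([0.0] * 20)
        comp.iloc[14] = 9.0  # day 15 of the record
        ingz.iloc[14] = 3.0
        pairs = outlier_coincidences(comp, ingz, cfg)
        assert pairs == [(dt.date(2021, 3, 15), dt.date(2021, 3, 15))]

    def test_lag_beyond_one_day_rejected(self, cfg):
        comp = self._series([1.0] * 20)
        ingz = self._series([0.0] * 20)
        comp.iloc[9] = 9.0
        ingz.iloc[11] = 3.0  # two days later
        assert outlier_coincidences(comp, ingz, cfg) == []

    def test_lag_symmetric_within_one_day(self, cfg):
        comp = self._series([1.0] * 20)
        ingz = self._series([0.0] * 20)
        comp.iloc[9] = 9.0
        ingz.iloc[8] = -3.0  # ingestion outlier the day before, two-sided
        pairs = outlier_coincidences(comp, ingz, cfg)
        assert pairs == [(dt.date(2021, 3, 10), dt.date(2021, 3, 9))]

    def test_single_day_rule_drops_clustered_outliers(self, cfg):
        comp = self._series([1.0] * 20)
        ingz = self._series([0.0] * 20)
        comp.iloc[9] = 9.0
        comp.iloc[10] = 9.5  # neighbouring outlier day
        ingz.iloc[9] = 3.0
        assert outlier_coincidences(comp, ingz, cfg) == []
        relaxed = cfg.model_copy(update={"single_day_outliers": False})
        assert len(outlier_coincidences(comp, ingz, relaxed)) == 2
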