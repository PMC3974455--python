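"""DAM monitor I/O, re-binning, dead-fly filtering."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from circatox import dam_io
from circatox.dam_io import (
    ActivitySeries,
    ActivitySeriesSet,
    LightSchedule,
    ScheduleSegment,
    filter_dead,
    mean_activity,
    read_dam_monitor,
    rebin,
    slice_segment,
    write_dam_monitor,
)

from conftest import make_series


def _make_set(count_matrix, bin_width_min=1.0):
    sched = LightSchedule.constant("DD")
    return ActivitySeriesSet(
        [
            make_series(row, bin_width_min=bin_width_min, schedule=sched, fly_id=f"f{i}")
            for i, row in enumerate(count_matrix)
        ]
    )


class TestSchedule:
    def test_standard_protocol_segments(self):
        sched = LightSchedule.standard_ld_dd()
        assert sched.regime_at(0.0) == "LD"
        assert sched.regime_at(71.9) == "LD"
        assert sched.regime_at(72.0) == "DD"
        assert sched.is_light(6.0) and not sched.is_light(13.0)
        assert not sched.is_light(80.0)

    def test_zt_anchored_to_lights_on(self):
        sched = LightSchedule.standard_ld_dd(lights_on_offset_h=8.0)
        assert sched.zt(8.0) == 0.0
        assert sched.zt(20.0) == 12.0

    def test_invalid_schedules_rejected(self):
        with pytest.raises(ValueError):
            LightSchedule(())
        with pytest.raises(ValueError):
            LightSchedule((ScheduleSegment(0, "DD", 0, 12.0),))  # DD w/ photoperiod
        with pytest.raises(ValueError):
            LightSchedule(
                (ScheduleSegment(24, "LD"), ScheduleSegment(0, "DD", 0, 0.0))
            )  # out of order

    def test_yaml_round_trip(self, tmp_path):
        p = tmp_path / "sched.yaml"
        p.write_text(
            "day_length_h: 24\n"
            "segments:\n"
            "  - {start_h: 0, regime: LD, photoperiod_h: 12}\n"
            "  - {start_h: 72, regime: DD}\n"
        )
        sched = dam_io.load_schedule(p)
        assert sched == LightSchedule.standard_ld_dd()


class TestDamFile:
    def test_zero_monitor_round_trip(self, tmp_path):
        sset = _make_set(np.zeros((32, 3), dtype=int))
        path = write_dam_monitor(sset, tmp_path / "Monitor1.txt")
        back = read_dam_monitor(path)
        assert len(back) == 32
        assert all(len(s) == 3 and s.counts.sum() == 0 for s in back)

    def test_counts_round_trip_exact(self, tmp_path):
        rng = np.random.default_rng(0)
        mat = rng.poisson(5, size=(32, 10))
        sset = _make_set(mat)
        path = write_dam_monitor(sset, tmp_path / "Monitor1.txt")
        back = read_dam_monitor(path)
        np.testing.assert_array_equal(
            np.vstack([s.counts for s in back]), mat
        )
        # write(read(f)) reproduces the count columns byte-identically
        path2 = write_dam_monitor(back, tmp_path / "Monitor2.txt")
        cols1 = [l.split("\t")[10:] for l in path.read_text().splitlines()]
        cols2 = [l.split("\t")[10:] for l in path2.read_text().splitlines()]
        assert cols1 == cols2

    def test_channel_sum_from_fixture(self, tmp_path):
        mat = np.zeros((32, 3), dtype=int)
        mat[0] = [3, 5, 0]
        path = write_dam_monitor(_make_set(mat), tmp_path / "m.txt")
        back = read_dam_monitor(path)
        assert back[0].counts.sum() == 8
        assert back[0].bin_width_min == 1.0

    def test_bad_status_rows_dropped(self, tmp_path):
        path = write_dam_monitor(_make_set(np.ones((1, 4), dtype=int)), tmp_path / "m.txt")
        lines = path.read_text().splitlines()
        cols = lines[1].split("\t")
        cols[3] = "51"  # error status
        lines[1] = "\t".join(cols)
        path.write_text("\n".join(lines) + "\n")
        back = read_dam_monitor(path)
        assert len(back[0]) == 3

    def test_malformed_row_names_line(self, tmp_path):
        path = write_dam_monitor(_make_set(np.ones((1, 3), dtype=int)), tmp_path / "m.txt")
        path.write_text(path.read_text() + "not\ta\tdata\trow\n")
        with pytest.raises(ValueError, match="line 4"):
            read_dam_monitor(path)

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "empty.txt"
        p.write_text("")
        with pytest.raises(ValueError):
            read_dam_monitor(p)

    def test_write_limits(self, tmp_path):
        with pytest.raises(ValueError):
            write_dam_monitor(ActivitySeriesSet([]), tmp_path / "x.txt")
        with pytest.raises(ValueError):
            write_dam_monitor(_make_set(np.zeros((33, 2), dtype=int)), tmp_path / "x.txt")

    def test_channel_map_metadata(self, tmp_path):
        path = write_dam_monitor(_make_set(np.zeros((2, 3), dtype=int)), tmp_path / "m.txt")
        back = read_dam_monitor(
            path, channel_map={1: {"fly_id": "w1118_01", "genotype": "elav>51D", "dae": 2}}
        )
        assert back[0].fly_id == "w1118_01"
        assert back[0].genotype == "elav>51D"
        assert back[1].fly_id.endswith("_ch02")


class TestRebin:
    def test_constant_series(self):
        s = make_series([1] * 120, bin_width_min=1.0)
        r = rebin(s, 30.0)
        np.testing.assert_array_equal(r.counts, [30, 30, 30, 30])

    def test_identity_width(self):
        s = make_series([1, 2, 3], bin_width_min=30.0)
        np.testing.assert_array_equal(rebin(s, 30.0).counts, s.counts)

    def test_arithmetic_series_sums(self):
        s = make_series(np.arange(60), bin_width_min=1.0)
        np.testing.assert_array_equal(rebin(s, 30.0).counts, [435, 1335])

    def test_non_multiple_rejected(self):
        s = make_series([1, 2, 3], bin_width_min=30.0)
        with pytest.raises(ValueError):
            rebin(s, 45.0)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        counts=st.lists(st.integers(0, 50), min_size=10, max_size=200),
        k=st.integers(2, 7),
    )
    def test_total_counts_conserved_minus_remainder(self, counts, k):
        s = make_series(counts, bin_width_min=1.0)
        r = rebin(s, float(k))
        n_full = len(counts) // k
        assert r.counts.sum() == sum(counts[: n_full * k])

    def test_mean_scales_with_bin_width(self):
        rng = np.random.default_rng(1)
        s = make_series(rng.poisson(3, size=240), bin_width_min=1.0)
        m1 = mean_activity(s)
        m30 = mean_activity(rebin(s, 30.0))
        assert m30 == pytest.approx(30 * m1)


class TestFilterAndMean:
    def test_dead_fly_removed_live_kept(self):
        dead = make_series([5] * 24 + [0] * 48, bin_width_min=60.0, fly_id="dead")
        alive = make_series([0] * 71 + [1], bin_width_min=60.0, fly_id="alive")
        kept, removed = filter_dead(ActivitySeriesSet([dead, alive]), window_h=24.0)
        assert removed == ["dead"]
        assert [s.fly_id for s in kept] == ["alive"]

    def test_mixed_cohort_counts(self):
        rng = np.random.default_rng(2)
        series = []
        for i in range(10):
            c = rng.poisson(4, size=96)
            if i < 3:
                c[-48:] = 0  # dead for the final 24 h of 30-min bins
            else:
                c[-1] = max(c[-1], 1)
            series.append(make_series(c, fly_id=f"f{i}"))
        kept, removed = filter_dead(ActivitySeriesSet(series))
        assert len(kept) == 7 and len(removed) == 3

    def test_mean_activity(self):
        assert mean_activity(make_series([5] * 10)) == 5.0
        assert mean_activity(make_series([0, 10])) == 5.0

    def test_mean_activity_poisson_clt(self):
        rng = np.random.default_rng(3)
        s = make_series(rng.poisson(8, size=480))
        assert abs(mean_activity(s) - 8) < 3 * np.sqrt(8 / 480)


class TestSliceSegment:
    def test_dd_slice_of_standard_protocol(self, ld_dd_schedule):
        s = make_series(np.arange(480), schedule=ld_dd_schedule)  # 10 d of 30-min bins
        dd = slice_segment(s, "DD")
        assert dd.t0_h == 72.0
        assert len(dd) == 336
        np.testing.assert_array_equal(dd.counts, np.arange(144, 480))

    def test_missing_regime_rejected(self, dd_schedule):
        s = make_series([1, 2, 3], schedule=dd_schedule)
        with pytest.raises(ValueError):
            slice_segment(s, "LL")


class TestLongCsv:
    def test_round_trip(self, tmp_path):
        sset = _make_set(np.arange(12).reshape(3, 4), bin_width_min=30.0)
        for s in sset:
            s.genotype, s.age_at_start = "g", 2.0
        p = tmp_path / "long.csv"
        dam_io.write_long_csv(sset, p)
        back = dam_io.read_long_csv(p)
        assert len(back) == 3
        np.testing.assert_array_equal(back[1].counts, sset[1].counts)
        assert back[0].genotype == "g"
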