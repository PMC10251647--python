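"""Dive detection, phase labelling, downsampling and segmentation."""

from __future__ import annotations

import numpy as np
import pytest

import divebuzz as db
from divebuzz.dives import ASCENT, BOTTOM, DESCENT, label_phases


def series(depths, rate_hz=1.0, ind="w1"):
    depths = np.asarray(depths, dtype=float)
    return db.DepthSeries(
        individual_id=ind,
        times=np.arange(depths.size) / rate_hz,
        depths=depths,
        rate_hz=rate_hz,
    )


def v_dive(depth=600.0, speed=2.0):
    """Surface -> depth -> surface triangle flanked by surface samples."""
    down = np.arange(0.0, depth, speed)
    up = np.arange(depth, 0.0, -speed)
    return np.concatenate([[0.0], down, [depth], up, [0.0]])


class TestDepthSeries:
    def test_negative_noise_clipped(self):
        s = series([-0.5, 0.0, 30.0])
        assert s.depths[0] == 0.0

    def test_deep_negative_rejected(self):
        with pytest.raises(ValueError):
            series([-5.0, 0.0, 30.0])

    def test_nonuniform_sampling_rejected(self):
        with pytest.raises(ValueError, match="non-uniform"):
            db.DepthSeries("w1", np.array([0.0, 1.0, 3.0]), np.zeros(3), 1.0)


class TestDownsample:
    def test_25hz_constant(self):
        s = series(np.full(250, 42.0), rate_hz=25.0)
        out = db.downsample(s)
        assert len(out) == 10
        assert np.all(out.depths == 42.0)
        assert out.rate_hz == 1.0

    def test_1hz_identity(self):
        s = series(np.arange(10.0))
        assert db.downsample(s) is s

    def test_20hz_ramp_decimation(self):
        # depth = index / 20 m sampled at 20 Hz: keeping the first sample of
        # each second gives exactly 0, 1, ..., 9 m
        s = series(np.arange(200) / 20.0, rate_hz=20.0)
        out = db.downsample(s)
        assert np.allclose(out.depths, np.arange(10.0))

    def test_floor_length_with_partial_block(self):
        s = series(np.arange(205) / 20.0, rate_hz=20.0)
        assert len(db.downsample(s)) == 205 // 20

    def test_non_integer_ratio_rejected(self):
        s = series(np.zeros(30), rate_hz=2.5)
        with pytest.raises(ValueError, match="2.5"):
            db.downsample(s)

    def test_idempotent(self):
        s = series(np.random.default_rng(0).uniform(0, 100, 500), rate_hz=25.0)
        once = db.downsample(s)
        twice = db.downsample(once)
        assert np.array_equal(once.depths, twice.depths)


class TestLabelPhases:
    def test_strict_v_dive_has_empty_bottom(self):
        d = np.concatenate([np.arange(0, 300, 2.0), [300.0], np.arange(300, 0, -2.0)])
        labels = label_phases(d)
        assert set(labels) == {DESCENT, ASCENT}
        # descent block strictly precedes ascent block
        first_ascent = int(np.argmax(labels == ASCENT))
        assert np.all(labels[:first_ascent] == DESCENT)
        assert np.all(labels[first_ascent:] == ASCENT)

    def test_brief_reversal_absorbed_into_descent(self):
        # 5 s upward blip (tolerance 10 s) in an otherwise monotone descent
        down1 = np.arange(0, 300, 1.5)
        blip = down1[-1] - np.arange(1, 6) * 1.0
        down2 = blip[-1] + np.arange(1, 150) * 1.5
        up = np.arange(down2[-1], 0, -2.0)
        d = np.concatenate([down1, blip, down2, up])
        labels = label_phases(d, reversal_tolerance_s=10)
        blip_idx = np.arange(down1.size, down1.size + 5)
        assert np.all(labels[blip_idx] == DESCENT)

    def test_square_dive_bottom_duration(self):
        # 300 s down, 600 s flat with +/-2 m jitter, 300 s up
        rng = np.random.default_rng(42)
        down = np.arange(300) * 2.0
        flat = 600.0 + rng.uniform(-2, 2, 600)
        up = 600.0 - np.arange(1, 301) * 2.0
        labels = label_phases(np.concatenate([down, flat, up]), reversal_tolerance_s=10)
        n_bottom = int(np.sum(labels == BOTTOM))
        assert abs(n_bottom - 600) <= 2 * 10  # within tolerance at each boundary

    def test_phase_order_invariant(self):
        rng = np.random.default_rng(3)
        d = np.concatenate(
            [np.arange(0, 500, 1.4), 500 + np.cumsum(rng.normal(0, 2, 400)),
             np.arange(500, 0, -1.6)]
        )
        labels = label_phases(np.clip(d, 0, None))
        codes = {DESCENT: 0, BOTTOM: 1, ASCENT: 2}
        seq = [codes[x] for x in labels]
        assert seq == sorted(seq)  # descent, then bottom, then ascent
        assert len(labels) == d.size

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            label_phases(np.array([0.0, 10.0]))


class TestDetectDives:
    def buzz(self, t, ind="w1"):
        return db.BuzzEvent(ind, t, t + 6.0)

    def test_first_dive_dropped(self):
        d = np.concatenate([v_dive(), np.zeros(70), v_dive(), np.zeros(70), v_dive()])
        s = series(d)
        dives = db.detect_dives(s, [])
        assert len(dives) == 2  # first excursion excluded

    def test_buzz_only_in_second_excursion(self):
        d = np.concatenate([v_dive(), np.zeros(70), v_dive()])
        s = series(d)
        t_deep = float(np.flatnonzero(d > 100)[-1])
        dives = db.detect_dives(s, [self.buzz(t_deep)])
        assert len(dives) == 1
        assert dives[0].is_foraging

    def test_three_excursions_buzz_in_each(self):
        chunks, buzzes, t = [], [], 0
        for _ in range(3):
            prof = v_dive()
            deep = np.flatnonzero(prof > 100)
            buzzes.append(self.buzz(t + float(deep[len(deep) // 2])))
            chunks.extend([prof, np.zeros(70)])
            t += prof.size + 70
        dives = db.detect_dives(series(np.concatenate(chunks)), buzzes)
        assert sum(d.is_foraging for d in dives) == 2

    def test_never_deep_series_empty(self):
        assert db.detect_dives(series(np.full(500, 10.0)), []) == []

    def test_boundary_samples_and_interior(self):
        d = np.concatenate([v_dive(), np.zeros(70), v_dive()])
        s = series(d)
        (dive,) = db.detect_dives(s, [], drop_first=True)
        assert s.depths[dive.start_index] <= 25.0
        assert s.depths[dive.end_index - 1] <= 25.0
        assert np.all(s.depths[dive.interior_start : dive.interior_end] > 25.0)
        assert dive.max_depth == s.depths[dive.interior_start : dive.interior_end].max()

    def test_requires_1hz(self):
        s = series(np.zeros(100), rate_hz=25.0)
        with pytest.raises(ValueError, match="1 Hz"):
            db.detect_dives(s, [])


class TestSegmentDives:
    def make_dive(self, duration=950, depth=600.0):
        prof = np.concatenate(
            [np.arange(0, depth, 2.0), np.full(duration, depth),
             np.arange(depth, 0, -2.0)]
        )
        d = np.concatenate([v_dive(), np.zeros(70), prof, np.zeros(70)])
        s = series(d)
        dives = db.detect_dives(s, [])
        return s, dives

    def test_floor_arithmetic(self):
        s, dives = self.make_dive()
        (dive,) = dives
        segs = db.segment_dives(dives, s, [], 300)
        assert len(segs) == dive.duration_s // 300

    def test_boundary_buzz_in_later_window(self):
        s, dives = self.make_dive()
        (dive,) = dives
        t_boundary = s.times[dive.interior_start] + 300.0  # exactly 2nd window start
        segs = db.segment_dives(
            dives, s, [db.BuzzEvent("w1", t_boundary, t_boundary + 6.0)], 300
        )
        assert [g.buzz_count for g in segs[:2]] == [0, 1]

    def test_conservation_against_loop(self, small_deployment):
        """Sum of segment buzz counts + buzzes in the discarded tail equals
        buzzes starting in the dive, for every dive and duration."""
        dep = small_deployment
        for dur in (30, 180, 300):
            for ind, s in dep.depth_series.items():
                dives = db.detect_dives(s, dep.buzz_events)
                segs = db.segment_dives(dives, s, dep.buzz_events, dur)
                starts = np.array(
                    [b.start_s for b in dep.buzz_events if b.individual_id == ind]
                )
                for dive in dives:
                    t0 = s.times[dive.interior_start]
                    t1 = t0 + dive.duration_s
                    in_dive = int(np.sum((starts >= t0) & (starts < t1)))
                    n_complete = dive.duration_s // dur
                    t_tail = t0 + n_complete * dur
                    in_tail = int(np.sum((starts >= t_tail) & (starts < t1)))
                    seg_sum = sum(
                        g.buzz_count for g in segs if g.dive_id == dive.dive_id
                    )
                    assert seg_sum + in_tail == in_dive

    def test_segment_depth_length_and_phase(self, small_deployment):
        dep = small_deployment
        ind, s = next(iter(dep.depth_series.items()))
        dives = db.detect_dives(s, dep.buzz_events)
        segs = db.segment_dives(dives, s, dep.buzz_events, 180)
        assert segs, "fixture must produce segments"
        for g in segs:
            assert g.depths.size == 180
            assert g.phase in {DESCENT, BOTTOM, ASCENT}

    def test_invalid_duration(self, small_deployment):
        dep = small_deployment
        ind, s = next(iter(dep.depth_series.items()))
        with pytest.raises(ValueError):
            db.segment_dives([], s, [], 0)
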