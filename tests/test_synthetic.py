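import dataclasses

import numpy as np
import pytest
from scipy.signal import welch

from remoterep.synthetic import (
    EventSpec,
    PlaceCellSet,
    PositionTrace,
    SyntheticSessionConfig,
    generate_marked_spikes,
    inject_remote_events,
    simulate_lfp,
    simulate_place_cells,
    simulate_trajectory,
    synthesize_session,
)
from remoterep.track import SEG_ARM1


def count_arm_visits(trace, geometry, arm, exploration_end):
    """Number of entries into the arm-end region during exploration."""
    sel = trace.t < exploration_end
    end_mask = geometry.mask(f"{arm}_end")
    in_end = end_mask[geometry.bin_of(trace.linear[sel])] & (
        trace.segment[sel] == (SEG_ARM1 if arm == "arm1" else 2)
    )
    entries = np.flatnonzero(np.diff(in_end.astype(int)) == 1)
    return len(entries) + int(in_end[0])


class TestTrajectory:
    def test_exactly_12_visits_per_arm(self, small_session):
        s = small_session
        for arm in ("arm1", "arm2"):
            assert count_arm_visits(s.trace, s.geometry, arm, s.exploration_end) == 12

    def test_zero_feedback_ends_at_exploration(self):
        cfg = SyntheticSessionConfig(seed=1, feedback_minutes=0.0,
                                     exploration_minutes=3.0, visits_per_arm=12)
        g = cfg.geometry()
        trace, expl_end = simulate_trajectory(cfg, g)
        assert trace.t[-1] == pytest.approx(expl_end, abs=0.5)

    def test_speed_matches_independent_recomputation(self, small_session):
        tr = small_session.trace
        n = len(tr.t)
        speed = np.zeros(n)
        disp = np.linalg.norm(tr.xy[2:] - tr.xy[:-2], axis=1)
        speed[1:-1] = disp / (tr.t[2:] - tr.t[:-2])
        speed[0], speed[-1] = speed[1], speed[-2]
        speed = np.convolve(speed, np.ones(5) / 5.0, mode="same")
        np.testing.assert_allclose(speed, tr.head_speed, atol=1e-6)

    def test_feedback_near_port(self, small_session):
        s = small_session
        fb = s.trace.t >= s.exploration_end
        d = np.linalg.norm(
            s.trace.xy[fb] - s.geometry.center_port_xy[None, :], axis=1
        )
        assert np.mean(d < 17.0) >= 0.8
        assert np.mean(s.trace.head_speed[fb] < 4.0) > 0.5  # stillness bouts


class TestPlaceCells:
    def test_tuning_peak_equals_peak_rate(self, geometry):
        cfg = SyntheticSessionConfig(seed=0, peak_rate=20.0, baseline_rate=0.1)
        cells = simulate_place_cells(cfg, geometry)
        rates = cells.rate(cells.centers_lin, cells.centers_seg, geometry)
        np.testing.assert_allclose(np.diagonal(rates), 20.0, rtol=1e-9)

    def test_fraction_in_target_counts(self, geometry):
        cfg = SyntheticSessionConfig(seed=3, n_cells=60, fraction_in_target=0.2)
        cells = simulate_place_cells(cfg, geometry)
        end1 = geometry.mask("arm1_end")
        in_end = end1[geometry.bin_of(cells.centers_lin)] & (
            cells.centers_seg == SEG_ARM1
        )
        assert in_end.sum() == 12

    def test_mark_clusters_separated(self, geometry):
        cfg = SyntheticSessionConfig(seed=0)
        cells = simulate_place_cells(cfg, geometry)
        for tet in range(cfg.n_tetrodes):
            mm = cells.mark_means[cells.tetrode_of_cell == tet]
            for i in range(len(mm)):
                for j in range(i + 1, len(mm)):
                    assert np.linalg.norm(mm[i] - mm[j]) >= cfg.mark_cluster_separation


def _still_trace_at(xy, duration, fs=30.0):
    n = int(duration * fs)
    t = np.arange(n) / fs
    pts = np.tile(np.asarray(xy, float), (n, 1))
    return PositionTrace(
        t=t, xy=pts, head_direction=np.zeros(n),
        linear=np.zeros(n), segment=np.zeros(n, int),
        head_speed=np.zeros(n), offtrack=np.zeros(n, bool),
    )


class TestSpikes:
    def test_silent_cell_never_in_field(self, geometry):
        # a cell with zero baseline whose field is never visited emits nothing
        cfg = SyntheticSessionConfig(
            seed=5, n_cells=8, n_tetrodes=8, baseline_rate=0.0,
            still_baseline_rate=0.0, still_local_fraction=0.0,
        )
        cells = PlaceCellSet(
            centers_lin=np.full(8, geometry.arm_offset("arm2") + 100.0),
            centers_seg=np.full(8, 2),
            sigma=6.0, peak_rate=20.0, baseline_rate=0.0,
            tetrode_of_cell=np.arange(8),
            mark_means=np.full((8, 4), 150.0),
        )
        trace = _still_trace_at(geometry.center_port_xy, 30.0)
        trace.linear[:] = geometry.box_extent - 25.0
        spikes, _ = generate_marked_spikes(cells, trace, cfg, geometry)
        assert spikes.total() == 0

    def test_zero_mark_sd_gives_identical_marks(self, geometry):
        cfg = SyntheticSessionConfig(seed=6, n_cells=8, n_tetrodes=8,
                                     mark_cluster_sd=0.0, exploration_minutes=1)
        trace, _ = simulate_trajectory(
            dataclasses.replace(cfg, feedback_minutes=0.0, visits_per_arm=2),
            geometry,
        )
        cells = simulate_place_cells(cfg, geometry)
        spikes, ids = generate_marked_spikes(cells, trace, cfg, geometry)
        for tet in spikes.times:
            for c in np.unique(ids[tet]):
                marks = spikes.marks[tet][ids[tet] == c]
                if len(marks) > 1:
                    assert np.ptp(marks, axis=0).max() == 0.0

    def test_rate_map_recovers_field_centers(self, small_session):
        from remoterep.assemblies import place_maps_from_units

        s = small_session
        cells = s.ground_truth.cells
        maps = place_maps_from_units(
            s.unit_spike_times, s.trace, s.geometry, s.exploration_end
        )
        for c, st in enumerate(s.unit_spike_times):
            if len(st[st < s.exploration_end]) < 100:
                continue
            peak_pos = s.geometry.bin_centers[maps[c].argmax()]
            err = abs(peak_pos - cells.centers_lin[c])
            assert err < 2 * s.geometry.bin_size


class TestEvents:
    def test_overlapping_events_rejected(self, geometry):
        cfg = SyntheticSessionConfig(seed=0)
        cells = simulate_place_cells(cfg, geometry)
        trace = _still_trace_at(geometry.center_port_xy, 10.0)
        spikes, ids = generate_marked_spikes(cells, trace, cfg, geometry)
        events = [
            EventSpec(time=1.0, kind="jump", duration=0.12),
            EventSpec(time=1.05, kind="jump", duration=0.12),
        ]
        with pytest.raises(ValueError, match="overlap"):
            inject_remote_events(spikes, ids, cells, events, cfg, geometry)

    def test_jump_spikes_come_from_end_cells(self, geometry):
        # construction: end cells plus far-away cells with zero baseline
        cfg = SyntheticSessionConfig(
            seed=9, n_cells=8, n_tetrodes=4, baseline_rate=0.0,
            still_baseline_rate=0.0, still_local_fraction=0.0,
        )
        end_lin = geometry.arm_offset("arm1") + geometry.arm_length - 12.5
        centers = np.array([end_lin - 4, end_lin, end_lin + 4, end_lin + 8,
                            10.0, 15.0, 20.0, 25.0])
        cells = PlaceCellSet(
            centers_lin=centers,
            centers_seg=np.array([1, 1, 1, 1, 0, 0, 0, 0]),
            sigma=6.0, peak_rate=20.0, baseline_rate=0.0,
            tetrode_of_cell=np.arange(8) % 4,
            mark_means=np.tile(np.eye(4)[np.arange(8) % 4] * 80 + 150, (1, 1)),
        )
        trace = _still_trace_at(geometry.center_port_xy, 10.0)
        spikes, ids = generate_marked_spikes(cells, trace, cfg, geometry)
        assert spikes.total() == 0
        events = [EventSpec(time=2.0, kind="jump", target_arm="arm1")]
        spikes, ids, _ = inject_remote_events(
            spikes, ids, cells, events, cfg, geometry
        )
        fired = np.concatenate([ids[t] for t in ids])
        assert spikes.total() > 0
        assert np.all(fired < 4)  # only the end cells fire

    def test_long_trajectory_span_covers_45cm(self, small_session):
        gt = [e for e in small_session.ground_truth.events
              if e.kind == "long_trajectory"]
        assert gt, "fixture must contain long trajectory events"
        from remoterep.synthetic import _EVENT_DEFAULTS

        assert _EVENT_DEFAULTS["long_trajectory"]["span"] >= 45.0

    def test_injected_window_decodes_to_target_end(self, small_session, small_decode):
        _, _, decoded_fb, _ = small_decode
        s = small_session
        end_mask = s.geometry.mask("arm1_end")
        jumps = [e for e in s.ground_truth.events if e.kind == "jump"]
        fracs = []
        for ev in jumps:
            sel = (decoded_fb.times > ev.time) & (
                decoded_fb.times <= ev.time + ev.duration
            )
            sel &= decoded_fb.informative
            if sel.any():
                fracs.append(decoded_fb.posterior[sel][:, end_mask].sum(axis=1).mean())
        assert np.median(fracs) >= 0.7


class TestLFP:
    def test_ground_truth_ripple_count(self, geometry):
        trace = _still_trace_at(geometry.center_port_xy, 60.0)
        cfg = SyntheticSessionConfig(seed=2)
        swr_times = np.linspace(5, 55, 20)
        lfp, gt = simulate_lfp(trace, cfg, swr_times)
        assert len(gt) == 20

    def test_theta_peak_during_movement(self, small_session):
        s = small_session
        moving = np.interp(s.lfp.t, s.trace.t, (s.trace.head_speed > 4).astype(float))
        seg = s.lfp.samples[moving > 0.5]
        f, p = welch(seg, fs=s.lfp.fs, nperseg=4096)
        band = (f > 4) & (f < 14)
        assert 7.5 <= f[band][p[band].argmax()] <= 8.5

    def test_ripple_during_movement_warns(self, geometry):
        trace = _still_trace_at(geometry.center_port_xy, 30.0)
        trace.head_speed[:] = 20.0
        cfg = SyntheticSessionConfig(seed=2)
        with pytest.warns(UserWarning, match="movement"):
            simulate_lfp(trace, cfg, [10.0])


class TestDeterminism:
    def test_identical_seed_identical_session(self):
        cfg = SyntheticSessionConfig(
            seed=77, exploration_minutes=2.0, feedback_minutes=2.0,
            visits_per_arm=3, event_mix={"jump": 3}, n_swr=3,
        )
        a = synthesize_session(cfg)
        b = synthesize_session(cfg)
        np.testing.assert_array_equal(a.trace.xy, b.trace.xy)
        for tet in a.spikes.times:
            np.testing.assert_array_equal(a.spikes.times[tet], b.spikes.times[tet])
            np.testing.assert_array_equal(a.spikes.marks[tet], b.spikes.marks[tet])
        np.testing.assert_array_equal(a.lfp.samples, b.lfp.samples)

    def test_ground_truth_guard(self):
        cfg = SyntheticSessionConfig(
            seed=78, exploration_minutes=2.0, feedback_minutes=0.0, visits_per_arm=3
        )
        s = synthesize_session(cfg)
        guarded = s.guarded()
        with pytest.raises(RuntimeError, match="blocked"):
            _ = guarded.ground_truth
        assert s.ground_truth is not None  # unguarded access still works
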