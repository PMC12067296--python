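"""Synthetic Y-maze sessions with known ground truth.

Generates everything a real session provides — a position trace (cued
exploration with a fixed number of visits per arm, then a feedback phase spent
near the center port), place-cell spiking with tetrode-specific waveform-mark
clusters, injected remote-representation events, and a surrogate LFP with
movement-gated theta and injected ripples — so that the decoder, detector,
classifier, and every downstream statistic can be validated end to end.

What the generator emulates and what it does not is documented in
``docs/methods.md``. Ground truth (cell identities, injected-event log, ripple
intervals) is carried in a sidecar object that analysis stages never read; the
pipeline enforces this with a read guard.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal import butter, filtfilt, hilbert

from .track import (
    SEG_ARM1,
    SEG_ARM2,
    SEG_BOX,
    TrackGeometry,
    build_track,
    linearize,
)

__all__ = [
    "SyntheticSessionConfig",
    "EventSpec",
    "PositionTrace",
    "MarkedSpikes",
    "LFPTrace",
    "PlaceCellSet",
    "Session",
    "GroundTruth",
    "default_event_mix",
    "simulate_trajectory",
    "simulate_place_cells",
    "generate_marked_spikes",
    "inject_remote_events",
    "schedule_event_times",
    "simulate_lfp",
    "synthesize_session",
]

EVENT_KINDS = ("jump", "jump_arm_base", "medium_trajectory", "long_trajectory")

# Default spans, replay speeds, and hold depths per event kind. Trajectory
# events sweep at awake-replay compression speeds (7-10.5 m/s) to a hold
# point inside the distal 25 cm; spans are sized so the arm span visible in
# the 90 ms before the trigger lands inside the category's coverage window.
_EVENT_DEFAULTS = {
    "jump": dict(duration=0.120, span=None, speed=None),
    "jump_arm_base": dict(duration=0.120, span=None, speed=None),
    "medium_trajectory": dict(duration=0.115, span=52.0, speed=700.0, hold=10.0),
    "long_trajectory": dict(duration=0.115, span=78.0, speed=1050.0, hold=12.5),
}
_TRAJ_PREFIX_S = 0.0     # optional box-local content before the sweep
_JUMP_DEPTH_CM = 12.5    # jump anchor inside the distal 25 cm


@dataclass(frozen=True)
class EventSpec:
    """One injected remote-representation event.

    ``time`` is the event onset in seconds (session clock); ``span`` is the
    length (cm) of the represented sweep for trajectory kinds, ignored for
    jumps.
    """

    time: float
    kind: str
    target_arm: str = "arm1"
    duration: float = 0.120
    span: Optional[float] = None

    def __post_init__(self):
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")


@dataclass
class PositionTrace:
    """Head position trace sampled at the camera rate (default 30 Hz)."""

    t: np.ndarray
    xy: np.ndarray              # (n, 2) cm
    head_direction: np.ndarray  # radians
    linear: np.ndarray          # cm on the linearized track
    segment: np.ndarray         # int codes
    head_speed: np.ndarray      # cm/s, smoothed finite difference
    offtrack: np.ndarray        # bool

    @property
    def fs(self) -> float:
        return 1.0 / float(np.median(np.diff(self.t)))

    def at_times(self, times):
        """Nearest-frame index for arbitrary times."""
        idx = np.searchsorted(self.t, np.asarray(times))
        return np.clip(idx, 0, len(self.t) - 1)


@dataclass
class MarkedSpikes:
    """Per-tetrode spike times with 4-channel amplitude marks (µV)."""

    times: dict    # tetrode -> (n_i,) sorted seconds
    marks: dict    # tetrode -> (n_i, 4) µV

    @property
    def n_tetrodes(self) -> int:
        return len(self.times)

    def total(self) -> int:
        return int(sum(len(t) for t in self.times.values()))


@dataclass
class LFPTrace:
    t0: float
    fs: float
    samples: np.ndarray  # µV

    @property
    def t(self) -> np.ndarray:
        return self.t0 + np.arange(len(self.samples)) / self.fs


@dataclass
class PlaceCellSet:
    """Unimodal spatial tuning curves plus tetrode and mark-cluster assignment."""

    centers_lin: np.ndarray   # (n_cells,) cm
    centers_seg: np.ndarray   # (n_cells,) segment codes
    sigma: float              # field width, cm
    peak_rate: float          # Hz
    baseline_rate: float      # Hz
    tetrode_of_cell: np.ndarray
    mark_means: np.ndarray    # (n_cells, 4) µV

    @property
    def n_cells(self) -> int:
        return len(self.centers_lin)

    def rate(self, lin, seg, geometry: TrackGeometry) -> np.ndarray:
        """Firing rate (Hz) of every cell at positions (lin, seg).

        Returns an (n_cells, n_positions) array. Fields are confined to the
        segment holding their center (a bell over linear position does not
        wrap around the junction: fields at choice points are shaped by the
        trajectory, not spread symmetrically into all three segments).
        """
        lin = np.atleast_1d(np.asarray(lin, dtype=float))
        seg = np.atleast_1d(np.asarray(seg))
        out = np.empty((self.n_cells, len(lin)))
        for c in range(self.n_cells):
            d = np.abs(lin - self.centers_lin[c])
            bump = np.exp(-0.5 * (d / self.sigma) ** 2)
            bump[seg != self.centers_seg[c]] = 0.0
            out[c] = self.baseline_rate + (
                self.peak_rate - self.baseline_rate
            ) * bump
        return out


@dataclass
class GroundTruth:
    """Sidecar ground truth; never read by analysis stages."""

    cells: PlaceCellSet
    spike_cell_ids: dict          # tetrode -> (n_i,) cell id per spike
    events: list                  # realized EventSpec list
    ripple_intervals: np.ndarray  # (n, 2) seconds


@dataclass
class Session:
    """One complete synthetic session."""

    config: "SyntheticSessionConfig"
    geometry: TrackGeometry
    trace: PositionTrace
    spikes: MarkedSpikes
    unit_spike_times: list        # sorted single units (one array per unit)
    lfp: LFPTrace
    exploration_end: float
    feedback_end: float
    target_arm: str
    session_type: str             # "neurofeedback" or "head_direction"
    _ground_truth: Optional[GroundTruth] = field(default=None, repr=False)
    _guard: bool = field(default=False, repr=False)

    @property
    def ground_truth(self) -> GroundTruth:
        if self._guard:
            raise RuntimeError(
                "ground truth access is blocked for analysis stages"
            )
        if self._ground_truth is None:
            raise ValueError("session carries no ground truth")
        return self._ground_truth

    def guarded(self) -> "Session":
        """A view of the session whose ground truth cannot be read."""
        return replace(self, _guard=True)


@dataclass(frozen=True)
class SyntheticSessionConfig:
    """Study conditions for one synthetic session.

    Defaults follow the task design: 12 visits per arm during exploration, a
    feedback phase capped at 30 minutes spent near the center port, ~8 Hz
    theta during movement, and ripples injected during stillness.
    """

    seed: int = 0
    target_arm: str = "arm1"
    session_type: str = "neurofeedback"
    n_cells: int = 60
    n_tetrodes: int = 8
    visits_per_arm: int = 12
    exploration_minutes: float = 15.0
    feedback_minutes: float = 30.0
    # track
    arm_length: float = 120.0
    box_extent: float = 50.0
    bin_size: float = 5.0
    # behavior
    position_fs: float = 30.0
    run_speed: float = 20.0       # cm/s during cued arm runs
    # tuning
    field_width_sigma: float = 6.0
    peak_rate: float = 30.0
    baseline_rate: float = 0.1
    fraction_in_target: float = 0.2   # fraction of cells per arm-end region
    # stillness spiking: out-of-field cells are nearly silent during
    # immobility; residual activity is local (current-location) spiking
    still_baseline_rate: float = 0.02
    still_local_fraction: float = 0.15
    # marks
    mark_base_uv: float = 150.0
    mark_cluster_sd: float = 20.0
    mark_cluster_separation: float = 80.0
    # events
    injected_events: Optional[tuple] = None  # None -> default_event_mix
    event_mix: Optional[dict] = None         # kind -> count, for the default mix
    event_rate_gain: float = 5.0             # x movement rate during events
    # lfp
    lfp_fs: float = 1500.0
    theta_freq: float = 8.0
    theta_amp_moving: float = 40.0
    theta_amp_still: float = 8.0
    lfp_noise_sd: float = 15.0
    n_swr: int = 20
    swr_times: Optional[tuple] = None        # None -> scheduled in stillness
    swr_amplitude_sd: float = 6.0            # envelope SDs above baseline mean
    # nosepoke behavior
    poke_prob: float = 0.95
    poke_latency: tuple = (0.2, 1.0)

    def __post_init__(self):
        if self.n_cells < self.n_tetrodes:
            raise ValueError("need at least one cell per tetrode")
        if min(self.peak_rate, self.baseline_rate) < 0:
            raise ValueError("rates must be non-negative")
        if self.target_arm not in ("arm1", "arm2"):
            raise ValueError("target_arm must be 'arm1' or 'arm2'")

    def geometry(self) -> TrackGeometry:
        return build_track(self.arm_length, self.box_extent, self.bin_size)


def default_event_mix(
    n_jump: int = 30,
    n_jump_arm_base: int = 6,
    n_medium: int = 2,
    n_long: int = 2,
    target_arm: str = "arm1",
) -> list:
    """Event kinds (times unset) roughly matching the observed category mix:
    mostly jumps, some with concurrent arm-base content, rare trajectories."""
    specs = []
    for kind, n in (
        ("jump", n_jump),
        ("jump_arm_base", n_jump_arm_base),
        ("medium_trajectory", n_medium),
        ("long_trajectory", n_long),
    ):
        d = _EVENT_DEFAULTS[kind]
        specs += [
            EventSpec(time=np.nan, kind=kind, target_arm=target_arm,
                      duration=d["duration"], span=d["span"])
            for _ in range(n)
        ]
    return specs


# ---------------------------------------------------------------------------
# trajectory
# ---------------------------------------------------------------------------

def _smooth_speed(t: np.ndarray, xy: np.ndarray) -> np.ndarray:
    """Centered finite-difference speed, boxcar-smoothed (width 5 frames)."""
    n = len(t)
    speed = np.zeros(n)
    if n > 2:
        disp = np.linalg.norm(xy[2:] - xy[:-2], axis=1)
        speed[1:-1] = disp / (t[2:] - t[:-2])
        speed[0] = speed[1]
        speed[-1] = speed[-2]
    return np.convolve(speed, np.ones(5) / 5.0, mode="same")


class _PathBuilder:
    """Assemble a piecewise run/pause program sampled at the camera rate."""

    def __init__(self, fs: float):
        self.fs = fs
        self.points: list[np.ndarray] = []

    def run(self, a: np.ndarray, b: np.ndarray, speed: float):
        dist = float(np.linalg.norm(b - a))
        n = max(1, int(round(dist / speed * self.fs)))
        frac = (np.arange(1, n + 1) / n)[:, None]
        self.points.extend(a[None, :] + frac * (b - a)[None, :])
        return b

    def pause(self, at: np.ndarray, duration: float):
        n = max(1, int(round(duration * self.fs)))
        self.points.extend(np.repeat(at[None, :], n, axis=0))
        return at

    def assemble(self) -> np.ndarray:
        return np.asarray(self.points)


def _arm_tip(geometry: TrackGeometry, arm: str) -> np.ndarray:
    return np.asarray(geometry.skeleton[arm][1])


def _box_point(geometry: TrackGeometry, s: float) -> np.ndarray:
    # s in [0, box_extent]: 0 = far box wall, box_extent = center port
    return np.array([0.0, -(geometry.box_extent - s)])


def simulate_trajectory(
    config: SyntheticSessionConfig, geometry: TrackGeometry, rng=None
):
    """Simulate the exploration and feedback phases of one session.

    Exploration: exactly ``visits_per_arm`` cued runs to each arm end in a
    randomized interleaving, with box wandering between visits scaled so the
    phase lasts approximately ``exploration_minutes``. Feedback: the animal
    stays near the center port (>=80% of frames within 17 cm), in long
    stillness bouts broken by brief in-box movements.

    Returns ``(trace, exploration_end)`` where ``exploration_end`` is the
    time (s) at which the feedback phase starts.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    fs = config.position_fs
    pb = _PathBuilder(fs)
    center = geometry.center_port_xy.copy()

    # visit order: exactly visits_per_arm of each, random interleaving
    order = ["arm1"] * config.visits_per_arm + ["arm2"] * config.visits_per_arm
    order = [order[i] for i in rng.permutation(len(order))]

    # wandering time per visit cycle to hit the exploration duration target
    run_time = 2.0 * geometry.arm_length / config.run_speed + 1.5
    n_cycles = len(order)
    dwell = (config.exploration_minutes * 60.0 - n_cycles * run_time) / n_cycles
    dwell = float(np.clip(dwell, 2.0, 60.0))

    pos = pb.pause(_box_point(geometry, geometry.box_extent / 2), 1.0)
    for arm in order:
        # wander inside the box
        t_wandered = 0.0
        while t_wandered < dwell:
            target = _box_point(geometry, rng.uniform(0, geometry.box_extent))
            speed = rng.uniform(8.0, 12.0)
            t_wandered += np.linalg.norm(target - pos) / speed
            pos = pb.run(pos, target, speed)
            p = rng.uniform(0.3, 0.8)
            pos = pb.pause(pos, p)
            t_wandered += p
        # cued run to the arm end and back, routed through the junction
        junction = np.zeros(2)
        pos = pb.run(pos, junction, rng.uniform(8.0, 12.0))
        tip = _arm_tip(geometry, arm)
        pos = pb.run(pos, tip, config.run_speed)
        pos = pb.pause(pos, 1.5)
        pos = pb.run(pos, junction, config.run_speed)
        pos = pb.run(pos, center, rng.uniform(8.0, 12.0))

    exploration_frames = len(pb.points)

    # feedback phase: still bouts at the port with occasional box walks
    t_feedback = 0.0
    feedback_target = config.feedback_minutes * 60.0
    while t_feedback < feedback_target:
        spot = center + rng.normal(0.0, 2.0, size=2)
        spot[1] = min(spot[1], -0.5)  # stay on the box side of the port
        still = rng.uniform(4.0, 12.0)
        pos = pb.run(pos, spot, 6.0)
        pos = pb.pause(pos, still)
        t_feedback += still + 1.0
        if rng.random() < 0.25:
            away = rng.uniform(8.0, 22.0)
            target = _box_point(geometry, max(0.0, geometry.box_extent - away))
            speed = rng.uniform(6.0, 10.0)
            walk = 2.0 * np.linalg.norm(target - pos) / speed
            pos = pb.run(pos, target, speed)
            pos = pb.pause(pos, rng.uniform(0.5, 1.5))
            pos = pb.run(pos, center + np.array([0.0, -1.0]), speed)
            t_feedback += walk + 1.0

    xy = pb.assemble()
    # small tracking jitter, smoothed so stillness stays below 4 cm/s
    jitter = gaussian_filter1d(rng.normal(0.0, 0.35, size=xy.shape), 3.0, axis=0)
    xy = xy + jitter
    t = np.arange(len(xy)) / fs
    exploration_end = exploration_frames / fs

    linear, segment, offtrack = linearize(xy, geometry)
    # carry the last valid position forward for off-track samples
    bad = np.flatnonzero(offtrack)
    for i in bad:
        if i > 0:
            linear[i] = linear[i - 1]
            segment[i] = segment[i - 1]

    # head direction: direction of motion, held through pauses, plus a slow
    # angular random walk while still (so head-direction feedback has content)
    disp = np.diff(xy, axis=0, prepend=xy[:1])
    moving = np.linalg.norm(disp, axis=1) * fs > 4.0
    hd = np.zeros(len(xy))
    angle = np.pi / 2
    wander = gaussian_filter1d(rng.normal(0.0, 0.9, size=len(xy)), 25.0)
    wander = wander / max(wander.std(), 1e-9) * np.deg2rad(35.0)
    for i in range(len(xy)):
        if moving[i]:
            angle = float(np.arctan2(disp[i, 1], disp[i, 0]))
            hd[i] = angle
        else:
            hd[i] = angle + wander[i]

    speed = _smooth_speed(t, xy)
    trace = PositionTrace(
        t=t, xy=xy, head_direction=hd, linear=linear,
        segment=segment, head_speed=speed, offtrack=offtrack,
    )
    return trace, float(exploration_end)


# ---------------------------------------------------------------------------
# place cells and spikes
# ---------------------------------------------------------------------------

def _mark_mean_for(config: SyntheticSessionConfig, index_on_tetrode: int):
    """Deterministic cluster mean: vertices of a 4D lattice spaced by the
    configured separation (any two cells on a tetrode differ on >=1 channel).
    """
    bits = [(index_on_tetrode >> b) & 1 for b in range(4)]
    return config.mark_base_uv + config.mark_cluster_separation * np.asarray(
        bits, dtype=float
    )


def simulate_place_cells(
    config: SyntheticSessionConfig, geometry: TrackGeometry, rng=None
) -> PlaceCellSet:
    """Draw unimodal place fields; a configurable fraction of cells sit in
    each arm's distal 25 cm, the rest tile the track (stratified uniform
    placement, one center per equal-width stratum, as real populations cover
    the whole environment). Field centers are kept at least 12 cm (path
    distance) from the three-way junction: fields there are shaped by the
    animal's trajectory rather than spreading symmetrically into all three
    segments, which a path-distance tuning model cannot express."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_cells
    n_end = int(round(config.fraction_in_target * n))
    centers = np.empty(n)
    # tiling cells cover the track outside the two designated end regions, so
    # the count of end-region fields is exactly what the fraction specifies
    a1_end_start = geometry.arm_offset("arm1") + geometry.arm_length - 25.0
    a2_end_start = geometry.arm_offset("arm2") + geometry.arm_length - 25.0
    open_spans = [
        (0.0, a1_end_start),
        (geometry.arm_offset("arm2"), a2_end_start),
    ]
    open_len = sum(b - a for a, b in open_spans)
    m = n - 2 * n_end
    stratum = open_len / max(m, 1)

    def _open_coord(p):
        for a, b in open_spans:
            if p < b - a:
                return a + p
            p -= b - a
        return open_spans[-1][1] - 1e-9

    for i in range(n):
        if i < n_end:  # target-end cells, arm1
            centers[i] = rng.uniform(a1_end_start, a1_end_start + 25.0)
        elif i < 2 * n_end:  # arm2 end cells
            centers[i] = rng.uniform(a2_end_start, a2_end_start + 25.0)
        else:
            centers[i] = _open_coord(
                (i - 2 * n_end + rng.uniform(0.0, 1.0)) * stratum
            )
    # push centers out of the 12 cm junction-exclusion zone
    gap = 12.0
    be = geometry.box_extent
    a1, a2 = geometry.arm_offset("arm1"), geometry.arm_offset("arm2")
    near_box = (centers < be) & (be - centers < gap)
    centers[near_box] = be - gap
    for off in (a1, a2):
        near = (centers >= off) & (centers - off < gap) & (
            centers < off + geometry.arm_length
        )
        centers[near] = off + gap
    seg = np.empty(n, dtype=int)
    seg[centers < geometry.box_extent] = SEG_BOX
    seg[
        (centers >= geometry.box_extent)
        & (centers < geometry.box_extent + geometry.arm_length)
    ] = SEG_ARM1
    seg[centers >= geometry.box_extent + geometry.arm_length] = SEG_ARM2

    tet = np.arange(n) % config.n_tetrodes
    mark_means = np.empty((n, 4))
    counters = {}
    for c in range(n):
        k = counters.get(tet[c], 0)
        if k >= 16:
            raise ValueError("more than 16 cells on one tetrode")
        mark_means[c] = _mark_mean_for(config, k)
        counters[tet[c]] = k + 1

    return PlaceCellSet(
        centers_lin=centers,
        centers_seg=seg,
        sigma=config.field_width_sigma,
        peak_rate=config.peak_rate,
        baseline_rate=config.baseline_rate,
        tetrode_of_cell=tet,
        mark_means=mark_means,
    )


def generate_marked_spikes(
    cells: PlaceCellSet,
    trace: PositionTrace,
    config: SyntheticSessionConfig,
    geometry: TrackGeometry,
    rng=None,
):
    """Inhomogeneous-Poisson background spiking with mark clusters.

    Each cell fires at its tuning-curve rate while the animal moves
    (speed > 4 cm/s). During stillness, spiking collapses to a scaled-down
    local (current-location) component plus a small out-of-field floor,
    reflecting the near-silence of CA1 place cells outside their field during
    immobility. Marks are drawn from the cell's spherical cluster.

    Returns ``(spikes, cell_ids)`` where ``cell_ids`` maps tetrode to the
    ground-truth cell id of each spike.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    dt = 1.0 / trace.fs
    rates = cells.rate(trace.linear, trace.segment, geometry)
    still = trace.head_speed <= 4.0
    rates[:, still] = (
        config.still_baseline_rate
        + config.still_local_fraction * rates[:, still]
    )

    times_all, cell_all = [], []
    counts = rng.poisson(rates * dt)
    for c in range(cells.n_cells):
        idx = np.flatnonzero(counts[c])
        if idx.size == 0:
            continue
        reps = counts[c, idx]
        frame_t = np.repeat(trace.t[idx], reps)
        st = frame_t + rng.uniform(0.0, dt, size=len(frame_t))
        times_all.append(st)
        cell_all.append(np.full(len(st), c))
    if times_all:
        times_cat = np.concatenate(times_all)
        cells_cat = np.concatenate(cell_all)
    else:
        times_cat = np.empty(0)
        cells_cat = np.empty(0, dtype=int)

    return _bundle_spikes(times_cat, cells_cat, cells, config, rng)


def _bundle_spikes(times, cell_ids, cells, config, rng):
    spike_times, spike_marks, spike_cells = {}, {}, {}
    for tet in range(config.n_tetrodes):
        on_tet = np.isin(cell_ids, np.flatnonzero(cells.tetrode_of_cell == tet))
        tt = times[on_tet]
        cc = cell_ids[on_tet].astype(int)
        order = np.argsort(tt, kind="stable")
        tt, cc = tt[order], cc[order]
        marks = cells.mark_means[cc] + rng.normal(
            0.0, config.mark_cluster_sd, size=(len(cc), 4)
        )
        spike_times[tet] = tt
        spike_marks[tet] = marks
        spike_cells[tet] = cc
    return MarkedSpikes(times=spike_times, marks=spike_marks), spike_cells


def _event_path(
    spec: EventSpec, geometry: TrackGeometry, rng, dt: float = 0.001
):
    """Represented (lin, seg, segment-codes) path of an injected event, 1 ms grid.

    Jumps hold a position inside the target arm end (with 2 cm jitter).
    jump_arm_base events alternate arm-base and arm-end content in 12 ms
    blocks over their first 60 ms (base mass appears in distinct bins before
    detection without any monotone progression), then hold at the end.
    Trajectory events sweep at replay speed through the arm to a hold point
    inside the distal 25 cm and stay there for the remainder of the duration;
    the 30 ms average triggers a few bins after the representation enters the
    end region, and the default spans are sized so the arm span visible in
    the 90 ms before that moment lands inside the category's coverage window.
    """
    seg_code = SEG_ARM1 if spec.target_arm == "arm1" else SEG_ARM2
    off = geometry.arm_offset(spec.target_arm)
    tip = off + geometry.arm_length
    n = max(2, int(round(spec.duration / dt)))
    tt = np.arange(n) * dt
    seg = np.full(n, seg_code)
    if spec.kind == "jump":
        anchor = tip - _JUMP_DEPTH_CM  # middle of the distal 25 cm
        lin = anchor + rng.normal(0.0, 2.0, size=n)
        lin = np.clip(lin, tip - 24.0, tip - 1.0)
    elif spec.kind == "jump_arm_base":
        anchor = tip - _JUMP_DEPTH_CM
        lin = anchor + rng.normal(0.0, 2.0, size=n)
        lin = np.clip(lin, tip - 24.0, tip - 1.0)
        # 12 ms alternating blocks guarantee a pure 6 ms decode bin per block
        # regardless of how the event aligns with the decoding grid
        block = np.floor(tt / 0.012).astype(int)
        base = (block % 2 == 0) & (tt < 0.060)
        lin[base] = off + rng.uniform(8.0, 14.0, size=int(base.sum()))
    else:
        span = spec.span if spec.span is not None else _EVENT_DEFAULTS[spec.kind]["span"]
        hold_pos = tip - _EVENT_DEFAULTS[spec.kind]["hold"]
        # short arms cannot hold the default spans; keep the sweep start
        # above the proximal 15 cm so trajectories never begin in the base
        span = min(span, hold_pos - off - 16.0)
        if span <= 0:
            raise ValueError("trajectory span exceeds arm length")
        start = hold_pos - span
        lin = np.empty(n)
        prefix = tt < _TRAJ_PREFIX_S
        # content at the animal's location (the port, inside the box) before
        # the sweep departs
        port_box_lin = geometry.box_extent - abs(float(geometry.center_port_xy[1]))
        lin[prefix] = port_box_lin + rng.normal(0.0, 1.5, int(prefix.sum()))
        seg[prefix] = SEG_BOX
        sweep_t = span / _EVENT_DEFAULTS[spec.kind]["speed"]
        sweeping = ~prefix & (tt < _TRAJ_PREFIX_S + sweep_t)
        frac = (tt[sweeping] - _TRAJ_PREFIX_S) / sweep_t
        lin[sweeping] = start + frac * span
        hold = tt >= _TRAJ_PREFIX_S + sweep_t
        lin[hold] = hold_pos + rng.normal(0.0, 1.0, int(hold.sum()))
        lin[hold] = np.clip(lin[hold], tip - 24.0, tip - 1.0)
    return tt, lin, seg


def inject_remote_events(
    spikes: MarkedSpikes,
    cell_ids: dict,
    cells: PlaceCellSet,
    events: Sequence[EventSpec],
    config: SyntheticSessionConfig,
    geometry: TrackGeometry,
    rng=None,
):
    """Superpose remote-representation spiking on the background.

    During each event window spiking is generated as if the animal occupied
    the represented path, at ``event_rate_gain`` times the movement rate.
    Overlapping events raise ``ValueError``. Returns
    ``(spikes, cell_ids, realized_events)``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    events = sorted(events, key=lambda e: e.time)
    for a, b in zip(events[:-1], events[1:]):
        if a.time + a.duration > b.time:
            raise ValueError("injected events overlap")

    dt = 0.001
    new_times, new_cells = [], []
    for spec in events:
        tt, lin, seg = _event_path(spec, geometry, rng, dt)
        rates = config.event_rate_gain * cells.rate(lin, seg, geometry)
        counts = rng.poisson(rates * dt)
        cell_idx, step_idx = np.nonzero(counts)
        if len(cell_idx):
            st = spec.time + tt[step_idx] + rng.uniform(0, dt, size=len(step_idx))
            new_times.append(st)
            new_cells.append(cell_idx)

    if new_times:
        add_t = np.concatenate(new_times)
        add_c = np.concatenate(new_cells)
        inj, inj_cells = _bundle_spikes(add_t, add_c, cells, config, rng)
        merged_t, merged_m, merged_c = {}, {}, {}
        for tet in spikes.times:
            tt = np.concatenate([spikes.times[tet], inj.times[tet]])
            mm = np.concatenate([spikes.marks[tet], inj.marks[tet]])
            cc = np.concatenate([cell_ids[tet], inj_cells[tet]])
            order = np.argsort(tt, kind="stable")
            merged_t[tet] = tt[order]
            merged_m[tet] = mm[order]
            merged_c[tet] = cc[order]
        spikes = MarkedSpikes(times=merged_t, marks=merged_m)
        cell_ids = merged_c
    return spikes, cell_ids, list(events)


def schedule_event_times(
    specs: Sequence[EventSpec],
    trace: PositionTrace,
    geometry: TrackGeometry,
    exploration_end: float,
    feedback_end: float,
    rng,
    min_gap: float = 8.0,
    max_port_distance: float = 15.0,
) -> list:
    """Assign onset times to event specs: during feedback-phase stillness,
    near the center port, spaced at least ``min_gap`` apart."""
    port_d = np.linalg.norm(trace.xy - geometry.center_port_xy[None, :], axis=1)
    ok = (
        (trace.t >= exploration_end + 5.0)
        & (trace.t < feedback_end - 1.0)
        & (trace.head_speed < 3.0)
        & (port_d < max_port_distance)
    )
    candidate_t = trace.t[ok]
    if len(candidate_t) == 0:
        raise ValueError("no eligible stillness periods for event injection")
    chosen: list[float] = []
    shuffled = candidate_t[rng.permutation(len(candidate_t))]
    for tc in shuffled:
        if all(abs(tc - c) >= min_gap for c in chosen):
            chosen.append(float(tc))
        if len(chosen) == len(specs):
            break
    if len(chosen) < len(specs):
        raise ValueError(
            f"could only place {len(chosen)} of {len(specs)} events; "
            "increase feedback duration or reduce min_gap"
        )
    chosen.sort()
    # keep kinds interleaved deterministically
    order = rng.permutation(len(specs))
    out = [replace(specs[order[i]], time=chosen[i]) for i in range(len(specs))]
    return sorted(out, key=lambda e: e.time)


# ---------------------------------------------------------------------------
# LFP
# ---------------------------------------------------------------------------

def _ripple_envelope(samples: np.ndarray, fs: float, smooth_ms: float = 4.0):
    b, a = butter(4, [150.0, 250.0], btype="bandpass", fs=fs)
    filt = filtfilt(b, a, samples)
    env = np.abs(hilbert(filt))
    return gaussian_filter1d(env, smooth_ms * fs / 1000.0)


def simulate_lfp(
    trace: PositionTrace,
    config: SyntheticSessionConfig,
    swr_times: Sequence[float],
    rng=None,
):
    """Surrogate LFP: broadband noise + movement-gated theta + injected ripples.

    Ripple bursts (200 Hz, 60-120 ms, Hann envelope) are scaled so that their
    ripple-band envelope peaks ``swr_amplitude_sd`` SDs above the baseline
    envelope mean, measured on the pre-injection signal. A ripple scheduled
    during movement triggers a warning but is still injected.

    Returns ``(lfp, ground_truth_intervals)``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    fs = config.lfp_fs
    duration = float(trace.t[-1]) + 1.0 / trace.fs
    n = int(round(duration * fs))
    t = np.arange(n) / fs

    noise = rng.normal(0.0, config.lfp_noise_sd, size=n)
    moving = np.interp(t, trace.t, (trace.head_speed > 4.0).astype(float))
    amp = config.theta_amp_still + (
        config.theta_amp_moving - config.theta_amp_still
    ) * gaussian_filter1d(moving, 0.25 * fs)
    theta = amp * np.sin(2.0 * np.pi * config.theta_freq * t)
    samples = noise + theta

    env = _ripple_envelope(samples, fs)
    target_peak = env.mean() + config.swr_amplitude_sd * env.std()

    intervals = []
    speed_at = np.interp(np.asarray(swr_times, dtype=float), trace.t, trace.head_speed)
    for k, t0 in enumerate(np.sort(np.asarray(swr_times, dtype=float))):
        if speed_at[k] > 4.0:
            warnings.warn(
                f"ripple at t={t0:.2f}s scheduled during movement; injecting anyway"
            )
        dur = rng.uniform(0.06, 0.12)
        i0 = int(round(t0 * fs))
        i1 = min(n, i0 + int(round(dur * fs)))
        if i1 - i0 < 8:
            continue
        win = np.hanning(i1 - i0)
        burst = target_peak * win * np.sin(
            2.0 * np.pi * 200.0 * (t[i0:i1] - t[i0])
        )
        samples[i0:i1] += burst
        intervals.append((t0, i1 / fs))

    lfp = LFPTrace(t0=0.0, fs=fs, samples=samples)
    return lfp, np.asarray(intervals, dtype=float).reshape(-1, 2)


def _schedule_swr_times(trace, exploration_end, n, rng, min_gap=2.0):
    still = (trace.head_speed < 3.0) & (trace.t > exploration_end + 2.0)
    cand = trace.t[still]
    if len(cand) == 0:
        return []
    chosen: list[float] = []
    for tc in cand[rng.permutation(len(cand))]:
        if all(abs(tc - c) >= min_gap for c in chosen):
            chosen.append(float(tc))
        if len(chosen) == n:
            break
    return sorted(chosen)


# ---------------------------------------------------------------------------
# top level
# ---------------------------------------------------------------------------

def synthesize_session(config: SyntheticSessionConfig) -> Session:
    """Generate a full session: trajectory, spikes, events, LFP, units.

    A single seed expands into per-component substreams (trajectory, cells,
    spikes, events, LFP) so a component can be varied while holding the
    others fixed. Identical config (same seed) gives an identical session.
    """
    streams = np.random.SeedSequence(config.seed).spawn(5)
    rng_traj, rng_cells, rng_spk, rng_evt, rng_lfp = (
        np.random.default_rng(s) for s in streams
    )
    geometry = config.geometry()
    trace, exploration_end = simulate_trajectory(config, geometry, rng_traj)
    feedback_end = float(trace.t[-1])

    cells = simulate_place_cells(config, geometry, rng_cells)
    spikes, cell_ids = generate_marked_spikes(
        cells, trace, config, geometry, rng_spk
    )

    specs = config.injected_events
    if specs is None and feedback_end - exploration_end < 30.0:
        specs = []  # feedback phase too short to place events
    if specs is None and config.session_type == "neurofeedback":
        mix = config.event_mix
        if mix is None:
            mix = {"jump": 30, "jump_arm_base": 6,
                   "medium_trajectory": 2, "long_trajectory": 2}
        specs = default_event_mix(
            n_jump=mix.get("jump", 0),
            n_jump_arm_base=mix.get("jump_arm_base", 0),
            n_medium=mix.get("medium_trajectory", 0),
            n_long=mix.get("long_trajectory", 0),
            target_arm=config.target_arm,
        )
    realized: list = []
    if specs:
        specs = list(specs)
        if any(not np.isfinite(s.time) for s in specs):
            specs = schedule_event_times(
                specs, trace, geometry, exploration_end, feedback_end, rng_evt
            )
        spikes, cell_ids, realized = inject_remote_events(
            spikes, cell_ids, cells, specs, config, geometry, rng_evt
        )

    swr_times = config.swr_times
    if swr_times is None:
        swr_times = _schedule_swr_times(trace, exploration_end, config.n_swr, rng_lfp)
    lfp, ripple_intervals = simulate_lfp(trace, config, swr_times, rng_lfp)

    # sorted single units = ground-truth cells (stands in for spike sorting,
    # which is outside this package's scope)
    unit_times: list[np.ndarray] = [np.empty(0)] * cells.n_cells
    per_cell: dict[int, list] = {}
    for tet in spikes.times:
        for c in np.unique(cell_ids[tet]):
            per_cell.setdefault(int(c), []).append(
                spikes.times[tet][cell_ids[tet] == c]
            )
    for c, chunks in per_cell.items():
        unit_times[c] = np.sort(np.concatenate(chunks))

    gt = GroundTruth(
        cells=cells,
        spike_cell_ids=cell_ids,
        events=realized,
        ripple_intervals=ripple_intervals,
    )
    return Session(
        config=config,
        geometry=geometry,
        trace=trace,
        spikes=spikes,
        unit_spike_times=unit_times,
        lfp=lfp,
        exploration_end=exploration_end,
        feedback_end=feedback_end,
        target_arm=config.target_arm,
        session_type=config.session_type,
        _ground_truth=gt,
    )
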