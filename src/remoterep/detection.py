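"""Closed-loop neurofeedback trigger logic.

Implements the remote-representation reward criteria evaluated on the 30 ms
running average of the decoded posterior — >40% posterior mass in the target
arm end, <20% in the opposite arm, <20% in the box, at least 2 tetrodes with
spatially specific spikes within the window, and the rat within 17 cm of the
center port (all inequalities strict, as specified) — together with the
head-direction feedback control condition and the tone -> nosepoke -> reward
accounting (3 s nosepoke window, 75-reward / 30-minute session limits).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "DetectionCriteria",
    "DetectionEvent",
    "NosepokeModel",
    "spatial_specificity",
    "evaluate_remote_criteria",
    "detect_events",
    "head_direction_feedback",
    "head_direction_tolerance",
    "audit_events",
]


def spatial_specificity(likelihood, factor: float = 3.0) -> bool:
    """A likelihood is spatially specific if its peak exceeds ``factor``
    times the uniform level (1/n_bins)."""
    like = np.asarray(likelihood, dtype=float)
    return bool(like.max() > factor / like.size)


@dataclass(frozen=True)
class DetectionCriteria:
    """Trigger criteria for remote-representation neurofeedback.

    ``min_specific_tetrodes`` defaults to 2; a single-tetrode override (used
    for one animal in the original experiment) is a config change, not a code
    path.
    """

    target_region: str = "arm1_end"
    p_target_min: float = 0.40
    p_opposite_max: float = 0.20
    p_box_max: float = 0.20
    min_specific_tetrodes: int = 2
    max_port_distance: float = 17.0
    window_ms: float = 30.0
    lockout_s: float = 5.0
    nosepoke_window_s: float = 3.0
    max_rewards: int = 75
    max_duration_min: float = 30.0
    specificity_factor: float = 3.0

    def __post_init__(self):
        for f in (self.p_target_min, self.p_opposite_max, self.p_box_max):
            if not 0.0 <= f <= 1.0:
                raise ValueError("mass fractions must be in [0, 1]")
        if self.p_target_min <= self.p_opposite_max:
            raise ValueError("p_target_min must exceed p_opposite_max")

    @property
    def target_arm(self) -> str:
        return self.target_region.split("_")[0]


@dataclass
class DetectionEvent:
    """A time at which the feedback criteria were satisfied."""

    time: float
    kind: str                    # "remote_rep" or "head_direction"
    snapshot: dict = field(repr=False)
    rewarded: bool = False
    nosepoke_latency: Optional[float] = None


class NosepokeModel:
    """Simulated nosepoke behavior: after each tone the animal pokes with a
    fixed probability, at a uniform latency."""

    def __init__(self, rng, prob: float = 0.95, latency=(0.2, 1.0)):
        self.rng = rng
        self.prob = prob
        self.latency = latency

    def __call__(self, tone_time: float) -> Optional[float]:
        if self.rng.random() < self.prob:
            return float(self.rng.uniform(*self.latency))
        return None


def evaluate_remote_criteria(
    avg_posterior: np.ndarray,
    n_specific_tetrodes: int,
    port_distance: float,
    criteria: DetectionCriteria,
    geometry,
):
    """Evaluate the five trigger conditions on one averaged posterior.

    Returns ``(ok, snapshot)`` where the snapshot records the four mass
    fractions, the tetrode count and the port distance.
    """
    arm = criteria.target_arm
    p = np.asarray(avg_posterior, dtype=float)
    m_target = float(p[geometry.mask(criteria.target_region)].sum())
    m_opp = float(p[geometry.mask(geometry.opposite_arm(arm))].sum())
    m_box = float(p[geometry.mask("box")].sum())
    m_arm = float(p[geometry.mask(arm)].sum())
    ok = (
        (m_target > criteria.p_target_min)
        and (m_opp < criteria.p_opposite_max)
        and (m_box < criteria.p_box_max)
        and (n_specific_tetrodes >= criteria.min_specific_tetrodes)
        and (port_distance < criteria.max_port_distance)
    )
    snapshot = {
        "mass_target_end": m_target,
        "mass_target_arm": m_arm,
        "mass_opposite_arm": m_opp,
        "mass_box": m_box,
        "n_specific_tetrodes": int(n_specific_tetrodes),
        "port_distance": float(port_distance),
    }
    return ok, snapshot


def _port_distance_series(trace, geometry) -> np.ndarray:
    return np.linalg.norm(trace.xy - geometry.center_port_xy[None, :], axis=1)


def detect_events(
    averaged,
    trace,
    criteria: DetectionCriteria,
    geometry,
    feedback_start: float,
    nosepokes: Optional[np.ndarray] = None,
    poke_model: Optional[NosepokeModel] = None,
) -> list:
    """Scan the averaged posterior stream and emit detection events.

    The first eligible averaged bin satisfying all criteria triggers a tone;
    a lockout then suppresses re-triggering. An event is rewarded iff a
    nosepoke occurs within the nosepoke window (either from an observed
    nosepoke-time array or from a simulated poke model). The stream ends
    after ``max_duration_min`` of feedback or at ``max_rewards`` rewards,
    whichever comes first.
    """
    times = averaged.times
    port_d = np.interp(times, trace.t, _port_distance_series(trace, geometry))
    t_stop = feedback_start + criteria.max_duration_min * 60.0

    candidates = np.flatnonzero(
        averaged.eligible
        & (times >= feedback_start)
        & (times < t_stop)
        & (port_d < criteria.max_port_distance)
        & (averaged.n_specific_tetrodes >= criteria.min_specific_tetrodes)
    )

    events: list[DetectionEvent] = []
    rewards = 0
    next_allowed = -np.inf
    nosepokes = None if nosepokes is None else np.asarray(nosepokes, dtype=float)
    for i in candidates:
        t = float(times[i])
        if t < next_allowed:
            continue
        ok, snap = evaluate_remote_criteria(
            averaged.posterior[i],
            int(averaged.n_specific_tetrodes[i]),
            float(port_d[i]),
            criteria,
            geometry,
        )
        if not ok:
            continue
        latency = _resolve_poke(t, criteria, nosepokes, poke_model)
        ev = DetectionEvent(
            time=t,
            kind="remote_rep",
            snapshot=snap,
            rewarded=latency is not None,
            nosepoke_latency=latency,
        )
        events.append(ev)
        if ev.rewarded:
            rewards += 1
            if rewards >= criteria.max_rewards:
                break
        next_allowed = t + criteria.lockout_s
    return events


def _resolve_poke(t, criteria, nosepokes, poke_model):
    if nosepokes is not None:
        after = nosepokes[(nosepokes > t) & (nosepokes <= t + criteria.nosepoke_window_s)]
        return float(after[0] - t) if len(after) else None
    if poke_model is not None:
        lat = poke_model(t)
        if lat is not None and lat < criteria.nosepoke_window_s:
            return lat
        return None
    return None


def head_direction_tolerance(reward_count: int) -> float:
    """Angular tolerance (degrees) as a function of rewards earned so far:
    linear from ±20° at reward 0 to ±3° at reward 25, constant after."""
    if reward_count >= 25:
        return 3.0
    return 20.0 - reward_count * (17.0 / 25.0)


def _wrap_angle(a):
    return (a + np.pi) % (2.0 * np.pi) - np.pi


def head_direction_feedback(
    trace,
    target_arm: str,
    criteria: DetectionCriteria,
    geometry,
    feedback_start: float,
    nosepokes: Optional[np.ndarray] = None,
    poke_model: Optional[NosepokeModel] = None,
) -> list:
    """Head-direction feedback control condition.

    The target is a head turn 30° to the left (arm1) or right (arm2) of
    forward; an event fires when the head angle is within the reward-count
    dependent tolerance and the rat is within 17 cm of the center port, with
    the same nosepoke / lockout / session-limit logic as the remote
    representation condition.
    """
    # forward (toward the arms) is +y; arm1 is 30° left, arm2 30° right
    target_angle = np.deg2rad(120.0 if target_arm == "arm1" else 60.0)
    port_d = _port_distance_series(trace, geometry)
    t_stop = feedback_start + criteria.max_duration_min * 60.0
    sel = np.flatnonzero(
        (trace.t >= feedback_start)
        & (trace.t < t_stop)
        & (port_d < criteria.max_port_distance)
    )
    err_deg = np.rad2deg(np.abs(_wrap_angle(trace.head_direction - target_angle)))

    events: list[DetectionEvent] = []
    rewards = 0
    next_allowed = -np.inf
    nosepokes = None if nosepokes is None else np.asarray(nosepokes, dtype=float)
    for i in sel:
        t = float(trace.t[i])
        if t < next_allowed:
            continue
        tol = head_direction_tolerance(rewards)
        if err_deg[i] >= tol:
            continue
        latency = _resolve_poke(t, criteria, nosepokes, poke_model)
        ev = DetectionEvent(
            time=t,
            kind="head_direction",
            snapshot={
                "head_angle_error_deg": float(err_deg[i]),
                "tolerance_deg": float(tol),
                "port_distance": float(port_d[i]),
            },
            rewarded=latency is not None,
            nosepoke_latency=latency,
        )
        events.append(ev)
        if ev.rewarded:
            rewards += 1
            if rewards >= criteria.max_rewards:
                break
        next_allowed = t + criteria.lockout_s
    return events


def audit_events(events, criteria: DetectionCriteria) -> bool:
    """Re-evaluate every emitted event against its own criteria snapshot.

    Returns True iff every snapshot satisfies the criteria it was emitted
    under (and rewarded events have a latency inside the nosepoke window).
    """
    for ev in events:
        s = ev.snapshot
        if ev.kind == "remote_rep":
            ok = (
                s["mass_target_end"] > criteria.p_target_min
                and s["mass_opposite_arm"] < criteria.p_opposite_max
                and s["mass_box"] < criteria.p_box_max
                and s["n_specific_tetrodes"] >= criteria.min_specific_tetrodes
                and s["port_distance"] < criteria.max_port_distance
            )
        else:
            ok = (
                s["head_angle_error_deg"] < s["tolerance_deg"]
                and s["port_distance"] < criteria.max_port_distance
            )
        if not ok:
            return False
        if ev.rewarded and not (
            ev.nosepoke_latency is not None
            and ev.nosepoke_latency < criteria.nosepoke_window_s
        ):
            return False
    return True
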