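"""Prevalence of remote representations and session-level comparisons.

The prevalence statistic counts 6 ms time bins, while the rat is within 17 cm
of the center reward port, in which more than 40% of the decoded posterior
mass lies in a named region, as a fraction of all eligible (informative,
near-port) bins. Comparisons between head-direction and neurofeedback
sessions use the Mann-Whitney test; longitudinal trends use OLS on
(optionally z-scored) prevalence against session index. Grouped mixed-effects
inference is out of scope here; per-session statistics are the deliverable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .stats import MannWhitneyResult, linear_trend, mann_whitney
from .track import TrackGeometry

__all__ = [
    "PrevalenceResult",
    "region_prevalence",
    "detection_exclusion_windows",
    "high_reward_filter",
    "compare_session_types",
    "longitudinal_trend",
]

MASS_THRESHOLD = 0.40          # strict > , as printed
PORT_DISTANCE_CM = 17.0        # strict <
MAX_REWARDS = 75
HIGH_REWARD_FRACTION = 0.9
# excision around each tone: the triggering 30 ms window plus the 90 ms
# before it (the span is not pinned down by the source; configurable)
EXCISION_BEFORE_S = 0.120


@dataclass
class PrevalenceResult:
    region: str
    qualifying_bins: int
    eligible_bins: int
    prevalence: float
    tone_bins_removed: bool


def detection_exclusion_windows(events) -> np.ndarray:
    """(start, end) windows around each detection to excise from prevalence."""
    if not events:
        return np.empty((0, 2))
    t = np.asarray([ev.time for ev in events], dtype=float)
    return np.column_stack([t - EXCISION_BEFORE_S, t])


def region_prevalence(
    decoded,
    trace,
    geometry: TrackGeometry,
    region: str,
    feedback_start: float,
    feedback_end: Optional[float] = None,
    exclude_windows: Optional[np.ndarray] = None,
    mass_threshold: float = MASS_THRESHOLD,
    max_port_distance: float = PORT_DISTANCE_CM,
) -> PrevalenceResult:
    """Fraction of eligible feedback bins whose ``region`` mass exceeds 40%.

    Eligible bins are informative 6 ms bins within the feedback phase with
    the animal strictly within 17 cm of the center port, minus any excised
    detection windows. Raises if no bin is eligible.
    """
    times = decoded.times
    mid = times - decoded.bin_s / 2.0
    fi = trace.at_times(mid)
    port_d = np.linalg.norm(
        trace.xy[fi] - geometry.center_port_xy[None, :], axis=1
    )

    eligible = decoded.informative & (mid >= feedback_start)
    if feedback_end is not None:
        eligible &= mid < feedback_end
    eligible &= port_d < max_port_distance

    removed = False
    if exclude_windows is not None and len(exclude_windows):
        removed = True
        for lo, hi in np.asarray(exclude_windows, dtype=float):
            eligible &= ~((times > lo) & (times <= hi))

    n_eligible = int(eligible.sum())
    if n_eligible == 0:
        raise ValueError("no eligible bins for prevalence")
    mass = decoded.posterior[eligible][:, geometry.mask(region)].sum(axis=1)
    n_qual = int((mass > mass_threshold).sum())
    return PrevalenceResult(
        region=region,
        qualifying_bins=n_qual,
        eligible_bins=n_eligible,
        prevalence=n_qual / n_eligible,
        tone_bins_removed=removed,
    )


def high_reward_filter(
    reward_counts: Sequence[int],
    max_rewards: int = MAX_REWARDS,
    fraction: float = HIGH_REWARD_FRACTION,
) -> np.ndarray:
    """Boolean mask keeping sessions with rewards > fraction * max_rewards
    (matched-reward restriction: 68 of 75 is kept, 67 is dropped)."""
    counts = np.asarray(reward_counts, dtype=float)
    return counts > fraction * max_rewards


def compare_session_types(
    prevalences_hd: Sequence[float],
    prevalences_nf: Sequence[float],
) -> MannWhitneyResult:
    """Two-sided Mann-Whitney comparison of per-session prevalence between
    head-direction and neurofeedback sessions (>=3 sessions per group)."""
    if min(len(prevalences_hd), len(prevalences_nf)) < 3:
        raise ValueError("need at least 3 sessions per group")
    return mann_whitney(prevalences_hd, prevalences_nf)


def longitudinal_trend(prevalence_by_session, z: bool = True):
    """Slope and p-value of prevalence against session index.

    Requires >=5 sessions; with ``z`` the series is z-scored first (the
    grouped-analysis convention). Constant series returns (0, 1).
    """
    v = np.asarray(prevalence_by_session, dtype=float)
    if len(v) < 5:
        raise ValueError("need at least 5 sessions for a trend")
    return linear_trend(v, z=z)
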