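"""Classification of detected remote representations.

Each detection is examined over a segment of raw 6 ms posteriors covering the
90 ms before detection plus the detection bin, and assigned exactly one of
four categories:

* ``long_trajectory``   — significant linear progression of the represented
  target-arm position covering >= 45 cm,
* ``medium_trajectory`` — same with coverage >= 35 cm,
* ``jump_arm_base``     — target-end mass > 0.4 together with > 0.2 mass in
  the proximal 15 cm of the arm in a pre-detection bin,
* ``jump``              — target-end mass > 0.4 and none of the above,

with ``other`` as the fallback. Trajectories take precedence because a full
sweep also satisfies the jump mass criterion. "Significant linear regression"
is ordinary least squares of the posterior-mass-weighted mean target-arm
position against time, over informative bins carrying >= 0.2 mass in the arm;
coverage is the range of the fitted values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats as sps

from .track import TrackGeometry, path_distance

__all__ = ["ClassifiedEvent", "classify_event", "classify_detections",
           "jump_distance", "peripheral_flags"]

PRE_DETECTION_S = 0.090
MIN_SEGMENT_BINS = 16          # 15 pre-detection bins + the detection bin
ARM_MASS_MIN = 0.2             # bin enters the regression above this arm mass
LONG_SPAN_CM = 45.0
MEDIUM_SPAN_CM = 35.0
BASE_MASS_MIN = 0.2
JUMP_END_MASS_MIN = 0.4
FLAG_MASS_THRESHOLD = 0.2
REGRESSION_ALPHA = 0.05


@dataclass
class ClassifiedEvent:
    time: float
    category: str
    jump_distance_cm: Optional[float]
    visual_field_flag: bool
    reward_port_flag: bool
    regression_slope: Optional[float] = None
    regression_p: Optional[float] = None
    coverage_cm: Optional[float] = None


def _arm_weighted_positions(posterior_seg, arm_mask, centers):
    """Per-bin arm mass and mass-weighted mean arm position."""
    arm_p = posterior_seg[:, arm_mask]
    mass = arm_p.sum(axis=1)
    with np.errstate(invalid="ignore"):
        mean_pos = arm_p @ centers[arm_mask] / np.where(mass > 0, mass, np.nan)
    return mass, mean_pos


def classify_event(
    posterior_seg: np.ndarray,
    informative: np.ndarray,
    times: np.ndarray,
    geometry: TrackGeometry,
    target_arm: str,
    flag_threshold: float = FLAG_MASS_THRESHOLD,
    alpha: float = REGRESSION_ALPHA,
) -> ClassifiedEvent:
    """Classify one detection from its posterior segment.

    ``posterior_seg`` holds the 6 ms posteriors of the segment (>= 16 bins,
    last bin = detection bin); ``informative`` flags bins with spikes;
    ``times`` are the bin times (s).
    """
    posterior_seg = np.asarray(posterior_seg, dtype=float)
    if len(posterior_seg) < MIN_SEGMENT_BINS:
        raise ValueError(
            f"segment must span at least {MIN_SEGMENT_BINS} bins "
            f"(got {len(posterior_seg)})"
        )
    informative = np.asarray(informative, dtype=bool)
    times = np.asarray(times, dtype=float)

    arm_mask = geometry.mask(target_arm)
    end_mass = posterior_seg[:, geometry.mask(f"{target_arm}_end")].sum(axis=1)
    base15_mass = posterior_seg[:, geometry.mask(f"{target_arm}_base15")].sum(axis=1)

    arm_mass, mean_pos = _arm_weighted_positions(
        posterior_seg, arm_mask, geometry.bin_centers
    )
    fit_sel = informative & (arm_mass >= ARM_MASS_MIN)

    slope = p_val = coverage = None
    category = "other"
    if fit_sel.sum() >= 3 and np.ptp(times[fit_sel]) > 0:
        res = sps.linregress(times[fit_sel], mean_pos[fit_sel])
        slope, p_val = float(res.slope), float(res.pvalue)
        if np.isnan(p_val):
            p_val = 1.0
        fitted = res.intercept + res.slope * times[fit_sel]
        coverage = float(np.ptp(fitted))
        if p_val < alpha and coverage >= LONG_SPAN_CM:
            category = "long_trajectory"
        elif p_val < alpha and coverage >= MEDIUM_SPAN_CM:
            category = "medium_trajectory"

    has_end = bool((end_mass[informative] > JUMP_END_MASS_MIN).any())
    if category == "other" and has_end:
        pre = informative.copy()
        pre[-1] = False  # pre-detection bins only
        if (base15_mass[pre] > BASE_MASS_MIN).any():
            category = "jump_arm_base"
        else:
            category = "jump"

    vf, rp = peripheral_flags(
        posterior_seg, informative, geometry, target_arm, flag_threshold
    )
    return ClassifiedEvent(
        time=float(times[-1]),
        category=category,
        jump_distance_cm=None,
        visual_field_flag=vf,
        reward_port_flag=rp,
        regression_slope=slope,
        regression_p=p_val,
        coverage_cm=coverage,
    )


def peripheral_flags(
    posterior_seg,
    informative,
    geometry: TrackGeometry,
    target_arm: str,
    threshold: float = FLAG_MASS_THRESHOLD,
):
    """(visual_field_flag, reward_port_flag): does any informative segment bin
    put more than ``threshold`` mass in the first / last 5 cm of the arm?"""
    posterior_seg = np.asarray(posterior_seg, dtype=float)
    informative = np.asarray(informative, dtype=bool)
    vf_mass = posterior_seg[:, geometry.mask(f"{target_arm}_visual_field")].sum(axis=1)
    rp_mass = posterior_seg[:, geometry.mask(f"{target_arm}_reward_port")].sum(axis=1)
    vf = bool((vf_mass[informative] > threshold).any())
    rp = bool((rp_mass[informative] > threshold).any())
    return vf, rp


def jump_distance(
    posterior_seg,
    informative,
    geometry: TrackGeometry,
    target_arm: str,
    animal_linear: float,
    animal_segment: int,
    end_mass_min: float = JUMP_END_MASS_MIN,
) -> float:
    """Along-track distance (cm) from the animal's position at detection to
    the represented position: the posterior mode of the first segment bin
    whose target-end mass exceeds the detection threshold (falling back to
    the detection bin)."""
    posterior_seg = np.asarray(posterior_seg, dtype=float)
    informative = np.asarray(informative, dtype=bool)
    end_mass = posterior_seg[:, geometry.mask(f"{target_arm}_end")].sum(axis=1)
    qualifying = np.flatnonzero(informative & (end_mass > end_mass_min))
    idx = qualifying[0] if len(qualifying) else len(posterior_seg) - 1
    mode = int(posterior_seg[idx].argmax())
    return float(
        path_distance(
            geometry.bin_centers[mode],
            geometry.segment_of_bin[mode],
            animal_linear,
            animal_segment,
            geometry,
        )
    )


def classify_detections(
    decoded,
    events,
    trace,
    geometry: TrackGeometry,
    target_arm: str,
    flag_threshold: float = FLAG_MASS_THRESHOLD,
) -> list:
    """Classify every detection event from the raw 6 ms posterior stream.

    The segment for each event covers the detection bin and the 90 ms before
    it; the jump distance is measured from the animal's linearized position
    at detection time.
    """
    n_pre = int(round(PRE_DETECTION_S / decoded.bin_s))
    out = []
    for ev in events:
        i_det = int(decoded.bin_index(ev.time - decoded.bin_s / 2))
        lo = i_det - n_pre
        if lo < 0:
            continue
        seg_post = decoded.posterior[lo : i_det + 1]
        seg_inf = decoded.informative[lo : i_det + 1]
        seg_times = decoded.times[lo : i_det + 1]
        ce = classify_event(
            seg_post, seg_inf, seg_times, geometry, target_arm, flag_threshold
        )
        fi = trace.at_times(ev.time)
        ce.jump_distance_cm = jump_distance(
            seg_post,
            seg_inf,
            geometry,
            target_arm,
            float(trace.linear[fi]),
            int(trace.segment[fi]),
        )
        out.append(ce)
    return out
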