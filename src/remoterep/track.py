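"""Y-maze geometry, 2D-to-linear position mapping, and named spatial regions.

The environment is a central "box" area with a reward port at its center and
two outward arms ("arm1", left; "arm2", right), each ending in a reward port.
For decoding, position is linearized onto a skeleton of three straight
segments that meet at the box center (the center port):

* ``box``  — from the far box wall to the center port,
* ``arm1`` — from the center port outward at 120 degrees,
* ``arm2`` — from the center port outward at 60 degrees.

The linear coordinate is 0 at the far end of the box and increases through
the center port and then outward along each arm; the three segments are
concatenated on one axis (box, arm1, arm2) so that a posterior over position
is a single vector. All intervals are half-open ``[start, end)``.

Named regions (per arm, measured from the arm's boxward edge):

* ``visual_field`` — first 5 cm of the arm (visible from the center port),
* ``base15``       — first 15 cm (used by event classification),
* ``arm_base``     — first 25 cm (the non-rewarded control region),
* ``arm_end``      — distal 25 cm (the neurofeedback target region),
* ``reward_port``  — last 5 cm (the physical reward port location).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TrackGeometry",
    "build_track",
    "linearize",
    "distance_to_center_port",
    "path_distance",
]

# region lengths in cm, fixed by the task design
VISUAL_FIELD_CM = 5.0
BASE15_CM = 15.0
ARM_BASE_CM = 25.0
ARM_END_CM = 25.0
REWARD_PORT_CM = 5.0

SEG_BOX, SEG_ARM1, SEG_ARM2 = 0, 1, 2
SEGMENT_NAMES = ("box", "arm1", "arm2")

# arm directions: "forward" (toward the arms) is +y; arm1 is 30 deg to the
# left of forward, arm2 is 30 deg to the right
_ARM_ANGLES = {"arm1": np.deg2rad(120.0), "arm2": np.deg2rad(60.0)}


@dataclass(frozen=True)
class TrackGeometry:
    """Linearized Y-maze with named regions.

    Attributes
    ----------
    arm_length, box_extent, bin_size : float
        Geometry parameters in cm.
    n_bins : int
        Number of linear position bins (``ceil(total_length / bin_size)``).
    bin_centers : ndarray, shape (n_bins,)
        Linear coordinate of each bin center, cm.
    segment_of_bin : ndarray of int, shape (n_bins,)
        Segment code per bin (0 = box, 1 = arm1, 2 = arm2).
    region_masks : dict[str, ndarray of bool]
        Boolean masks over bins for every named region.
    center_port_xy : ndarray, shape (2,)
        2D coordinates of the center reward port, cm.
    """

    arm_length: float
    box_extent: float
    bin_size: float
    n_bins: int
    bin_centers: np.ndarray
    segment_of_bin: np.ndarray
    region_masks: dict = field(repr=False)
    center_port_xy: np.ndarray
    skeleton: dict = field(repr=False)

    @property
    def total_length(self) -> float:
        return self.box_extent + 2.0 * self.arm_length

    def arm_offset(self, arm: str) -> float:
        """Linear coordinate of the boxward edge of ``arm``."""
        if arm == "arm1":
            return self.box_extent
        if arm == "arm2":
            return self.box_extent + self.arm_length
        raise ValueError(f"unknown arm {arm!r}")

    def mask(self, region: str) -> np.ndarray:
        return self.region_masks[region]

    def target_end(self, arm: str) -> np.ndarray:
        return self.region_masks[f"{arm}_end"]

    def opposite_arm(self, arm: str) -> str:
        return "arm2" if arm == "arm1" else "arm1"

    def bin_of(self, linear: np.ndarray) -> np.ndarray:
        """Bin index of a linear position (clipped into range)."""
        idx = np.floor(np.asarray(linear) / self.bin_size).astype(int)
        return np.clip(idx, 0, self.n_bins - 1)


def _interval_mask(centers: np.ndarray, start: float, end: float) -> np.ndarray:
    return (centers >= start) & (centers < end)


def build_track(
    arm_length: float = 120.0,
    box_extent: float = 50.0,
    bin_size: float = 5.0,
    port_inset: float = 25.0,
) -> TrackGeometry:
    """Build the Y-maze geometry with all named region masks.

    Parameters are in cm. ``port_inset`` places the center reward port inside
    the box, that far from the junction where the three segments meet (the
    port is central to the box area, away from the arm entrances). Raises
    ``ValueError`` if the 25 cm base and end regions cannot fit on an arm
    (``arm_length < 25``) or if ``bin_size`` is not positive.
    """
    if arm_length < ARM_END_CM:
        raise ValueError(
            f"arm_length={arm_length} cm cannot hold the {ARM_END_CM:g} cm "
            "base/end regions"
        )
    if bin_size <= 0 or box_extent <= 0:
        raise ValueError("bin_size and box_extent must be positive")
    if not 0 <= port_inset < box_extent:
        raise ValueError("port_inset must lie within the box")

    total = box_extent + 2.0 * arm_length
    n_bins = int(np.ceil(total / bin_size))
    centers = (np.arange(n_bins) + 0.5) * bin_size

    segment_of_bin = np.full(n_bins, SEG_ARM2, dtype=int)
    segment_of_bin[_interval_mask(centers, 0.0, box_extent)] = SEG_BOX
    segment_of_bin[
        _interval_mask(centers, box_extent, box_extent + arm_length)
    ] = SEG_ARM1

    masks: dict[str, np.ndarray] = {
        "box": segment_of_bin == SEG_BOX,
        "arm1": segment_of_bin == SEG_ARM1,
        "arm2": segment_of_bin == SEG_ARM2,
    }
    # box_far25: the 25 cm of box farthest from the center port; used as an
    # equal-length candidate region when labeling cell assemblies
    masks["box_far25"] = _interval_mask(centers, 0.0, min(ARM_BASE_CM, box_extent))
    for arm in ("arm1", "arm2"):
        off = box_extent if arm == "arm1" else box_extent + arm_length
        masks[f"{arm}_visual_field"] = _interval_mask(centers, off, off + VISUAL_FIELD_CM)
        masks[f"{arm}_base15"] = _interval_mask(centers, off, off + BASE15_CM)
        masks[f"{arm}_base"] = _interval_mask(centers, off, off + ARM_BASE_CM)
        masks[f"{arm}_end"] = _interval_mask(
            centers, off + arm_length - ARM_END_CM, off + arm_length
        )
        masks[f"{arm}_reward_port"] = _interval_mask(
            centers, off + arm_length - REWARD_PORT_CM, off + arm_length
        )
        # keep masks inside their segment even for odd bin sizes
        for key in (
            f"{arm}_visual_field",
            f"{arm}_base15",
            f"{arm}_base",
            f"{arm}_end",
            f"{arm}_reward_port",
        ):
            masks[key] &= masks[arm]

    center = np.array([0.0, -float(port_inset)])
    junction = np.zeros(2)
    box_end = np.array([0.0, -box_extent])
    skeleton = {
        "box": (box_end, junction),
        "arm1": (
            junction,
            arm_length * np.array(
                [np.cos(_ARM_ANGLES["arm1"]), np.sin(_ARM_ANGLES["arm1"])]
            ),
        ),
        "arm2": (
            junction,
            arm_length * np.array(
                [np.cos(_ARM_ANGLES["arm2"]), np.sin(_ARM_ANGLES["arm2"])]
            ),
        ),
    }

    geom = TrackGeometry(
        arm_length=float(arm_length),
        box_extent=float(box_extent),
        bin_size=float(bin_size),
        n_bins=n_bins,
        bin_centers=centers,
        segment_of_bin=segment_of_bin,
        region_masks=masks,
        center_port_xy=center,
        skeleton=skeleton,
    )
    _assert_region_consistency(geom)
    return geom


def _assert_region_consistency(geom: TrackGeometry) -> None:
    """Every bin belongs to exactly one segment; regions nest correctly."""
    seg_union = (
        geom.region_masks["box"].astype(int)
        + geom.region_masks["arm1"].astype(int)
        + geom.region_masks["arm2"].astype(int)
    )
    if not np.all(seg_union == 1):
        raise AssertionError("segments do not partition the linear bins")
    for arm in ("arm1", "arm2"):
        m = geom.region_masks
        if np.any(m[f"{arm}_reward_port"] & ~m[f"{arm}_end"]):
            raise AssertionError("reward_port must be a subset of arm_end")
        if np.any(m[f"{arm}_visual_field"] & ~m[f"{arm}_base"]):
            raise AssertionError("visual_field must be a subset of arm_base")
        for key in ("visual_field", "base15", "base", "end", "reward_port"):
            if np.any(m[f"{arm}_{key}"] & ~m[arm]):
                raise AssertionError(f"{arm}_{key} leaves its segment")


def _project_to_segment(xy: np.ndarray, a: np.ndarray, b: np.ndarray):
    """Project points onto the segment a->b; return (t in [0,1], distance)."""
    d = b - a
    L2 = float(d @ d)
    t = np.clip(((xy - a) @ d) / L2, 0.0, 1.0)
    proj = a[None, :] + t[:, None] * d[None, :]
    dist = np.linalg.norm(xy - proj, axis=1)
    return t, dist


def linearize(
    xy: np.ndarray,
    geometry: TrackGeometry,
    tolerance: float = 10.0,
):
    """Map 2D positions onto the linearized track.

    Parameters
    ----------
    xy : array-like, shape (n, 2) or (2,)
        Positions in cm.
    tolerance : float
        Positions farther than this from every skeleton segment are flagged
        off-track (they are still snapped; callers decide whether to carry
        the last valid position forward).

    Returns
    -------
    linear : ndarray (n,) — linear coordinate, cm
    segment : ndarray (n,) of int — segment code per point
    offtrack : ndarray (n,) of bool
    """
    xy = np.atleast_2d(np.asarray(xy, dtype=float))
    n = len(xy)
    best_dist = np.full(n, np.inf)
    linear = np.zeros(n)
    segment = np.zeros(n, dtype=int)

    offsets = {
        "box": (0.0, geometry.box_extent, SEG_BOX),
        "arm1": (geometry.box_extent, geometry.arm_length, SEG_ARM1),
        "arm2": (
            geometry.box_extent + geometry.arm_length,
            geometry.arm_length,
            SEG_ARM2,
        ),
    }
    for name, (a, b) in geometry.skeleton.items():
        off, length, code = offsets[name]
        t, dist = _project_to_segment(xy, np.asarray(a), np.asarray(b))
        # keep endpoints strictly inside the half-open segment interval
        t = np.minimum(t, 1.0 - 1e-12)
        better = dist < best_dist
        best_dist[better] = dist[better]
        linear[better] = off + t[better] * length
        segment[better] = code

    offtrack = best_dist > tolerance
    return linear, segment, offtrack


def distance_to_center_port(xy: np.ndarray, geometry: TrackGeometry) -> np.ndarray:
    """Euclidean 2D distance (cm) from each position to the center port."""
    xy = np.atleast_2d(np.asarray(xy, dtype=float))
    d = np.linalg.norm(xy - geometry.center_port_xy[None, :], axis=1)
    return d if d.size > 1 else float(d[0])


def _dist_to_center_linear(
    linear: np.ndarray, segment: np.ndarray, geometry: TrackGeometry
) -> np.ndarray:
    """Along-track distance from a linear coordinate to the center port."""
    linear = np.asarray(linear, dtype=float)
    segment = np.asarray(segment)
    out = np.empty_like(linear, dtype=float)
    box = segment == SEG_BOX
    out[box] = geometry.box_extent - linear[box]
    a1 = segment == SEG_ARM1
    out[a1] = linear[a1] - geometry.box_extent
    a2 = segment == SEG_ARM2
    out[a2] = linear[a2] - (geometry.box_extent + geometry.arm_length)
    return out


def path_distance(
    lin_a, seg_a, lin_b, seg_b, geometry: TrackGeometry
) -> np.ndarray:
    """Along-track distance between two linearized positions.

    Within a segment this is ``|a - b|``; across segments the path runs
    through the center port where the three segments meet.
    """
    lin_a = np.asarray(lin_a, dtype=float)
    lin_b = np.asarray(lin_b, dtype=float)
    seg_a = np.asarray(seg_a)
    seg_b = np.asarray(seg_b)
    lin_a, lin_b, seg_a, seg_b = np.broadcast_arrays(lin_a, lin_b, seg_a, seg_b)
    same = seg_a == seg_b
    out = np.empty(lin_a.shape, dtype=float)
    out[same] = np.abs(lin_a[same] - lin_b[same])
    cross = ~same
    out[cross] = _dist_to_center_linear(
        lin_a[cross], seg_a[cross], geometry
    ) + _dist_to_center_linear(lin_b[cross], seg_b[cross], geometry)
    return out if out.ndim else float(out)
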