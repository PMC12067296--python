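"""Cell-assembly detection (PCA + ICA) and activation at remote events.

Spike counts of sorted units in 30 ms bins are z-scored per unit; the number
of assemblies is the count of correlation-matrix eigenvalues above the
Marchenko-Pastur bound λ_max = (1 + sqrt(N_units / N_bins))², and assembly
weight vectors are extracted by ICA on the projection onto the significant
eigenspace. The activation strength of assembly k at time t is the
zero-diagonal quadratic form

    R_k(t) = z_tᵀ P_k z_t,   P_k = w_k w_kᵀ with diag(P_k) = 0,

which removes single-unit contributions. Assemblies are labeled target /
non-target from the place-field mass of their high-weight units.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.decomposition import FastICA

from .stats import mann_whitney
from .track import TrackGeometry

__all__ = [
    "AssemblyModel",
    "marchenko_pastur_lambda_max",
    "bin_and_zscore",
    "detect_assemblies",
    "assembly_strength",
    "label_assemblies",
    "activation_ratio",
    "count_active_high_weight_cells",
    "place_maps_from_units",
]

BIN_S = 0.030
HIGH_WEIGHT_SD = 2.0     # high-weight unit: weight > mean + 2 SD
# equal-length (25 cm) candidate regions for the target-labeling argmax rule
_CANDIDATE_REGIONS = ("arm1_end", "arm2_end", "arm1_base", "arm2_base", "box_far25")


def marchenko_pastur_lambda_max(n_units: int, n_bins: int) -> float:
    """Upper edge of the Marchenko-Pastur eigenvalue distribution."""
    return (1.0 + np.sqrt(n_units / n_bins)) ** 2


@dataclass
class AssemblyModel:
    weights: np.ndarray            # (n_units, n_assemblies), unit columns
    n_significant: int
    lambda_max: float
    eigenvalues: np.ndarray
    unit_indices: np.ndarray       # kept (non-silent) unit ids
    bin_edges: np.ndarray
    labels: Optional[list] = None  # "target"/"non_target" per assembly
    label_flags: Optional[list] = field(default=None, repr=False)

    @property
    def n_assemblies(self) -> int:
        return self.weights.shape[1]


def bin_and_zscore(
    unit_spike_times: Sequence[np.ndarray],
    t_start: float,
    t_end: float,
    bin_s: float = BIN_S,
):
    """Bin unit spike trains and z-score each unit's count row.

    Units with zero count variance in the epoch are dropped with a warning.
    Returns ``(zmatrix, kept_indices, bin_edges)``.
    """
    if len(unit_spike_times) < 2:
        raise ValueError("need at least 2 units")
    edges = np.arange(t_start, t_end + bin_s, bin_s)
    if len(edges) - 1 < 100:
        raise ValueError("epoch must span at least 100 bins")
    counts = np.array(
        [np.histogram(st, bins=edges)[0] for st in unit_spike_times], dtype=float
    )
    sd = counts.std(axis=1, ddof=0)
    keep = sd > 0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} silent/constant units")
    counts = counts[keep]
    z = (counts - counts.mean(axis=1, keepdims=True)) / sd[keep][:, None]
    return z, np.flatnonzero(keep), edges


def detect_assemblies(
    zmatrix: np.ndarray,
    bin_edges: Optional[np.ndarray] = None,
    unit_indices: Optional[np.ndarray] = None,
    random_state: int = 0,
    tw_constant: float = 2.0,
) -> AssemblyModel:
    """PCA significance test + ICA extraction of assembly weight vectors.

    Eigenvalues of the unit correlation matrix above the Marchenko-Pastur
    bound define the number of assemblies; ICA is run on the projection onto
    that eigenspace and each resulting weight vector is normalized to unit
    length with the largest-magnitude weight made positive. Zero significant
    eigenvalues yields a valid, empty model.

    At finite sample sizes the top noise eigenvalue fluctuates above the
    asymptotic Marchenko-Pastur edge on the Tracy-Widom scale, so the
    significance threshold adds ``tw_constant`` (~99th percentile at 2.0)
    times that scale; set ``tw_constant=0`` for the bare asymptotic bound.
    """
    z = np.asarray(zmatrix, dtype=float)
    n_units, n_bins = z.shape
    corr = (z @ z.T) / n_bins
    evals, evecs = np.linalg.eigh(corr)
    lam_max = marchenko_pastur_lambda_max(n_units, n_bins)
    q = n_units / n_bins
    tw_scale = n_bins ** (-2.0 / 3.0) * (1 + np.sqrt(q)) ** (4.0 / 3.0) * q ** (-1.0 / 6.0)
    sig = evals > lam_max + tw_constant * tw_scale
    k = int(sig.sum())
    if unit_indices is None:
        unit_indices = np.arange(n_units)
    if bin_edges is None:
        bin_edges = np.arange(n_bins + 1, dtype=float)

    if k == 0:
        weights = np.empty((n_units, 0))
    elif k == 1:
        w = evecs[:, sig][:, 0]
        weights = _normalize_signs(w[:, None])
    else:
        P = evecs[:, sig]                       # (n_units, k)
        projected = P.T @ z                     # (k, n_bins)
        ica = FastICA(
            n_components=k, random_state=random_state, whiten="unit-variance",
            max_iter=1000,
        )
        ica.fit(projected.T)
        # unmixing in PC space -> assembly patterns in unit space
        weights = _normalize_signs(P @ ica.components_.T)
    return AssemblyModel(
        weights=weights,
        n_significant=k,
        lambda_max=lam_max,
        eigenvalues=evals,
        unit_indices=np.asarray(unit_indices),
        bin_edges=np.asarray(bin_edges),
    )


def _normalize_signs(W: np.ndarray) -> np.ndarray:
    W = W / np.linalg.norm(W, axis=0, keepdims=True)
    flip = W[np.abs(W).argmax(axis=0), np.arange(W.shape[1])] < 0
    W[:, flip] *= -1.0
    return W


def assembly_strength(weights: np.ndarray, zmatrix: np.ndarray) -> np.ndarray:
    """Activation strength R_k(t) for every assembly and bin.

    Computed as (wᵀz)² − Σ_i w_i² z_i², the quadratic form with the diagonal
    of the outer-product projector removed. Returns (n_assemblies, n_bins).
    """
    W = np.atleast_2d(np.asarray(weights, dtype=float))
    if W.shape[0] != zmatrix.shape[0]:
        W = W.T
    proj = W.T @ zmatrix                 # (k, n_bins)
    diag = (W**2).T @ (zmatrix**2)       # single-unit contributions
    return proj**2 - diag


def place_maps_from_units(
    unit_spike_times: Sequence[np.ndarray],
    trace,
    geometry: TrackGeometry,
    exploration_end: float,
    speed_threshold: float = 4.0,
) -> np.ndarray:
    """Occupancy-normalized linear rate maps from exploration movement."""
    frames = (trace.t < exploration_end) & (trace.head_speed > speed_threshold)
    occ, _ = np.histogram(
        trace.linear[frames],
        bins=geometry.n_bins,
        range=(0.0, geometry.n_bins * geometry.bin_size),
    )
    occ_t = occ / trace.fs
    maps = np.zeros((len(unit_spike_times), geometry.n_bins))
    for u, st in enumerate(unit_spike_times):
        st = st[st < exploration_end]
        fi = trace.at_times(st)
        moving = trace.head_speed[fi] > speed_threshold
        cnt, _ = np.histogram(
            trace.linear[fi[moving]],
            bins=geometry.n_bins,
            range=(0.0, geometry.n_bins * geometry.bin_size),
        )
        with np.errstate(divide="ignore", invalid="ignore"):
            maps[u] = np.where(occ_t > 0, cnt / occ_t, 0.0)
    return maps


def high_weight_units(weights_k: np.ndarray, sd_factor: float = HIGH_WEIGHT_SD):
    w = np.asarray(weights_k, dtype=float)
    return np.flatnonzero(w > w.mean() + sd_factor * w.std(ddof=0))


def label_assemblies(
    model: AssemblyModel,
    place_maps: np.ndarray,
    geometry: TrackGeometry,
    target_arm: str,
) -> AssemblyModel:
    """Label each assembly target / non-target by an argmax rule.

    An assembly is ``target`` iff the weight-weighted place-map mass of its
    high-weight units inside the target arm end exceeds the same quantity for
    every other equal-length candidate region (the opposite arm end, the two
    arm bases, and the far 25 cm of the box). Assemblies with no high-weight
    unit are labeled non_target and flagged.
    """
    target_region = f"{target_arm}_end"
    labels, flags = [], []
    norm_maps = place_maps / np.maximum(
        place_maps.sum(axis=1, keepdims=True), 1e-12
    )
    for k in range(model.n_assemblies):
        w = model.weights[:, k]
        hw = high_weight_units(w)
        if len(hw) == 0:
            labels.append("non_target")
            flags.append("no_high_weight_units")
            continue
        units = model.unit_indices[hw]
        ww = w[hw] / w[hw].sum()
        scores = {
            r: float(ww @ norm_maps[units][:, geometry.mask(r)].sum(axis=1))
            for r in _CANDIDATE_REGIONS
        }
        best = max(scores, key=scores.get)
        labels.append("target" if best == target_region else "non_target")
        flags.append(None)
    model.labels = labels
    model.label_flags = flags
    return model


def activation_ratio(
    strength: np.ndarray,
    event_bins: np.ndarray,
    eligible_bins: np.ndarray,
    n_random: int,
    rng,
    exclude_events_from_pool: bool = True,
):
    """Mean strength at event bins over mean strength at matched random bins.

    Random bins are drawn (without replacement when possible) from the
    eligible set — feedback-phase bins satisfying the same port-distance
    constraint as detections. Returns ``(ratio, MannWhitneyResult)``.
    """
    event_bins = np.asarray(event_bins, dtype=int)
    if len(event_bins) < 10:
        raise ValueError("need at least 10 events")
    pool = np.asarray(eligible_bins, dtype=int)
    if exclude_events_from_pool:
        pool = np.setdiff1d(pool, event_bins)
    if len(pool) == 0:
        raise ValueError("no eligible bins to sample random times from")
    replace = len(pool) < n_random
    rand_bins = rng.choice(pool, size=n_random, replace=replace)
    ev = strength[event_bins]
    rd = strength[rand_bins]
    denom = rd.mean()
    ratio = float(ev.mean() / denom) if denom != 0 else np.inf
    return ratio, mann_whitney(ev, rd)


def count_active_high_weight_cells(
    weights_k: np.ndarray,
    unit_spike_times: Sequence[np.ndarray],
    unit_indices: np.ndarray,
    event_time: float,
    pre_window_s: float = 0.090,
):
    """Number (and fraction) of an assembly's high-weight units with at least
    one spike in the pre-detection window."""
    hw = high_weight_units(weights_k)
    if len(hw) == 0:
        return 0, 0.0
    lo, hi = event_time - pre_window_s, event_time
    n_active = 0
    for u in unit_indices[hw]:
        st = unit_spike_times[int(u)]
        i0, i1 = np.searchsorted(st, [lo, hi])
        if i1 > i0:
            n_active += 1
    return n_active, n_active / len(hw)
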