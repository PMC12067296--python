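"""Clusterless marked point-process decoding of linearized position.

The encoding model stores, per tetrode, every above-threshold exploration
spike as a (4-channel amplitude mark, linearized position) pair, plus a
kernel-smoothed occupancy. A new spike's spatial likelihood is a
kernel-weighted sum over the encoding spikes,

    l(x)  ∝  Σ_i  K_m(m - m_i) · K_x(x - x_i) / occupancy(x),

with Gaussian kernels in mark space (spherical over the 4 channels) and in
along-track position. Per 6 ms time bin, the likelihoods of all spikes in the
bin are multiplied and renormalized; zero-spike bins are uniform and flagged
uninformative. No state-transition prior is applied: the only temporal
smoothing is the causal 30 ms running average used by the detector.

Decoding does not require spike sorting; unit identity enters nowhere.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .track import SEG_ARM1, SEG_ARM2, SEG_BOX, TrackGeometry, path_distance

__all__ = [
    "EncodingModel",
    "DecodedPosterior",
    "AveragedPosterior",
    "fit_encoding_model",
    "spike_spatial_likelihood",
    "decode_session",
    "running_average_posterior",
    "decoding_quality",
    "decoding_error",
]

TIME_BIN_S = 0.006
AVG_WINDOW_BINS = 5          # 30 ms / 6 ms
OCCUPANCY_FLOOR = 1e-5       # fraction of total occupancy mass
MIN_ENCODING_SPIKES = 50
_LOG_FLOOR = 1e-300


@dataclass
class _TetrodeEncoding:
    marks: np.ndarray            # (n_i, 4) µV
    positions: np.ndarray        # (n_i,) linear cm
    segments: np.ndarray         # (n_i,) segment codes
    spatial_profile: np.ndarray  # (n_i, n_bins): K_x / occupancy, row-normalized


@dataclass
class EncodingModel:
    """Marked point-process encoding model fitted on exploration movement."""

    mark_bandwidth: float
    position_bandwidth: float
    amplitude_threshold: float
    occupancy: np.ndarray
    valid_bins: np.ndarray       # occupancy above floor
    tetrodes: dict = field(repr=False)
    n_bins: int = 0

    @property
    def tetrode_ids(self):
        return sorted(self.tetrodes)


@dataclass
class DecodedPosterior:
    """Per-6-ms-bin posterior over linear position bins."""

    t0: float
    bin_s: float
    posterior: np.ndarray          # (n_t, n_bins)
    informative: np.ndarray        # (n_t,) bool: >=1 decoded spike
    n_spikes: np.ndarray           # (n_t,)
    tetrode_specific: np.ndarray   # (n_t, n_tet) bool: spatially specific spike
    tetrode_ids: list

    @property
    def n_t(self) -> int:
        return len(self.posterior)

    @property
    def times(self) -> np.ndarray:
        """End time of each bin (the moment the bin becomes available)."""
        return self.t0 + (np.arange(self.n_t) + 1) * self.bin_s

    def bin_index(self, t) -> np.ndarray:
        idx = np.floor((np.asarray(t) - self.t0) / self.bin_s).astype(int)
        return np.clip(idx, 0, self.n_t - 1)


@dataclass
class AveragedPosterior:
    """Causal 30 ms running average of the decoded posterior."""

    t0: float
    bin_s: float
    posterior: np.ndarray        # (n_t, n_bins)
    eligible: np.ndarray         # (n_t,) bool: >=2 informative constituents
    n_informative: np.ndarray    # (n_t,)
    n_specific_tetrodes: np.ndarray  # (n_t,) tetrodes specific within window

    @property
    def times(self) -> np.ndarray:
        return self.t0 + (np.arange(len(self.posterior)) + 1) * self.bin_s


def _smooth_by_segment(values: np.ndarray, geometry: TrackGeometry, sigma_bins: float):
    out = values.astype(float).copy()
    for code in (SEG_BOX, SEG_ARM1, SEG_ARM2):
        m = geometry.segment_of_bin == code
        if m.any():
            out[m] = gaussian_filter1d(values[m].astype(float), sigma_bins, mode="nearest")
    return out


def fit_encoding_model(
    spikes,
    trace,
    geometry: TrackGeometry,
    exploration_end: float,
    mark_bandwidth: float = 20.0,
    position_bandwidth: float = 6.0,
    amplitude_threshold: float = 100.0,
    speed_threshold: float = 4.0,
    min_encoding_spikes: int = MIN_ENCODING_SPIKES,
) -> EncodingModel:
    """Fit the encoding model on exploration-phase movement data.

    Keeps every exploration spike above ``amplitude_threshold`` (µV, max
    channel) emitted while speed > ``speed_threshold``; occupancy is the
    speed-filtered position histogram, kernel-smoothed within each track
    segment and normalized. Tetrodes with fewer than 50 encoding spikes are
    excluded with a warning.
    """
    frames = (trace.t < exploration_end) & (trace.head_speed > speed_threshold)
    occ_counts, _ = np.histogram(
        trace.linear[frames],
        bins=geometry.n_bins,
        range=(0.0, geometry.n_bins * geometry.bin_size),
    )
    occ = _smooth_by_segment(
        occ_counts, geometry, position_bandwidth / geometry.bin_size
    )
    total = occ.sum()
    if total <= 0:
        raise ValueError("no movement samples in the exploration phase")
    occ = occ / total
    valid = occ >= OCCUPANCY_FLOOR

    # pairwise along-track distances between bin centers, for K_x
    centers = geometry.bin_centers
    segs = geometry.segment_of_bin
    D = path_distance(
        centers[:, None], segs[:, None], centers[None, :], segs[None, :], geometry
    )

    tets = {}
    for tet in sorted(spikes.times):
        st = spikes.times[tet]
        sm = spikes.marks[tet]
        sel = (st < exploration_end) & (sm.max(axis=1) > amplitude_threshold)
        fi = trace.at_times(st[sel])
        moving = trace.head_speed[fi] > speed_threshold
        st_k = st[sel][moving]
        sm_k = sm[sel][moving]
        if len(st_k) < min_encoding_spikes:
            warnings.warn(
                f"tetrode {tet}: only {len(st_k)} encoding spikes; excluded"
            )
            continue
        fi = fi[moving]
        pos = trace.linear[fi]
        seg = trace.segment[fi]
        pos_bins = geometry.bin_of(pos)
        kx = np.exp(
            -0.5 * (D[pos_bins] / position_bandwidth) ** 2
        )  # (n_i, n_bins)
        profile = np.where(valid[None, :], kx / np.maximum(occ, OCCUPANCY_FLOOR), 0.0)
        tets[tet] = _TetrodeEncoding(
            marks=np.ascontiguousarray(sm_k, dtype=np.float64),
            positions=pos,
            segments=seg,
            spatial_profile=np.ascontiguousarray(profile),
        )
    return EncodingModel(
        mark_bandwidth=float(mark_bandwidth),
        position_bandwidth=float(position_bandwidth),
        amplitude_threshold=float(amplitude_threshold),
        occupancy=occ,
        valid_bins=valid,
        tetrodes=tets,
        n_bins=geometry.n_bins,
    )


def _mark_weights(queries: np.ndarray, enc_marks: np.ndarray, bw: float):
    """Gaussian product-kernel weights in mark space, (n_q, n_i)."""
    q2 = np.sum(queries**2, axis=1)[:, None]
    e2 = np.sum(enc_marks**2, axis=1)[None, :]
    d2 = q2 + e2 - 2.0 * queries @ enc_marks.T
    np.maximum(d2, 0.0, out=d2)
    return np.exp(-0.5 * d2 / bw**2)


def spike_spatial_likelihood(mark, model: EncodingModel, tetrode) -> np.ndarray:
    """Spatial likelihood (normalized over bins) of a single spike's mark.

    If every kernel weight underflows, a uniform likelihood is returned (the
    low-information case; such a spike carries no spatial evidence).
    """
    like, _ = _likelihoods_batch(np.atleast_2d(np.asarray(mark, float)), model, tetrode)
    return like[0]


def _likelihoods_batch(marks: np.ndarray, model: EncodingModel, tetrode, chunk=2048):
    """Likelihood rows for many spikes of one tetrode; returns (like, flat)."""
    enc = model.tetrodes[tetrode]
    n_q = len(marks)
    out = np.empty((n_q, model.n_bins))
    flat = np.zeros(n_q, dtype=bool)
    for lo in range(0, n_q, chunk):
        hi = min(n_q, lo + chunk)
        w = _mark_weights(marks[lo:hi], enc.marks, model.mark_bandwidth)
        like = w @ enc.spatial_profile
        s = like.sum(axis=1)
        bad = s <= 0
        if bad.any():
            like[bad] = model.valid_bins.astype(float)
            s[bad] = like[bad].sum(axis=1)
            flat[lo:hi][bad] = True
        out[lo:hi] = like / s[:, None]
    return out, flat


def decode_session(
    spikes,
    model: EncodingModel,
    geometry: TrackGeometry,
    t_start: float,
    t_end: float,
    bin_s: float = TIME_BIN_S,
    specificity_factor: float = 3.0,
) -> DecodedPosterior:
    """Decode the posterior over position for every time bin in an epoch.

    Per bin the posterior is proportional to the product of the spatial
    likelihoods of all above-threshold spikes in the bin (accumulated in log
    space); bins with no spikes are uniform and flagged uninformative.
    ``tetrode_specific`` records, per bin and tetrode, whether the tetrode
    contributed at least one spatially specific spike (peak more than
    ``specificity_factor`` times the uniform level).
    """
    n_t = max(0, int(np.ceil((t_end - t_start) / bin_s)))
    n_bins = model.n_bins
    log_post = np.zeros((n_t, n_bins))
    n_spikes = np.zeros(n_t, dtype=int)
    tet_ids = model.tetrode_ids
    specific = np.zeros((n_t, len(tet_ids)), dtype=bool)

    uniform_level = 1.0 / n_bins
    for j, tet in enumerate(tet_ids):
        st = spikes.times[tet]
        sm = spikes.marks[tet]
        sel = (
            (st >= t_start)
            & (st < t_end)
            & (sm.max(axis=1) > model.amplitude_threshold)
        )
        if not sel.any():
            continue
        st_k = st[sel]
        like, flat = _likelihoods_batch(np.asarray(sm[sel], float), model, tet)
        tb = np.floor((st_k - t_start) / bin_s).astype(int)
        tb = np.clip(tb, 0, n_t - 1)
        np.add.at(log_post, tb, np.log(np.maximum(like, _LOG_FLOOR)))
        np.add.at(n_spikes, tb, 1)
        spec = (like.max(axis=1) > specificity_factor * uniform_level) & ~flat
        if spec.any():
            np.logical_or.at(specific[:, j], tb[spec], True)

    informative = n_spikes > 0
    posterior = np.full((n_t, n_bins), uniform_level)
    if informative.any():
        lp = log_post[informative]
        lp -= lp.max(axis=1, keepdims=True)
        p = np.exp(lp)
        posterior[informative] = p / p.sum(axis=1, keepdims=True)
    return DecodedPosterior(
        t0=float(t_start),
        bin_s=float(bin_s),
        posterior=posterior,
        informative=informative,
        n_spikes=n_spikes,
        tetrode_specific=specific,
        tetrode_ids=list(tet_ids),
    )


def running_average_posterior(
    decoded: DecodedPosterior, window_bins: int = AVG_WINDOW_BINS
) -> AveragedPosterior:
    """Causal running average over the last ``window_bins`` time bins.

    Only informative constituents enter the mean; windows with fewer than two
    informative bins are flagged ineligible. The per-window count of tetrodes
    with a spatially specific spike is aggregated over the same window.
    """
    post = decoded.posterior
    inf = decoded.informative.astype(float)
    n_t, n_bins = post.shape

    weighted = post * inf[:, None]
    csum = np.cumsum(np.vstack([np.zeros((1, n_bins)), weighted]), axis=0)
    cnt = np.cumsum(np.concatenate([[0.0], inf]))
    lo = np.maximum(0, np.arange(n_t) - window_bins + 1)
    hi = np.arange(n_t) + 1
    window_sum = csum[hi] - csum[lo]
    window_cnt = cnt[hi] - cnt[lo]

    eligible = window_cnt >= 2
    avg = np.full_like(post, 1.0 / n_bins)
    avg[eligible] = window_sum[eligible] / window_cnt[eligible, None]

    spec = decoded.tetrode_specific.astype(int)
    cspec = np.cumsum(np.vstack([np.zeros((1, spec.shape[1]), int), spec]), axis=0)
    win_spec = (cspec[hi] - cspec[lo]) > 0
    n_specific = win_spec.sum(axis=1)

    return AveragedPosterior(
        t0=decoded.t0,
        bin_s=decoded.bin_s,
        posterior=avg,
        eligible=eligible,
        n_informative=window_cnt.astype(int),
        n_specific_tetrodes=n_specific,
    )


def _true_position_at_bins(decoded: DecodedPosterior, trace):
    mid = decoded.t0 + (np.arange(decoded.n_t) + 0.5) * decoded.bin_s
    fi = trace.at_times(mid)
    return trace.linear[fi], trace.segment[fi], trace.head_speed[fi], fi


def decoding_error(
    decoded: DecodedPosterior,
    trace,
    geometry: TrackGeometry,
    movement_only: bool = True,
    speed_threshold: float = 4.0,
) -> np.ndarray:
    """Along-track |argmax - true position| (cm) for informative bins."""
    lin, seg, speed, _ = _true_position_at_bins(decoded, trace)
    sel = decoded.informative.copy()
    if movement_only:
        sel &= speed > speed_threshold
    amax = decoded.posterior[sel].argmax(axis=1)
    dec_lin = geometry.bin_centers[amax]
    dec_seg = geometry.segment_of_bin[amax]
    return path_distance(dec_lin, dec_seg, lin[sel], seg[sel], geometry)


def decoding_quality(
    decoded: DecodedPosterior,
    trace,
    geometry: TrackGeometry,
    target_arm: str,
    exploration_end: float,
    speed_threshold: float = 4.0,
    inclusion_threshold: float = 0.65,
):
    """Session-inclusion check: fraction of informative bins whose posterior
    argmax lies in the target arm, over exploration bins where the animal is
    in the target-arm end running outward.

    Returns ``(fraction, included)``. Raises if no bin qualifies.
    """
    lin, seg, speed, fi = _true_position_at_bins(decoded, trace)
    mid = decoded.t0 + (np.arange(decoded.n_t) + 0.5) * decoded.bin_s
    end_mask = geometry.mask(f"{target_arm}_end")
    in_end = end_mask[geometry.bin_of(lin)] & (
        seg == (SEG_ARM1 if target_arm == "arm1" else SEG_ARM2)
    )
    # outward: linear coordinate increasing (both arms point away from 0)
    dlin = np.gradient(trace.linear, trace.t)
    outward = dlin[fi] > 0
    sel = (
        decoded.informative
        & (mid < exploration_end)
        & in_end
        & (speed > speed_threshold)
        & outward
    )
    if not sel.any():
        raise ValueError("no qualifying exploration bins for the quality check")
    amax = decoded.posterior[sel].argmax(axis=1)
    arm_mask = geometry.mask(target_arm)
    frac = float(arm_mask[amax].mean())
    return frac, frac >= inclusion_threshold
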