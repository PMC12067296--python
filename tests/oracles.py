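"""Independent brute-force oracles used by the tests.

These deliberately re-derive quantities with plain loops and textbook
formulas, sharing no code with the package implementation.
"""

import itertools
import math

import numpy as np


def brute_force_likelihood(mark, enc_marks, enc_pos_bins, bin_dists, occupancy,
                           mark_bw, pos_bw, occ_floor):
    """Kernel likelihood of one spike by explicit double loop."""
    n_bins = bin_dists.shape[0]
    like = np.zeros(n_bins)
    for b in range(n_bins):
        if occupancy[b] < occ_floor:
            continue
        total = 0.0
        for i in range(len(enc_marks)):
            km = math.exp(
                -0.5 * sum((mark[c] - enc_marks[i][c]) ** 2 for c in range(4))
                / mark_bw**2
            )
            kx = math.exp(-0.5 * (bin_dists[enc_pos_bins[i], b] / pos_bw) ** 2)
            total += km * kx
        like[b] = total / max(occupancy[b], occ_floor)
    s = like.sum()
    return like / s if s > 0 else np.full(n_bins, 1.0 / n_bins)


def brute_force_decode_bin(marks_by_tet, enc, bin_dists, occupancy,
                           mark_bw, pos_bw, occ_floor):
    """Posterior of one time bin: product over spikes of their likelihoods."""
    n_bins = bin_dists.shape[0]
    post = np.ones(n_bins)
    for tet, marks in marks_by_tet.items():
        enc_marks, enc_pos_bins = enc[tet]
        for m in marks:
            like = brute_force_likelihood(
                m, enc_marks, enc_pos_bins, bin_dists, occupancy,
                mark_bw, pos_bw, occ_floor,
            )
            post = post * like
    return post / post.sum()


def mann_whitney_enumeration(x, y):
    """Exact two-sided Mann-Whitney p by full enumeration of assignments."""
    from scipy.stats import rankdata

    x, y = list(x), list(y)
    nx = len(x)
    combined = np.asarray(x + y, dtype=float)
    ranks = rankdata(combined)
    u_obs = ranks[:nx].sum() - nx * (nx + 1) / 2
    u_lo = min(u_obs, nx * len(y) - u_obs)
    u_hi = nx * len(y) - u_lo
    count = total = 0
    for subset in itertools.combinations(range(len(combined)), nx):
        u = ranks[list(subset)].sum() - nx * (nx + 1) / 2
        total += 1
        if u <= u_lo + 1e-12 or u >= u_hi - 1e-12:
            count += 1
    return u_obs, count / total


def ols_slope_p(x, y):
    """Slope and slope-t-test p from the normal equations, hand-coded."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    xbar, ybar = x.mean(), y.mean()
    sxx = ((x - xbar) ** 2).sum()
    slope = ((x - xbar) * (y - ybar)).sum() / sxx
    intercept = ybar - slope * xbar
    resid = y - intercept - slope * x
    s2 = (resid**2).sum() / (n - 2)
    se = math.sqrt(s2 / sxx)
    from scipy.stats import t as tdist

    tstat = slope / se
    p = 2 * tdist.sf(abs(tstat), n - 2)
    return slope, p


def quadrature_phase(samples, fs, f_lo, f_hi):
    """Phase via an independent quadrature (two-filter) estimate: band-pass,
    then atan2 of the normalized derivative against the signal, with 0 at the
    trough."""
    from scipy.signal import butter, filtfilt

    b, a = butter(4, [f_lo, f_hi], btype="bandpass", fs=fs)
    x = filtfilt(b, a, samples)
    dx = np.gradient(x) * fs
    w = 2 * np.pi * (f_lo + f_hi) / 2
    phase_peak0 = np.arctan2(-dx / w, x)
    # shift so 0 is the trough (same convention as the package)
    return (phase_peak0 + 2 * np.pi) % (2 * np.pi) - np.pi
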