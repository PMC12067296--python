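"""Brain-state segmentation: SWR detection, stillness/movement labeling,
theta phase, and state-composition statistics.

Sharp-wave ripples are detected on the ripple band (150-250 Hz) of the LFP:
analytic-signal envelope, smoothed 4 ms, events where the envelope stays
above mean + 3.5 SD for at least 15 ms, extended to the mean + 1 SD
boundaries and merged across gaps shorter than 10 ms. Each 6 ms bin is then labeled
``swr`` (overlapping a ripple), ``moving`` (head speed > 4 cm/s) or ``still``.
Theta phase is the analytic-signal phase of the 6-10 Hz band with 0 at the
LFP trough (the convention is reported alongside results). Circular
concentration of phases uses the Rayleigh test with the standard small-sample
correction.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import stats as sps
from scipy.ndimage import gaussian_filter1d
from scipy.signal import butter, filtfilt, hilbert
from statsmodels.stats.proportion import proportions_ztest

__all__ = [
    "detect_swr",
    "label_states",
    "theta_phase_at",
    "rayleigh_test",
    "state_composition",
]

SPEED_THRESHOLD = 4.0
RIPPLE_BAND = (150.0, 250.0)
THETA_BAND = (6.0, 10.0)
STATES = ("swr", "still", "moving")


def _bandpass(samples, fs, band, order=4):
    b, a = butter(order, band, btype="bandpass", fs=fs)
    return filtfilt(b, a, samples)


def detect_swr(
    lfp,
    band=RIPPLE_BAND,
    threshold_sd: float = 3.5,
    boundary_sd: float = 1.0,
    min_duration_s: float = 0.015,
    merge_gap_s: float = 0.010,
    smooth_ms: float = 4.0,
) -> np.ndarray:
    """Detect ripple intervals; returns an (n, 2) array of (start, end) s.

    Requires at least 10 s of LFP for a stable envelope baseline.
    """
    fs = lfp.fs
    x = np.asarray(lfp.samples, dtype=float)
    if len(x) / fs < 10.0:
        raise ValueError("need at least 10 s of LFP for a stable baseline")
    env = np.abs(hilbert(_bandpass(x, fs, band)))
    env = gaussian_filter1d(env, smooth_ms * fs / 1000.0)
    mu, sd = env.mean(), env.std()
    hi_thr = mu + threshold_sd * sd
    lo_thr = mu + boundary_sd * sd

    above = env > hi_thr
    if not above.any():
        return np.empty((0, 2))
    idx = np.flatnonzero(above)
    breaks = np.flatnonzero(np.diff(idx) > 1)
    run_starts = np.concatenate([[idx[0]], idx[breaks + 1]])
    run_ends = np.concatenate([idx[breaks], [idx[-1]]]) + 1

    min_len = int(round(min_duration_s * fs))
    keep = (run_ends - run_starts) >= min_len
    run_starts, run_ends = run_starts[keep], run_ends[keep]
    if len(run_starts) == 0:
        return np.empty((0, 2))

    # extend to the low-threshold boundaries
    below_lo = env <= lo_thr
    ext = []
    for s, e in zip(run_starts, run_ends):
        left = np.flatnonzero(below_lo[:s])
        s2 = left[-1] + 1 if len(left) else 0
        right = np.flatnonzero(below_lo[e:])
        e2 = e + right[0] if len(right) else len(env)
        ext.append((s2, e2))

    # merge across short gaps
    merged = [list(ext[0])]
    gap = int(round(merge_gap_s * fs))
    for s, e in ext[1:]:
        if s - merged[-1][1] < gap:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    out = np.asarray(merged, dtype=float) / fs + lfp.t0
    return out


def label_states(trace, swr_intervals, bin_edges) -> np.ndarray:
    """State per time bin: 'swr' if the bin overlaps a ripple interval, else
    'moving' if head speed > 4 cm/s at the bin midpoint, else 'still'."""
    edges = np.asarray(bin_edges, dtype=float)
    lo, hi = edges[:-1], edges[1:]
    mid = (lo + hi) / 2.0
    speed = np.interp(mid, trace.t, trace.head_speed)
    states = np.where(speed > SPEED_THRESHOLD, "moving", "still").astype(object)
    for s, e in np.asarray(swr_intervals, dtype=float).reshape(-1, 2):
        states[(hi > s) & (lo < e)] = "swr"
    return np.asarray(states, dtype="U6")


def theta_phase_at(times, lfp, band=THETA_BAND) -> np.ndarray:
    """Theta phase (radians, in (-pi, pi]) at arbitrary times.

    Convention: phase 0 at the trough of the reference LFP, increasing with
    time (reported in output metadata, since "late theta" depends on it).
    """
    analytic = hilbert(_bandpass(np.asarray(lfp.samples, float), lfp.fs, band))
    # angle() is 0 at the peak; shift by pi so 0 is the trough
    unwrapped = np.unwrap(np.angle(analytic)) + np.pi
    ph = np.interp(np.asarray(times, dtype=float), lfp.t, unwrapped)
    return (ph + np.pi) % (2.0 * np.pi) - np.pi


def rayleigh_test(phases):
    """Rayleigh test of circular uniformity.

    Z = n * R̄² with R̄ the mean resultant length; the p-value uses the
    standard series correction
    p = exp(-Z) * (1 + (2Z - Z²)/(4n) - (24Z - 132Z² + 76Z³ - 9Z⁴)/(288n²)),
    clipped to [0, 1]. For n < 10 the correction terms are unstable; a
    warning is raised and the uncorrected exp(-Z) is reported.
    """
    ph = np.asarray(phases, dtype=float)
    n = len(ph)
    if n == 0:
        raise ValueError("no phases")
    r_bar = np.abs(np.exp(1j * ph).sum()) / n
    z = n * r_bar**2
    if n < 10:
        warnings.warn("n < 10: Rayleigh p reported without correction terms")
        p = np.exp(-z)
    else:
        p = np.exp(-z) * (
            1.0
            + (2.0 * z - z**2) / (4.0 * n)
            - (24.0 * z - 132.0 * z**2 + 76.0 * z**3 - 9.0 * z**4)
            / (288.0 * n**2)
        )
    return float(z), float(np.clip(p, 0.0, 1.0))


def state_composition(states_by_condition: dict):
    """State composition of remote-representation bins across conditions.

    Parameters
    ----------
    states_by_condition : dict
        Condition name -> array of state labels ('swr'/'still'/'moving') of
        the remote-representation bins in that condition.

    Returns a dict with per-condition state fractions, the chi-square test
    over the 3 x k contingency table, and post-hoc two-proportion z-tests for
    the moving and swr fractions between every pair of conditions. Expected
    cell counts below 5 set ``low_expected`` (with a Fisher exact fallback
    when the table is 2x2).
    """
    conds = list(states_by_condition)
    table = np.array(
        [
            [int(np.sum(np.asarray(states_by_condition[c]) == s)) for c in conds]
            for s in STATES
        ]
    )
    totals = table.sum(axis=0)
    fractions = {
        c: {s: table[i, j] / totals[j] if totals[j] else np.nan
            for i, s in enumerate(STATES)}
        for j, c in enumerate(conds)
    }
    nonzero_rows = table.sum(axis=1) > 0
    chi2, p, dof, expected = sps.chi2_contingency(table[nonzero_rows])
    low_expected = bool((expected < 5).any())
    fisher_p = None
    if low_expected and table[nonzero_rows].shape == (2, 2):
        _, fisher_p = sps.fisher_exact(table[nonzero_rows])

    posthoc = {}
    for i, a in enumerate(conds):
        for b in conds[i + 1:]:
            for s in ("moving", "swr"):
                si = STATES.index(s)
                ca, cb = table[si, conds.index(a)], table[si, conds.index(b)]
                na, nb = totals[conds.index(a)], totals[conds.index(b)]
                if na and nb:
                    _, zp = proportions_ztest([ca, cb], [na, nb])
                else:
                    zp = np.nan
                posthoc[(a, b, s)] = float(zp)
    return {
        "fractions": fractions,
        "chi2": float(chi2),
        "chi2_p": float(p),
        "dof": int(dof),
        "low_expected": low_expected,
        "fisher_p": fisher_p,
        "posthoc_z_p": posthoc,
        "table": table,
        "conditions": conds,
    }
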