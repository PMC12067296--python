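import numpy as np
import pytest

from oracles import brute_force_decode_bin, brute_force_likelihood
from remoterep.decoding import (
    OCCUPANCY_FLOOR,
    decode_session,
    decoding_error,
    decoding_quality,
    fit_encoding_model,
    running_average_posterior,
    spike_spatial_likelihood,
)
from remoterep.synthetic import MarkedSpikes, PositionTrace
from remoterep.track import build_track, path_distance


def make_tiny_setup(rng, n_enc=10, n_tets=2, arm_length=25.0, box_extent=25.0,
                    bin_size=15.0):
    """A hand-built 5-bin decoding instance: a trace sweeping all bins and a
    chosen set of encoding spikes per tetrode."""
    geometry = build_track(arm_length, box_extent, bin_size, port_inset=10.0)
    assert geometry.n_bins == 5
    # trace: walk the whole track slowly (speed > 4 so everything is encoding)
    fs = 30.0
    n = 600
    t = np.arange(n) / fs
    lin = np.linspace(0.5, geometry.total_length - 0.5, n)
    seg = geometry.segment_of_bin[geometry.bin_of(lin)]
    trace = PositionTrace(
        t=t, xy=np.zeros((n, 2)), head_direction=np.zeros(n),
        linear=lin, segment=seg,
        head_speed=np.full(n, 10.0), offtrack=np.zeros(n, bool),
    )
    times, marks = {}, {}
    for tet in range(n_tets):
        idx = rng.choice(n, size=n_enc, replace=False)
        idx.sort()
        times[tet] = t[idx] + 1e-4
        marks[tet] = rng.uniform(120.0, 300.0, size=(n_enc, 4))
    spikes = MarkedSpikes(times=times, marks=marks)
    model = fit_encoding_model(
        spikes, trace, geometry, exploration_end=t[-1] + 1.0,
        mark_bandwidth=40.0, position_bandwidth=10.0, min_encoding_spikes=1,
    )
    # oracle ingredients
    centers = geometry.bin_centers
    segs = geometry.segment_of_bin
    bin_dists = path_distance(
        centers[:, None], segs[:, None], centers[None, :], segs[None, :], geometry
    )
    enc = {}
    for tet in range(n_tets):
        pos = model.tetrodes[tet].positions
        enc[tet] = (model.tetrodes[tet].marks, geometry.bin_of(pos))
    return geometry, trace, spikes, model, bin_dists, enc


class TestLikelihood:
    def test_matches_brute_force_oracle(self, rng):
        geometry, _, _, model, bin_dists, enc = make_tiny_setup(rng)
        for tet in (0, 1):
            for _ in range(5):
                mark = rng.uniform(120.0, 300.0, size=4)
                ours = spike_spatial_likelihood(mark, model, tet)
                oracle = brute_force_likelihood(
                    mark, enc[tet][0], enc[tet][1], bin_dists,
                    model.occupancy, 40.0, 10.0, OCCUPANCY_FLOOR,
                )
                np.testing.assert_allclose(ours, oracle, rtol=1e-10)

    def test_single_atom_peaks_at_its_bin(self, rng):
        geometry, trace, _, _, _, _ = make_tiny_setup(rng)
        # one encoding spike at a known position, huge mark bandwidth
        t_at = trace.t[300]
        spikes = MarkedSpikes(
            times={0: np.full(60, t_at) + np.linspace(0, 1, 60)},
            marks={0: np.full((60, 4), 200.0)},
        )
        model = fit_encoding_model(
            spikes, trace, geometry, exploration_end=trace.t[-1] + 1,
            mark_bandwidth=1e6, position_bandwidth=5.0,
        )
        like = spike_spatial_likelihood(np.full(4, 500.0), model, 0)
        target_bin = geometry.bin_of(trace.linear[310])
        assert like.argmax() == target_bin

    def test_symmetric_bimodal_for_equidistant_mark(self, rng):
        geometry, trace, _, _, _, _ = make_tiny_setup(rng)
        # two encoding spike groups at mirrored arm positions, marks equidistant
        lin = trace.linear
        i1 = np.argmin(np.abs(lin - (geometry.box_extent + 7.5)))     # arm1 bin
        i2 = np.argmin(np.abs(lin - (geometry.box_extent + 25 + 7.5)))  # arm2 bin
        m1, m2 = np.full(4, 150.0), np.full(4, 250.0)
        assert trace.t[i1] + 0.6 < trace.t[i2]  # groups are time-ordered
        spikes = MarkedSpikes(
            times={0: np.concatenate([
                trace.t[i1] + np.linspace(0, 0.5, 50),
                trace.t[i2] + np.linspace(0, 0.5, 50),
            ])},
            marks={0: np.vstack([np.tile(m1, (50, 1)), np.tile(m2, (50, 1))])},
        )
        model = fit_encoding_model(
            spikes, trace, geometry, exploration_end=trace.t[-1] + 1,
            mark_bandwidth=40.0, position_bandwidth=5.0,
        )
        like = spike_spatial_likelihood((m1 + m2) / 2, model, 0)
        b1 = geometry.bin_of(lin[i1])
        b2 = geometry.bin_of(lin[i2])
        assert like[b1] == pytest.approx(like[b2], rel=0.2)
        assert like[b1] + like[b2] > 0.5


class TestOccupancy:
    def test_matches_independent_histogram(self, rng):
        from scipy.ndimage import gaussian_filter1d

        geometry, trace, spikes, model, _, _ = make_tiny_setup(rng)
        frames = trace.head_speed > 4.0
        counts, _ = np.histogram(
            trace.linear[frames], bins=geometry.n_bins,
            range=(0, geometry.n_bins * geometry.bin_size),
        )
        smoothed = counts.astype(float).copy()
        for code in (0, 1, 2):
            m = geometry.segment_of_bin == code
            smoothed[m] = gaussian_filter1d(
                counts[m].astype(float), 10.0 / geometry.bin_size, mode="nearest"
            )
        np.testing.assert_allclose(model.occupancy, smoothed / smoothed.sum(),
                                   atol=1e-12)

    def test_unvisited_arm_has_zero_occupancy(self, rng):
        geometry = build_track(120, 50, 5)
        fs, n = 30.0, 1200
        t = np.arange(n) / fs
        lin = np.linspace(1, geometry.box_extent + 100, n)  # box + arm1 only
        seg = geometry.segment_of_bin[geometry.bin_of(lin)]
        trace = PositionTrace(
            t=t, xy=np.zeros((n, 2)), head_direction=np.zeros(n),
            linear=lin, segment=seg, head_speed=np.full(n, 10.0),
            offtrack=np.zeros(n, bool),
        )
        spikes = MarkedSpikes(
            times={0: t[rng.choice(n, 200, replace=False)]},
            marks={0: rng.uniform(120, 250, (200, 4))},
        )
        model = fit_encoding_model(spikes, trace, geometry, t[-1] + 1)
        assert model.occupancy[geometry.mask("arm2")].sum() == 0.0

    def test_sparse_tetrode_excluded(self, rng):
        geometry, trace, spikes, _, _, _ = make_tiny_setup(rng)
        spikes.times[1] = spikes.times[1][:3]
        spikes.marks[1] = spikes.marks[1][:3]
        with pytest.warns(UserWarning, match="excluded"):
            model = fit_encoding_model(spikes, trace, geometry, trace.t[-1] + 1)
        assert 1 not in model.tetrodes


class TestDecode:
    def test_window_matches_brute_force(self, rng):
        geometry, trace, spikes, model, bin_dists, enc = make_tiny_setup(rng)
        # craft a 6 ms window with spikes on both tetrodes
        t0 = trace.t[-1] + 10.0
        q0 = rng.uniform(120, 300, (2, 4))
        q1 = rng.uniform(120, 300, (1, 4))
        qspikes = MarkedSpikes(
            times={0: t0 + np.array([0.001, 0.004]), 1: t0 + np.array([0.002])},
            marks={0: q0, 1: q1},
        )
        decoded = decode_session(qspikes, model, geometry, t0, t0 + 0.006)
        oracle = brute_force_decode_bin(
            {0: q0, 1: q1}, enc, bin_dists, model.occupancy,
            40.0, 10.0, OCCUPANCY_FLOOR,
        )
        np.testing.assert_allclose(decoded.posterior[0], oracle, rtol=1e-10)

    def test_single_spike_bin_equals_likelihood(self, rng):
        geometry, trace, spikes, model, _, _ = make_tiny_setup(rng)
        t0 = trace.t[-1] + 10.0
        mark = rng.uniform(120, 300, 4)
        qspikes = MarkedSpikes(
            times={0: np.array([t0 + 0.003]), 1: np.array([])},
            marks={0: mark[None, :], 1: np.empty((0, 4))},
        )
        decoded = decode_session(qspikes, model, geometry, t0, t0 + 0.006)
        like = spike_spatial_likelihood(mark, model, 0)
        np.testing.assert_allclose(decoded.posterior[0], like, rtol=1e-9)

    def test_two_identical_spikes_sharpen(self, rng):
        geometry, trace, spikes, model, _, _ = make_tiny_setup(rng)
        t0 = trace.t[-1] + 10.0
        mark = rng.uniform(120, 300, 4)
        qspikes = MarkedSpikes(
            times={0: np.array([t0 + 0.001, t0 + 0.004]), 1: np.array([])},
            marks={0: np.vstack([mark, mark]), 1: np.empty((0, 4))},
        )
        decoded = decode_session(qspikes, model, geometry, t0, t0 + 0.006)
        like = spike_spatial_likelihood(mark, model, 0)
        sq = like**2
        np.testing.assert_allclose(decoded.posterior[0], sq / sq.sum(), rtol=1e-9)
        assert decoded.posterior[0].max() >= like.max()

    def test_zero_spike_bins_uniform_flagged(self, rng):
        geometry, trace, spikes, model, _, _ = make_tiny_setup(rng)
        t0 = trace.t[-1] + 10.0
        qspikes = MarkedSpikes(times={0: np.array([]), 1: np.array([])},
                               marks={0: np.empty((0, 4)), 1: np.empty((0, 4))})
        decoded = decode_session(qspikes, model, geometry, t0, t0 + 0.03)
        assert not decoded.informative.any()
        np.testing.assert_allclose(decoded.posterior, 1.0 / geometry.n_bins)

    def test_informative_posteriors_normalized(self, small_decode):
        _, decoded_expl, decoded_fb, _ = small_decode
        for d in (decoded_expl, decoded_fb):
            sums = d.posterior[d.informative].sum(axis=1)
            np.testing.assert_allclose(sums, 1.0, atol=1e-9)


class TestRunningAverage:
    def _mk(self, posterior, informative):
        from remoterep.decoding import DecodedPosterior

        n_t = len(posterior)
        return DecodedPosterior(
            t0=0.0, bin_s=0.006, posterior=np.asarray(posterior, float),
            informative=np.asarray(informative, bool),
            n_spikes=np.asarray(informative, int),
            tetrode_specific=np.zeros((n_t, 2), bool), tetrode_ids=[0, 1],
        )

    def test_identical_posteriors_average_to_same(self):
        row = np.array([0.1, 0.2, 0.3, 0.4])
        d = self._mk(np.tile(row, (5, 1)), [True] * 5)
        avg = running_average_posterior(d)
        np.testing.assert_allclose(avg.posterior[-1], row)
        assert avg.eligible[-1]

    def test_uninformative_window_ineligible(self):
        d = self._mk(np.full((6, 4), 0.25), [False] * 6)
        avg = running_average_posterior(d)
        assert not avg.eligible.any()

    def test_matches_independent_sliding_mean(self, rng):
        post = rng.dirichlet(np.ones(8), size=40)
        inf = rng.random(40) > 0.3
        d = self._mk(post, inf)
        avg = running_average_posterior(d)
        for t in range(40):
            lo = max(0, t - 4)
            members = [k for k in range(lo, t + 1) if inf[k]]
            if len(members) >= 2:
                assert avg.eligible[t]
                np.testing.assert_allclose(
                    avg.posterior[t], post[members].mean(axis=0), atol=1e-12
                )
            else:
                assert not avg.eligible[t]


class TestQualityAndError:
    def _decoded_at_truth(self, small_session, forced_bin=None):
        from remoterep.decoding import DecodedPosterior

        s = small_session
        g = s.geometry
        n_t = int(s.exploration_end / 0.006)
        mid = (np.arange(n_t) + 0.5) * 0.006
        fi = s.trace.at_times(mid)
        bins = g.bin_of(s.trace.linear[fi]) if forced_bin is None else np.full(
            n_t, forced_bin
        )
        post = np.zeros((n_t, g.n_bins))
        post[np.arange(n_t), bins] = 1.0
        return DecodedPosterior(
            t0=0.0, bin_s=0.006, posterior=post,
            informative=np.ones(n_t, bool), n_spikes=np.ones(n_t, int),
            tetrode_specific=np.ones((n_t, 1), bool), tetrode_ids=[0],
        )

    def test_perfect_decode_quality_one(self, small_session):
        d = self._decoded_at_truth(small_session)
        frac, included = decoding_quality(
            d, small_session.trace, small_session.geometry, "arm1",
            small_session.exploration_end,
        )
        assert frac == 1.0 and included

    def test_box_forced_decode_quality_zero(self, small_session):
        d = self._decoded_at_truth(small_session, forced_bin=0)
        frac, included = decoding_quality(
            d, small_session.trace, small_session.geometry, "arm1",
            small_session.exploration_end,
        )
        assert frac == 0.0 and not included

    def test_movement_error_small_on_synthetic(self, small_session, small_decode):
        _, decoded_expl, _, _ = small_decode
        err = decoding_error(decoded_expl, small_session.trace, small_session.geometry)
        assert np.median(err) < 10.0

    def test_shuffled_encoding_degrades_error(self, small_session, small_decode, rng):
        import dataclasses as dc

        s = small_session
        model, decoded_expl, _, _ = small_decode
        err0 = np.median(
            decoding_error(decoded_expl, s.trace, s.geometry)
        )
        shuffled = dc.replace(model, tetrodes={
            tet: dc.replace(
                enc,
                spatial_profile=enc.spatial_profile[
                    rng.permutation(len(enc.positions))
                ],
            )
            for tet, enc in model.tetrodes.items()
        })
        # decode a one-minute movement window under the shuffled pairing
        t0 = 60.0
        d_shuf = decode_session(s.spikes, shuffled, s.geometry, t0, t0 + 60.0)
        err1 = np.median(decoding_error(d_shuf, s.trace, s.geometry))
        assert err1 >= 3.0 * err0
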