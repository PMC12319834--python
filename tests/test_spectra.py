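"""Multitaper spectra, NMF band decomposition, power maps and projections."""

import numpy as np
import pytest

import brainstates as bs
from brainstates.hmm import StateTimeCourse
from brainstates.preprocess import ParcelRecording
from brainstates.spectra import (
    StateSpectra,
    band_power_map,
    group_state_spectra,
    nmf,
    nmf_bands,
    project_networks,
    state_multitaper,
    top_parcels,
)


def always_on(T, K=1, state=0):
    post = np.zeros((T, K))
    post[:, state] = 1.0
    return StateTimeCourse(post, np.full(T, state))


class TestStateMultitaper:
    def test_tone_peak_location(self):
        rec = ParcelRecording(
            "t",
            np.sin(2 * np.pi * 10.0 * np.arange(30 * 250) / 250.0)[None, :],
            250.0,
        )
        ss = state_multitaper(rec, always_on(rec.n_times))
        peak = ss.frequencies[np.argmax(ss.psd[0, 0, 0])]
        assert abs(peak - 10.0) <= 0.5

    def test_white_noise_flat_within_factor_two(self, rng):
        rec = ParcelRecording("w", rng.normal(size=(1, int(120 * 250))), 250.0)
        ss = state_multitaper(rec, always_on(rec.n_times))
        p = ss.psd[0, 0, 0]
        assert p.max() / p.min() <= 2.0

    def test_parseval_total_power_matches_variance(self, rng):
        rec = ParcelRecording("w", rng.normal(size=(2, int(60 * 250))), 250.0)
        ss = state_multitaper(rec, always_on(rec.n_times), fmin=1e-6, fmax=125.0)
        for p in range(2):
            total = np.trapezoid(ss.psd[0, 0, p], ss.frequencies)
            assert abs(total - rec.data[p].var()) / rec.data[p].var() < 0.10

    def test_two_states_gate_two_tones(self, rng):
        fs, T = 250.0, int(120 * 250)
        half = T // 2
        x = np.empty(T)
        t = np.arange(T) / fs
        x[:half] = np.sin(2 * np.pi * 8.0 * t[:half])
        x[half:] = np.sin(2 * np.pi * 25.0 * t[half:])
        x += 0.1 * rng.normal(size=T)
        rec = ParcelRecording("g", x[None, :], fs)
        post = np.zeros((T, 2))
        post[:half, 0] = 1.0
        post[half:, 1] = 1.0
        stc = StateTimeCourse(post, (np.arange(T) >= half).astype(int))
        ss = state_multitaper(rec, stc)
        peak0 = ss.frequencies[np.argmax(ss.psd[0, 0, 0])]
        peak1 = ss.frequencies[np.argmax(ss.psd[0, 1, 0])]
        assert abs(peak0 - 8.0) <= 0.5
        assert abs(peak1 - 25.0) <= 0.5

    def test_negligible_state_weight_gives_nan(self, rng):
        rec = ParcelRecording("n", rng.normal(size=(1, 2500)), 250.0)
        post = np.zeros((2500, 2))
        post[:, 0] = 1.0  # state 1 never active
        ss = state_multitaper(rec, StateTimeCourse(post, np.zeros(2500, dtype=int)))
        assert np.all(np.isnan(ss.psd[0, 1]))
        assert np.all(np.isfinite(ss.psd[0, 0]))

    def test_invalid_band_rejected(self, rng):
        rec = ParcelRecording("n", rng.normal(size=(1, 2500)), 250.0)
        with pytest.raises(ValueError):
            state_multitaper(rec, always_on(2500), fmin=10.0, fmax=5.0)


class TestNmf:
    def _planted_band_psd(self, rng, n_rows=60, n_freq=89):
        freqs = np.linspace(1.0, 45.0, n_freq)
        supports = [(1, 4), (4, 8), (8, 13), (13, 30)]
        profiles = np.stack(
            [((freqs >= lo) & (freqs < hi)).astype(float) for lo, hi in supports]
        )
        # band-dominant rows keep the planted factorization identifiable
        weights = rng.uniform(0.0, 0.2, size=(n_rows, 4))
        weights[np.arange(n_rows), rng.integers(0, 4, size=n_rows)] += rng.uniform(
            1.0, 2.0, size=n_rows
        )
        V = weights @ profiles
        return freqs, profiles, V

    def test_recovers_planted_rectangular_bands(self, rng):
        freqs, true_profiles, V = self._planted_band_psd(rng)
        W, H, err = nmf(V, 4, n_iter=800, seed=0)
        # Jaccard of supports after greedy matching
        got_supports = H > 0.25 * H.max(axis=1, keepdims=True)
        true_supports = true_profiles > 0
        used = set()
        for i in range(4):
            best_j, best = None, -1.0
            for j in range(4):
                if j in used:
                    continue
                inter = (true_supports[i] & got_supports[j]).sum()
                union = (true_supports[i] | got_supports[j]).sum()
                if inter / union > best:
                    best, best_j = inter / union, j
            used.add(best_j)
            assert best >= 0.9

    def test_reconstruction_error_non_increasing(self, rng):
        V = rng.uniform(size=(30, 50))
        _, _, err = nmf(V, 4, n_iter=200, seed=1)
        assert np.all(np.diff(err) <= 1e-10)

    def test_factors_non_negative(self, rng):
        V = rng.uniform(size=(20, 40))
        W, H, _ = nmf(V, 3, n_iter=100, seed=2)
        assert np.all(W >= 0) and np.all(H >= 0)

    def test_rank_one_recovers_mean_shape(self, rng):
        shape = np.abs(np.sin(np.linspace(0, 3, 64))) + 0.1
        V = rng.uniform(0.5, 2.0, size=(40, 1)) @ shape[None, :]
        _, H, _ = nmf(V, 1, n_iter=500, seed=3)
        cos = H[0] @ shape / (np.linalg.norm(H[0]) * np.linalg.norm(shape))
        assert cos >= 0.99

    def test_matches_sklearn_reconstruction_quality(self, rng):
        # independent cross-check: our MU solver reaches the same loss scale
        from sklearn.decomposition import NMF as SkNMF

        V = rng.uniform(size=(40, 60))
        _, _, err = nmf(V, 4, n_iter=500, seed=4)
        sk = SkNMF(n_components=4, solver="mu", init="random", random_state=0, max_iter=500, tol=0.0)
        sk_err = np.linalg.norm(V - sk.fit_transform(V) @ sk.components_)
        assert err[-1] <= 1.1 * sk_err

    def test_all_zero_input_rejected(self):
        with pytest.raises(ValueError):
            nmf(np.zeros((5, 5)), 2)

    def test_nmf_bands_slices_state(self, rng):
        freqs, _, V = self._planted_band_psd(rng, n_rows=12)
        psd = np.tile(V.reshape(12, 1, -1), (1, 2, 1)).reshape(12, 2, 1, V.shape[1])
        ss = StateSpectra(psd, freqs)
        dec = nmf_bands(ss, state=0, n_bands=4, seed=0)
        assert dec.band_profiles.shape == (4, freqs.size)
        assert np.all(np.diff(dec.reconstruction_errors) <= 1e-10)


class TestPowerMaps:
    def test_rectangular_band_integral_of_flat_psd(self):
        freqs = np.linspace(1.0, 45.0, 441)  # 0.1 Hz grid
        psd = np.ones((3, 2, 5, freqs.size))
        profile = ((freqs >= 10.0) & (freqs <= 20.0)).astype(float)
        power = band_power_map(StateSpectra(psd, freqs), profile)
        assert np.allclose(power, 10.0, atol=0.11)  # rectangle width 10 Hz

    def test_departure_mode_identical_states_zero(self, rng):
        freqs = np.linspace(1.0, 45.0, 89)
        one = rng.uniform(size=(1, 1, 4, freqs.size))
        psd = np.tile(one, (2, 3, 1, 1))
        power = band_power_map(StateSpectra(psd, freqs), np.ones(freqs.size), departure=True)
        assert np.allclose(power, 0.0, atol=1e-12)

    def test_planted_oscillator_parcels_ranked_first(self, rng):
        freqs = np.linspace(1.0, 45.0, 89)
        psd = np.full((2, 2, 6, freqs.size), 1.0)
        bump = (freqs >= 8) & (freqs <= 12)
        psd[:, 0, 2, bump] += 5.0  # state 0, parcel 2 carries alpha power
        power = band_power_map(StateSpectra(psd, freqs), bump.astype(float), departure=True)
        assert top_parcels(power, state=0, n=1)[0] == 2

    def test_grid_mismatch_rejected(self, rng):
        freqs = np.linspace(1.0, 45.0, 89)
        psd = np.ones((1, 1, 2, freqs.size))
        with pytest.raises(ValueError):
            band_power_map(StateSpectra(psd, freqs), np.ones(10))


class TestNetworkProjection:
    def test_identity_weights(self, rng):
        pm = rng.normal(size=(3, 4))
        assert np.allclose(project_networks(pm, np.eye(4)), pm)

    def test_single_network_aggregates_rows(self, rng):
        pm = rng.normal(size=(3, 4))
        w = np.ones((4, 1))
        with pytest.raises(ValueError):
            project_networks(pm, w * 2.0)  # rows must sum to <= 1
        got = project_networks(pm, w)
        assert np.allclose(got[:, 0], pm.sum(axis=1))

    def test_block_weights_manual_product(self):
        pm = np.array([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]])
        w = np.array([[1.0, 0.0], [0.5, 0.5], [0.0, 1.0]])
        got = project_networks(pm, w)
        assert np.allclose(got, [[2.0, 4.0], [6.5, 8.5]])


class TestTopParcels:
    def test_full_request_returns_all(self, rng):
        pm = rng.normal(size=(2, 7))
        assert sorted(top_parcels(pm, 0, 7).tolist()) == list(range(7))

    def test_scale_invariance(self, rng):
        pm = rng.normal(size=(2, 9))
        a = top_parcels(pm, 1, 4)
        b = top_parcels(pm * 17.3, 1, 4)
        assert np.array_equal(a, b)

    def test_ties_break_by_index(self):
        pm = np.array([[1.0, 1.0, 2.0, 1.0]])
        assert top_parcels(pm, 0, 3).tolist() == [2, 0, 1]


def test_pipeline_band_assignment_matches_planted_oscillators(rng):
    # end-to-end: states gating distinct bands get assigned distinct NMF bands
    fs = 250.0
    cfg = bs.SimulationConfig(
        n_parcels=4, n_states=2, duration=120.0, sampling_rate=fs,
        transition_matrix=np.array([[0.99, 0.01], [0.01, 0.99]]),
        state_oscillators=[
            [(np.array([0, 1]), 6.0, 2.0)],
            [(np.array([2, 3]), 30.0, 2.0)],
        ],
        seed=21,
    )
    path = bs.simulate_state_chain(cfg)
    rec = bs.simulate_recording(path, cfg)
    post = np.zeros((path.size, 2))
    post[np.arange(path.size), path] = 1.0
    stc = StateTimeCourse(post, path)
    ss = group_state_spectra([rec], [stc])
    from brainstates.spectra import assign_bands

    decs = [nmf_bands(ss, k, seed=0) for k in range(2)]
    assign_bands(ss, decs)
    # each state's band of interest peaks at its planted frequency
    for k, f0 in ((0, 6.0), (1, 30.0)):
        prof = decs[k].band_profiles[decs[k].band_assignment[0]]
        assert abs(ss.frequencies[np.argmax(prof)] - f0) <= 2.0
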