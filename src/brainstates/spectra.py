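"""State-wise multitaper spectra, data-driven band decomposition, power maps.

Spectral content is estimated on the *unprepared* parcel signals: the HMM is
trained in the embedded/PCA space, but its posteriors are brought back and
used as soft weights on windowed multitaper periodograms of the raw parcel
data. Per state, windows are averaged with weights equal to that state's mean
posterior in the window, so short visits still contribute.

The frequency axis is then factorized with non-negative matrix factorization
(multiplicative updates, Frobenius loss) into a small number of band profiles
(4 by default), each state is assigned its band of interest, and band power
maps — optionally expressed as departure from the across-state mean, i.e.
from static activity — are integrated, projected onto networks, and ranked
to select each state's most active parcels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import windows

from .hmm import StateTimeCourse
from .preprocess import ParcelRecording

__all__ = [
    "StateSpectra",
    "BandDecomposition",
    "state_multitaper",
    "group_state_spectra",
    "nmf",
    "nmf_bands",
    "band_power_map",
    "project_networks",
    "top_parcels",
]


@dataclass
class StateSpectra:
    """Subject x state x parcel x frequency PSD stack (power density units)."""

    psd: np.ndarray
    frequencies: np.ndarray

    def __post_init__(self) -> None:
        self.psd = np.asarray(self.psd, dtype=float)
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if np.any(np.diff(self.frequencies) <= 0):
            raise ValueError("frequency grid must be strictly increasing")
        if np.nanmin(self.psd) < -1e-12:
            raise ValueError("PSD must be non-negative")


@dataclass
class BandDecomposition:
    """NMF band profiles over frequency plus each state's band of interest."""

    band_profiles: np.ndarray  # (n_bands, n_freqs), non-negative
    band_assignment: np.ndarray | None = None  # per state, index of its band
    reconstruction_errors: np.ndarray | None = None  # per-iteration Frobenius loss


def state_multitaper(
    rec: ParcelRecording,
    stc: StateTimeCourse,
    window: float = 2.0,
    n_tapers: int = 4,
    fmin: float = 1.0,
    fmax: float = 45.0,
    time_bandwidth: float = 2.5,
    min_weight: float = 1.0,
) -> StateSpectra:
    """State-weighted multitaper PSD of one subject.

    The recording is cut into non-overlapping windows of ``window`` seconds;
    each window's PSD is the average of ``n_tapers`` DPSS-tapered
    periodograms (one-sided density, so the full-band integral matches the
    signal variance). Per state the window PSDs are averaged with weights
    equal to the state's mean posterior inside the window, normalized by the
    total weight. States whose total weight falls below ``min_weight``
    (in units of windows) get NaN spectra rather than zeros.

    Returns a :class:`StateSpectra` with a leading singleton subject axis.
    """
    fs = rec.sampling_rate
    nwin = int(round(window * fs))
    if nwin > rec.n_times:
        raise ValueError("window longer than the recording")
    if not (0.0 < fmin < fmax <= fs / 2.0):
        raise ValueError("need 0 < fmin < fmax <= Nyquist")
    T = min(rec.n_times, stc.posteriors.shape[0])
    n_blocks = T // nwin
    if n_blocks < 1:
        raise ValueError("no complete window fits the overlap of data and posteriors")
    K = stc.n_states
    P = rec.n_parcels

    tapers = windows.dpss(nwin, NW=time_bandwidth, Kmax=n_tapers)  # (n_tapers, nwin), unit energy
    freqs = np.fft.rfftfreq(nwin, d=1.0 / fs)
    sel = (freqs >= fmin) & (freqs <= fmax)

    x = rec.data[:, : n_blocks * nwin].reshape(P, n_blocks, nwin)
    # (P, n_blocks, n_tapers, nfreq)
    spec = np.fft.rfft(x[:, :, None, :] * tapers[None, None, :, :], axis=-1)
    psd_win = (np.abs(spec) ** 2).mean(axis=2) / fs
    # one-sided density: double everything except DC and Nyquist
    one_sided = np.full(freqs.size, 2.0)
    one_sided[0] = 1.0
    if nwin % 2 == 0:
        one_sided[-1] = 1.0
    psd_win *= one_sided

    gamma = stc.posteriors[: n_blocks * nwin].reshape(n_blocks, nwin, K).mean(axis=1)  # (B, K)
    weight_tot = gamma.sum(axis=0)  # per state
    psd = np.full((1, K, P, int(sel.sum())), np.nan)
    for k in range(K):
        if weight_tot[k] < min_weight:
            continue
        w = gamma[:, k] / weight_tot[k]
        psd[0, k] = np.tensordot(psd_win[:, :, sel], w, axes=([1], [0]))
    return StateSpectra(psd, freqs[sel])


def group_state_spectra(
    recordings: list[ParcelRecording],
    stcs: list[StateTimeCourse],
    **kwargs,
) -> StateSpectra:
    """Stack :func:`state_multitaper` over subjects (shared frequency grid)."""
    if len(recordings) != len(stcs):
        raise ValueError("need one state time course per recording")
    parts = [state_multitaper(r, s, **kwargs) for r, s in zip(recordings, stcs)]
    freqs = parts[0].frequencies
    for p in parts[1:]:
        if not np.allclose(p.frequencies, freqs):
            raise ValueError("subjects disagree on the frequency grid")
    return StateSpectra(np.concatenate([p.psd for p in parts], axis=0), freqs)


def nmf(
    V: np.ndarray,
    n_components: int,
    n_iter: int = 400,
    seed: int | None = 0,
    n_restarts: int = 5,
    eps: float = 1e-12,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Frobenius NMF ``V ~ W H`` by multiplicative updates with restarts.

    Multiplicative updates only find a local minimum, so the factorization is
    repeated from ``n_restarts`` random initializations and the solution with
    the lowest final reconstruction error is kept. Returns ``(W, H, errors)``
    with the kept run's per-iteration reconstruction error (non-increasing by
    the multiplicative-update guarantee).
    """
    V = np.asarray(V, dtype=float)
    if np.any(V < 0):
        raise ValueError("NMF input must be non-negative")
    if not np.any(V > 0):
        raise ValueError("NMF input is all zero")
    rng = np.random.default_rng(seed)
    n, m = V.shape
    scale = np.sqrt(V.mean() / n_components)
    best: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None
    for _ in range(max(1, n_restarts)):
        W = rng.uniform(0.1, 1.0, size=(n, n_components)) * scale
        H = rng.uniform(0.1, 1.0, size=(n_components, m)) * scale
        errors = np.empty(n_iter)
        for it in range(n_iter):
            H *= (W.T @ V) / (W.T @ W @ H + eps)
            W *= (V @ H.T) / (W @ (H @ H.T) + eps)
            errors[it] = np.linalg.norm(V - W @ H)
        if best is None or errors[-1] < best[2][-1]:
            best = (W, H, errors)
    return best


def nmf_bands(
    spectra: StateSpectra,
    state: int,
    n_bands: int = 4,
    seed: int | None = 0,
    n_iter: int = 400,
) -> BandDecomposition:
    """Factorize one state's (subjects x parcels) x frequencies PSD into bands."""
    slab = spectra.psd[:, state]  # (subjects, parcels, freqs)
    V = slab.reshape(-1, slab.shape[-1])
    V = V[np.all(np.isfinite(V), axis=1)]
    if V.size == 0:
        raise ValueError(f"state {state} has no defined spectra")
    W, H, errors = nmf(V, n_bands, n_iter=n_iter, seed=seed)
    return BandDecomposition(band_profiles=H, reconstruction_errors=errors)


def assign_bands(
    spectra: StateSpectra, decompositions: list[BandDecomposition]
) -> np.ndarray:
    """Band of interest per state, matched on the *dynamic* state spectrum.

    Each state's group-mean spectrum has the across-state (static) mean
    subtracted and is rectified, so only frequencies where the state carries
    power *above* static activity drive the match; the band profile with the
    largest non-negative-least-squares contribution (coefficient times
    profile mass) wins.
    """
    from scipy.optimize import nnls

    K = spectra.psd.shape[1]
    group = np.nanmean(spectra.psd, axis=(0, 2))  # (K, F) mean over subjects, parcels
    static = group.mean(axis=0)
    out = np.empty(K, dtype=int)
    for k in range(K):
        dynamic = np.clip(group[k] - static, 0.0, None)
        if not np.any(dynamic > 0):
            dynamic = group[k]
        H = decompositions[k].band_profiles
        coef, _ = nnls(H.T, dynamic)
        contrib = coef * H.sum(axis=1)
        out[k] = int(np.argmax(contrib))
        decompositions[k].band_assignment = np.array([out[k]])
    return out


def band_power_map(
    spectra: StateSpectra, band_profile: np.ndarray, departure: bool = False
) -> np.ndarray:
    """Integrate the group-mean PSD against a band profile -> states x parcels.

    Trapezoidal, profile-weighted integration over the frequency grid. With
    ``departure`` the across-state mean map is subtracted, expressing each
    state's band power as departure from static activity.
    """
    band_profile = np.asarray(band_profile, dtype=float)
    if band_profile.shape[0] != spectra.frequencies.size:
        raise ValueError("band profile length must match the frequency grid")
    group = np.nanmean(spectra.psd, axis=0)  # (K, P, F)
    power = np.trapezoid(group * band_profile, spectra.frequencies, axis=-1)
    if departure:
        power = power - power.mean(axis=0, keepdims=True)
    return power


def project_networks(power_map: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Project a states x parcels map onto networks via an overlap matrix.

    ``weights`` is parcels x networks, non-negative, rows summing to <= 1
    (fractional volumetric overlap). Signs of the (possibly mean-subtracted)
    power map pass through unchanged.
    """
    weights = np.asarray(weights, dtype=float)
    if power_map.shape[1] != weights.shape[0]:
        raise ValueError("power map parcel count must match weight rows")
    if np.any(weights < 0):
        raise ValueError("overlap weights must be non-negative")
    if np.any(weights.sum(axis=1) > 1 + 1e-9):
        raise ValueError("overlap weight rows must sum to at most 1")
    return power_map @ weights


def top_parcels(power_map: np.ndarray, state: int, n: int = 20) -> np.ndarray:
    """Top-``n`` parcels by absolute departure band power for one state.

    ``power_map`` should be in departure-from-static mode. Ties are broken
    toward the smaller parcel index.
    """
    row = np.abs(np.asarray(power_map, dtype=float)[state])
    if n > row.size:
        raise ValueError("n exceeds the parcel count")
    order = np.lexsort((np.arange(row.size), -row))
    return order[:n]
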