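"""Light signal conditioning for parcel-level time series.

The unit of data is a :class:`ParcelRecording`: one subject's ``parcels x time``
matrix with its sampling rate and an optional per-sample bad-segment mask.
Conditioning steps offered here are the ones that make sense once data are
already in source/parcel space: zero-phase band-pass and notch filtering,
anti-aliased downsampling, automated bad-segment detection with the
generalized extreme studentized deviate (G-ESD) test, cross-subject dipole
sign alignment, and per-parcel standardization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal, stats

__all__ = [
    "ParcelRecording",
    "bandpass",
    "notch",
    "downsample",
    "detect_bad_segments",
    "gesd_outliers",
    "align_signs",
    "standardize",
]


@dataclass
class ParcelRecording:
    """One subject's parcel time courses.

    Parameters
    ----------
    subject_id:
        Label for the subject.
    data:
        ``(n_parcels, n_times)`` array, signal units.
    sampling_rate:
        Sampling rate in Hz.
    bad_mask:
        Boolean per-time-point mask, ``True`` where the sample belongs to a
        bad segment. ``None`` means "no samples flagged".
    """

    subject_id: str
    data: np.ndarray
    sampling_rate: float
    bad_mask: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D (parcels x time) array")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains NaN or Inf")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.bad_mask is not None:
            self.bad_mask = np.asarray(self.bad_mask, dtype=bool)
            if self.bad_mask.shape != (self.n_times,):
                raise ValueError("bad_mask length must equal the time axis")

    @property
    def n_parcels(self) -> int:
        return self.data.shape[0]

    @property
    def n_times(self) -> int:
        return self.data.shape[1]

    @property
    def nyquist(self) -> float:
        return self.sampling_rate / 2.0

    def good_data(self) -> np.ndarray:
        """Data restricted to unmasked samples."""
        if self.bad_mask is None:
            return self.data
        return self.data[:, ~self.bad_mask]


def _with_data(rec: ParcelRecording, data: np.ndarray) -> ParcelRecording:
    return replace(rec, data=data)


def bandpass(rec: ParcelRecording, low: float, high: float, order: int = 5) -> ParcelRecording:
    """Zero-phase Butterworth band-pass filter.

    Applied forward-backward (``sosfiltfilt``) so the pass band is preserved
    without phase distortion; the effective attenuation is the square of the
    single-pass magnitude response.
    """
    if not (0.0 < low < high < rec.nyquist):
        raise ValueError(
            f"band edges must satisfy 0 < low < high < Nyquist ({rec.nyquist} Hz); "
            f"got [{low}, {high}]"
        )
    sos = signal.butter(order, [low, high], btype="bandpass", fs=rec.sampling_rate, output="sos")
    return _with_data(rec, signal.sosfiltfilt(sos, rec.data, axis=-1))


def notch(rec: ParcelRecording, freqs: list[float], width: float = 2.0) -> ParcelRecording:
    """Zero-phase IIR notch filters at the given frequencies.

    ``width`` is the -3 dB bandwidth of each notch in Hz. An empty frequency
    list is the identity.
    """
    out = rec.data
    for f0 in freqs:
        if f0 >= rec.nyquist:
            raise ValueError(f"notch frequency {f0} Hz is at or above Nyquist ({rec.nyquist} Hz)")
        b, a = signal.iirnotch(f0, Q=f0 / width, fs=rec.sampling_rate)
        out = signal.filtfilt(b, a, out, axis=-1)
    return _with_data(rec, out)


def downsample(rec: ParcelRecording, target_rate: float) -> ParcelRecording:
    """Anti-aliased polyphase resampling to ``target_rate``.

    The output has ``floor(T * target_rate / sampling_rate)`` samples.
    Passing the current rate is the identity.
    """
    if target_rate > rec.sampling_rate:
        raise ValueError("target_rate must not exceed the current sampling rate")
    if target_rate == rec.sampling_rate:
        return rec
    from fractions import Fraction

    frac = Fraction(target_rate / rec.sampling_rate).limit_denominator(1000)
    up, down = frac.numerator, frac.denominator
    out = signal.resample_poly(rec.data, up, down, axis=-1)
    n_out = int(np.floor(rec.n_times * target_rate / rec.sampling_rate))
    out = out[:, :n_out]
    return ParcelRecording(rec.subject_id, out, target_rate)


def gesd_outliers(x: np.ndarray, alpha: float = 0.05, max_outliers: int | None = None) -> np.ndarray:
    """Indices flagged by the generalized extreme studentized deviate test.

    Iteratively removes the observation with the largest studentized absolute
    deviation and compares each test statistic ``R_i`` against the t-based
    critical value ``lambda_i``; the number of outliers declared is the
    largest ``i`` with ``R_i > lambda_i``.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if max_outliers is None:
        max_outliers = max(1, n // 5)
    if max_outliers <= 0:
        return np.empty(0, dtype=int)

    remaining = np.arange(n)
    vals = x.copy()
    candidates: list[int] = []
    n_out = 0
    for i in range(1, max_outliers + 1):
        m = vals.size
        if m < 3:
            break
        sd = vals.std(ddof=1)
        if sd <= 1e-12 * max(1.0, float(np.abs(vals.mean()))):
            break  # degenerate spread: no deviation statistic to test
        dev = np.abs(vals - vals.mean())
        j = int(np.argmax(dev))
        r = dev[j] / sd
        p = 1.0 - alpha / (2.0 * (n - i + 1))
        t = stats.t.ppf(p, n - i - 1)
        lam = (n - i) * t / np.sqrt((n - i - 1 + t**2) * (n - i + 1))
        candidates.append(int(remaining[j]))
        if r > lam:
            n_out = i
        remaining = np.delete(remaining, j)
        vals = np.delete(vals, j)
    return np.array(sorted(candidates[:n_out]), dtype=int)


def detect_bad_segments(
    rec: ParcelRecording,
    window: float = 1.0,
    alpha: float = 0.05,
    max_outliers: int | None = None,
) -> np.ndarray:
    """Flag bad segments by G-ESD screening of per-window log-variance.

    The recording is split into non-overlapping windows of ``window`` seconds;
    the screening metric is the log of the variance pooled across parcels in
    each window (variance bursts being the dominant artifact signature, the
    log transform improves normality of the null). Windows flagged by the
    G-ESD procedure are marked ``True`` in the returned per-sample mask.
    """
    win_len = int(round(window * rec.sampling_rate))
    if win_len > rec.n_times:
        raise ValueError("window longer than the recording")
    n_win = rec.n_times // win_len
    if n_win < 10:
        raise ValueError(f"need at least 10 windows, got {n_win}")

    segs = rec.data[:, : n_win * win_len].reshape(rec.n_parcels, n_win, win_len)
    metric = np.log(segs.var(axis=(0, 2)) + np.finfo(float).tiny)
    bad_windows = gesd_outliers(metric, alpha=alpha, max_outliers=max_outliers)

    mask = np.zeros(rec.n_times, dtype=bool)
    for w in bad_windows:
        mask[w * win_len : (w + 1) * win_len] = True
    return mask


def _lagged_cov(data: np.ndarray, lags: np.ndarray) -> np.ndarray:
    """Lagged cross-covariance stack ``(n_lags, P, P)`` of a parcels x time array."""
    x = data - data.mean(axis=1, keepdims=True)
    T = x.shape[1]
    out = np.empty((lags.size, x.shape[0], x.shape[0]))
    for i, l in enumerate(lags):
        if l >= 0:
            a, b = x[:, : T - l], x[:, l:]
        else:
            a, b = x[:, -l:], x[:, : T + l]
        out[i] = a @ b.T / a.shape[1]
    return out


def align_signs(
    recordings: list[ParcelRecording],
    lags: np.ndarray | None = None,
    n_restarts: int = 3,
    max_iter: int = 50,
    seed: int | None = 0,
) -> np.ndarray:
    """Resolve per-subject dipole sign ambiguity by greedy template matching.

    Source-reconstructed parcel signals have an arbitrary sign per parcel and
    subject. Each subject is summarized by its stack of lagged cross-covariance
    matrices; flipping parcel ``p`` of subject ``s`` flips row/column ``p`` of
    every matrix in that subject's stack. Signs are chosen greedily to maximize
    the inner product of each subject's signed stack with the group-mean
    template, iterated to a fixed point, with random restarts. The gauge is
    fixed by making the across-subject majority sign of every parcel positive.

    Returns an ``(n_subjects, n_parcels)`` array of +/-1 signs. A single
    subject returns identity signs with a warning.
    """
    if len(recordings) == 0:
        raise ValueError("no recordings given")
    n_parcels = recordings[0].n_parcels
    if any(r.n_parcels != n_parcels for r in recordings):
        raise ValueError("all recordings must share the parcel count")
    if len(recordings) == 1:
        warnings.warn("single subject: sign alignment is the identity", stacklevel=2)
        return np.ones((1, n_parcels))
    if lags is None:
        lags = np.arange(-3, 4)
    lags = np.asarray(lags, dtype=int)

    covs = np.stack([_lagged_cov(r.data, lags) for r in recordings])  # (S, L, P, P)
    n_subj = covs.shape[0]
    rng = np.random.default_rng(seed)

    def signed(c: np.ndarray, f: np.ndarray) -> np.ndarray:
        return c * f[None, :, None] * f[None, None, :]

    def objective(flips: np.ndarray) -> float:
        stacks = np.stack([signed(covs[s], flips[s]) for s in range(n_subj)])
        template = stacks.mean(axis=0)
        return float(np.sum(stacks * template))

    best_flips, best_obj = None, -np.inf
    for r in range(n_restarts):
        if r == 0:
            flips = np.ones((n_subj, n_parcels))
        else:
            flips = rng.choice([-1.0, 1.0], size=(n_subj, n_parcels))
        for _ in range(max_iter):
            changed = False
            stacks = np.stack([signed(covs[s], flips[s]) for s in range(n_subj)])
            template = stacks.mean(axis=0)
            for s in range(n_subj):
                # template without subject s, to avoid self-matching bias
                tmpl_s = (template * n_subj - stacks[s]) / (n_subj - 1)
                for p in range(n_parcels):
                    trial = flips[s].copy()
                    trial[p] *= -1
                    gain = np.sum(signed(covs[s], trial) * tmpl_s) - np.sum(stacks[s] * tmpl_s)
                    if gain > 1e-12:
                        flips[s] = trial
                        stacks[s] = signed(covs[s], flips[s])
                        changed = True
            if not changed:
                break
        obj = objective(flips)
        if obj > best_obj:
            best_obj, best_flips = obj, flips.copy()

    # gauge fixing: the objective is invariant to a global flip of any subject
    # (C -> ff^T C with f = -1 everywhere) and to a global flip of any parcel
    # across all subjects; canonicalize with majority-positive rows, then columns
    row = best_flips.sum(axis=1)
    best_flips[row < 0] *= -1
    col = best_flips.sum(axis=0)
    best_flips[:, col < 0] *= -1
    return best_flips


def standardize(rec: ParcelRecording) -> ParcelRecording:
    """Scale each parcel to zero mean, unit variance over unmasked samples."""
    good = rec.good_data()
    mu = good.mean(axis=1, keepdims=True)
    sd = good.std(axis=1, keepdims=True)
    flat = np.flatnonzero(sd.ravel() == 0)
    if flat.size:
        raise ValueError(f"constant parcel(s) cannot be standardized: indices {flat.tolist()}")
    return _with_data(rec, (rec.data - mu) / sd)
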