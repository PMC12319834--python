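"""Synthetic Markov-switching recordings and cohorts with planted structure.

Two generators live here:

* a multichannel signal simulator — a hidden Markov chain switches which
  parcel subsets carry band-limited oscillations on top of Gaussian (optionally
  1/f-shaped) background noise, the generative structure a time-delay embedded
  HMM is designed to recover; dwell times are geometric, arising solely from
  the chain's self-transition probabilities;

* a cohort simulator — per-subject cognitive scores load, through planted
  unit-norm saliences, on latent components whose age trajectories are built
  from the two piecewise quadratic age polynomials (ascending-then-plateau and
  plateau-then-descending, knotted at 55 years by default). The planted latents
  are also injected into the brain-feature block so brain--behavior covariance
  exists for recovery tests, and all ground truth is returned alongside.

Every operation is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import ParcelRecording

__all__ = [
    "SimulationConfig",
    "CohortConfig",
    "stationary_distribution",
    "simulate_state_chain",
    "simulate_recording",
    "simulate_cohort",
    "default_oscillators",
]

COGNITIVE_SCORES = [
    "naming",
    "verbal_fluency",
    "tip_of_the_tongue",
    "proverb",
    "sentence_comprehension",
    "story_recall",
    "fluid_reasoning",
    "multitasking",
]


def default_oscillators(
    n_states: int, n_parcels: int, amplitude: float = 1.0
) -> list[list[tuple[np.ndarray, float, float]]]:
    """One oscillator per state: a disjoint parcel block at a state-specific
    frequency spread across 2-35 Hz (within the 1-45 Hz band of interest)."""
    freqs = np.linspace(2.0, 35.0, n_states)
    block = max(1, n_parcels // n_states)
    out = []
    for k in range(n_states):
        parcels = np.arange(k * block, min((k + 1) * block, n_parcels))
        if parcels.size == 0:
            parcels = np.array([k % n_parcels])
        out.append([(parcels, float(freqs[k]), amplitude)])
    return out


@dataclass
class SimulationConfig:
    """Generative settings for a Markov-switching multichannel recording.

    ``state_oscillators[k]`` is a list of ``(parcel_indices, freq_hz, amplitude)``
    tuples active while state ``k`` is on. ``one_over_f`` > 0 shapes the
    background noise spectrum as ``f**(-one_over_f)`` in power (0 = white).
    """

    n_subjects: int = 1
    n_parcels: int = 52
    n_states: int = 8
    sampling_rate: float = 250.0
    duration: float = 60.0
    transition_matrix: np.ndarray | None = None
    state_oscillators: list[list[tuple[np.ndarray, float, float]]] | None = None
    noise_sd: float = 1.0
    one_over_f: float = 0.0
    initial_state: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.transition_matrix is None:
            # sticky chain, ~100 ms mean dwell at 250 Hz
            stay = 0.96
            A = np.full((self.n_states, self.n_states), (1 - stay) / max(1, self.n_states - 1))
            np.fill_diagonal(A, stay if self.n_states > 1 else 1.0)
            self.transition_matrix = A
        self.transition_matrix = np.asarray(self.transition_matrix, dtype=float)
        if self.state_oscillators is None:
            self.state_oscillators = default_oscillators(self.n_states, self.n_parcels)
        self.validate()

    def validate(self) -> None:
        A = self.transition_matrix
        if A.shape != (self.n_states, self.n_states):
            raise ValueError("transition_matrix must be n_states x n_states")
        if np.any(A < 0):
            raise ValueError("transition probabilities must be non-negative")
        rowsum = A.sum(axis=1)
        bad = np.flatnonzero(np.abs(rowsum - 1.0) > 1e-12)
        if bad.size:
            raise ValueError(
                f"transition_matrix row(s) {bad.tolist()} do not sum to 1 "
                f"(sums {rowsum[bad].tolist()})"
            )
        nyq = self.sampling_rate / 2.0
        for k, oscs in enumerate(self.state_oscillators):
            for parcels, f0, _amp in oscs:
                if not (0.0 < f0 < nyq):
                    raise ValueError(
                        f"state {k} oscillator frequency {f0} Hz outside (0, Nyquist={nyq})"
                    )
                if np.max(parcels) >= self.n_parcels:
                    raise ValueError(f"state {k} oscillator parcel index out of range")
        n_samp = self.duration * self.sampling_rate
        if abs(n_samp - round(n_samp)) > 1e-9:
            raise ValueError("duration x sampling_rate must be an integer sample count")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.sampling_rate))


def stationary_distribution(A: np.ndarray) -> np.ndarray:
    """Stationary distribution of a row-stochastic matrix (left unit eigenvector)."""
    w, v = np.linalg.eig(A.T)
    i = int(np.argmin(np.abs(w - 1.0)))
    pi = np.real(v[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()


def simulate_state_chain(config: SimulationConfig, seed: int | None = None) -> np.ndarray:
    """Sample a hidden-state path of length ``duration * sampling_rate``.

    The initial state is ``config.initial_state`` if set, otherwise drawn from
    the stationary distribution of the transition matrix.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    A = config.transition_matrix
    T = config.n_samples
    cum = np.cumsum(A, axis=1)
    path = np.empty(T, dtype=np.int64)
    if config.initial_state is not None:
        path[0] = config.initial_state
    else:
        path[0] = rng.choice(config.n_states, p=stationary_distribution(A))
    u = rng.random(T)
    for t in range(1, T):
        path[t] = np.searchsorted(cum[path[t - 1]], u[t], side="right")
    return path


def _runs(path: np.ndarray) -> list[tuple[int, int, int]]:
    """Contiguous runs as (state, start, stop) with stop exclusive."""
    change = np.flatnonzero(np.diff(path)) + 1
    starts = np.concatenate([[0], change])
    stops = np.concatenate([change, [path.size]])
    return [(int(path[a]), int(a), int(b)) for a, b in zip(starts, stops)]


def _shaped_noise(rng: np.random.Generator, shape: tuple[int, int], sd: float, alpha: float) -> np.ndarray:
    """White Gaussian noise, optionally spectrally shaped as f**(-alpha) in power."""
    x = rng.normal(0.0, sd, size=shape)
    if alpha <= 0 or sd == 0:
        return x
    spec = np.fft.rfft(x, axis=-1)
    f = np.fft.rfftfreq(shape[-1])
    gain = np.ones_like(f)
    gain[1:] = f[1:] ** (-alpha / 2.0)
    shaped = np.fft.irfft(spec * gain, n=shape[-1], axis=-1)
    # restore the requested marginal variance
    shaped *= sd / shaped.std(axis=-1, keepdims=True)
    return shaped


def simulate_recording(
    path: np.ndarray,
    config: SimulationConfig,
    subject_id: str = "sim",
    seed: int | None = None,
) -> ParcelRecording:
    """Render a state path into a multichannel recording.

    While state ``k`` is active, each of its oscillators adds a sinusoid at its
    center frequency to its parcel subset, with phase re-randomized at every
    state visit (burst-like oscillations, no spurious long-range coherence).
    All parcels carry Gaussian background noise throughout.
    """
    config.validate()
    path = np.asarray(path)
    if path.size != config.n_samples:
        raise ValueError(
            f"path length {path.size} does not match duration x sampling_rate = {config.n_samples}"
        )
    rng = np.random.default_rng(config.seed if seed is None else seed)
    fs = config.sampling_rate
    data = _shaped_noise(rng, (config.n_parcels, path.size), config.noise_sd, config.one_over_f)

    for state, start, stop in _runs(path):
        for parcels, f0, amp in config.state_oscillators[state]:
            if amp == 0:
                continue
            phase = rng.uniform(0.0, 2.0 * np.pi)
            t = np.arange(start, stop) / fs
            data[np.asarray(parcels)[:, None], np.arange(start, stop)[None, :]] += amp * np.sin(
                2.0 * np.pi * f0 * t + phase
            )
    return ParcelRecording(subject_id, data, fs)


def _raw_age_basis(ages: np.ndarray, knot: float) -> np.ndarray:
    """Unscaled piecewise quadratic basis: ascending (plateaus after the knot)
    and descending (flat before, accelerates after) columns."""
    x = np.asarray(ages, dtype=float) - knot
    asc = -np.minimum(x, 0.0) ** 2
    desc = -np.maximum(x, 0.0) ** 2
    return np.column_stack([asc, desc])


@dataclass
class CohortConfig:
    """Planted structure for a synthetic cohort.

    ``salience_brain`` (``n_components x n_brain_features``) and
    ``salience_cog`` (``n_components x 8``) are normalized to unit rows; the
    default cognitive saliences are random *orthonormal* rows — planted
    components are only identifiable by an SVD when their loading vectors are
    orthogonal, so user-supplied saliences should be near-orthogonal too.
    ``trajectories`` gives per-component coefficients on the (ascending,
    descending) piecewise age polynomials: ``(1, -1)`` is a monotone
    (linear-like) lifespan trend, ``(1, 1)`` an inverted U peaking at the knot.
    ``component_scale`` sets the relative strength of each component (distinct
    values keep the singular values separated — equal strengths leave the
    planted subspace rotationally degenerate); ``effect_size`` scales the
    latent injected into the brain block, in units of brain-feature SD. The
    defaults (2.0 with scales 1.0/0.6, score noise SD 0.5) make recovery at
    n around 200 reliable but far from noiseless.
    """

    n_subjects: int = 200
    age_range: tuple[float, float] = (18.0, 88.0)
    knot: float = 55.0
    salience_brain: np.ndarray | None = None
    salience_cog: np.ndarray | None = None
    trajectories: np.ndarray | None = None
    component_scale: np.ndarray | None = None
    effect_size: float = 2.0
    noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.age_range[0] < self.knot < self.age_range[1]):
            raise ValueError("knot must lie strictly inside age_range")
        if self.trajectories is None:
            self.trajectories = np.array([[1.0, -1.0], [1.0, 1.0]])
        self.trajectories = np.atleast_2d(np.asarray(self.trajectories, dtype=float))
        n_comp = self.trajectories.shape[0]
        if self.component_scale is None:
            self.component_scale = 0.6 ** np.arange(n_comp)
        self.component_scale = np.asarray(self.component_scale, dtype=float)
        if self.component_scale.shape != (n_comp,):
            raise ValueError("component_scale must have one entry per component")
        if self.salience_cog is None:
            rng = np.random.default_rng(12345)
            self.salience_cog = _orthonormal_rows(
                rng.normal(size=(n_comp, len(COGNITIVE_SCORES)))
            )
        self.salience_cog = _unit_rows(np.atleast_2d(self.salience_cog))
        if self.salience_brain is not None:
            self.salience_brain = _unit_rows(np.atleast_2d(self.salience_brain))
            if self.salience_brain.shape[0] != n_comp:
                raise ValueError("salience_brain and trajectories disagree on component count")
        if self.salience_cog.shape[0] != n_comp:
            raise ValueError("salience_cog and trajectories disagree on component count")

    @property
    def n_components(self) -> int:
        return self.trajectories.shape[0]


def _unit_rows(m: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(m, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise ValueError("planted salience vectors must be non-zero")
    return m / norms


def _orthonormal_rows(m: np.ndarray) -> np.ndarray:
    q, _ = np.linalg.qr(m.T)
    return np.ascontiguousarray(q.T[: m.shape[0]])


def simulate_cohort(
    brain_features: np.ndarray,
    config: CohortConfig,
) -> tuple[pd.DataFrame, dict, np.ndarray]:
    """Generate a cohort table with planted brain--behavior couplings.

    Returns ``(cohort, ground_truth, coupled_brain_features)`` where the third
    element is ``brain_features`` plus ``effect_size x latent x salience_brain``
    (identity copy when ``salience_brain`` is None). ``ground_truth`` carries
    ages, the standardized latent scores, and every planted loading.
    """
    brain_features = np.asarray(brain_features, dtype=float)
    if brain_features.shape[0] != config.n_subjects:
        raise ValueError("brain_features row count must equal n_subjects")
    rng = np.random.default_rng(config.seed)

    ages = rng.uniform(config.age_range[0], config.age_range[1], size=config.n_subjects)
    basis = _raw_age_basis(ages, config.knot)
    basis_z = (basis - basis.mean(axis=0)) / basis.std(axis=0)

    latent = basis_z @ config.trajectories.T  # (n, n_components)
    sd = latent.std(axis=0)
    sd[sd == 0] = 1.0
    latent = (latent - latent.mean(axis=0)) / sd
    scaled = latent * config.component_scale

    scores = scaled @ config.salience_cog + rng.normal(
        0.0, config.noise_sd, size=(config.n_subjects, len(COGNITIVE_SCORES))
    )

    if config.salience_brain is not None:
        sb = config.salience_brain
        x_sd = brain_features.std(axis=0)
        x_sd[x_sd == 0] = 1.0
        coupled = brain_features + config.effect_size * (scaled @ sb) * x_sd
    else:
        coupled = brain_features.copy()

    cohort = pd.DataFrame(
        {
            "subject": [f"sub-{i:04d}" for i in range(config.n_subjects)],
            "age": ages,
            "sex": rng.integers(0, 2, size=config.n_subjects),
            "volume_proxy": rng.normal(1500.0, 120.0, size=config.n_subjects),
            "screening_proxy": rng.integers(26, 31, size=config.n_subjects),
            "education": rng.integers(1, 11, size=config.n_subjects),
            "timepoint_count": rng.integers(130_000, 140_001, size=config.n_subjects),
        }
    )
    for j, name in enumerate(COGNITIVE_SCORES):
        cohort[name] = scores[:, j]

    ground_truth = {
        "ages": ages,
        "latent": latent,
        "component_scale": config.component_scale,
        "trajectories": config.trajectories,
        "salience_cog": config.salience_cog,
        "salience_brain": config.salience_brain,
        "knot": config.knot,
        "effect_size": config.effect_size,
    }
    return cohort, ground_truth, coupled
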