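"""Group-level hidden Markov model with zero-mean full-covariance Gaussian states.

The observation model is ``P(Y_t | x_t = k) ~ N(0, Sigma(k))``: states differ
only in their covariance, which on time-delay embedded data means they differ
in autocovariance across lags, i.e. in spectral content. Inference is
expectation-maximization (Baum-Welch) with

* scaled forward-backward recursions (per-step normalization) for posteriors,
* closed-form M-steps: ``Sigma(k) = sum_t gamma_t(k) Y_t Y_t' / sum_t gamma_t(k)``
  with a small diagonal ridge (1e-6 x mean diagonal) to keep every state
  covariance positive-definite on short runs,
* subject boundaries breaking the chain — no transition is counted or
  propagated across subjects,
* several random restarts, keeping the restart with the highest final
  log-likelihood (``fit_score``).

Decoding offers both the smoothed posteriors ``gamma_t(k)`` and the log-space
Viterbi path (ties broken toward the smallest state index).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

__all__ = ["HmmModel", "StateTimeCourse", "fit", "posterior", "viterbi", "select_model"]

_LOG2PI = np.log(2.0 * np.pi)


@dataclass
class HmmModel:
    """Fitted model: K state covariances, transition matrix, initial distribution."""

    covariances: np.ndarray  # (K, D, D)
    transition: np.ndarray  # (K, K) row-stochastic
    initial: np.ndarray  # (K,)
    fit_score: float = np.nan  # final log-likelihood, nats
    loglik_history: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.covariances = np.asarray(self.covariances, dtype=float)
        self.transition = np.asarray(self.transition, dtype=float)
        self.initial = np.asarray(self.initial, dtype=float)
        K = self.n_states
        if self.covariances.shape[0] != K or self.initial.shape != (K,):
            raise ValueError("inconsistent state counts across parameters")
        if np.any(np.abs(self.transition.sum(axis=1) - 1.0) > 1e-9):
            raise ValueError("transition rows must sum to 1")
        for k in range(K):
            S = self.covariances[k]
            if np.max(np.abs(S - S.T)) > 1e-8:
                raise ValueError(f"covariance of state {k} is not symmetric")

    @property
    def n_states(self) -> int:
        return self.transition.shape[0]

    @property
    def n_channels(self) -> int:
        return self.covariances.shape[1]


@dataclass
class StateTimeCourse:
    """Per-sample smoothed posteriors and the Viterbi path for one subject."""

    posteriors: np.ndarray  # (T, K)
    viterbi_path: np.ndarray  # (T,)
    subject_id: str = "sim"

    @property
    def n_states(self) -> int:
        return self.posteriors.shape[1]


def _log_emissions(data: np.ndarray, covariances: np.ndarray) -> np.ndarray:
    """(T, K) log N(y_t; 0, Sigma_k) via Cholesky solves."""
    T, D = data.shape
    K = covariances.shape[0]
    out = np.empty((T, K))
    for k in range(K):
        L = linalg.cholesky(covariances[k], lower=True)
        logdet = 2.0 * np.sum(np.log(np.diag(L)))
        z = linalg.solve_triangular(L, data.T, lower=True)
        out[:, k] = -0.5 * (D * _LOG2PI + logdet + np.einsum("ij,ij->j", z, z))
    return out


def _forward_backward_batch(
    logb: np.ndarray, transition: np.ndarray, initial: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float, np.ndarray]:
    """Scaled forward-backward over a batch of equal-length sequences.

    ``logb`` is ``(S, T, K)``; the recursion is vectorized across the batch
    axis (each sequence keeps its own chain — nothing propagates between
    batch members). Returns ``(gamma (S,T,K), xi_sum (K,K) summed over batch
    and time, total log-likelihood, gamma at t=0 summed over batch)``.
    """
    S, T, K = logb.shape
    shift = logb.max(axis=2)
    B = np.exp(logb - shift[..., None])

    alpha = np.empty((S, T, K))
    c = np.empty((S, T))
    a = initial[None, :] * B[:, 0]
    c[:, 0] = a.sum(axis=1)
    alpha[:, 0] = a / c[:, 0, None]
    for t in range(1, T):
        a = (alpha[:, t - 1] @ transition) * B[:, t]
        c[:, t] = a.sum(axis=1)
        alpha[:, t] = a / c[:, t, None]

    beta = np.empty((S, T, K))
    beta[:, -1] = 1.0
    xi_sum = np.zeros((K, K))
    for t in range(T - 2, -1, -1):
        bb = B[:, t + 1] * beta[:, t + 1]
        scaled = bb / c[:, t + 1, None]
        beta[:, t] = scaled @ transition.T
        xi_sum += (alpha[:, t].T @ scaled) * transition

    gamma = alpha * beta
    gamma /= gamma.sum(axis=2, keepdims=True)
    loglik = float(np.sum(np.log(c)) + np.sum(shift))
    return gamma, xi_sum, loglik, gamma[:, 0].sum(axis=0)


def _forward_backward(
    logb: np.ndarray, transition: np.ndarray, initial: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Scaled forward-backward on one sequence (batch of one)."""
    gamma, xi_sum, loglik, _ = _forward_backward_batch(logb[None], transition, initial)
    return gamma[0], xi_sum, loglik


def _regularize(cov: np.ndarray, eps_scale: float = 1e-6) -> np.ndarray:
    eps = eps_scale * np.mean(np.diag(cov))
    return cov + max(eps, 1e-12) * np.eye(cov.shape[0])


def _init_params(
    data_list: list[np.ndarray], K: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Random block initialization: contiguous chunks assigned to random states."""
    D = data_list[0].shape[1]
    moments = np.zeros((K, D, D))
    counts = np.zeros(K)
    pooled = np.zeros((D, D))
    n_tot = 0
    for data in data_list:
        T = data.shape[0]
        n_blocks = max(2 * K, 8)
        edges = np.linspace(0, T, n_blocks + 1).astype(int)
        labels = rng.integers(0, K, size=n_blocks)
        for b in range(n_blocks):
            seg = data[edges[b] : edges[b + 1]]
            k = labels[b]
            moments[k] += seg.T @ seg
            counts[k] += seg.shape[0]
        pooled += data.T @ data
        n_tot += T
    pooled /= n_tot
    covs = np.empty((K, D, D))
    for k in range(K):
        if counts[k] < D + 1:
            covs[k] = _regularize(pooled * np.exp(rng.normal(0, 0.1)))
        else:
            covs[k] = _regularize(moments[k] / counts[k])
    stay = 0.9
    A = np.full((K, K), (1 - stay) / max(K - 1, 1))
    np.fill_diagonal(A, stay if K > 1 else 1.0)
    pi = np.full(K, 1.0 / K)
    return covs, A, pi


def _group_by_length(data_list: list[np.ndarray]) -> list[np.ndarray]:
    """Stack subjects with equal sequence length into (S, T, D) batches."""
    by_len: dict[int, list[np.ndarray]] = {}
    for d in data_list:
        by_len.setdefault(d.shape[0], []).append(d)
    return [np.stack(group) for group in by_len.values()]


def _em_once(
    data_list: list[np.ndarray],
    K: int,
    max_iter: int,
    tol: float,
    rng: np.random.Generator,
) -> HmmModel:
    D = data_list[0].shape[1]
    batches = _group_by_length(data_list)
    covs, A, pi = _init_params(data_list, K, rng)
    history: list[float] = []
    prev = -np.inf
    for _ in range(max_iter):
        moments = np.zeros((K, D, D))
        weights = np.zeros(K)
        xi_tot = np.zeros((K, K))
        pi_tot = np.zeros(K)
        loglik = 0.0
        for batch in batches:
            S, T, _ = batch.shape
            flat = batch.reshape(S * T, D)
            logb = _log_emissions(flat, covs).reshape(S, T, K)
            gamma, xi_sum, ll, g0 = _forward_backward_batch(logb, A, pi)
            loglik += ll
            xi_tot += xi_sum
            pi_tot += g0
            g = gamma.reshape(S * T, K)
            for k in range(K):
                moments[k] += (flat * g[:, k : k + 1]).T @ flat
            weights += g.sum(axis=0)
        if not np.isfinite(loglik):
            raise FloatingPointError("non-finite likelihood during EM")
        history.append(loglik)
        if loglik - prev < tol and np.isfinite(prev):
            break
        prev = loglik
        # M-step
        for k in range(K):
            covs[k] = _regularize(moments[k] / max(weights[k], 1e-10))
            covs[k] = 0.5 * (covs[k] + covs[k].T)
        rows = xi_tot.sum(axis=1, keepdims=True)
        A = np.where(rows > 0, xi_tot / np.maximum(rows, 1e-300), 1.0 / K)
        A /= A.sum(axis=1, keepdims=True)
        pi = pi_tot / pi_tot.sum()
    return HmmModel(covs, A, pi, fit_score=history[-1], loglik_history=np.array(history))


def fit(
    data_list: list[np.ndarray] | np.ndarray,
    K: int = 8,
    n_restarts: int = 5,
    max_iter: int = 50,
    tol: float = 1e-3,
    seed: int = 0,
) -> HmmModel:
    """Fit the group HMM by EM with multiple random restarts.

    ``data_list`` holds one ``(T_s, D)`` array per subject; the chain is never
    propagated across subject boundaries. The restart with the highest final
    log-likelihood is returned; restarts whose likelihood degenerates are
    dropped, and an error is raised only if every restart fails.
    """
    if isinstance(data_list, np.ndarray):
        data_list = [data_list]
    data_list = [np.ascontiguousarray(np.asarray(d, dtype=float)) for d in data_list]
    if any(d.ndim != 2 for d in data_list):
        raise ValueError("each subject's data must be (time, channels)")
    rng = np.random.default_rng(seed)
    best: HmmModel | None = None
    errors: list[str] = []
    for r in range(n_restarts):
        try:
            model = _em_once(data_list, K, max_iter, tol, rng)
        except (FloatingPointError, linalg.LinAlgError) as exc:  # degenerate restart
            errors.append(f"restart {r}: {exc}")
            continue
        if best is None or model.fit_score > best.fit_score:
            best = model
    if best is None:
        raise RuntimeError("all EM restarts failed: " + "; ".join(errors))
    return best


def posterior(model: HmmModel, data: np.ndarray, subject_id: str = "sim") -> StateTimeCourse:
    """Smoothed state posteriors and Viterbi path for one subject."""
    data = np.asarray(data, dtype=float)
    if data.shape[1] != model.n_channels:
        raise ValueError(
            f"data has {data.shape[1]} channels but model expects {model.n_channels}"
        )
    logb = _log_emissions(data, model.covariances)
    gamma, _, _ = _forward_backward(logb, model.transition, model.initial)
    path = _viterbi_from_logb(logb, model.transition, model.initial)
    return StateTimeCourse(gamma, path, subject_id=subject_id)


def _viterbi_from_logb(logb: np.ndarray, transition: np.ndarray, initial: np.ndarray) -> np.ndarray:
    T, K = logb.shape
    with np.errstate(divide="ignore"):
        logA = np.log(transition)
        logpi = np.log(initial)
    delta = logpi + logb[0]
    back = np.zeros((T, K), dtype=np.int64)
    for t in range(1, T):
        cand = delta[:, None] + logA
        back[t] = np.argmax(cand, axis=0)  # argmax takes the smallest index on ties
        delta = cand[back[t], np.arange(K)] + logb[t]
    path = np.empty(T, dtype=np.int64)
    path[-1] = int(np.argmax(delta))
    for t in range(T - 2, -1, -1):
        path[t] = back[t + 1, path[t + 1]]
    return path


def viterbi(model: HmmModel, data: np.ndarray) -> np.ndarray:
    """Most probable state path (log-space; ties -> smallest state index)."""
    data = np.asarray(data, dtype=float)
    if data.shape[1] != model.n_channels:
        raise ValueError(
            f"data has {data.shape[1]} channels but model expects {model.n_channels}"
        )
    logb = _log_emissions(data, model.covariances)
    return _viterbi_from_logb(logb, model.transition, model.initial)


def select_model(models: list[HmmModel]) -> HmmModel:
    """Best model across restarts: highest log-likelihood ``fit_score``."""
    if not models:
        raise ValueError("empty model list")
    ks = {m.n_states for m in models}
    if len(ks) != 1:
        raise ValueError("models must share the state count")
    return max(models, key=lambda m: m.fit_score)
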