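"""Temporal summary statistics of state time courses.

All metrics are computed from one run-length decomposition of a hard state
path, which makes the accounting identity ``FO_k = SR_k * LT_k`` exact:

* fractional occupancy (FO) — fraction of samples assigned to a state;
* mean lifetime (LT, s) — mean length of a contiguous visit;
* mean interval (INT, s) — mean gap strictly between successive visits of the
  same state (undefined, NaN, for states visited fewer than twice);
* switching rate (SR, 1/s) — visit onsets per second.

Boundary runs (touching either recording edge) count toward LT and SR; that
inclusion is what preserves the FO identity. Transition probabilities are
computed on the run-collapsed visit sequence by default (self-transitions
excluded by construction), with a frame-wise variant available.
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np

__all__ = [
    "StateMetrics",
    "fractional_occupancy",
    "mean_lifetime",
    "mean_interval",
    "switching_rate",
    "transition_matrix",
    "state_metrics",
    "most_likely_cycle",
]

from dataclasses import dataclass


@dataclass
class StateMetrics:
    """Per-subject temporal metrics; vectors indexed by state."""

    fractional_occupancy: np.ndarray
    mean_lifetime: np.ndarray
    mean_interval: np.ndarray
    switching_rate: np.ndarray
    transition: np.ndarray
    subject_id: str = "sim"


def _check_path(path: np.ndarray, K: int) -> np.ndarray:
    path = np.asarray(path, dtype=np.int64)
    if path.size == 0:
        raise ValueError("empty state path")
    if path.min() < 0 or path.max() >= K:
        raise ValueError("path values must lie in {0..K-1}")
    return path


def _run_lengths(path: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(states, starts, lengths) of the contiguous runs of a path."""
    change = np.flatnonzero(np.diff(path)) + 1
    starts = np.concatenate([[0], change])
    stops = np.concatenate([change, [path.size]])
    return path[starts], starts, stops - starts


def fractional_occupancy(path: np.ndarray, K: int) -> np.ndarray:
    """FO_k = #{t : path_t = k} / T. Sums to 1."""
    path = _check_path(path, K)
    return np.bincount(path, minlength=K) / path.size


def mean_lifetime(path: np.ndarray, K: int, fs: float) -> np.ndarray:
    """Mean contiguous visit duration per state, in seconds (NaN if never visited)."""
    if fs <= 0:
        raise ValueError("fs must be positive")
    path = _check_path(path, K)
    states, _, lengths = _run_lengths(path)
    out = np.full(K, np.nan)
    for k in range(K):
        sel = states == k
        if sel.any():
            out[k] = lengths[sel].mean() / fs
    return out


def mean_interval(path: np.ndarray, K: int, fs: float) -> np.ndarray:
    """Mean gap between successive visits of a state, in seconds.

    A gap spans the samples strictly between the end of one visit and the
    start of the next. States with fewer than two visits get NaN.
    """
    if fs <= 0:
        raise ValueError("fs must be positive")
    path = _check_path(path, K)
    states, starts, lengths = _run_lengths(path)
    out = np.full(K, np.nan)
    for k in range(K):
        idx = np.flatnonzero(states == k)
        if idx.size >= 2:
            gaps = starts[idx[1:]] - (starts[idx[:-1]] + lengths[idx[:-1]])
            out[k] = gaps.mean() / fs
    return out


def switching_rate(path: np.ndarray, K: int, fs: float) -> np.ndarray:
    """Visit onsets of each state per second of recording."""
    if fs <= 0:
        raise ValueError("fs must be positive")
    path = _check_path(path, K)
    states, _, _ = _run_lengths(path)
    visits = np.bincount(states, minlength=K)
    return visits / (path.size / fs)


def transition_matrix(
    path: np.ndarray, K: int, exclude_self: bool = True
) -> np.ndarray:
    """Empirical state-to-state transition probabilities.

    With ``exclude_self`` (default) counts are taken over the run-collapsed
    visit sequence — the probability that each state gets active after
    another — so the diagonal is structurally zero. Otherwise frame-wise
    counts are used. Rows with no outgoing transitions are left all-zero
    with a warning.
    """
    path = _check_path(path, K)
    if path.size < 2:
        raise ValueError("path must have at least 2 samples")
    if exclude_self:
        seq = _run_lengths(path)[0]
    else:
        seq = path
    counts = np.zeros((K, K))
    np.add.at(counts, (seq[:-1], seq[1:]), 1.0)
    if exclude_self:
        np.fill_diagonal(counts, 0.0)
    rows = counts.sum(axis=1, keepdims=True)
    empty = np.flatnonzero(rows.ravel() == 0)
    if empty.size:
        warnings.warn(
            f"state(s) {empty.tolist()} have no outgoing transitions; rows left zero",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(rows > 0, counts / np.maximum(rows, 1.0), 0.0)
    return out


def state_metrics(
    path: np.ndarray, K: int, fs: float, subject_id: str = "sim"
) -> StateMetrics:
    """All temporal metrics of one subject's hard state path."""
    return StateMetrics(
        fractional_occupancy=fractional_occupancy(path, K),
        mean_lifetime=mean_lifetime(path, K, fs),
        mean_interval=mean_interval(path, K, fs),
        switching_rate=switching_rate(path, K, fs),
        transition=transition_matrix(path, K),
        subject_id=subject_id,
    )


def most_likely_cycle(
    transitions: np.ndarray | list[np.ndarray], cycle_length: int = 4
) -> tuple[tuple[int, ...], float]:
    """Most likely ordered cycle of distinct states under mean transitions.

    Exhaustively scores every ordered cycle of ``cycle_length`` distinct
    states by the sum of log mean transition probabilities around the loop,
    and returns the best cycle in canonical rotation (starting at its
    smallest state), ties broken lexicographically. Input is one K x K
    matrix or a list to be averaged (e.g. a group of subjects).
    """
    mats = [transitions] if isinstance(transitions, np.ndarray) else list(transitions)
    A = np.mean(np.stack([np.asarray(m, dtype=float) for m in mats]), axis=0)
    K = A.shape[0]
    if cycle_length < 2:
        raise ValueError("cycle_length must be at least 2")
    if cycle_length > K:
        raise ValueError("cycle_length cannot exceed the state count")
    with np.errstate(divide="ignore"):
        logA = np.log(A)

    best_cycle: tuple[int, ...] | None = None
    best_score = -np.inf
    # fix the smallest state first: each cycle is enumerated exactly once,
    # already in canonical rotation, in lexicographic order
    for first in range(K - cycle_length + 1):
        rest = [s for s in range(first + 1, K)]
        for perm in itertools.permutations(rest, cycle_length - 1):
            cyc = (first, *perm)
            score = logA[cyc[-1], cyc[0]] + sum(
                logA[cyc[i], cyc[i + 1]] for i in range(cycle_length - 1)
            )
            if score > best_score + 1e-15:
                best_score, best_cycle = score, cyc
    assert best_cycle is not None
    return best_cycle, float(best_score)
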