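"""Time-delay embedding and group PCA reduction.

A TDE-HMM does not model the raw parcel signals: each time point is augmented
with a symmetric window of lagged copies of every parcel, so that a state's
(zero-mean) covariance in the embedded space encodes autocovariance across
lags, i.e. spectral content. With 52 parcels and 15 lags the embedded space
has 780 channels and each state autocovariance carries 780*779/2 = 303,810
unique off-diagonal parameters, which motivates the PCA step down to twice
the parcel count (104 channels for 52 parcels).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocess import ParcelRecording

__all__ = ["EmbeddedData", "embed", "autocov_param_count", "pca_reduce", "default_lags"]


def default_lags(n_lags: int) -> np.ndarray:
    """Symmetric consecutive sample lags, e.g. 15 -> -7..+7."""
    if n_lags < 1 or n_lags % 2 == 0:
        raise ValueError("n_lags must be a positive odd count (symmetric window)")
    half = n_lags // 2
    return np.arange(-half, half + 1)


@dataclass
class EmbeddedData:
    """Embedded (and possibly PCA-reduced) observations for one subject.

    ``data`` is ``channels x time``. Before PCA the channel axis is ordered
    (parcel-major, lag-minor): row ``p * n_lags + l`` holds parcel ``p``
    shifted by ``lags[l]``. After PCA, channels are principal components and
    ``pca_basis`` (components x embedded-channels, orthonormal rows) maps back.
    """

    data: np.ndarray
    lags: np.ndarray
    subject_id: str = "sim"
    pca_basis: np.ndarray | None = field(default=None)
    explained_variance_fraction: float | None = None

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_times(self) -> int:
        return self.data.shape[1]


def embed(rec: ParcelRecording, n_lags: int = 15) -> EmbeddedData:
    """Time-delay embed a recording with a symmetric window of ``n_lags`` lags.

    Row ``(p, l)`` at (output) time ``t`` holds parcel ``p`` at input time
    ``t + lags[l]``. Times whose lag window would run off either edge are
    dropped, so the output has ``T - n_lags + 1`` columns.
    """
    lags = default_lags(n_lags)
    half = n_lags // 2
    T = rec.n_times
    if T <= n_lags:
        raise ValueError(f"recording of {T} samples is shorter than the {n_lags}-lag window")
    n_valid = T - 2 * half
    P = rec.n_parcels
    out = np.empty((P * n_lags, n_valid))
    for p in range(P):
        for j, lag in enumerate(lags):
            out[p * n_lags + j] = rec.data[p, half + lag : half + lag + n_valid]
    return EmbeddedData(out, lags, subject_id=rec.subject_id)


def autocov_param_count(n_parcels: int, n_lags: int) -> int:
    """Unique off-diagonal entries of one state's embedded autocovariance.

    ``(n_parcels * n_lags) * (n_parcels * n_lags - 1) / 2``; 52 parcels with
    15 lags give 303,810.
    """
    if n_parcels < 1 or n_lags < 1:
        raise ValueError("counts must be positive")
    c = n_parcels * n_lags
    return c * (c - 1) // 2


def pca_reduce(
    embedded: EmbeddedData | list[EmbeddedData],
    n_components: int | None = None,
) -> list[EmbeddedData]:
    """Project embedded data onto a shared group PCA basis and standardize.

    The basis is computed from the covariance of the data pooled over all
    subjects (a group HMM needs one shared observation space), each subject is
    projected onto the top ``n_components`` axes, and every retained component
    is scaled to zero mean, unit variance over the pooled data. The default
    component count is twice the parcel count implied by the embedding.

    Returns a list of :class:`EmbeddedData` with ``pca_basis`` and
    ``explained_variance_fraction`` filled in (same objects order as input).
    """
    items = [embedded] if isinstance(embedded, EmbeddedData) else list(embedded)
    if not items:
        raise ValueError("no embedded data given")
    n_chan = items[0].n_channels
    n_lags = items[0].lags.size
    if any(e.n_channels != n_chan for e in items):
        raise ValueError("all subjects must share the embedded channel count")
    if n_components is None:
        n_components = 2 * (n_chan // n_lags)
    if n_components > n_chan:
        raise ValueError(f"cannot retain {n_components} components from {n_chan} channels")

    # pooled covariance, accumulated subject by subject to bound memory
    total_t = sum(e.n_times for e in items)
    mean = sum(e.data.sum(axis=1) for e in items) / total_t
    cov = np.zeros((n_chan, n_chan))
    for e in items:
        x = e.data - mean[:, None]
        cov += x @ x.T
    cov /= total_t

    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    rank = int(np.sum(evals > max(evals[0], 0) * 1e-12))
    if n_components > rank:
        raise ValueError(f"requested {n_components} components but data rank is {rank}")
    basis = evecs[:, :n_components].T  # components x channels, orthonormal rows
    explained = float(evals[:n_components].sum() / evals.sum())

    # pooled per-component scale so standardization is shared across subjects
    comp_var = evals[:n_components].copy()
    comp_sd = np.sqrt(comp_var)

    out = []
    for e in items:
        proj = basis @ (e.data - mean[:, None])
        proj /= comp_sd[:, None]
        out.append(
            EmbeddedData(
                proj,
                e.lags,
                subject_id=e.subject_id,
                pca_basis=basis,
                explained_variance_fraction=explained,
            )
        )
    return out
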