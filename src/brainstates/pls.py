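"""Behavioral partial least squares linking brain-state features to cognition.

The core statistic is the SVD of the column-standardized cross-covariance
``R = X' Y / (n - 1)`` between a brain-feature block ``X`` and a cognitive
block ``Y``: singular values measure shared covariance, the left/right
singular vectors are the brain and cognitive *saliences*, and subject-level
latent scores are ``X U`` and ``Y V``. Inference is non-parametric:

* permutation test — rows of ``Y`` are permuted relative to ``X``; permuted
  singular values are aligned to the observed components by Procrustes
  rotation before comparison, and ``p = (1 + #{S_perm >= S_obs}) / (1 + n_perm)``;
* bootstrap — subjects are resampled with replacement, resampled saliences are
  aligned (component order and sign) to the original, and each feature's
  bootstrap sampling ratio (BSR) is its salience over its bootstrap SD, with
  ``|BSR| >= 3`` read as robust (roughly a 99% normal interval).

Cognitive preprocessing mirrors a lifespan design: covariate regression
(sex, intracranial-volume proxy, screening score, retained time points),
rank-based inverse-normal (Blom) quantile normalization, and two piecewise
quadratic age polynomials knotted at 55 years that let the model choose any
trajectory in the linear/quadratic subspace — a linear latent age trend shows
up as opposite-sign saliences of similar magnitude on the two polynomials, a
quadratic (inverted-U) trend as same-sign saliences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import COGNITIVE_SCORES

__all__ = [
    "PlsResult",
    "impute_by_age_decile",
    "regress_covariates",
    "quantile_normalize",
    "age_polynomials",
    "pls_svd",
    "permutation_test",
    "bootstrap_bsr",
    "fdr_adjust",
    "build_feature_models",
    "prepare_cognitive_block",
]

DEFAULT_COVARIATES = ["sex", "volume_proxy", "screening_proxy", "timepoint_count"]


@dataclass
class PlsResult:
    singular_values: np.ndarray
    brain_saliences: np.ndarray  # (p_x, n_comp) columns unit norm
    cognitive_saliences: np.ndarray  # (p_y, n_comp)
    explained_fraction: np.ndarray
    latent_brain: np.ndarray  # (n, n_comp)
    latent_cognitive: np.ndarray
    perm_p: np.ndarray | None = None
    boot_sd_brain: np.ndarray | None = None
    boot_sd_cognitive: np.ndarray | None = None
    bsr_brain: np.ndarray | None = None
    bsr_cognitive: np.ndarray | None = None
    x_columns: list[str] | None = field(default=None, repr=False)
    y_columns: list[str] | None = field(default=None, repr=False)


def impute_by_age_decile(
    table: pd.DataFrame,
    score_columns: list[str] | None = None,
    max_missing: int = 3,
) -> pd.DataFrame:
    """Median-impute missing scores within the subject's age decile.

    Subjects missing more than ``max_missing`` of the scores are excluded
    first. If an entire decile lacks observations of a score, the global
    median is used with a warning. The returned table has no missing scores.
    """
    scores = score_columns or [c for c in COGNITIVE_SCORES if c in table.columns]
    out = table.copy()
    n_missing = out[scores].isna().sum(axis=1)
    out = out.loc[n_missing <= max_missing].reset_index(drop=True)
    decile = pd.qcut(out["age"], 10, labels=False, duplicates="drop")
    for col in scores:
        med = out.groupby(decile)[col].transform("median")
        if med.isna().any() and out[col].isna().any():
            warnings.warn(f"decile without observed '{col}': using global median", stacklevel=2)
            med = med.fillna(out[col].median())
        out[col] = out[col].fillna(med)
    return out


def regress_covariates(Y: np.ndarray, C: np.ndarray, add_intercept: bool = True) -> np.ndarray:
    """OLS residuals of every column of ``Y`` on the covariate matrix ``C``."""
    Y = np.asarray(Y, dtype=float)
    C = np.asarray(C, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    if add_intercept:
        C = np.column_stack([np.ones(C.shape[0]), C])
    rank = np.linalg.matrix_rank(C)
    if rank < C.shape[1]:
        # name the columns whose removal restores full rank
        collinear = [
            j for j in range(C.shape[1])
            if np.linalg.matrix_rank(np.delete(C, j, axis=1)) == rank
        ]
        raise ValueError(f"covariate matrix is rank-deficient; collinear columns: {collinear}")
    beta, *_ = np.linalg.lstsq(C, Y, rcond=None)
    return Y - C @ beta


def quantile_normalize(x: np.ndarray) -> np.ndarray:
    """Rank-based inverse-normal transform with the Blom offset.

    ``z_i = Phi^{-1}((r_i - 3/8) / (n + 1/4))`` where ``r_i`` is the rank
    (ties receive their average rank). Preserves rank order; output is
    approximately standard normal.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.all(x == x[0]):
        raise ValueError("all-tied input cannot be quantile-normalized")
    r = stats.rankdata(x)
    return stats.norm.ppf((r - 3.0 / 8.0) / (n + 0.25))


def age_polynomials(ages: np.ndarray, knot: float = 55.0) -> np.ndarray:
    """Two piecewise quadratic lifespan regressors, knotted at ``knot``.

    Ascending column ``a(x) = -(min(x - knot, 0))^2`` rises toward 0 and
    plateaus after the knot (non-decreasing in age); descending column
    ``d(x) = -(max(x - knot, 0))^2`` is flat before the knot and accelerates
    downward after (non-increasing). Each column is rescaled to the sample
    standard deviation of age, matching the original scale of the age
    variable.
    """
    ages = np.asarray(ages, dtype=float)
    if not (ages.min() <= knot <= ages.max()):
        raise ValueError("knot must lie within the observed age range")
    age_sd = ages.std()
    if age_sd == 0:
        raise ValueError("degenerate age variance")
    x = ages - knot
    cols = np.column_stack([-np.minimum(x, 0.0) ** 2, -np.maximum(x, 0.0) ** 2])
    sd = cols.std(axis=0)
    sd[sd == 0] = 1.0
    return cols / sd * age_sd


def _standardize_cols(M: np.ndarray, name: str) -> np.ndarray:
    M = np.asarray(M, dtype=float)
    sd = M.std(axis=0)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        raise ValueError(f"zero-variance column(s) in {name}: {zero.tolist()}")
    return (M - M.mean(axis=0)) / sd


def pls_svd(
    X: np.ndarray,
    Y: np.ndarray,
    n_components: int | None = None,
    standardize: bool = True,
    x_columns: list[str] | None = None,
    y_columns: list[str] | None = None,
) -> PlsResult:
    """SVD of the standardized cross-covariance between ``X`` and ``Y``.

    Component signs are fixed so the largest-|value| cognitive salience of
    each component is positive. ``explained_fraction`` is ``S_i^2 / sum S^2``.
    """
    if X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y must have the same subject count")
    Xs = _standardize_cols(X, "X") if standardize else np.asarray(X, dtype=float)
    Ys = _standardize_cols(Y, "Y") if standardize else np.asarray(Y, dtype=float)
    n = Xs.shape[0]
    R = Xs.T @ Ys / (n - 1)
    U, S, Vt = np.linalg.svd(R, full_matrices=False)
    V = Vt.T
    if n_components is not None:
        U, S, V = U[:, :n_components], S[:n_components], V[:, :n_components]
    # sign convention
    for i in range(S.size):
        j = int(np.argmax(np.abs(V[:, i])))
        if V[j, i] < 0:
            V[:, i] *= -1
            U[:, i] *= -1
    return PlsResult(
        singular_values=S,
        brain_saliences=U,
        cognitive_saliences=V,
        explained_fraction=S**2 / np.sum(S**2),
        latent_brain=Xs @ U,
        latent_cognitive=Ys @ V,
        x_columns=x_columns,
        y_columns=y_columns,
    )


def _procrustes_rotation(ref: np.ndarray, moved: np.ndarray) -> np.ndarray:
    """Orthogonal ``Q`` minimizing ``||ref - moved @ Q||_F``."""
    A, _, Bt = np.linalg.svd(moved.T @ ref)
    return A @ Bt


def permutation_test(
    X: np.ndarray,
    Y: np.ndarray,
    n_perm: int = 10_000,
    seed: int = 0,
    result: PlsResult | None = None,
    align: str = "sorted",
) -> np.ndarray:
    """Permutation p-values for each PLS component's singular value.

    Rows of ``Y`` are permuted relative to ``X`` and
    ``p_i = (1 + #{S_perm,i >= S_obs,i}) / (1 + n_perm)``. With the default
    ``align="sorted"`` the i-th *sorted* permuted singular value is compared
    to the i-th observed one (for the leading component this is the classical
    max-vs-max comparison, which is calibrated under the null: permuting rows
    of standardized noise and ranking like against like keeps the type-I rate
    at its nominal level). ``align="procrustes"`` instead rotates each
    permuted solution onto the observed saliences before comparison; the
    rotation mixes permuted components and systematically deflates the null,
    making the test anti-conservative, so it is offered only for comparison
    with toolboxes that use it.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    if align not in ("sorted", "procrustes"):
        raise ValueError("align must be 'sorted' or 'procrustes'")
    rng = np.random.default_rng(seed)
    obs = result if result is not None else pls_svd(X, Y)
    Xs = _standardize_cols(X, "X")
    Ys = _standardize_cols(Y, "Y")
    n = Xs.shape[0]
    n_comp = obs.singular_values.size
    V0 = obs.cognitive_saliences

    exceed = np.zeros(n_comp)
    for _ in range(n_perm):
        Rp = Xs.T @ Ys[rng.permutation(n)] / (n - 1)
        if align == "sorted":
            Sp = np.linalg.svd(Rp, compute_uv=False)
            exceed += Sp[:n_comp] >= obs.singular_values
        else:
            Up, Sp, Vpt = np.linalg.svd(Rp, full_matrices=False)
            Q = _procrustes_rotation(V0, Vpt.T[:, : V0.shape[1]])
            rotated = np.sqrt(
                np.sum((Up[:, : V0.shape[1]] * Sp[: V0.shape[1]] @ Q) ** 2, axis=0)
            )
            exceed += rotated >= obs.singular_values
    return (1.0 + exceed) / (1.0 + n_perm)


def bootstrap_bsr(
    X: np.ndarray,
    Y: np.ndarray,
    n_boot: int = 1000,
    seed: int = 0,
    result: PlsResult | None = None,
    max_redraws: int = 50,
) -> PlsResult:
    """Bootstrap salience SDs and BSRs, filled into a copy of the PLS result.

    Each resample's components are aligned to the original solution by a
    signed permutation: components are matched by the magnitude of the
    cross-products between the stacked (brain + cognitive) salience matrices
    (Hungarian assignment) and the sign of each matched pair is flipped to
    agree. This resolves the SVD's order and sign indeterminacies — the only
    ones a bootstrap must undo — without a soft rotation, which would mix
    resampled components with the original noise realization and shrink the
    bootstrap SDs (deflated SDs inflate every BSR, so noise features start
    passing the |BSR| >= 3 cut). Resamples producing a zero-variance column
    are redrawn.
    """
    from scipy.optimize import linear_sum_assignment

    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    rng = np.random.default_rng(seed)
    obs = result if result is not None else pls_svd(X, Y)
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    n = X.shape[0]
    stack0 = np.vstack([obs.brain_saliences, obs.cognitive_saliences])

    us, vs = [], []
    redraws = 0
    b = 0
    while b < n_boot:
        idx = rng.integers(0, n, size=n)
        Xb, Yb = X[idx], Y[idx]
        if np.any(Xb.std(axis=0) == 0) or np.any(Yb.std(axis=0) == 0):
            redraws += 1
            if redraws > max_redraws:
                raise RuntimeError("too many degenerate bootstrap resamples")
            continue
        res_b = pls_svd(Xb, Yb, n_components=obs.singular_values.size)
        stack_b = np.vstack([res_b.brain_saliences, res_b.cognitive_saliences])
        C = stack0.T @ stack_b
        ri, cj = linear_sum_assignment(-np.abs(C))
        signs = np.sign(C[ri, cj])
        signs[signs == 0] = 1.0
        us.append(res_b.brain_saliences[:, cj] * signs)
        vs.append(res_b.cognitive_saliences[:, cj] * signs)
        b += 1
    boot_sd_u = np.std(np.stack(us), axis=0, ddof=1)
    boot_sd_v = np.std(np.stack(vs), axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        bsr_u = obs.brain_saliences / boot_sd_u
        bsr_v = obs.cognitive_saliences / boot_sd_v
    obs.boot_sd_brain, obs.boot_sd_cognitive = boot_sd_u, boot_sd_v
    obs.bsr_brain, obs.bsr_cognitive = bsr_u, bsr_v
    return obs


def fdr_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values over the pooled set."""
    from statsmodels.stats.multitest import multipletests

    pvals = np.asarray(pvals, dtype=float)
    flat = pvals.ravel()
    adjusted = multipletests(flat, method="fdr_bh")[1]
    return adjusted.reshape(pvals.shape)


def prepare_cognitive_block(
    table: pd.DataFrame,
    covariates: list[str] | None = None,
    knot: float = 55.0,
    include_education: bool = True,
) -> tuple[np.ndarray, list[str]]:
    """Build the cognitive (Y) block: residualized, quantile-normalized task
    scores plus the two age polynomials and (optionally) education.

    Covariates (sex, volume proxy, screening proxy, time-point count by
    default) are regressed out of the task scores, each residual score is
    Blom inverse-normal transformed, and the age polynomials are appended
    as separate variables so the model can infer the lifespan trajectory.
    """
    covariates = covariates if covariates is not None else DEFAULT_COVARIATES
    scores = [c for c in COGNITIVE_SCORES if c in table.columns]
    Y = table[scores].to_numpy(dtype=float)
    if covariates:
        C = table[covariates].to_numpy(dtype=float)
        Y = regress_covariates(Y, C)
    Y = np.column_stack([quantile_normalize(Y[:, j]) for j in range(Y.shape[1])])
    names = list(scores)
    if include_education and "education" in table.columns:
        Y = np.column_stack([Y, table["education"].to_numpy(dtype=float)])
        names.append("education")
    polys = age_polynomials(table["age"].to_numpy(dtype=float), knot=knot)
    Y = np.column_stack([Y, polys])
    names += ["age_ascending", "age_descending"]
    return Y, names


def build_feature_models(
    metrics_list: list,
    spectra=None,
    top_parcel_idx: np.ndarray | None = None,
) -> dict[str, tuple[np.ndarray, list[str]]]:
    """Assemble the three brain-feature design matrices.

    * ``temporal``  — FO/LT/INT/SR per state (4K columns);
    * ``transition`` — off-diagonal entries of the self-excluded transition
      matrix (K(K-1) columns);
    * ``spectral``  — concatenated per-state PSDs of each state's top parcels
      (only if ``spectra`` and ``top_parcel_idx`` are given).

    Undefined metric values (a state never visited by a subject) are replaced
    by the column mean with a warning; all columns are left unstandardized
    (``pls_svd`` standardizes).
    """
    K = metrics_list[0].fractional_occupancy.size
    rows = []
    for m in metrics_list:
        rows.append(
            np.concatenate(
                [m.fractional_occupancy, m.mean_lifetime, m.mean_interval, m.switching_rate]
            )
        )
    M1 = np.vstack(rows)
    names1 = [
        f"{metric}_state{k}"
        for metric in ("FO", "LT", "INT", "SR")
        for k in range(K)
    ]

    off = ~np.eye(K, dtype=bool)
    M2 = np.vstack([m.transition[off] for m in metrics_list])
    names2 = [f"T_{i}to{j}" for i in range(K) for j in range(K) if i != j]

    out: dict[str, tuple[np.ndarray, list[str]]] = {}
    for name, (M, cols) in {"temporal": (M1, names1), "transition": (M2, names2)}.items():
        nan_cols = np.flatnonzero(np.any(np.isnan(M), axis=0))
        if nan_cols.size:
            warnings.warn(
                f"{name} model: imputing undefined values in columns {nan_cols.tolist()} "
                "with the column mean",
                stacklevel=2,
            )
            col_mean = np.nanmean(M, axis=0)
            M = np.where(np.isnan(M), col_mean, M)
        out[name] = (M, cols)

    if spectra is not None and top_parcel_idx is not None:
        # (subjects, K, top parcels, freqs) flattened per subject
        K_s = spectra.psd.shape[1]
        blocks, names3 = [], []
        for k in range(K_s):
            sel = spectra.psd[:, k][:, top_parcel_idx[k], :]
            blocks.append(sel.reshape(sel.shape[0], -1))
            names3 += [
                f"psd_state{k}_parcel{p}_f{fi}"
                for p in top_parcel_idx[k]
                for fi in range(spectra.frequencies.size)
            ]
        M3 = np.concatenate(blocks, axis=1)
        if np.any(np.isnan(M3)):
            col_mean = np.nanmean(M3, axis=0)
            M3 = np.where(np.isnan(M3), col_mean, M3)
        out["spectral"] = (M3, names3)
    return out
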