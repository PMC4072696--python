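"""Differential expression via surrogate-variable-adjusted moderated t-statistics.

Each feature is fit by ordinary least squares on a model matrix consisting of
an intercept, a tumor/normal indicator, and optional surrogate-variable (or
pairing) covariates.  Per-feature residual variances are shrunk toward a
scaled-F empirical-Bayes prior whose hyperparameters (d0 prior degrees of
freedom, s0^2 prior variance) are estimated in closed form by matching the
first two moments of log s_g^2, and the resulting moderated t is referred to
a t distribution with d_g + d0 degrees of freedom.  Surrogate variables are
the leading right singular vectors of the residual matrix after removing the
condition effect, retained by a permutation test on the singular-value
spectrum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, polygamma

from .types import ExpressionMatrix, SampleDesign, SchemaError

logger = logging.getLogger(__name__)

P_FLOOR = 1e-300

DE_COLUMNS = ["delta", "t_mod", "p", "fdr", "direction"]


@dataclass
class ModeratedTParams:
    """Empirical-Bayes hyperparameters and per-feature variance bookkeeping."""

    d0: float  # prior degrees of freedom (may be inf)
    s0_sq: float  # prior variance
    d_g: float  # residual degrees of freedom (common to all features)
    s_g_sq: np.ndarray  # per-feature residual variances

    def posterior_var(self) -> np.ndarray:
        if np.isinf(self.d0):
            return np.full_like(self.s_g_sq, self.s0_sq)
        return (self.d0 * self.s0_sq + self.d_g * self.s_g_sq) / (self.d0 + self.d_g)


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x <= 0:
        raise ValueError("trigamma inverse requires a positive argument")
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(75):
        tri = polygamma(1, y)
        dif = tri * (1.0 - tri / x) / polygamma(2, y)
        y = y + dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def estimate_prior(s_g_sq: np.ndarray, d_g: float) -> tuple:
    """Estimate (d0, s0_sq) by moment-matching log s_g^2 to a scaled-F prior."""
    s = np.asarray(s_g_sq, dtype=float)
    s = s[s > 0]
    if s.size == 0:
        raise SchemaError("all residual variances are zero (degenerate input)")
    z = np.log(s)
    e = z - digamma(d_g / 2.0) + np.log(d_g / 2.0)
    e_mean = float(np.mean(e))
    n = e.size
    if n < 2:
        return np.inf, float(np.exp(e_mean))
    e_var = float(np.sum((e - e_mean) ** 2) / (n - 1))
    rhs = e_var - float(polygamma(1, d_g / 2.0))
    if rhs <= 0:
        return np.inf, float(np.exp(e_mean))
    d0 = 2.0 * _trigamma_inverse(rhs)
    s0_sq = float(np.exp(e_mean + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_sq


def _model_matrix(
    design: SampleDesign,
    sample_ids,
    covariates: np.ndarray | None,
    paired: bool,
) -> np.ndarray:
    cond = design.condition_indicator(sample_ids)
    cols = [np.ones_like(cond), cond]
    if paired:
        labels = design.pair_labels(sample_ids)
        uniq = sorted({p for p in labels if p})
        # drop one level to keep the matrix full rank
        for level in uniq[:-1]:
            cols.append(np.array([1.0 if p == level else 0.0 for p in labels]))
    if covariates is not None and covariates.size:
        cov = np.asarray(covariates, dtype=float)
        if cov.shape[0] != len(sample_ids):
            raise SchemaError("covariate rows must match the sample count")
        cols.extend(cov[:, j] for j in range(cov.shape[1]))
    return np.column_stack(cols)


def fit_moderated_t(
    matrix: ExpressionMatrix,
    design: SampleDesign,
    covariates: np.ndarray | None = None,
    paired: bool = False,
    prior_df: float | None = None,
    prior_var: float | None = None,
) -> tuple:
    """Fit the moderated t-statistic for every feature.

    Returns ``(results, params)`` where ``results`` is a DataFrame indexed by
    feature id with columns delta, t_mod, p, fdr, direction, and ``params``
    holds the empirical-Bayes hyperparameters.  ``prior_df``/``prior_var``
    override the estimated hyperparameters (prior_df=0 reproduces the
    ordinary equal-variance t-test on the same model).
    """
    sample_ids = matrix.sample_ids
    X = _model_matrix(design, sample_ids, covariates, paired)
    n, p = X.shape
    d_g = n - p
    if d_g <= 0:
        raise SchemaError("no residual degrees of freedom left after the model fit")

    Y = matrix.values.to_numpy(dtype=float)
    variances = Y.var(axis=1)
    keep = variances > 0
    if not keep.all():
        dropped = int((~keep).sum())
        logger.warning("dropping %d zero-variance features", dropped)
    if not keep.any():
        raise SchemaError("all features have zero variance across samples")
    Y = Y[keep]
    feature_ids = [f for f, k in zip(matrix.feature_ids, keep) if k]

    xtx_inv = np.linalg.inv(X.T @ X)
    beta = Y @ X @ xtx_inv  # features x p
    resid = Y - beta @ X.T
    rss = np.sum(resid**2, axis=1)
    s_g_sq = rss / d_g

    if prior_df is None:
        d0, s0_sq = estimate_prior(s_g_sq, d_g)
    else:
        d0 = float(prior_df)
        s0_sq = float(prior_var) if prior_var is not None else float(np.median(s_g_sq))
    params = ModeratedTParams(d0=d0, s0_sq=s0_sq, d_g=float(d_g), s_g_sq=s_g_sq)

    delta = beta[:, 1]  # coefficient of the tumor indicator
    c = np.sqrt(xtx_inv[1, 1])
    s_post = np.sqrt(params.posterior_var())
    with np.errstate(divide="ignore"):
        t_mod = delta / (s_post * c)
    df_total = d_g + d0
    if np.isinf(df_total):
        pvals = 2.0 * stats.norm.sf(np.abs(t_mod))
    else:
        pvals = 2.0 * stats.t.sf(np.abs(t_mod), df_total)
    pvals = np.clip(pvals, P_FLOOR, 1.0)

    direction = np.where(t_mod >= 0, 1, -1)
    results = pd.DataFrame(
        {
            "delta": delta,
            "t_mod": t_mod,
            "p": pvals,
            "fdr": bh_adjust(pvals),
            "direction": direction,
        },
        index=pd.Index(feature_ids, name="feature_id"),
    )
    return results, params


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def call_differential(results: pd.DataFrame, threshold: float) -> pd.DataFrame:
    """Subset of features with fdr <= threshold (inclusive), directions retained."""
    return results[results["fdr"] <= threshold].copy()


def fold_change_filter(results: pd.DataFrame, fc_threshold: float) -> pd.DataFrame:
    """Keep features over/under-expressed by at least ``fc_threshold`` fold.

    delta is on the log2 scale, so the condition is |delta| >= log2(fc).
    """
    cut = np.log2(fc_threshold)
    return results[np.abs(results["delta"]) >= cut].copy()


def estimate_surrogate_variables(
    matrix: ExpressionMatrix,
    design: SampleDesign,
    n_permutations: int = 100,
    alpha: float = 0.10,
    seed: int = 0,
    max_k: int | None = None,
) -> np.ndarray:
    """Estimate surrogate variables from the residual space of the condition fit.

    Residuals of every feature on (intercept, condition) are decomposed by
    SVD; the number of retained right singular vectors k is chosen by
    comparing each component's variance proportion against ``n_permutations``
    row-wise permutations of the residual matrix (significance ``alpha``,
    monotone p-values).  Returns a samples x k orthonormal matrix (k may be 0).
    """
    sample_ids = matrix.sample_ids
    cond = design.condition_indicator(sample_ids)
    n_tumor = int(cond.sum())
    n_normal = len(cond) - n_tumor
    if n_tumor < 3 or n_normal < 3:
        raise SchemaError(
            f"surrogate-variable estimation needs >=3 samples per condition "
            f"(got {n_normal} normal, {n_tumor} tumor)"
        )
    X = np.column_stack([np.ones_like(cond), cond])
    H = X @ np.linalg.inv(X.T @ X) @ X.T
    proj = np.eye(len(cond)) - H

    Y = matrix.values.to_numpy(dtype=float)
    R = Y @ proj
    n_comp = len(cond) - X.shape[1]
    if n_comp < 1 or n_permutations == 0:
        return np.zeros((len(cond), 0))

    sv = np.linalg.svd(R, compute_uv=False)[:n_comp]
    obs_prop = sv**2 / np.sum(sv**2)

    rng = np.random.default_rng(seed)
    exceed = np.zeros(n_comp)
    for _ in range(n_permutations):
        Rp = rng.permuted(R, axis=1) @ proj
        sv_p = np.linalg.svd(Rp, compute_uv=False)[:n_comp]
        prop_p = sv_p**2 / np.sum(sv_p**2)
        exceed += prop_p >= obs_prop
    pvals = (1.0 + exceed) / (n_permutations + 1.0)
    pvals = np.maximum.accumulate(pvals)  # keep p monotone along the spectrum

    k = int(np.argmax(pvals > alpha)) if (pvals > alpha).any() else n_comp
    if max_k is not None:
        k = min(k, max_k)
    if k == 0:
        return np.zeros((len(cond), 0))
    _, _, vt = np.linalg.svd(R, full_matrices=False)
    return vt[:k].T


def write_de_table(results: pd.DataFrame, path) -> None:
    out = results.reset_index()
    out.to_csv(path, sep="\t", index=False)


def read_de_table(path) -> pd.DataFrame:
    tab = pd.read_csv(path, sep="\t")
    return tab.set_index("feature_id")
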