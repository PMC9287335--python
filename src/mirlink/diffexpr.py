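"""Differential expression via the voom / weighted-least-squares /
empirical-Bayes recipe.

The chain is: filter lowly expressed features, TMM normalization, voom
precision weights (a lowess trend of sqrt residual standard deviation
against mean log2 count, inverted to observation-level weights sd^-4),
a weighted group-means linear fit with an explicit treatment-minus-
reference contrast, empirical-Bayes variance moderation (prior degrees of
freedom d0 and prior variance s0^2 estimated by moment-matching on
log sigma^2 with digamma/trigamma corrections), moderated t statistics
with d0 + df degrees of freedom, and Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, polygamma
from statsmodels.nonparametric.smoothers_lowess import lowess

from .correlate import bh_adjust
from .preprocess import NormalizationResult, tmm_factors

__all__ = [
    "DesignSpec",
    "ContrastFit",
    "filter_counts_de",
    "voom_transform",
    "fit_contrast",
    "ebayes_moderate",
    "summarize_de",
    "run_de_pipeline",
]


@dataclass(frozen=True)
class DesignSpec:
    """Sample-to-group assignment plus the contrast of interest."""

    groups: dict[str, str]                 # sample id -> group label
    contrast: tuple[str, str]              # (treatment, reference)

    def validate(self, sample_ids) -> None:
        missing = [s for s in sample_ids if s not in self.groups]
        if missing:
            raise ValueError(f"samples without group label, e.g. {missing[0]!r}")
        labels = pd.Series([self.groups[s] for s in sample_ids])
        counts = labels.value_counts()
        if (counts < 2).any():
            raise ValueError("each group needs >= 2 samples for variance estimation")
        for g in self.contrast:
            if g not in set(labels):
                raise ValueError(f"contrast group {g!r} has no samples")

    def matrix(self, sample_ids) -> tuple[np.ndarray, list[str]]:
        """Group-means design matrix (one indicator column per group)."""
        levels = sorted({self.groups[s] for s in sample_ids})
        X = np.zeros((len(sample_ids), len(levels)))
        for row, s in enumerate(sample_ids):
            X[row, levels.index(self.groups[s])] = 1.0
        return X, levels


def filter_counts_de(
    counts: pd.DataFrame,
    min_count: float = 1.0,
    min_fraction: float = 0.25,
    mode: str = "code",
) -> pd.DataFrame:
    """Keep features detected in enough samples before DE.

    ``mode="code"`` keeps features with count strictly greater than
    ``min_count`` in at least ``ceil(n_samples * min_fraction)`` samples
    (the default, matching ``rowSums(counts > 1) >= ncol/4``); ``"text"``
    keeps features with count >= 1 in strictly more than ``min_fraction``
    of samples.
    """
    n = counts.shape[1]
    if mode == "code":
        keep = (counts > min_count).sum(axis=1) >= math.ceil(n * min_fraction)
    elif mode == "text":
        keep = (counts >= 1).sum(axis=1) > n * min_fraction
    else:
        raise ValueError(f"unknown filter mode {mode!r}")
    return counts.loc[keep]


# ---------------------------------------------------------------------------
# voom
# ---------------------------------------------------------------------------

def _wls_fit(y: np.ndarray, X: np.ndarray, w: np.ndarray | None):
    """Per-feature weighted least squares.

    Returns (coefficients, fitted values, sigma, df_residual,
    covariance-of-coefficients unscaled).  ``y`` is features x samples,
    ``w`` matching weights or None.
    """
    n_feat, n = y.shape
    k = X.shape[1]
    df = n - k
    coef = np.empty((n_feat, k))
    fitted = np.empty_like(y)
    sigma = np.empty(n_feat)
    xtx_inv = np.empty((n_feat, k, k))
    for g in range(n_feat):
        wg = np.ones(n) if w is None else w[g]
        sw = np.sqrt(wg)
        Xw = X * sw[:, None]
        yw = y[g] * sw
        XtX = Xw.T @ Xw
        beta = np.linalg.solve(XtX, Xw.T @ yw)
        coef[g] = beta
        fitted[g] = X @ beta
        resid = yw - Xw @ beta
        rss = float(resid @ resid)
        sigma[g] = math.sqrt(rss / df) if df > 0 else float("nan")
        xtx_inv[g] = np.linalg.inv(XtX)
    return coef, fitted, sigma, df, xtx_inv


def voom_transform(
    counts: pd.DataFrame,
    design: DesignSpec,
    norm: NormalizationResult,
    span: float = 0.5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Voom: log2-CPM values plus observation-level precision weights.

    log2cpm = log2((count + 0.5) / (effective libsize + 1) * 1e6).  The
    mean-variance trend is a lowess fit (span 0.5) of sqrt residual sd
    against average log2 count, evaluated at each observation's fitted
    log2 count via piecewise-linear interpolation with constant
    extrapolation; weights are the predicted sd to the power -4.
    """
    samples = list(counts.columns)
    design.validate(samples)
    X, _levels = design.matrix(samples)
    if counts.shape[1] - X.shape[1] < 1:
        raise ValueError("fewer than 1 residual degree of freedom")

    lib = norm.effective_libsizes.reindex(samples).to_numpy()
    y = np.log2((counts.to_numpy(dtype=float) + 0.5) / (lib + 1.0)[None, :] * 1e6)

    _coef, fitted, sigma, _df, _ = _wls_fit(y, X, None)
    amean = y.mean(axis=1)
    # back-map to the log2-count scale the trend is fitted on
    sx = amean + np.mean(np.log2(lib + 1.0)) - math.log2(1e6)
    sy = np.sqrt(sigma)

    trend = lowess(sy, sx, frac=span, it=3, delta=0.01 * (sx.max() - sx.min()))
    tx, ty = trend[:, 0], trend[:, 1]
    tx, idx = np.unique(tx, return_index=True)
    ty = ty[idx]

    fitted_cpm = 2.0 ** fitted
    fitted_count = 1e-6 * fitted_cpm * (lib + 1.0)[None, :]
    fitted_logcount = np.log2(fitted_count)
    pred_sd = np.interp(fitted_logcount, tx, ty)  # constant extrapolation at ends
    w = pred_sd ** -4
    if not np.all(np.isfinite(w)) or (w <= 0).any():
        raise ValueError("voom produced non-positive or non-finite weights")
    return (
        pd.DataFrame(y, index=counts.index, columns=samples),
        pd.DataFrame(w, index=counts.index, columns=samples),
    )


# ---------------------------------------------------------------------------
# contrast fit + moderation
# ---------------------------------------------------------------------------

@dataclass
class ContrastFit:
    features: pd.Index
    coef: np.ndarray               # contrast coefficient per feature
    stdev_unscaled: np.ndarray     # stderr / sigma
    sigma: np.ndarray
    df_residual: int
    amean: np.ndarray


def fit_contrast(
    log2cpm: pd.DataFrame,
    weights: pd.DataFrame | None,
    design: DesignSpec,
) -> ContrastFit:
    """Weighted group-means fit with a treatment-minus-reference contrast."""
    samples = list(log2cpm.columns)
    design.validate(samples)
    X, levels = design.matrix(samples)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    treat, ref = design.contrast
    c = np.zeros(X.shape[1])
    c[levels.index(treat)] = 1.0
    c[levels.index(ref)] = -1.0

    y = log2cpm.to_numpy(dtype=float)
    w = None if weights is None else weights.reindex(index=log2cpm.index, columns=samples).to_numpy()
    coefs, _fitted, sigma, df, xtx_inv = _wls_fit(y, X, w)
    contrast_coef = coefs @ c
    stdev_unscaled = np.sqrt(np.einsum("i,gij,j->g", c, xtx_inv, c))
    return ContrastFit(
        features=log2cpm.index,
        coef=contrast_coef,
        stdev_unscaled=stdev_unscaled,
        sigma=sigma,
        df_residual=df,
        amean=y.mean(axis=1),
    )


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return float("inf")
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = float(polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(polygamma(2, x))
        x += dif
        if abs(dif / x) < 1e-8:
            break
    return x


def fit_variance_prior(sigma2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-matching estimate of the variance prior (d0, s0^2).

    Matches the mean and variance of log(sigma^2) to a scaled-F model
    using digamma/trigamma corrections.  Returns d0 = inf when the
    observed spread of log variances is no larger than sampling noise
    (e.g. all variances identical).
    """
    s2 = np.asarray(sigma2, dtype=float)
    m = float(np.median(s2))
    if m == 0:
        warnings.warn("more than half of residual variances are exactly zero", stacklevel=2)
        m = 1.0
    s2 = np.maximum(s2, 1e-5 * m)  # keep log finite for exact-zero variances
    z = np.log(s2)
    e = z - digamma(df / 2.0) + math.log(df / 2.0)
    emean = float(np.mean(e))
    evar = float(np.var(e, ddof=1)) - float(polygamma(1, df / 2.0)) if e.size > 1 else 0.0
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s02 = math.exp(emean + float(digamma(d0 / 2.0)) - math.log(d0 / 2.0))
    else:
        # observed spread no larger than sampling noise: common variance,
        # estimated by the pooled mean
        d0 = float("inf")
        s02 = float(np.mean(s2))
    return d0, s02


def ebayes_moderate(
    fit: ContrastFit,
    prior_df: float | None = None,
    prior_var: float | None = None,
) -> pd.DataFrame:
    """Empirical-Bayes moderated t-tests for a fitted contrast.

    The posterior variance is the convex combination
    s~^2 = (d0 s0^2 + df s^2) / (d0 + df); the moderated t uses d0 + df
    degrees of freedom.  With d0 = inf every feature is assigned the
    common prior variance (the identical-variance branch).  ``prior_df``
    and ``prior_var`` override the moment estimates (e.g. to recover
    ordinary t-statistics in the d0 -> 0 limit).
    """
    if len(fit.features) < 10:
        warnings.warn("fewer than 10 features; the variance prior is poorly determined", stacklevel=2)
    df = float(fit.df_residual)
    s2 = fit.sigma**2
    d0, s02 = fit_variance_prior(s2, df)
    if prior_df is not None:
        d0 = prior_df
    if prior_var is not None:
        s02 = prior_var
    # total df capped at the pooled residual df so an infinite prior still
    # yields a proper reference distribution
    df_pooled = df * len(fit.features)
    if math.isinf(d0):
        s2_post = np.full_like(s2, s02)
        df_total = df_pooled
    else:
        s2_post = (d0 * s02 + df * s2) / (d0 + df)
        df_total = min(d0 + df, df_pooled)
    t = fit.coef / (fit.stdev_unscaled * np.sqrt(s2_post))
    p = 2.0 * stats.t.sf(np.abs(t), df=df_total)
    table = pd.DataFrame(
        {
            "logFC": fit.coef,
            "mean_log2cpm": fit.amean,
            "t": t,
            "p": p,
            "p_adj": bh_adjust(p),
            "df_residual": df,
            "prior_df": d0,
            "prior_var": s02,
        },
        index=fit.features,
    )
    return table.rename_axis("transcript")


@dataclass
class DESummary:
    n_sig: int
    n_up: int
    n_down: int
    n_up_lfc: int
    n_down_lfc: int
    asymmetry_chi2: float
    asymmetry_p: float


def summarize_de(table: pd.DataFrame, alpha: float = 0.05, lfc_cut: float = 1.0) -> DESummary:
    """Volcano-style counts plus the down/up asymmetry test.

    The asymmetry test is a goodness-of-fit chi-squared of the
    |logFC| > lfc_cut significant counts [n_down_lfc, n_up_lfc] against a
    50:50 split, without continuity correction; it is skipped (NaN) when
    both counts are zero.
    """
    sig = table[table["p_adj"] < alpha]
    up = sig[sig["logFC"] > 0]
    down = sig[sig["logFC"] < 0]
    n_up_lfc = int((up["logFC"] > lfc_cut).sum())
    n_down_lfc = int((down["logFC"] < -lfc_cut).sum())
    if n_up_lfc + n_down_lfc == 0:
        chi2, p = float("nan"), float("nan")
    else:
        chi2, p = stats.chisquare([n_down_lfc, n_up_lfc])
        chi2, p = float(chi2), float(p)
    return DESummary(
        n_sig=len(sig),
        n_up=len(up),
        n_down=len(down),
        n_up_lfc=n_up_lfc,
        n_down_lfc=n_down_lfc,
        asymmetry_chi2=chi2,
        asymmetry_p=p,
    )


def run_de_pipeline(
    counts: pd.DataFrame,
    design: DesignSpec,
    min_count: float = 1.0,
    min_fraction: float = 0.25,
) -> pd.DataFrame:
    """Filter -> TMM -> voom -> weighted fit -> moderation, in one call."""
    filtered = filter_counts_de(counts, min_count=min_count, min_fraction=min_fraction)
    norm = tmm_factors(filtered)
    y, w = voom_transform(filtered, design, norm)
    fit = fit_contrast(y, w, design)
    return ebayes_moderate(fit)
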