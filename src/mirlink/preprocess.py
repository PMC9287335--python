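"""CPM transformation, expression filters and TMM normalization.

TMM (trimmed mean of M-values) estimates per-sample scaling factors that
correct for composition bias between RNA-seq libraries: for each sample a
log-ratio (M) and log-abundance (A) value is computed per feature against a
reference sample, both tails are trimmed (30% on M, 5% on A) and the factor
is 2 to the precision-weighted mean of the surviving M values.  The
procedure here follows the edgeR defaults (weighted trimming, reference
chosen by upper-quartile proximity, factors rescaled to geometric mean 1).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "NormalizationResult",
    "cpm",
    "log2cpm",
    "filter_min_cpm_all_samples",
    "top_expressed_fraction",
    "tmm_factors",
]


@dataclass
class NormalizationResult:
    tmm_factors: pd.Series
    effective_libsizes: pd.Series
    log2cpm: pd.DataFrame

    def __post_init__(self) -> None:
        f = self.tmm_factors.to_numpy()
        if (f <= 0).any():
            raise ValueError("TMM factors must be positive")


def _counts_frame(counts) -> pd.DataFrame:
    # accept either an ExpressionMatrix or a bare DataFrame
    return counts.counts if hasattr(counts, "counts") else counts


def cpm(counts, prior_count: float = 0.0) -> pd.DataFrame:
    """Counts per million: ``(count + prior) / (libsize + 2*prior) * 1e6``.

    ``prior_count=0`` is used for expression filtering; voom's internal
    transform uses 0.5 (giving the familiar +0.5 / +1 offsets).
    """
    df = _counts_frame(counts)
    libsize = df.sum(axis=0)
    zero = libsize[libsize <= 0]
    if len(zero):
        raise ValueError(f"zero library size for sample {zero.index[0]!r}")
    return (df + prior_count) / (libsize + 2.0 * prior_count) * 1e6


def log2cpm(counts, prior_count: float = 0.5) -> pd.DataFrame:
    """log2 of prior-offset CPM; the default prior matches voom's 0.5."""
    return np.log2(cpm(counts, prior_count=prior_count))


def filter_min_cpm_all_samples(counts, min_cpm: float = 1.0) -> pd.DataFrame:
    """Keep features with CPM strictly above ``min_cpm`` in every sample."""
    df = _counts_frame(counts)
    keep = (cpm(df, prior_count=0.0) > min_cpm).all(axis=1)
    if not keep.any():
        warnings.warn("expression filter removed every feature", stacklevel=2)
    return df.loc[keep]


def top_expressed_fraction(counts, fraction: float) -> pd.DataFrame:
    """Keep the ``fraction`` highest-expressed features.

    Features are ranked by mean log2-CPM (prior 0.5) descending;
    ``ceil(fraction * n)`` survive, ties broken by lexical feature id.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    df = _counts_frame(counts)
    mean_expr = log2cpm(df, prior_count=0.5).mean(axis=1)
    n_keep = math.ceil(fraction * len(df))
    order = sorted(df.index, key=lambda fid: (-mean_expr[fid], fid))
    keep = set(order[:n_keep])
    return df.loc[[fid for fid in df.index if fid in keep]]


# ---------------------------------------------------------------------------
# TMM
# ---------------------------------------------------------------------------

def _quantile_factor(df: pd.DataFrame, libsize: pd.Series, p: float = 0.75) -> pd.Series:
    return df.div(libsize, axis=1).quantile(p, axis=0)


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    lib_obs: float,
    lib_ref: float,
    logratio_trim: float = 0.3,
    sum_trim: float = 0.05,
) -> float:
    """Log2 TMM factor of one sample against the reference column."""
    with np.errstate(divide="ignore", invalid="ignore"):
        p_obs = obs / lib_obs
        p_ref = ref / lib_ref
        log_r = np.log2(p_obs / p_ref)            # M values
        abs_e = (np.log2(p_obs) + np.log2(p_ref)) / 2.0  # A values
        # asymptotic variance of M via the delta method (binomial sampling)
        v = (lib_obs - obs) / (lib_obs * obs) + (lib_ref - ref) / (lib_ref * ref)

    finite = np.isfinite(log_r) & np.isfinite(abs_e) & (abs_e > -1e10)
    log_r, abs_e, v = log_r[finite], abs_e[finite], v[finite]
    if log_r.size == 0:
        return 0.0
    if np.max(np.abs(log_r)) < 1e-6:
        return 0.0

    n = log_r.size
    lo_l = math.floor(n * logratio_trim) + 1
    hi_l = n + 1 - lo_l
    lo_s = math.floor(n * sum_trim) + 1
    hi_s = n + 1 - lo_s
    rank_r = rankdata(log_r)
    rank_e = rankdata(abs_e)
    keep = (rank_r >= lo_l) & (rank_r <= hi_l) & (rank_e >= lo_s) & (rank_e <= hi_s)
    if not keep.any():
        return 0.0
    f = np.sum(log_r[keep] / v[keep]) / np.sum(1.0 / v[keep])
    return 0.0 if not np.isfinite(f) else float(f)


def tmm_factors(counts, ref_sample: str | None = None) -> NormalizationResult:
    """edgeR-default TMM normalization factors.

    The reference is the sample whose upper quartile of CPM is closest to
    the mean upper quartile (unless ``ref_sample`` is given); each sample's
    factor is 2 to the doubly-trimmed, inverse-variance-weighted mean of
    its M values against the reference, and the factors are rescaled to
    geometric mean 1.
    """
    df = _counts_frame(counts).astype(float)
    if df.shape[1] < 2:
        raise ValueError("TMM requires at least 2 samples")
    libsize = df.sum(axis=0)
    if (libsize <= 0).any():
        raise ValueError(f"zero library size for sample {libsize.index[libsize <= 0][0]!r}")

    if ref_sample is None:
        f75 = _quantile_factor(df, libsize)
        if f75.median() < 1e-20:
            warnings.warn("majority of features are zero at the upper quartile", stacklevel=2)
            ref_sample = libsize.div(libsize.sum()).idxmax()
        else:
            ref_sample = (f75 - f75.mean()).abs().idxmin()
    elif ref_sample not in df.columns:
        raise KeyError(f"reference sample {ref_sample!r} not in matrix")

    ref = df[ref_sample].to_numpy()
    lib_ref = float(libsize[ref_sample])
    log_factors = {}
    for sample in df.columns:
        obs = df[sample].to_numpy()
        both_positive = (obs > 0) & (ref > 0)
        if not both_positive.any():
            warnings.warn(
                f"sample {sample!r} shares no positive feature with the reference; factor 1",
                stacklevel=2,
            )
            log_factors[sample] = 0.0
            continue
        log_factors[sample] = _tmm_pair(obs, ref, float(libsize[sample]), lib_ref)

    factors = pd.Series({s: 2.0 ** f for s, f in log_factors.items()}, name="tmm_factor")
    factors = factors.reindex(df.columns)
    factors /= np.exp(np.mean(np.log(factors)))
    effective = libsize * factors
    lcpm = np.log2((df + 0.5).div(effective + 1.0, axis=1) * 1e6)
    return NormalizationResult(tmm_factors=factors, effective_libsizes=effective, log2cpm=lcpm)
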