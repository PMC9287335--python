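"""All-pairs Pearson correlation between miRNA and mRNA expression.

Per pair the coefficient r is tested via the exact t transform
``t = r * sqrt((n-2) / (1 - r^2))`` against a t distribution with n-2
degrees of freedom (two-sided), and Benjamini-Hochberg FDR adjustment is
applied jointly across every testable pair in the table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .ioformats import MirnaLocusAnnotation

__all__ = [
    "CorrelationCensus",
    "LocusShiftResult",
    "all_pairs_pearson",
    "bh_adjust",
    "census",
    "stratify_by_locus",
]


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def all_pairs_pearson(
    mirna_expr: pd.DataFrame, mrna_expr: pd.DataFrame
) -> pd.DataFrame:
    """Pearson r, raw p and BH-adjusted p for every miRNA x mRNA pair.

    Both inputs are feature x sample matrices of (log-scale) expression
    over the same samples in the same order.  Zero-variance features yield
    NaN rows that are excluded from the BH family size.
    """
    if list(mirna_expr.columns) != list(mrna_expr.columns):
        raise ValueError("miRNA and mRNA matrices must share the same samples in order")
    n = mirna_expr.shape[1]
    if n < 3:
        raise ValueError("at least 3 samples are required")

    A = mirna_expr.to_numpy(dtype=float)
    B = mrna_expr.to_numpy(dtype=float)
    A = A - A.mean(axis=1, keepdims=True)
    B = B - B.mean(axis=1, keepdims=True)
    a_norm = np.sqrt((A**2).sum(axis=1))
    b_norm = np.sqrt((B**2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (A @ B.T) / np.outer(a_norm, b_norm)
    r[np.outer(a_norm == 0, np.ones(len(b_norm), dtype=bool))] = np.nan
    r[np.outer(np.ones(len(a_norm), dtype=bool), b_norm == 0)] = np.nan
    np.clip(r, -1.0, 1.0, out=r)

    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.isinf(t)] = 0.0  # |r| == 1 exactly

    mir_ids = np.repeat(mirna_expr.index.to_numpy(), mrna_expr.shape[0])
    gene_ids = np.tile(mrna_expr.index.to_numpy(), mirna_expr.shape[0])
    table = pd.DataFrame(
        {"mirna_id": mir_ids, "mrna_id": gene_ids, "r": r.ravel(), "p": p.ravel()}
    )
    table["p_adj"] = np.nan
    finite = np.isfinite(table["p"].to_numpy())
    if finite.any():
        table.loc[finite, "p_adj"] = bh_adjust(table.loc[finite, "p"].to_numpy())
    return table


@dataclass
class CorrelationCensus:
    n_pairs: int
    n_sig_pos: int
    n_sig_neg: int
    pct_sig_pos: float
    pct_sig_neg: float
    mean_r_sig_pos: float
    mean_r_sig_neg: float


def census(table: pd.DataFrame, alpha: float = 0.05) -> CorrelationCensus:
    """Count and summarize significantly correlated pairs.

    Percentages are relative to all testable (finite-p) pairs; means are
    over the significant positive / negative subsets and NaN when a subset
    is empty.
    """
    finite = table[np.isfinite(table["p"])]
    n_pairs = len(finite)
    sig = finite[finite["p_adj"] < alpha]
    pos = sig[sig["r"] > 0]
    neg = sig[sig["r"] < 0]
    return CorrelationCensus(
        n_pairs=n_pairs,
        n_sig_pos=len(pos),
        n_sig_neg=len(neg),
        pct_sig_pos=100.0 * len(pos) / n_pairs if n_pairs else float("nan"),
        pct_sig_neg=100.0 * len(neg) / n_pairs if n_pairs else float("nan"),
        mean_r_sig_pos=float(pos["r"].mean()) if len(pos) else float("nan"),
        mean_r_sig_neg=float(neg["r"].mean()) if len(neg) else float("nan"),
    )


@dataclass
class LocusShiftResult:
    intragenic_r: np.ndarray
    intergenic_r: np.ndarray
    ks_D: float
    ks_p: float

    @property
    def mean_shift(self) -> float:
        return float(np.mean(self.intragenic_r) - np.mean(self.intergenic_r))


def stratify_by_locus(
    table: pd.DataFrame,
    annotations: list[MirnaLocusAnnotation],
    mode: str = "host_pair_only",
) -> LocusShiftResult:
    """Compare correlation coefficients of intragenic vs intergenic miRNAs.

    ``host_pair_only`` takes each intragenic miRNA's r with its own host
    gene; ``all_pairs`` takes all r of intragenic miRNAs.  Either sample
    is tested against all r of intergenic miRNAs with a one-sided KS test
    for the intragenic sample being stochastically larger (more positive),
    the signature of host/miRNA co-transcription.
    """
    if mode not in ("host_pair_only", "all_pairs"):
        raise ValueError(f"unknown mode {mode!r}")
    from .targets import ks_one_sided  # local import to avoid a cycle

    host_of = {a.mirna_id: a.host_gene_id for a in annotations if a.host_gene_id}
    intergenic = {a.mirna_id for a in annotations if a.host_gene_id is None}
    if not host_of:
        raise ValueError("no intragenic miRNAs in the annotation")
    covered = {a.mirna_id for a in annotations}
    missing = set(table["mirna_id"].unique()) - covered
    if missing:
        raise ValueError(f"annotation does not cover miRNAs, e.g. {sorted(missing)[0]!r}")

    finite = table[np.isfinite(table["r"])]
    if mode == "host_pair_only":
        pair_key = finite["mirna_id"].map(host_of)
        intra = finite.loc[pair_key.notna() & (pair_key == finite["mrna_id"]), "r"]
    else:
        intra = finite.loc[finite["mirna_id"].isin(host_of), "r"]
    inter = finite.loc[finite["mirna_id"].isin(intergenic), "r"]
    if intra.empty or inter.empty:
        raise ValueError("empty intragenic or intergenic correlation sample")
    D, p = ks_one_sided(intra.to_numpy(), inter.to_numpy(), alternative="a_above")
    return LocusShiftResult(
        intragenic_r=intra.to_numpy(), intergenic_r=inter.to_numpy(), ks_D=D, ks_p=p
    )
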