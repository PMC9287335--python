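"""Concordance between patient correlations and transfection log fold
changes.

Among transcripts that respond significantly in a mimic-transfection
experiment AND carry a predicted site for the transfected miRNA, the
patient-cohort correlation coefficients are split at their 20th/80th
percentiles ("lower Q20" = most negative coefficients) and the
transfection logFC of the two groups is compared with a one-sided
two-sample t-test: true targeting predicts the lower-Q20 group to be the
more down-regulated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["ConcordanceResult", "q20_concordance", "top_pair_selection"]


@dataclass
class ConcordanceResult:
    mirna_id: str
    n_lower_q20: int
    n_higher_q20: int
    mean_logFC_lower: float
    mean_logFC_higher: float
    t_stat: float
    p_one_sided: float


def _candidates(
    de: pd.DataFrame,
    corr: pd.DataFrame,
    grouping: pd.DataFrame,
    mirna_id: str,
    alpha: float,
) -> pd.DataFrame:
    predicted = set(grouping.loc[grouping["mirna_id"] == mirna_id, "mrna_id"])
    sub_corr = corr[(corr["mirna_id"] == mirna_id) & np.isfinite(corr["r"])]
    r_of = sub_corr.set_index("mrna_id")["r"]
    p_of = sub_corr.set_index("mrna_id")["p"]
    sig = de[de["p_adj"] < alpha]
    rows = []
    for gene in sig.index:
        if gene in predicted and gene in r_of.index:
            rows.append(
                {
                    "mrna_id": gene,
                    "r": float(r_of[gene]),
                    "p_corr": float(p_of[gene]),
                    "logFC": float(sig.loc[gene, "logFC"]),
                    "p_de": float(sig.loc[gene, "p"]),
                }
            )
    return pd.DataFrame(rows)


def q20_concordance(
    de: pd.DataFrame,
    corr: pd.DataFrame,
    grouping: pd.DataFrame,
    mirna_id: str,
    alpha: float = 0.05,
    q: float = 0.2,
    equal_var: bool = False,
) -> ConcordanceResult:
    """Quantile-group concordance test for one transfected miRNA.

    Candidate transcripts are DE-significant predicted targets; the lower
    group holds candidates with r at or below the q-quantile of candidate
    r values, the higher group those at or above the (1-q)-quantile
    (linear-interpolation quantiles).  Welch's one-sided t-test (pooled if
    ``equal_var``) asks whether the lower group's logFC mean is smaller.
    """
    if not 0 < q < 0.5:
        raise ValueError("q must be in (0, 0.5)")
    cand = _candidates(de, corr, grouping, mirna_id, alpha)
    if len(cand) < 5:
        raise ValueError(
            f"only {len(cand)} significant predicted targets for {mirna_id}; "
            "too few for quantile grouping"
        )
    lo_cut = float(np.quantile(cand["r"], q))
    hi_cut = float(np.quantile(cand["r"], 1.0 - q))
    if lo_cut == hi_cut:
        raise ValueError("degenerate correlation distribution: quantile cutpoints coincide")
    lower = cand[cand["r"] <= lo_cut]
    higher = cand[cand["r"] >= hi_cut]
    if len(lower) < 2 or len(higher) < 2:
        raise ValueError("quantile groups need >= 2 members each")
    if np.var(lower["logFC"]) == 0 and np.var(higher["logFC"]) == 0 and (
        lower["logFC"].mean() == higher["logFC"].mean()
    ):
        t, p = 0.0, 0.5  # no shift and no spread: maximally uninformative
    else:
        t, p = stats.ttest_ind(
            lower["logFC"], higher["logFC"], equal_var=equal_var, alternative="less"
        )
    return ConcordanceResult(
        mirna_id=mirna_id,
        n_lower_q20=len(lower),
        n_higher_q20=len(higher),
        mean_logFC_lower=float(lower["logFC"].mean()),
        mean_logFC_higher=float(higher["logFC"].mean()),
        t_stat=float(t),
        p_one_sided=float(p),
    )


def top_pair_selection(
    de: pd.DataFrame,
    corr: pd.DataFrame,
    grouping: pd.DataFrame,
    mirna_id: str,
    k: int = 4,
    prefilter: int = 25,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Two-stage pick of the strongest concordant miRNA-target pairs.

    Stage 1 keeps the ``prefilter`` most negatively correlated candidate
    pairs from the patient data; stage 2 re-ranks those by transfection
    p-value ascending and returns the top ``k``.
    """
    cand = _candidates(de, corr, grouping, mirna_id, alpha)
    if cand.empty:
        raise ValueError(f"no significant predicted targets for {mirna_id}")
    if len(cand) < k:
        warnings.warn(
            f"only {len(cand)} candidates for {mirna_id}; returning all", stacklevel=2
        )
    stage1 = cand.sort_values(["r", "mrna_id"]).head(prefilter)
    stage2 = stage1.sort_values(["p_de", "mrna_id"]).head(k)
    out = stage2.reset_index(drop=True)
    out.insert(0, "mirna_id", mirna_id)
    return out
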