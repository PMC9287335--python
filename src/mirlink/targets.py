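"""Target grouping and ECDF-shift testing.

Predicted targets are grouped by prediction source and TargetScan seed-
match site type (8mer, 7mer-m8, 7mer-1a — 8mer strongest), and the
distribution of a per-gene statistic (correlation coefficient with a
miRNA, or transfection log fold change) is compared between targets and
genes without any predicted site using a one-sided two-sample
Kolmogorov-Smirnov test: D+ = sup_x (F_target(x) - F_nontarget(x)) with
the asymptotic tail p = exp(-2 D^2 n_eff), n_eff = n_a n_b / (n_a + n_b).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "TARGET_GROUPS",
    "ShiftTestResult",
    "build_grouping",
    "intersect_predictions",
    "ks_one_sided",
    "ecdf_coordinates",
    "target_shift_analysis",
    "global_target_shift",
]

#: Analysis groups, each tested independently against the no-prediction
#: background; a pair may belong to several groups at once.
TARGET_GROUPS = ("8mer", "7mer-m8", "7mer-1a", "mirdb", "mirtarbase")


def build_grouping(predictions: pd.DataFrame) -> pd.DataFrame:
    """Map a filtered prediction table to (mirna_id, mrna_id, group) rows.

    TargetScan records map to their site-type group, miRDB records to
    "mirdb" and miRTarBase records to "mirtarbase".
    """
    rows = []
    for mir, gene, source, _score, site in predictions[
        ["mirna_id", "mrna_id", "source", "score", "site_type"]
    ].itertuples(index=False):
        group = site if source == "targetscan" else source
        rows.append((mir, gene, group))
    df = pd.DataFrame(rows, columns=["mirna_id", "mrna_id", "group"])
    bad = ~df["group"].isin(TARGET_GROUPS)
    if bad.any():
        raise ValueError(f"unmappable prediction group {df.loc[bad, 'group'].iloc[0]!r}")
    return df.drop_duplicates().reset_index(drop=True)


def intersect_predictions(predictions: pd.DataFrame) -> set[tuple[str, str]]:
    """Pairs predicted by both TargetScan and miRDB (post score filtering)."""
    ts = predictions[predictions["source"] == "targetscan"]
    db = predictions[predictions["source"] == "mirdb"]
    if ts.empty or db.empty:
        raise ValueError("both targetscan and mirdb records are required")
    ts_pairs = set(zip(ts["mirna_id"], ts["mrna_id"]))
    db_pairs = set(zip(db["mirna_id"], db["mrna_id"]))
    common = ts_pairs & db_pairs
    if not common:
        warnings.warn("TargetScan and miRDB predictions are disjoint", stacklevel=2)
    return common


# ---------------------------------------------------------------------------
# one-sided KS
# ---------------------------------------------------------------------------

def _ecdf_at(sample: np.ndarray, x: np.ndarray) -> np.ndarray:
    # right-continuous step ECDF
    return np.searchsorted(sample, x, side="right") / sample.size


def ks_one_sided(sample_a, sample_b, alternative: str = "a_below") -> tuple[float, float]:
    """One-sided two-sample KS statistic and asymptotic p-value.

    ``a_below`` tests that ``sample_a`` is stochastically smaller than
    ``sample_b`` (its ECDF lies above): D = sup_x (F_a(x) - F_b(x)).
    ``a_above`` tests the reverse.  p = exp(-2 D^2 n_eff), capped at 1.
    """
    a = np.sort(np.asarray(sample_a, dtype=float))
    b = np.sort(np.asarray(sample_b, dtype=float))
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    if alternative not in ("a_below", "a_above"):
        raise ValueError(f"unknown alternative {alternative!r}")
    grid = np.concatenate([a, b])
    diff = _ecdf_at(a, grid) - _ecdf_at(b, grid)
    D = float(np.max(diff)) if alternative == "a_below" else float(np.max(-diff))
    D = max(D, 0.0)
    n_eff = a.size * b.size / (a.size + b.size)
    p = float(min(1.0, np.exp(-2.0 * D * D * n_eff)))
    return D, p


def ecdf_coordinates(sample) -> pd.DataFrame:
    """Sorted values with ECDF heights, ready for step plotting."""
    x = np.sort(np.asarray(sample, dtype=float))
    return pd.DataFrame({"value": x, "ecdf": np.arange(1, x.size + 1) / x.size})


# ---------------------------------------------------------------------------
# shift analyses
# ---------------------------------------------------------------------------

@dataclass
class ShiftTestResult:
    group: str
    n_target: int
    n_nontarget: int
    ks_D: float
    ks_p: float
    mean_shift: float


def _shift_row(group: str, target: np.ndarray, nontarget: np.ndarray, alternative: str) -> ShiftTestResult:
    D, p = ks_one_sided(target, nontarget, alternative=alternative)
    return ShiftTestResult(
        group=group,
        n_target=int(target.size),
        n_nontarget=int(nontarget.size),
        ks_D=D,
        ks_p=p,
        mean_shift=float(np.mean(target) - np.mean(nontarget)),
    )


def target_shift_analysis(
    values: pd.Series,
    grouping: pd.DataFrame,
    mirna_id: str,
    alternative: str = "a_below",
) -> tuple[list[ShiftTestResult], dict[str, pd.DataFrame]]:
    """Per-group ECDF shift of a per-mRNA statistic for one miRNA.

    ``values`` maps mRNA id to the statistic (correlation r with
    ``mirna_id``, or transfection logFC).  For each group the member
    mRNAs' values are tested against mRNAs with no predicted site from any
    source, one-sided for the targets being shifted negative.  Returns the
    test results and per-group ECDF coordinates (group "none" included)
    for cumulative-distribution plotting.
    """
    sub = grouping[grouping["mirna_id"] == mirna_id]
    predicted_any = set(sub["mrna_id"])
    background = values.index.difference(predicted_any)
    nontarget = values.loc[background].to_numpy()
    if nontarget.size == 0:
        raise ValueError("no background mRNAs without predictions remain")

    results = []
    curves = {"none": ecdf_coordinates(nontarget)}
    for group in TARGET_GROUPS:
        members = sub.loc[sub["group"] == group, "mrna_id"]
        members = values.index.intersection(members)
        if len(members) == 0:
            warnings.warn(f"group {group!r} has no members for {mirna_id}", stacklevel=2)
            results.append(ShiftTestResult(group, 0, int(nontarget.size), float("nan"), float("nan"), float("nan")))
            continue
        target = values.loc[members].to_numpy()
        results.append(_shift_row(group, target, nontarget, alternative))
        curves[group] = ecdf_coordinates(target)
    return results, curves


def global_target_shift(
    corr: pd.DataFrame,
    pair_sets: dict[str, set[tuple[str, str]]],
    alternative: str = "a_below",
) -> list[ShiftTestResult]:
    """Pooled ECDF shift of correlation coefficients per prediction source.

    For each source, the r values of its predicted pairs are tested
    against the r of pairs predicted by no source at all.
    """
    finite = corr[np.isfinite(corr["r"])]
    pairs = list(zip(finite["mirna_id"], finite["mrna_id"]))
    r = finite["r"].to_numpy()
    any_predicted = set().union(*pair_sets.values()) if pair_sets else set()
    in_any = np.fromiter((p in any_predicted for p in pairs), bool, len(pairs))
    nontarget = r[~in_any]
    if nontarget.size == 0:
        raise ValueError("every pair is predicted; no non-target background")

    results = []
    for source in sorted(pair_sets):
        pset = pair_sets[source]
        mask = np.fromiter((p in pset for p in pairs), bool, len(pairs))
        if not mask.any():
            warnings.warn(f"source {source!r} predicts no testable pair", stacklevel=2)
            results.append(ShiftTestResult(source, 0, int(nontarget.size), float("nan"), float("nan"), float("nan")))
            continue
        results.append(_shift_row(source, r[mask], nontarget, alternative))
    return results


def shift_results_frame(results: list[ShiftTestResult]) -> pd.DataFrame:
    return pd.DataFrame([vars(x) for x in results])
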