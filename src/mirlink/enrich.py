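"""Gene-list enrichment machinery.

Two flavours: a 2x2 chi-squared test (Yates-corrected) for enrichment of a
disease gene list in correlation-decile gene sets, and hypergeometric
over-representation analysis (ORA) against user-supplied term -> gene-set
collections with GeneRatio/Count reporting, where GeneRatio = k/n with
k the overlap of the input list with a term's set and n the overlap of
the input list with the union of all sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .correlate import bh_adjust

__all__ = [
    "EnrichmentResult",
    "decile_enrichment",
    "ora",
    "select_go_input",
    "read_gmt",
    "write_gmt",
]


# ---------------------------------------------------------------------------
# correlation-decile chi-squared enrichment
# ---------------------------------------------------------------------------

def _per_gene_extremes(corr: pd.DataFrame) -> pd.DataFrame:
    finite = corr[np.isfinite(corr["r"])]
    g = finite.groupby("mrna_id")["r"]
    return pd.DataFrame({"max_r": g.max(), "min_r": g.min()})


def decile_enrichment(
    corr: pd.DataFrame,
    gene_list,
    decile_fraction: float = 0.1,
    contrast: str = "vs_negative_decile",
    rng_seed: int = 0,
) -> tuple[np.ndarray, float, float]:
    """Chi-squared enrichment of a gene list in the top positive decile.

    Each mRNA is summarized by its most positive r across miRNAs (most
    negative for the mirrored decile); the top ``decile_fraction`` genes
    form the test set and are contrasted against either the mirrored
    negative decile or an equal-size seeded uniform draw of the remaining
    genes.  Returns (2x2 table, chi2, p) with Yates continuity correction.
    """
    if not 0 < decile_fraction <= 0.5:
        raise ValueError("decile_fraction must be in (0, 0.5]")
    if contrast not in ("vs_negative_decile", "vs_random"):
        raise ValueError(f"unknown contrast {contrast!r}")
    genes = _per_gene_extremes(corr)
    n_set = int(np.ceil(decile_fraction * len(genes)))
    if n_set < 5:
        raise ValueError("decile smaller than 5 genes; enrichment is meaningless")
    # ties broken lexically for determinism
    top_pos = genes.assign(_id=genes.index).sort_values(
        ["max_r", "_id"], ascending=[False, True]
    ).index[:n_set]

    if contrast == "vs_negative_decile":
        other = genes.assign(_id=genes.index).sort_values(
            ["min_r", "_id"], ascending=[True, True]
        ).index[:n_set]
    else:
        pool = genes.index.difference(top_pos)
        rng = np.random.default_rng(rng_seed)
        other = pd.Index(rng.choice(pool.to_numpy(), size=min(n_set, len(pool)), replace=False))

    listed = set(gene_list)
    table = np.array(
        [
            [sum(g in listed for g in top_pos), sum(g not in listed for g in top_pos)],
            [sum(g in listed for g in other), sum(g not in listed for g in other)],
        ]
    )
    chi2, p = chi2_yates(table)
    return table, chi2, p


def chi2_yates(table: np.ndarray) -> tuple[float, float]:
    """Pearson chi-squared on a 2x2 table with Yates continuity correction."""
    table = np.asarray(table, dtype=float)
    if table.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        # a zero margin carries no information about association
        warnings.warn("degenerate 2x2 table with a zero margin", stacklevel=2)
        return 0.0, 1.0
    chi2, p, _dof, _exp = stats.chi2_contingency(table, correction=True)
    return float(chi2), float(p)


# ---------------------------------------------------------------------------
# hypergeometric over-representation analysis
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentResult:
    term_id: str
    k: int                 # input genes in this term's set ("Count")
    n: int                 # input genes in the union of all sets
    gene_ratio: float      # k / n
    p: float
    p_adj: float = float("nan")


def ora(
    input_genes,
    gene_sets: dict[str, set[str]],
    background_genes,
) -> list[EnrichmentResult]:
    """Hypergeometric over-representation of an input list in gene sets.

    Per term: population = background, successes = term set intersected
    with background, draws = input list; p = P(X >= k), upper tail only
    (enrichment).  BH adjustment across terms.
    """
    background = set(background_genes)
    input_set = set(input_genes)
    if not background or not input_set:
        raise ValueError("background and input gene lists must be nonempty")
    if not input_set <= background:
        stray = sorted(input_set - background)[0]
        raise ValueError(f"input gene {stray!r} is not in the background")

    union = set().union(*gene_sets.values()) if gene_sets else set()
    n = len(input_set & union & background)

    results = []
    M = len(background)
    N = len(input_set)
    for term in sorted(gene_sets):
        term_set = gene_sets[term] & background
        k = len(input_set & term_set)
        K = len(term_set)
        p = float(stats.hypergeom.sf(k - 1, M, K, N))
        results.append(
            EnrichmentResult(
                term_id=term,
                k=k,
                n=n,
                gene_ratio=k / n if n else float("nan"),
                p=min(1.0, p),
            )
        )
    if results:
        adj = bh_adjust([x.p for x in results])
        for res, pa in zip(results, adj):
            res.p_adj = float(pa)
    return results


def enrichment_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    df = pd.DataFrame([vars(x) for x in results])
    return df.rename(columns={"k": "Count", "gene_ratio": "GeneRatio", "p_adj": "Adj.p-value"})


# ---------------------------------------------------------------------------
# GO-input gene selection
# ---------------------------------------------------------------------------

def select_go_input(
    corr: pd.DataFrame,
    predictions: pd.DataFrame,
    mirdb_min: float = 92.8,
    context_max: float = -0.366,
    r_max: float = -0.1,
) -> dict[str, list[str]]:
    """Per-source gene lists for ontology analysis.

    A pair qualifies for the miRDB list when its miRDB score exceeds
    ``mirdb_min``, for the TargetScan list when its context score is below
    ``context_max``; in both cases the pair's patient correlation must be
    below ``r_max`` (a clearly negative in-vivo correlation).  Returns one
    sorted unique gene list per source.
    """
    r_of = dict(zip(zip(corr["mirna_id"], corr["mrna_id"]), corr["r"]))
    lists: dict[str, list[str]] = {}
    for source, score_pass in (
        ("mirdb", lambda s: s > mirdb_min),
        ("targetscan", lambda s: s < context_max),
    ):
        sub = predictions[predictions["source"] == source]
        genes = set()
        for mir, gene, score in sub[["mirna_id", "mrna_id", "score"]].itertuples(index=False):
            r = r_of.get((mir, gene))
            if r is not None and np.isfinite(r) and score_pass(score) and r < r_max:
                genes.add(gene)
        lists[source] = sorted(genes)
    return lists


# ---------------------------------------------------------------------------
# GMT reader/writer
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT file (term, description, gene, gene, ...) per line."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line {lineno}: fewer than 3 fields")
            term = fields[0]
            if term in sets:
                warnings.warn(f"duplicate GMT term {term!r}; records merged", stacklevel=2)
                sets[term] |= set(fields[2:])
            else:
                sets[term] = set(fields[2:])
    return sets


def write_gmt(gene_sets: dict[str, set[str]], path: str | Path, description: str = "synthetic") -> None:
    with open(path, "w") as fh:
        for term in sorted(gene_sets):
            fh.write("\t".join([term, description, *sorted(gene_sets[term])]) + "\n")
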