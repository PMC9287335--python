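"""Synthetic paired miRNA/mRNA cohorts with recorded ground truth.

The generator emulates the statistical structure a correlation-based
target-inference analysis assumes: per-sample library sizes, per-feature
log2 baselines, graded negative miRNA-to-target couplings by seed-match
site type, positive intragenic host-gene couplings, negative-binomial
counting noise, plus matched prediction tables, genomic annotation, a
disease gene list and a 3-vs-3 mimic/negative-control transfection
experiment.  Every coupling is recorded in a truth table so downstream
recovery can be scored.

Generative model, in full.  For sample :math:`s` draw library sizes
:math:`L^{mir}_s, L^{mrna}_s \\sim \\mathrm{LogNormal}(\\mu_L, \\sigma_L)`.
Per miRNA :math:`i` draw a baseline :math:`a_i \\sim N(5, 2^2)` (log2
units) and latent per-sample abundance :math:`z_{is} = a_i + e_{is}`,
:math:`e_{is} \\sim N(0, 1)`.  An intragenic miRNA with host :math:`h`
additionally receives :math:`\\gamma\\,(m_{hs} - b_h)` (host drives the
miRNA, co-transcription).  Per mRNA :math:`j` draw
:math:`b_j \\sim N(4, 2^2)` and set

.. math::

    m_{js} = b_j + \\sum_{i:(i,j)\\in\\text{pairs}} \\beta_{ij}(z_{is}-a_i)
             + \\varepsilon_{js},\\qquad \\varepsilon_{js} \\sim N(0,\\tau^2)

with :math:`\\beta_{ij} \\le 0` graded by site type.  Counts are drawn
negative-binomially with mean :math:`L_s\\,2^{x_s}/\\sum 2^{x}` (per-sample
softmax over features) and variance :math:`\\mu + \\phi\\mu^2`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .ioformats import ExpressionMatrix, PREDICTION_COLUMNS

__all__ = [
    "CohortConfig",
    "TruthTable",
    "TRUTH_SITE_TYPES",
    "generate_paired_cohort",
    "generate_prediction_tables",
    "generate_transfection_counts",
    "generate_annotation",
    "make_toy_gene_sets",
]

#: Site-type classes a true coupling can carry.  The first three are the
#: TargetScan seed-match classes (8mer strongest); "miRDB_only" couplings
#: are predicted only by the miRDB-style table and "validated" couplings
#: additionally appear in the miRTarBase-style table.
TRUTH_SITE_TYPES = ("8mer", "7mer-m8", "7mer-1a", "miRDB_only", "validated")
TARGETSCAN_SITES = ("8mer", "7mer-m8", "7mer-1a")


def _default_beta() -> dict[str, float]:
    return {
        "8mer": -0.6,
        "7mer-m8": -0.4,
        "7mer-1a": -0.2,
        "miRDB_only": -0.4,
        "validated": -0.5,
    }


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of the synthetic paired cohort.

    Defaults emulate an 86-sample myeloma-like cohort with 161
    well-expressed miRNAs and a scaled-down 2000-mRNA transcriptome,
    sequenced to roughly ten million counted reads per library.
    """

    n_samples: int = 86
    n_mirna: int = 161
    n_mrna: int = 2000
    #: fraction of the n_mirna x n_mrna pair grid carrying a true coupling
    #: (matches the ~3% density of common predicted pairs in a dual-tool
    #: TargetScan/miRDB screen of a well-expressed transcriptome)
    frac_true_pairs: float = 0.03
    beta_by_site: Mapping[str, float] = field(default_factory=_default_beta)
    #: per-pair multiplicative spread of the coupling coefficient
    #: (site efficacy varies between pairs even within a site class)
    beta_jitter: tuple[float, float] = (0.5, 1.5)
    n_intragenic: int = 15
    gamma_host: float = 1.0
    libsize_meanlog: float = math.log(1e7)
    libsize_sdlog: float = 0.3
    dispersion: float = 0.1
    noise_sd: float = 1.0
    #: residual log2 noise between cell-line replicates in the
    #: transfection experiment (far below patient-to-patient variation)
    transfection_noise_sd: float = 0.25
    #: NB dispersion between cell-line replicates (lower than the
    #: patient-cohort dispersion, as for technical-grade replicates)
    transfection_dispersion: float = 0.05
    fp_prediction_rate: float = 0.01
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_samples", "n_mirna", "n_mrna"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("frac_true_pairs", "fp_prediction_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if any(b > 0 for b in self.beta_by_site.values()):
            raise ValueError("coupling coefficients beta must be <= 0 (repression)")
        if self.gamma_host < 0:
            raise ValueError("gamma_host must be >= 0")
        lo, hi = self.beta_jitter
        if not 0 <= lo <= hi:
            raise ValueError("beta_jitter must satisfy 0 <= lo <= hi")
        if self.dispersion < 0 or self.transfection_dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.noise_sd < 0 or self.transfection_noise_sd < 0:
            raise ValueError("noise sd must be >= 0")
        if not 0 <= self.n_intragenic <= min(self.n_mirna, self.n_mrna):
            raise ValueError("n_intragenic must be <= min(n_mirna, n_mrna)")
        unknown = set(self.beta_by_site) - set(TRUTH_SITE_TYPES)
        if unknown:
            raise ValueError(f"unknown site types in beta_by_site: {sorted(unknown)}")
        n_true = round(self.frac_true_pairs * self.n_mirna * self.n_mrna)
        n_target_mrna = self.n_mrna - self.n_intragenic
        if n_true > self.n_mirna * n_target_mrna:
            raise ValueError(
                "frac_true_pairs too high: an mRNA would need more than "
                "n_mirna couplings"
            )


@dataclass
class TruthTable:
    """Recorded ground truth of a synthetic cohort.

    ``pairs`` holds one row per true coupling (mirna_id, mrna_id,
    site_type, beta); ``intragenic_map`` one row per host-coupled miRNA;
    ``transfection_truth`` is filled by :func:`generate_transfection_counts`
    with the realized per-transcript true log fold change.
    """

    pairs: pd.DataFrame
    intragenic_map: pd.DataFrame
    transfection_truth: pd.DataFrame | None = None

    def targets_of(self, mirna_id: str) -> pd.DataFrame:
        return self.pairs[self.pairs["mirna_id"] == mirna_id]


def _rng(config: CohortConfig, stream: int) -> np.random.Generator:
    # independent, reproducible streams per generator stage
    return np.random.default_rng(np.random.SeedSequence([config.seed, stream]))


def _nb_counts(rng: np.random.Generator, mu: np.ndarray, phi: float) -> np.ndarray:
    """Negative-binomial draws with variance mu + phi*mu^2 (gamma-Poisson)."""
    if phi == 0:
        return rng.poisson(mu)
    lam = rng.gamma(shape=1.0 / phi, scale=mu * phi)
    return rng.poisson(lam)


def _ids(prefix: str, n: int) -> list[str]:
    width = max(3, len(str(n)))
    return [f"{prefix}{k:0{width}d}" for k in range(1, n + 1)]


def _softmax_means(x: np.ndarray, libsizes: np.ndarray) -> np.ndarray:
    """Map log2 latent abundances to per-sample NB means summing to libsize."""
    expr = np.exp2(x - x.max(axis=0, keepdims=True))
    return libsizes[None, :] * expr / expr.sum(axis=0, keepdims=True)


def _draw_true_pairs(
    rng: np.random.Generator, config: CohortConfig, mirna_ids, mrna_ids, host_mrnas: set[str]
) -> pd.DataFrame:
    """Sample the true-coupling pair set, site types round-robin.

    Host mRNAs are excluded from being coupling targets so intragenic
    positive couplings and repressive couplings never collide on a gene.
    """
    target_mrnas = [m for m in mrna_ids if m not in host_mrnas]
    n_grid = config.n_mirna * len(target_mrnas)
    n_true = round(config.frac_true_pairs * config.n_mirna * config.n_mrna)
    n_true = min(n_true, n_grid)
    flat = rng.choice(n_grid, size=n_true, replace=False)
    flat.sort()
    site_types = [t for t in TRUTH_SITE_TYPES if t in config.beta_by_site]
    lo, hi = config.beta_jitter
    rows = []
    for k, idx in enumerate(flat):
        i, j = divmod(int(idx), len(target_mrnas))
        site = site_types[k % len(site_types)]
        beta = config.beta_by_site[site] * rng.uniform(lo, hi)
        rows.append((mirna_ids[i], target_mrnas[j], site, beta))
    return pd.DataFrame(rows, columns=["mirna_id", "mrna_id", "site_type", "beta"])


def generate_paired_cohort(
    config: CohortConfig,
) -> tuple[ExpressionMatrix, ExpressionMatrix, TruthTable]:
    """Generate one paired miRNA/mRNA count cohort plus its truth table."""
    config.validate()
    rng = _rng(config, 0)

    mirna_ids = _ids("miR-", config.n_mirna)
    mrna_ids = _ids("GENE", config.n_mrna)
    sample_ids = _ids("S", config.n_samples)
    n, p_mir, p_mrna = config.n_samples, config.n_mirna, config.n_mrna

    lib_mir = rng.lognormal(config.libsize_meanlog, config.libsize_sdlog, size=n)
    lib_mrna = rng.lognormal(config.libsize_meanlog, config.libsize_sdlog, size=n)

    a = rng.normal(5.0, 2.0, size=p_mir)
    e = rng.normal(0.0, 1.0, size=(p_mir, n))
    b = rng.normal(4.0, 2.0, size=p_mrna)
    eps = rng.normal(0.0, config.noise_sd, size=(p_mrna, n))

    # intragenic miRNAs: first n_intragenic miRNAs hosted by the last
    # n_intragenic mRNAs (deterministic assignment, ids shuffled by the rng
    # baselines anyway)
    host_rows = []
    mrna_index = {m: j for j, m in enumerate(mrna_ids)}
    for k in range(config.n_intragenic):
        host_rows.append((mirna_ids[k], mrna_ids[p_mrna - 1 - k]))
    intragenic_map = pd.DataFrame(host_rows, columns=["mirna_id", "host_mrna_id"])
    host_mrnas = set(intragenic_map["host_mrna_id"])

    pairs = _draw_true_pairs(rng, config, mirna_ids, mrna_ids, host_mrnas)

    # latent miRNA abundance; host deviation (= eps of host gene) feeds in
    # before coupling terms so host-driven variation propagates to targets
    z = a[:, None] + e
    for k, (mir, host) in enumerate(zip(intragenic_map["mirna_id"], intragenic_map["host_mrna_id"])):
        z[k] += config.gamma_host * eps[mrna_index[host]]

    mirna_index = {m: i for i, m in enumerate(mirna_ids)}
    m_log2 = b[:, None] + eps
    for mir, gene, _site, beta in pairs.itertuples(index=False):
        m_log2[mrna_index[gene]] += beta * (z[mirna_index[mir]] - a[mirna_index[mir]])

    mu_mir = _softmax_means(z, lib_mir)
    mu_mrna = _softmax_means(m_log2, lib_mrna)
    counts_mir = _nb_counts(rng, mu_mir, config.dispersion)
    counts_mrna = _nb_counts(rng, mu_mrna, config.dispersion)

    mirna = ExpressionMatrix(
        counts=pd.DataFrame(counts_mir, index=mirna_ids, columns=sample_ids),
        feature_class="miRNA",
    )
    mrna = ExpressionMatrix(
        counts=pd.DataFrame(counts_mrna, index=mrna_ids, columns=sample_ids),
        feature_class="mRNA",
    )
    truth = TruthTable(pairs=pairs, intragenic_map=intragenic_map)
    return mirna, mrna, truth


# ---------------------------------------------------------------------------
# prediction tables
# ---------------------------------------------------------------------------

def generate_prediction_tables(truth: TruthTable, config: CohortConfig) -> pd.DataFrame:
    """Emulated TargetScan / miRDB / miRTarBase exports for a truth table.

    True pairs with a TargetScan-class site type get a context score drawn
    Uniform(-0.8, -0.05); every true pair gets a miRDB score
    Uniform(80, 100); "validated" pairs additionally get a miRTarBase
    record (no score).  Non-coupled pairs receive spurious TargetScan and
    miRDB records at rate ``fp_prediction_rate``, with deliberately weaker
    scores (context Uniform(-0.3, 0), miRDB Uniform(50, 85)) so that
    stringent score thresholds enrich for true pairs.
    """
    config.validate()
    if truth.pairs.empty:
        raise ValueError("truth table has no pairs")
    rng = _rng(config, 1)
    rows: list[tuple] = []

    for mir, gene, site, _beta in truth.pairs.itertuples(index=False):
        if site in TARGETSCAN_SITES:
            rows.append((mir, gene, "targetscan", rng.uniform(-0.8, -0.05), site))
        rows.append((mir, gene, "mirdb", rng.uniform(80.0, 100.0), "none"))
        if site == "validated":
            rows.append((mir, gene, "mirtarbase", np.nan, "none"))

    mirna_ids = _ids("miR-", config.n_mirna)
    mrna_ids = _ids("GENE", config.n_mrna)
    true_set = set(zip(truth.pairs["mirna_id"], truth.pairs["mrna_id"]))
    n_grid = config.n_mirna * config.n_mrna
    n_null = n_grid - len(true_set)
    n_fp = rng.binomial(n_null, config.fp_prediction_rate)
    if n_fp > 0:
        # oversample the grid, drop true pairs, top up until n_fp distinct
        chosen: set[int] = set()
        while len(chosen) < n_fp:
            draw = rng.choice(n_grid, size=min(n_grid, 2 * (n_fp - len(chosen)) + 16), replace=False)
            for idx in draw:
                i, j = divmod(int(idx), config.n_mrna)
                if (mirna_ids[i], mrna_ids[j]) in true_set:
                    continue
                chosen.add(int(idx))
                if len(chosen) == n_fp:
                    break
        for idx in sorted(chosen):
            i, j = divmod(idx, config.n_mrna)
            site = TARGETSCAN_SITES[int(rng.integers(len(TARGETSCAN_SITES)))]
            rows.append((mirna_ids[i], mrna_ids[j], "targetscan", rng.uniform(-0.3, 0.0), site))
            rows.append((mirna_ids[i], mrna_ids[j], "mirdb", rng.uniform(50.0, 85.0), "none"))

    table = pd.DataFrame(rows, columns=PREDICTION_COLUMNS)
    return table.sort_values(["source", "mirna_id", "mrna_id"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# transfection experiment
# ---------------------------------------------------------------------------

def generate_transfection_counts(
    truth: TruthTable,
    config: CohortConfig,
    mirna_id: str,
    delta_logFC: float,
    weight_range: tuple[float, float] = (0.5, 1.5),
) -> ExpressionMatrix:
    """3-vs-3 mimic / negative-control transfection counts.

    True targets of ``mirna_id`` are repressed in the mimic group by
    ``2**(-delta_logFC * w_j * c_j)`` where w_j is a per-target weight
    drawn uniformly from ``weight_range`` and c_j = |beta_j| / mean|beta|
    scales repression with site strength, normalized so the mean scale is
    1 (stronger seed matches are repressed more upon over-expression,
    exactly as in the cohort — this is what makes patient correlations
    and transfection fold changes concordant).  Everything else is null.
    The realized per-gene true log2 fold change is recorded on
    ``truth.transfection_truth``.
    """
    config.validate()
    if delta_logFC < 0:
        raise ValueError("delta_logFC must be >= 0 (repression strength)")
    targets = truth.targets_of(mirna_id)
    if (
        targets.empty
        and mirna_id not in set(truth.pairs["mirna_id"])
        and mirna_id not in set(truth.intragenic_map["mirna_id"])
    ):
        raise KeyError(f"miRNA {mirna_id!r} not present in the truth table")
    rng = _rng(config, 2)

    mrna_ids = _ids("GENE", config.n_mrna)
    samples = ["mimic_1", "mimic_2", "mimic_3", "ctrl_1", "ctrl_2", "ctrl_3"]
    is_mimic = np.array([s.startswith("mimic") for s in samples])
    p, n = config.n_mrna, len(samples)

    b = rng.normal(4.0, 2.0, size=p)
    eps = rng.normal(0.0, config.transfection_noise_sd, size=(p, n))
    lo, hi = weight_range
    w = rng.uniform(lo, hi, size=len(targets))
    abs_beta = targets["beta"].abs().to_numpy()
    mean_beta = abs_beta.mean() if len(abs_beta) else 0.0
    site_scale = abs_beta / mean_beta if mean_beta > 0 else np.ones_like(abs_beta)

    true_lfc = pd.Series(0.0, index=mrna_ids, name="true_logFC")
    x = b[:, None] + eps
    index = {m: j for j, m in enumerate(mrna_ids)}
    for (gene, wk, ck) in zip(targets["mrna_id"], w, site_scale):
        true_lfc[gene] = -delta_logFC * wk * ck
        x[index[gene], is_mimic] += true_lfc[gene]

    libs = rng.lognormal(config.libsize_meanlog, config.libsize_sdlog, size=n)
    mu = _softmax_means(x, libs)
    counts = _nb_counts(rng, mu, config.transfection_dispersion)

    truth.transfection_truth = true_lfc.rename_axis("mrna_id").reset_index()
    return ExpressionMatrix(
        counts=pd.DataFrame(counts, index=mrna_ids, columns=samples),
        feature_class="mRNA",
    )


# ---------------------------------------------------------------------------
# annotation + disease gene list
# ---------------------------------------------------------------------------

def generate_annotation(
    truth: TruthTable,
    config: CohortConfig,
    n_disease_genes: int | None = None,
    disease_enrichment: float = 3.0,
) -> tuple[str, list[str]]:
    """GTF text plus a disease gene list for a synthetic cohort.

    Every mRNA becomes a protein-coding gene record; intragenic miRNAs are
    placed strictly inside their host's interval, intergenic miRNAs in the
    gaps between genes.  The disease list (default ~22% of the
    transcriptome, the dysregulated-gene ratio typical of a myeloma
    meta-analysis) is sampled with host genes of positively-coupled
    miRNAs up-weighted by ``disease_enrichment`` (ratio 1.0 reproduces a
    uniform draw).
    """
    config.validate()
    if disease_enrichment < 0:
        raise ValueError("disease_enrichment must be >= 0")
    rng = _rng(config, 3)

    mrna_ids = _ids("GENE", config.n_mrna)
    mirna_ids = _ids("miR-", config.n_mirna)
    host_of = dict(zip(truth.intragenic_map["mirna_id"], truth.intragenic_map["host_mrna_id"]))

    gene_span = 20_000
    gene_gap = 10_000
    lines = []
    gene_start: dict[str, int] = {}
    per_chrom = math.ceil(config.n_mrna / 22)
    for j, gene in enumerate(mrna_ids):
        chrom = f"chr{j // per_chrom + 1}"
        start = (j % per_chrom) * (gene_span + gene_gap) + 1
        end = start + gene_span - 1
        gene_start[gene] = start
        lines.append(
            f"{chrom}\tmirlink\tgene\t{start}\t{end}\t.\t+\t.\t"
            f'gene_id "{gene}"; gene_biotype "protein_coding";'
        )
    chrom_of = {g: f"chr{j // per_chrom + 1}" for j, g in enumerate(mrna_ids)}

    for k, mir in enumerate(mirna_ids):
        if mir in host_of:
            host = host_of[mir]
            start = gene_start[host] + 1000
            chrom = chrom_of[host]
        else:
            # intergenic miRNAs live on a gene-free chromosome
            chrom = "chrX"
            start = k * (gene_span + gene_gap) + gene_span + 2001
        end = start + 84  # pre-miRNA-sized interval
        lines.append(
            f"{chrom}\tmirlink\tgene\t{start}\t{end}\t.\t+\t.\t"
            f'gene_id "{mir}"; gene_biotype "miRNA";'
        )
    gtf_text = "\n".join(lines) + "\n"

    if n_disease_genes is None:
        n_disease_genes = round(0.22 * config.n_mrna)
    n_disease = min(n_disease_genes, config.n_mrna)
    host_genes = set(host_of.values()) if config.gamma_host > 0 else set()
    weights = np.array([disease_enrichment if g in host_genes else 1.0 for g in mrna_ids])
    if weights.sum() == 0:
        raise ValueError("disease gene sampling weights are all zero")
    disease = rng.choice(mrna_ids, size=n_disease, replace=False, p=weights / weights.sum())
    return gtf_text, sorted(disease.tolist())


def make_toy_gene_sets(
    truth: TruthTable,
    config: CohortConfig,
    n_terms: int = 20,
    term_size: int = 40,
    target_enrichment: float = 4.0,
) -> dict[str, set[str]]:
    """A small synthetic term -> gene-set collection (GMT-like, in memory).

    Half the terms are drawn uniformly from all mRNAs; the other half
    up-weight true coupling targets by ``target_enrichment`` so that
    over-representation analysis on recovered targets has signal.
    """
    rng = _rng(config, 4)
    mrna_ids = _ids("GENE", config.n_mrna)
    target_genes = set(truth.pairs["mrna_id"])
    sets: dict[str, set[str]] = {}
    for t in range(n_terms):
        if t % 2 == 0:
            w = np.ones(len(mrna_ids))
        else:
            w = np.array([target_enrichment if g in target_genes else 1.0 for g in mrna_ids])
        members = rng.choice(mrna_ids, size=min(term_size, len(mrna_ids)), replace=False, p=w / w.sum())
        sets[f"TERM{t:03d}"] = set(members.tolist())
    return sets


def write_truth(truth: TruthTable, pairs_path, intragenic_path, transfection_path=None) -> None:
    """Persist a truth table as TSV files."""
    truth.pairs.to_csv(pairs_path, sep="\t", index=False)
    truth.intragenic_map.to_csv(intragenic_path, sep="\t", index=False)
    if transfection_path is not None and truth.transfection_truth is not None:
        truth.transfection_truth.to_csv(transfection_path, sep="\t", index=False)
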