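"""End-to-end orchestration: cohort -> correlations -> target shifts ->
enrichment -> differential expression -> concordance.

``run_all`` executes the stages in study order, writing every intermediate
table as TSV into a run directory together with a JSON report; re-running
with the same configuration and seed reproduces all outputs byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .concordance import q20_concordance, top_pair_selection
from .correlate import all_pairs_pearson, census, stratify_by_locus
from .diffexpr import DesignSpec, run_de_pipeline, summarize_de
from .enrich import decile_enrichment, enrichment_frame, ora, select_go_input
from .ioformats import classify_mirna_loci, filter_predictions, write_counts, write_predictions
from .preprocess import cpm, filter_min_cpm_all_samples, top_expressed_fraction
from .synthdata import (
    CohortConfig,
    generate_annotation,
    generate_paired_cohort,
    generate_prediction_tables,
    generate_transfection_counts,
    make_toy_gene_sets,
    write_truth,
)
from .targets import (
    build_grouping,
    global_target_shift,
    intersect_predictions,
    shift_results_frame,
    target_shift_analysis,
)

__all__ = ["PipelineConfig", "PipelineStageError", "run_all"]

log = logging.getLogger("mirlink")


@dataclass(frozen=True)
class PipelineConfig:
    """Full threshold surface of the analysis plus the cohort source.

    Thresholds default to the study recipe: BH alpha 0.05 for both
    correlations and DE; expression above 1 CPM in all samples; top 40% of
    mRNAs entering the global target analysis with TargetScan context
    < -0.035 and the 5% best miRDB predictions; the stricter ontology-
    input filter (context < -0.366, miRDB > 92.8, r < -0.1); miRDB > 85
    for the per-miRNA analysis; |logFC| > 1 for the asymmetry count and
    Q20 quantile grouping for concordance.
    """

    cohort: CohortConfig = field(default_factory=CohortConfig)
    alpha_corr: float = 0.05
    alpha_de: float = 0.05
    min_cpm: float = 1.0
    top_mrna_fraction: float = 0.40
    context_general: float = -0.035
    mirdb_top_fraction: float = 0.05
    context_go: float = -0.366
    mirdb_go: float = 92.8
    mirdb_permirna: float = 85.0
    r_go_max: float = -0.1
    lfc_cut: float = 1.0
    q: float = 0.2
    transfection_delta: float = 1.0
    focus_mirna: str | None = None   # default: the miRNA with most true pairs

    def validate(self) -> None:
        self.cohort.validate()
        for name, lo, hi in (
            ("alpha_corr", 0, 1),
            ("alpha_de", 0, 1),
            ("top_mrna_fraction", 0, 1),
            ("mirdb_top_fraction", 0, 1),
            ("q", 0, 0.5),
        ):
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ValueError(f"{name}={v} outside [{lo}, {hi}]")


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in vars(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return v if np.isfinite(v) else None
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return None  # raw samples are persisted as TSV, not in the report
    return obj


def run_all(config: PipelineConfig, outdir: str | Path) -> Path:
    """Run the full synthetic-cohort analysis into ``outdir``.

    Every stage writes its tables under the run directory; the summary
    lands in ``report.json``.  Raises :class:`PipelineStageError` naming
    the failing stage; tables written before the failure are retained.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "mirlink_version": __version__,
        "seed": config.cohort.seed,
        "thresholds": {
            k: getattr(config, k)
            for k in (
                "alpha_corr", "alpha_de", "min_cpm", "top_mrna_fraction",
                "context_general", "mirdb_top_fraction", "context_go",
                "mirdb_go", "mirdb_permirna", "r_go_max", "lfc_cut", "q",
                "transfection_delta",
            )
        },
        "cohort_config": _jsonable(config.cohort),
    }
    stage = "simulate"
    try:
        log.info("stage %s", stage)
        mirna, mrna, truth = generate_paired_cohort(config.cohort)
        write_counts(mirna, outdir / "mirna_counts.tsv")
        write_counts(mrna, outdir / "mrna_counts.tsv")
        write_truth(truth, outdir / "truth_pairs.tsv", outdir / "truth_intragenic.tsv")
        predictions = generate_prediction_tables(truth, config.cohort)
        write_predictions(predictions, outdir / "predictions.tsv")
        gtf_text, disease_genes = generate_annotation(truth, config.cohort)
        (outdir / "annotation.gtf").write_text(gtf_text)
        (outdir / "disease_genes.txt").write_text("\n".join(disease_genes) + "\n")
        gene_sets = make_toy_gene_sets(truth, config.cohort)

        stage = "preprocess"
        log.info("stage %s", stage)
        mirna_kept = filter_min_cpm_all_samples(mirna.counts, config.min_cpm)
        mrna_kept = filter_min_cpm_all_samples(mrna.counts, config.min_cpm)
        report["n_mirna_expressed"] = len(mirna_kept)
        report["n_mrna_expressed"] = len(mrna_kept)
        mirna_l2 = np.log2(cpm(mirna_kept) + 1.0)
        mrna_l2 = np.log2(cpm(mrna_kept) + 1.0)

        stage = "correlate"
        log.info("stage %s", stage)
        corr = all_pairs_pearson(mirna_l2, mrna_l2)
        corr.to_csv(outdir / "correlations.tsv", sep="\t", index=False, float_format="%.6g")
        report["correlation_census"] = _jsonable(census(corr, config.alpha_corr))

        stage = "locus_stratification"
        log.info("stage %s", stage)
        annotations = classify_mirna_loci(outdir / "annotation.gtf")
        annotations = [a for a in annotations if a.mirna_id in set(mirna_kept.index)]
        if any(a.host_gene_id for a in annotations):
            locus = stratify_by_locus(corr, annotations, mode="host_pair_only")
            report["locus_shift"] = {
                "n_intragenic": int(locus.intragenic_r.size),
                "n_intergenic": int(locus.intergenic_r.size),
                "ks_D": locus.ks_D,
                "ks_p": locus.ks_p,
                "mean_shift": locus.mean_shift,
            }

        stage = "global_target_shift"
        log.info("stage %s", stage)
        top_mrna = top_expressed_fraction(mrna_kept, config.top_mrna_fraction)
        general = filter_predictions(
            predictions,
            targetscan_max_context=config.context_general,
            mirdb_top_fraction=config.mirdb_top_fraction,
        )
        expressed_top = set(top_mrna.index)
        general = general[general["mrna_id"].isin(expressed_top)]
        corr_top = corr[corr["mrna_id"].isin(expressed_top)]
        common = intersect_predictions(general)
        report["n_common_predicted_pairs"] = len(common)
        pair_sets = {
            source: set(
                zip(
                    general.loc[general["source"] == source, "mirna_id"],
                    general.loc[general["source"] == source, "mrna_id"],
                )
            )
            for source in ("targetscan", "mirdb")
        }
        shifts = global_target_shift(corr_top, pair_sets)
        shift_results_frame(shifts).to_csv(outdir / "global_shift.tsv", sep="\t", index=False)
        report["global_target_shift"] = [_jsonable(s) for s in shifts]

        stage = "per_mirna_shift"
        log.info("stage %s", stage)
        focus = config.focus_mirna
        if focus is None:
            focus = truth.pairs["mirna_id"].value_counts().sort_index().idxmax()
        report["focus_mirna"] = focus
        permirna_pred = filter_predictions(predictions, mirdb_min_score=config.mirdb_permirna)
        grouping = build_grouping(permirna_pred)
        r_values = (
            corr[(corr["mirna_id"] == focus) & np.isfinite(corr["r"])]
            .set_index("mrna_id")["r"]
        )
        per_shifts, curves = target_shift_analysis(r_values, grouping, focus)
        shift_results_frame(per_shifts).to_csv(outdir / "permirna_shift.tsv", sep="\t", index=False)
        for group, coords in curves.items():
            coords.to_csv(outdir / f"ecdf_{group}.tsv", sep="\t", index=False, float_format="%.6g")
        report["per_mirna_shift"] = [_jsonable(s) for s in per_shifts]

        stage = "enrichment"
        log.info("stage %s", stage)
        table, chi2, p = decile_enrichment(
            corr, disease_genes, contrast="vs_negative_decile", rng_seed=config.cohort.seed
        )
        report["decile_enrichment_vs_negative"] = {
            "table": table.tolist(), "chi2": chi2, "p": p,
        }
        table_r, chi2_r, p_r = decile_enrichment(
            corr, disease_genes, contrast="vs_random", rng_seed=config.cohort.seed
        )
        report["decile_enrichment_vs_random"] = {
            "table": table_r.tolist(), "chi2": chi2_r, "p": p_r,
        }
        go_pred = filter_predictions(predictions)  # unfiltered; select_go_input applies cuts
        go_lists = select_go_input(
            corr, go_pred, mirdb_min=config.mirdb_go,
            context_max=config.context_go, r_max=config.r_go_max,
        )
        background = sorted(mrna_kept.index)
        report["ora"] = {}
        for source, genes in sorted(go_lists.items()):
            (outdir / f"go_input_{source}.txt").write_text("\n".join(genes) + "\n")
            if not genes:
                continue
            results = ora(genes, gene_sets, background)
            enrichment_frame(results).to_csv(
                outdir / f"ora_{source}.tsv", sep="\t", index=False, float_format="%.6g"
            )
            top = min(results, key=lambda x: (x.p, x.term_id))
            report["ora"][source] = {
                "n_input": len(genes),
                "top_term": top.term_id,
                "top_p_adj": top.p_adj,
            }

        stage = "differential_expression"
        log.info("stage %s", stage)
        transf = generate_transfection_counts(
            truth, config.cohort, focus, config.transfection_delta
        )
        write_counts(transf, outdir / "transfection_counts.tsv")
        design = DesignSpec(
            groups={s: ("mimic" if s.startswith("mimic") else "ctrl") for s in transf.sample_ids},
            contrast=("mimic", "ctrl"),
        )
        de = run_de_pipeline(transf.counts, design)
        de.to_csv(outdir / "de_table.tsv", sep="\t", float_format="%.6g")
        volcano = pd.DataFrame(
            {"logFC": de["logFC"], "neg_log10_p_adj": -np.log10(de["p_adj"].clip(lower=1e-300))}
        )
        volcano.to_csv(outdir / "volcano.tsv", sep="\t", float_format="%.6g")
        report["de_summary"] = _jsonable(summarize_de(de, config.alpha_de, config.lfc_cut))

        stage = "transfection_target_shift"
        log.info("stage %s", stage)
        lfc = de["logFC"]
        de_shifts, _ = target_shift_analysis(lfc, grouping, focus)
        shift_results_frame(de_shifts).to_csv(outdir / "transfection_shift.tsv", sep="\t", index=False)
        report["transfection_target_shift"] = [_jsonable(s) for s in de_shifts]

        stage = "concordance"
        log.info("stage %s", stage)
        conc = q20_concordance(de, corr, grouping, focus, alpha=config.alpha_de, q=config.q)
        report["concordance"] = _jsonable(conc)
        top_pairs = top_pair_selection(de, corr, grouping, focus, alpha=config.alpha_de)
        top_pairs.to_csv(outdir / "top_pairs.tsv", sep="\t", index=False, float_format="%.6g")
        report["top_pairs"] = top_pairs["mrna_id"].tolist()
    except Exception as exc:  # noqa: BLE001 - re-raised with stage context
        raise PipelineStageError(stage, exc) from exc

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return outdir
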