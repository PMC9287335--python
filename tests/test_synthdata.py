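"""Generator contracts: determinism, shapes, moments and ground truth."""

import io

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import mirlink as ml
from mirlink.synthdata import TRUTH_SITE_TYPES, _nb_counts

ZERO_BETA = {k: 0.0 for k in TRUTH_SITE_TYPES}


def _cohort_tsv(cfg):
    mirna, mrna, truth = ml.generate_paired_cohort(cfg)
    buf = io.StringIO()
    mirna.counts.to_csv(buf, sep="\t")
    mrna.counts.to_csv(buf, sep="\t")
    truth.pairs.to_csv(buf, sep="\t", index=False)
    return buf.getvalue()


def test_same_seed_gives_byte_identical_output():
    cfg = ml.CohortConfig(n_samples=10, n_mirna=8, n_mrna=50, n_intragenic=2, seed=7)
    assert _cohort_tsv(cfg) == _cohort_tsv(cfg)


def test_different_seed_changes_output():
    a = ml.CohortConfig(n_samples=10, n_mirna=8, n_mrna=50, n_intragenic=2, seed=7)
    b = ml.CohortConfig(n_samples=10, n_mirna=8, n_mrna=50, n_intragenic=2, seed=8)
    assert _cohort_tsv(a) != _cohort_tsv(b)


def test_matrix_shapes_match_config():
    cfg = ml.CohortConfig(n_samples=86, n_mirna=161, n_mrna=2000, seed=0)
    mirna, mrna, truth = ml.generate_paired_cohort(cfg)
    assert mirna.shape == (161, 86)
    assert mrna.shape == (2000, 86)
    assert mirna.feature_class == "miRNA" and mrna.feature_class == "mRNA"
    # every truth pair references generated ids
    assert set(truth.pairs["mirna_id"]) <= set(mirna.feature_ids)
    assert set(truth.pairs["mrna_id"]) <= set(mrna.feature_ids)
    assert set(truth.pairs["site_type"]) <= set(TRUTH_SITE_TYPES)


@pytest.mark.parametrize("bad", [
    dict(n_samples=0),
    dict(frac_true_pairs=1.5),
    dict(beta_by_site={"8mer": 0.2}),
    dict(gamma_host=-1.0),
    dict(dispersion=-0.1),
    dict(n_intragenic=999),
])
def test_invalid_config_rejected(bad):
    base = dict(n_samples=10, n_mirna=5, n_mrna=20, n_intragenic=0)
    base.update(bad)
    with pytest.raises(ValueError):
        ml.CohortConfig(**base).validate()


def test_null_couplings_give_zero_mean_true_pair_correlation():
    """With all beta = 0 the 'true' pairs are null; their mean r is ~0."""
    cfg = ml.CohortConfig(
        n_samples=50, n_mirna=50, n_mrna=500, frac_true_pairs=0.08,
        beta_by_site=ZERO_BETA, gamma_host=0.0, n_intragenic=0, seed=2,
    )
    mirna, mrna, truth = ml.generate_paired_cohort(cfg)
    assert len(truth.pairs) == 2000
    mir_l2 = np.log2(ml.cpm(mirna.counts) + 1)
    mrna_l2 = np.log2(ml.cpm(mrna.counts) + 1)
    rs = [
        stats.pearsonr(mir_l2.loc[m], mrna_l2.loc[g]).statistic
        for m, g in zip(truth.pairs["mirna_id"], truth.pairs["mrna_id"])
    ]
    assert abs(np.mean(rs)) < 0.05


def test_nb_moments_match_mean_and_dispersion(rng):
    """Empirical NB mean/variance agree with mu and mu + phi mu^2."""
    mu, phi, n = 50.0, 0.2, 200_000
    draws = _nb_counts(rng, np.full(n, mu), phi).astype(float)
    target_var = mu + phi * mu * mu
    se_mean = np.sqrt(draws.var() / n)
    assert abs(draws.mean() - mu) < 3 * se_mean
    m4 = np.mean((draws - draws.mean()) ** 4)
    se_var = np.sqrt((m4 - draws.var() ** 2) / n)
    assert abs(draws.var(ddof=1) - target_var) < 3 * se_var


def test_poisson_limit_at_zero_dispersion(rng):
    draws = _nb_counts(rng, np.full(100_000, 20.0), 0.0).astype(float)
    assert abs(draws.var(ddof=1) / draws.mean() - 1.0) < 0.02


class TestPredictionTables:
    def test_zero_fp_rate_means_all_predictions_true(self, small_cohort):
        cfg, _, _, truth = small_cohort
        import dataclasses
        cfg0 = dataclasses.replace(cfg, fp_prediction_rate=0.0)
        pred = ml.generate_prediction_tables(truth, cfg0)
        true_set = set(zip(truth.pairs["mirna_id"], truth.pairs["mrna_id"]))
        assert set(zip(pred["mirna_id"], pred["mrna_id"])) <= true_set

    def test_spurious_record_count_follows_binomial_rate(self):
        cfg = ml.CohortConfig(
            n_samples=5, n_mirna=20, n_mrna=500, frac_true_pairs=0.01,
            fp_prediction_rate=0.01, n_intragenic=0, seed=3,
        )
        _, _, truth = ml.generate_paired_cohort(cfg)
        pred = ml.generate_prediction_tables(truth, cfg)
        true_set = set(zip(truth.pairs["mirna_id"], truth.pairs["mrna_id"]))
        fp_pairs = {
            p for p in zip(pred["mirna_id"], pred["mrna_id"]) if p not in true_set
        }
        n_null = 20 * 500 - len(true_set)
        expected = 0.01 * n_null
        sd = np.sqrt(n_null * 0.01 * 0.99)
        assert abs(len(fp_pairs) - expected) < 4 * sd

    def test_8mer_pair_appears_in_both_sources(self, small_cohort):
        cfg, _, _, truth = small_cohort
        pred = ml.generate_prediction_tables(truth, cfg)
        eightmer = truth.pairs[truth.pairs["site_type"] == "8mer"].iloc[0]
        pair = (eightmer["mirna_id"], eightmer["mrna_id"])
        for source in ("targetscan", "mirdb"):
            sub = pred[pred["source"] == source]
            assert pair in set(zip(sub["mirna_id"], sub["mrna_id"]))

    def test_score_stratification_enriches_true_pairs(self, small_cohort):
        """Stringent thresholds keep only generator-truth pairs."""
        cfg, _, _, truth = small_cohort
        pred = ml.generate_prediction_tables(truth, cfg)
        strict = ml.filter_predictions(pred, mirdb_min_score=92.8)
        true_set = set(zip(truth.pairs["mirna_id"], truth.pairs["mrna_id"]))
        kept = strict[strict["source"] == "mirdb"]
        assert set(zip(kept["mirna_id"], kept["mrna_id"])) <= true_set


class TestTransfection:
    def test_zero_delta_gives_all_zero_truth(self, small_cohort):
        cfg, _, _, truth = small_cohort
        focus = truth.pairs["mirna_id"].iloc[0]
        ml.generate_transfection_counts(truth, cfg, focus, 0.0)
        assert (truth.transfection_truth["true_logFC"] == 0).all()

    def test_degenerate_weights_single_class_give_exact_logfc(self):
        # one site class => site-strength scale is identically 1, and a
        # width-zero weight range pins w at 1, so every target is at -1
        cfg = ml.CohortConfig(
            n_samples=5, n_mirna=4, n_mrna=100, frac_true_pairs=0.05,
            beta_by_site={"8mer": -0.5}, beta_jitter=(1.0, 1.0),
            n_intragenic=0, seed=4,
        )
        _, _, truth = ml.generate_paired_cohort(cfg)
        focus = truth.pairs["mirna_id"].value_counts().idxmax()
        ml.generate_transfection_counts(truth, cfg, focus, 1.0, weight_range=(1.0, 1.0))
        tt = truth.transfection_truth.set_index("mrna_id")["true_logFC"]
        targets = set(truth.pairs.loc[truth.pairs["mirna_id"] == focus, "mrna_id"])
        assert np.allclose(tt[list(targets)], -1.0)
        assert (tt[~tt.index.isin(targets)] == 0).all()

    def test_unknown_mirna_raises_with_id(self, small_cohort):
        cfg, _, _, truth = small_cohort
        with pytest.raises(KeyError, match="miR-nope"):
            ml.generate_transfection_counts(truth, cfg, "miR-nope", 1.0)

    def test_design_is_three_vs_three(self, small_cohort):
        cfg, _, _, truth = small_cohort
        focus = truth.pairs["mirna_id"].iloc[0]
        transf = ml.generate_transfection_counts(truth, cfg, focus, 1.0)
        assert sorted(transf.sample_ids) == [
            "ctrl_1", "ctrl_2", "ctrl_3", "mimic_1", "mimic_2", "mimic_3",
        ]


class TestAnnotation:
    def test_intragenic_mirnas_contained_in_their_hosts(self, small_cohort, tmp_path):
        cfg, _, _, truth = small_cohort
        gtf, _ = ml.generate_annotation(truth, cfg)
        path = tmp_path / "ann.gtf"
        path.write_text(gtf)
        annotations = {a.mirna_id: a for a in ml.classify_mirna_loci(path)}
        for mir, host in truth.intragenic_map.itertuples(index=False):
            assert annotations[mir].host_gene_id == host
        intragenic = {a.mirna_id for a in annotations.values() if a.host_gene_id}
        assert intragenic == set(truth.intragenic_map["mirna_id"])

    def test_no_intragenic_config_yields_no_hosts(self, tmp_path):
        cfg = ml.CohortConfig(n_samples=5, n_mirna=10, n_mrna=50, n_intragenic=0, seed=5)
        _, _, truth = ml.generate_paired_cohort(cfg)
        gtf, _ = ml.generate_annotation(truth, cfg)
        path = tmp_path / "ann.gtf"
        path.write_text(gtf)
        assert all(a.host_gene_id is None for a in ml.classify_mirna_loci(path))

    def test_unit_enrichment_matches_random_overlap(self):
        cfg = ml.CohortConfig(n_samples=5, n_mirna=30, n_mrna=500, n_intragenic=20, seed=6)
        _, _, truth = ml.generate_paired_cohort(cfg)
        _, disease = ml.generate_annotation(truth, cfg, disease_enrichment=1.0)
        hosts = set(truth.intragenic_map["host_mrna_id"])
        overlap = len(hosts & set(disease))
        p_in = len(disease) / 500
        expected = len(hosts) * p_in
        sd = np.sqrt(len(hosts) * p_in * (1 - p_in))
        assert abs(overlap - expected) <= 3 * sd + 1
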