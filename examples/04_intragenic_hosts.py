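"""Intragenic miRNAs are positively correlated with their host genes.

A GTF is generated alongside the cohort; miRNAs fully contained in a
protein-coding gene's interval are classified intragenic (host = the
smallest containing gene) and their host-pair correlations are compared
against all correlations of intergenic miRNAs.
"""

import tempfile
from pathlib import Path

import numpy as np

import mirlink as ml

cfg = ml.CohortConfig(n_samples=86, n_mirna=30, n_mrna=300, frac_true_pairs=0.01,
                      n_intragenic=10, gamma_host=1.0, seed=3)
mirna, mrna, truth = ml.generate_paired_cohort(cfg)
gtf_text, _disease = ml.generate_annotation(truth, cfg)

with tempfile.TemporaryDirectory() as tmp:
    gtf = Path(tmp) / "annotation.gtf"
    gtf.write_text(gtf_text)
    annotations = ml.classify_mirna_loci(gtf)

n_intra = sum(a.locus_class == "intragenic" for a in annotations)
print(f"classified {n_intra} intragenic / {len(annotations) - n_intra} intergenic miRNAs")

corr = ml.all_pairs_pearson(
    np.log2(ml.cpm(ml.filter_min_cpm_all_samples(mirna.counts)) + 1),
    np.log2(ml.cpm(ml.filter_min_cpm_all_samples(mrna.counts)) + 1),
)
annotations = [a for a in annotations if a.mirna_id in set(corr["mirna_id"])]
res = ml.stratify_by_locus(corr, annotations, mode="host_pair_only")
print(f"mean host-pair r (intragenic): {res.intragenic_r.mean():+.3f}")
print(f"mean r (intergenic, all pairs): {res.intergenic_r.mean():+.3f}")
print(f"one-sided KS: D={res.ks_D:.3f}, p={res.ks_p:.2e}")
# With host->miRNA co-transcription (gamma=1) the intragenic sample sits
# far to the right: co-expression, not targeting, drives these positives.
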