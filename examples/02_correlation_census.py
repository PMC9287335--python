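"""All-pairs miRNA-mRNA Pearson correlation and its census.

Expression is filtered to features above 1 CPM in every sample, log2(CPM+1)
transformed, correlated pair-by-pair, tested with the exact t transform and
BH-adjusted across all pairs jointly.
"""

import numpy as np

import mirlink as ml

cfg = ml.CohortConfig(n_samples=60, n_mirna=40, n_mrna=500, frac_true_pairs=0.05, seed=1)
mirna, mrna, _truth = ml.generate_paired_cohort(cfg)

mir_l2 = np.log2(ml.cpm(ml.filter_min_cpm_all_samples(mirna.counts)) + 1)
mrna_l2 = np.log2(ml.cpm(ml.filter_min_cpm_all_samples(mrna.counts)) + 1)
corr = ml.all_pairs_pearson(mir_l2, mrna_l2)
cens = ml.census(corr, alpha=0.05)

print(f"testable pairs: {cens.n_pairs}")
print(f"significant positive: {cens.n_sig_pos} ({cens.pct_sig_pos:.2f}%), "
      f"mean r = {cens.mean_r_sig_pos:.3f}")
print(f"significant negative: {cens.n_sig_neg} ({cens.pct_sig_neg:.2f}%), "
      f"mean r = {cens.mean_r_sig_neg:.3f}")
# The negative excess reflects the embedded repressive couplings; under a
# pure null both percentages sit near zero after BH adjustment.
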