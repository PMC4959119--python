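"""Run the SNP preprocessing chain on a structured synthetic cohort.

Variant QC -> LD pruning (window 50, step 5, r^2 0.7) -> EIGENSTRAT-style
PCA -> ancestry-axis selection -> stratification correction -> logistic
prefilter at uncorrected p < 0.1.
"""

import numpy as np

from paraica import genotype_qc as qc
from paraica.synthetic import SyntheticConfig, generate_linked_dataset

cfg = SyntheticConfig(n_subjects=200, n_snps=600, grid_dims=(8, 8, 8),
                      blob_radius_vox=1.2, fst=0.1, ld_within_r=0.4, seed=5)
geno, _, covars, truth = generate_linked_dataset(cfg)

filtered, report = qc.filter_variants(geno)
print("variant QC removals:", report.removed, "->", report.n_retained, "SNPs kept")

kept_ids = qc.ld_prune(filtered, window_snps=50, step_snps=5, r2_max=0.7)
pruned = filtered.subset_snps(filtered.snp_records["snp_id"].isin(kept_ids).to_numpy())
print(f"LD pruning: {filtered.n_snps} -> {pruned.n_snps} SNPs "
      "(every retained within-window pair has r^2 <= 0.7)")

evecs, evals = qc.eigenstrat_pca(pruned, n_axes=5)
axes = qc.select_ancestry_axes(evecs, covars["ethnicity"], n_keep=2)
print(f"ancestry axes associated with self-reported ethnicity: {axes}")
r = np.corrcoef(evecs[:, axes[0]], truth.subpop_labels)[0, 1]
print(f"  leading selected axis vs true subpopulation: |r| = {abs(r):.3f}")

resid = qc.regress_out_covariates(qc.mean_impute(pruned.dosages), evecs[:, axes])
group = covars["group"].to_numpy()
Z = np.column_stack([covars["age"], covars["sex"], evecs[:, axes]])
retained, pvals, flags = qc.logistic_prefilter(resid, group, Z, alpha=0.1)
print(f"logistic prefilter: {len(retained)}/{pruned.n_snps} SNPs at p < 0.1 "
      f"({flags.sum()} flagged unstable) — these would enter the fusion step")
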