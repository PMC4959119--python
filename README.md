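# paraica

Coupled independent component analysis of SNP dosages and gray-matter
volumes, for imaging-genetics studies that look for *collections* of
variants and *patterns* of brain structure that co-vary across subjects —
rather than single-variant associations, which need far larger cohorts.

The package re-implements the full analysis chain as a tested Python
library:

1. **Genotype QC** — call-rate / MAF / exact Hardy-Weinberg filters (HWE in
   controls only), greedy windowed LD pruning (window 50 SNPs, step 5,
   r² ≤ 0.7), EIGENSTRAT-style stratification PCA with ancestry-axis
   selection against self-reported ethnicity, and a liberal per-SNP
   logistic prefilter (uncorrected p < 0.1, adjusting for age, sex and two
   ancestry eigenvectors) that selects the markers entering the fusion.
2. **Phenotype preparation** — Gaussian smoothing of modulated gray-matter
   maps (4 mm FWHM; σ = FWHM/√(8 ln 2)) and masked flattening into a
   subjects × voxels matrix.
3. **Fusion core** — model order per modality by the Wax–Kailath minimum
   description length criterion,
   `MDL(k) = −n(p−k)·log(GM_k/AM_k) + ½k(2p−k)·log n`,
   then parallel ICA: each modality X ≈ A·S is decomposed by
   natural-gradient Infomax on whitened data, while a coupling term
   ascends the gradient of corr²(aᵍᵢ, aᵇⱼ) for the strongest
   cross-modality pair of loading columns — so genuinely linked components
   align without being forced to. Component maps are thresholded at
   |z| > 1.5 with cluster size k > 50 voxels.
4. **Stability** — leave-5%-of-subjects-out refits, matched to the
   full-data sources by optimal |correlation| assignment.
5. **Association** — partial correlations between all loading pairs
   (controlling age, sex, ancestry axes, diagnosis) with Bonferroni
   threshold α/(K_gene·K_brain); pooled-variance t and Levene tests for
   group differences; exploratory clinical correlations.
6. **Genomics** — coordinate-overlap SNP→gene annotation, a VEGAS-style
   Monte-Carlo gene-based test (T = Σ χ²₁ calibrated against multivariate
   normal draws from the cohort LD matrix, removing gene-size bias), and
   hypergeometric pathway enrichment over GMT gene sets with
   Benjamini-Hochberg FDR.
7. **Synthetic data** — a first-class generator producing linked
   genotype/volume datasets with known ground truth: sparse heavy-tailed
   SNP sources, Gaussian-blob spatial sources, cross-modality loading
   correlation a₂ = r·a₁ + √(1−r²)·ε, patient-group loading shifts,
   Balding-Nichols two-subpopulation structure, block-exchangeable LD, and
   Hardy-Weinberg quantile discretization of dosages to {0,1,2}.

Since the kind of cohort this analysis targets is rarely shareable, every
claim the package makes is exercised end-to-end on the synthetic
generator, with recovery checked against the stored ground truth.

## Worked example

`examples/03_coupled_ica_recovery.py` generates a latent-mode linked
dataset (200 subjects, 1000 SNPs, 12³ voxel grid, 4 genetic + 3 brain
components, one linked pair at r = 0.6, noise at half the signal
amplitude), estimates the model orders, and fits the coupled
decomposition:

```
MDL model orders: 4 genetic, 3 brain (planted 4 and 3)
matched source correlations vs truth: gene [0.997 0.997 0.998 0.997], brain [0.995 0.995 0.978]
strongest linked pair: gene 1 x brain 0, loading r = 0.663 (truth 0.672)
```

The MDL criterion finds the planted orders; every recovered source
correlates ≥ 0.98 with its ground-truth counterpart (ICA is identified
only up to sign and permutation, which the matcher resolves); and the
strongest cross-modality loading correlation reproduces the realized
linkage within sampling error. The other examples walk the QC chain,
association tables, gene/pathway statistics, and the one-call pipeline;
`paraica run-all --seed 4 --out runs/demo` does the same from a shell.

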