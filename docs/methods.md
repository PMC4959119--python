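# Methods

This note records the models, the numerical choices, and what the
synthetic benchmark does and does not establish.

## The measurement model

Both modalities are treated as noisy linear mixtures over a shared
subject dimension:

* genetic: X_g (subjects × SNPs) ≈ A_g S_g,
* brain: X_b (subjects × voxels) ≈ A_b S_b,

with loading coefficients A (one column per component, one weight per
subject) and sources S (SNP-weight or voxel-weight patterns, unit-norm
rows). Cross-modality structure lives entirely in the loadings: a linked
pair (i, j) means corr(A_g[:,i], A_b[:,j]) ≠ 0. Group effects are mean
shifts of loading columns, not changes to the source patterns. These are
exactly the assumptions under which parallel ICA is the right estimator,
and the synthetic generator samples from this model by construction.

## Model order (MDL)

Orders are chosen per modality by the Wax–Kailath criterion over the
eigenvalues λ₁ ≥ … ≥ λ_p of the sample covariance, p = min(subjects,
features), subjects as observations:

    MDL(k) = −n (p−k) log(GM_k/AM_k) + ½ k (2p−k) log n

with GM/AM the geometric/arithmetic means of the trailing eigenvalues;
the estimate is the argmin over k ∈ [0, p−1]. Raw eigenvalues are used
(no smoothness correction). The criterion is reliable when the signal
eigenvalues stand clearly above the noise bulk (the benchmark uses
eigenvalue ratio ≥ 10); near the bulk edge it degrades like every
eigenvalue-based selector, which is why the pipeline accepts explicit K
overrides.

## Infomax and the coupling term

Each modality is reduced to K dimensions by PCA whitening (per-subject
means over features removed; top-K eigenvectors of the subject × subject
covariance). The unmixing matrix W starts at the identity and follows the
natural-gradient Infomax update with logistic nonlinearity
g(u) = 1/(1+e^{−u}):

    ΔW = η (I + (1 − 2 g(U)) Uᵀ / B) W,   U = W X_white,

over mini-batches (default 256 columns) in a per-epoch random order. The
learning rate (default 0.01) is multiplied by 0.9 whenever the angle
between successive weight changes exceeds 60°; the run stops when the
relative Frobenius change of W over an epoch falls below `tol` (default
1e−6) or at `max_epochs` (default 400 — the annealing schedule typically
reaches the tolerance shortly before 300 epochs on the benchmark sizes,
and runs that stop at the epoch cap are returned with `converged=False`
rather than discarded, since the sources are normally stable well before
the weight-change criterion is met).

The coupling step is taken once per epoch after both Infomax passes.
Loadings are read off as A = dewhiten · W⁻¹; the strongest pair (i, j)
by |corr(A_g[:,i], A_b[:,j])| is selected among pairs with |r| ≥ τ_link
(default 0.25, so noise pairs are not coupled) and |r| ≤ r_cap (default
0.95, so near-duplicate pairs are not driven into collapse); both W's
then take one analytic gradient-ascent step on corr², using
∂J/∂W = −W⁻ᵀ (dewhitenᵀ ∂J/∂a) W⁻ᵀ restricted to the selected columns.
The default coupling weight λ is set adaptively so the coupling gradient
norm is 10% of the first epoch's Infomax weight change. λ = 0 skips the
step entirely, and because each modality consumes its own seeded RNG
stream, the λ = 0 run is bit-identical to two independent single-modality
fits — a contract the tests assert exactly.

Finalization fixes the ICA indeterminacies: source rows are unit-norm
with positive skewness, components ordered by explained variance, and
loadings recomputed by least squares of the raw data on the sources
(so reported loadings live in the original data units).

## Synthetic generator

Defaults mirror the cohort scale this analysis is designed for: 200
subjects (~1:2 patients:controls), an exome-chip-like panel reduced to
~1000 markers, MAF ~ Uniform(0.05, 0.5), a 12³ voxel grid, a few
components per modality, one linked pair at r = 0.6, and a patient-group
loading shift of 0.5 SD on the linked components.

Choices worth stating explicitly:

* **Noise scale is relative.** Source rows are unit-norm, so one unit of
  component variance is spread across all features; `noise_sd = 0.5`
  therefore means additive Gaussian noise at half the RMS of the signal
  matrix, independent of grid size or panel width. `noise_sd = 0` gives
  an exact factorization (used by the decoupling and exact-recovery
  tests).
* **Dosages by quantile cuts.** The latent genetic matrix is discretized
  per SNP by within-subpopulation empirical quantiles that reproduce
  Hardy-Weinberg genotype frequencies at the subpopulation's
  Balding-Nichols allele frequency (Beta with mean p₀ and variance
  controlled by FST). The cut is monotone in the latent value, so
  component signal survives into the dosages while the marginal MAF is
  controlled. Allele frequencies are floored at 1/(2·n_subpop) so a
  feasible request never produces a monomorphic column; a requested MAF
  below the floor raises with the SNP index.
* **LD as block-exchangeable noise.** Within-block correlation is induced
  by sharing a latent Gaussian across adjacent SNPs in the *noise*
  channel. This is sufficient to exercise LD pruning and the gene test's
  LD calibration; it is not a haplotype/recombination model.
* **Spatial sources** are 1–3 Gaussian blobs with centers ≥ 3σ apart
  (greedy packing with restarts), making distinct sources essentially
  uncorrelated. **SNP sources** are Laplace-weighted with supports drawn
  preferentially from unused indices (pairwise overlap < 20%).
* **Clinical scores** are linear in the linked brain loading plus noise,
  to exercise the exploratory correlation stage.

What passing on this generator does *not* show: robustness to haplotype
LD structure, genotyping batch effects, registration/segmentation error
in real gray-matter maps, non-Gaussian site noise, or model misfit where
the brain signal is not low-rank. The generator is the model the
estimator assumes — the tests establish correctness of the estimation
machinery, not validity of the model for any particular cohort.

## QC layer

Thresholds default to field-standard exome-array values (call rate ≥
0.95, MAF ≥ 0.01, HWE exact p ≥ 1e−6 in controls), applied in that
order with per-filter counts reported. The HWE test is the exact
conditional test on heterozygote counts, two-sided by summing all
outcomes with probability ≤ the observed (no mid-p); it matches a
brute-force enumeration oracle to machine precision. LD pruning is
greedy within sliding windows; when a pair exceeds r², the lower-MAF
member is removed (tie: the later position) — deterministic and close to
common practice. EIGENSTRAT normalization uses the smoothed frequency
estimate p̂ = (1+count)/(2+2n). The logistic prefilter falls back to a
hand-rolled Firth-penalized Newton fit when the ML fit fails to converge
or shows separation-scale standard errors (> 50); SNPs still unstable
are excluded and flagged. Missing dosages use pairwise-complete
statistics in QC and per-SNP mean imputation immediately before fusion,
which requires a complete matrix.

## Stability harness

Each repeat removes a uniformly random 5% of subjects, refits with a
seed derived from the master seed, and matches subsample sources to the
full-data sources by Hungarian assignment on |correlation| over the
shared feature space. A component is "stable" when its mean matched
|correlation| over repeats (default 10) reaches τ_stab = 0.8; the report
exposes both the percent-stable figure and the mean correlations, since
either convention appears in practice. One empirical caveat the tests
encode: on very small voxel grids the voxel-wise ICA rotation is
sample-starved and wobbles at *every* noise level, and for pure-noise
data the top covariance directions of a fixed dataset are themselves
robust to dropping 5% of rows — so the clean "stability decreases with
noise" ordering is asserted on a grid large enough (12³) that the
rotation is well determined in the signal-dominated regime.

## Statistical layer

Partial correlation residualizes both variables on [1, Z] and refers
t = r√(df/(1−r²)), df = n − 2 − q, to the t distribution (two-tailed).
At the published operating point (n = 198, q = 5: age, sex, two ancestry
axes, diagnosis) r = 0.34 gives p = 1×10⁻⁶ and r = 0.31 gives 1×10⁻⁵ to
one significant figure. Pair testing over K_gene × K_brain components
uses the Bonferroni threshold α/(K_gene·K_brain) — 0.05/126 ≈ 3.97×10⁻⁴
at the 14 × 9 orders of the motivating study. Group tests are
pooled-variance t with Levene (mean-centered) alongside; sex is coded
0/1; no interactions. Clinical correlations control age and sex only,
are pairwise-complete over missing scores, and are flagged exploratory
(uncorrected p), with a column reporting what would survive Bonferroni
over the whole table.

## Gene-based test and enrichment

The gene statistic is T = Σᵢ F⁻¹_{χ²₁}(1 − pᵢ) over the gene's SNPs. Its
null distribution is simulated as T' = Σ zᵢ² with z ~ MVN(0, Σ_LD), Σ_LD
the dosage correlation matrix estimated from the analysis cohort (the
original approach used reference panels; cohort LD is self-contained and
matches the data actually tested). p = (1 + #{T' ≥ T})/(1 + n_sims), so
the floor is 1/(1+n_sims) rather than 0; simulations double while
p·n_sims < 10 (up to 10⁶) to keep Monte-Carlo resolution at small p.
Near-PSD LD matrices are repaired by eigenvalue clipping with the
adjustment magnitude checked against a tolerance. Per-SNP inputs default
to component-weight z-scores (two-sided normal p); external per-SNP trait
p-values are accepted as an alternative input, since both conventions are
defensible. Analytic checks: a single-SNP gene reproduces the SNP p; an
identity Σ matches the χ²(m) tail; an all-ones Σ collapses to the shared
SNP p; under the null, gene p is uniform and rank-independent of gene
size — the property that motivates the correction.

Enrichment is the exact upper-tail hypergeometric over pathways
intersected with the background (default background: all genes with ≥ 1
SNP entering the fusion), BH step-up q-values over all tested pathways.

## Problem sizes

Test and acceptance simulations use 100–500 subjects, 300–2000 SNPs and
8³–14³ grids with 3–10 stability repeats and 10³–10⁵ gene-test draws —
sizes chosen so the full property suite exercises every code path on
generated data in a few minutes while leaving the statistical assertions
(calibration bands, recovery thresholds) comfortably powered.

## Known limitations

* The coupling updates one pair per epoch by default (configurable to
  top-m); simultaneous coupling of many pairs can interact with the
  annealing schedule.
* MDL near the noise-bulk edge under- or over-shoots; K overrides exist
  for that reason.
* The Firth fallback implements the Jeffreys-penalized score directly
  and is adequate for prefiltering, but it is not a replacement for a
  full penalized-likelihood inference package.
* No X-chromosome handling, relatedness filtering, or imputation; the
  QC layer assumes autosomal, nominally unrelated samples.
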