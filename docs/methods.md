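# Methods

`igfresponse` analyzes the transcriptional response of patient-derived
neurons to IGF-1 treatment in a paired cohort design: patients measured in
replicate under a vehicle arm (H2O) and two treatment arms (acute, chronic),
split into a disease group (ASD) and neurotypical controls (CTL). This note
records the statistical models, the synthetic-cohort generator that stands
in for the unavailable sequencing data, the numerical choices, and the known
limits of what the test suite demonstrates.

## Differential expression

Counts are modeled per gene as negative binomial, Var = μ + φμ². The stack
re-implements the classic count-DE methodology rather than wrapping an R
package, so the whole pipeline runs in one process and each step is
testable in isolation:

* **TMM normalization.** Per-sample scaling factors from the weighted
  trimmed mean of per-gene log2 ratios against a reference sample (the one
  whose 0.75 count quantile is closest to the cohort mean). Trim fractions:
  30% on M, 5% on A; weights are the usual inverse delta-method variances;
  factors are rescaled to geometric mean 1. Exact numeric parity with any
  particular release of the reference implementation is a non-goal — the
  contract, enforced by a cross-check test against edgeR 4.0 via Rscript, is
  rank-level agreement of the resulting tests (Spearman ρ > 0.9 on p-values,
  r > 0.99 on logFC).
* **Dispersion estimation.** The Cox–Reid adjusted profile likelihood (APL)
  of each gene is evaluated on a log-spaced dispersion grid with IRLS
  warm-started across grid points. The common dispersion maximizes the
  pooled APL; the trend is a lowess fit (frac 0.4) of per-gene maxima
  against average logCPM; tagwise values maximize
  `APL_g + (prior_df / residual_df) * APL_local`, where `APL_local` is the
  moving average of APLs over the gene's abundance neighborhood (window 10%
  of genes) — an empirical-Bayes shrink toward the trend with prior df 10 by
  default. Estimates below the grid floor (1e-4) are snapped to it; at that
  level the extra-Poisson variance is negligible for the count ranges in
  play, and the snap keeps common/trended/tagwise mutually consistent in
  degenerate cases (e.g. a single-gene matrix, where normalization by the
  gene's own counts makes the data exactly Poisson).
* **Exact test** for two-group contrasts. Counts are first mapped to a
  common library size (geometric mean of effective sizes) by a monotone
  quantile transform using gamma distributions moment-matched to the NB on
  both sides; each gene's group sums are then tested conditionally on their
  total, with group sums treated as NB(n_i·μ, φ/n_i) and the two-sided p
  summing all splits no more probable than the observed one. In the φ→0
  limit with equal libraries this reduces exactly to the enumerated
  binomial split test (asserted by an oracle test). logFC uses normalized
  group means with a prior count of 0.125 per sample.
* **GLM likelihood-ratio test** for additive (`treatment + patient`) and
  interaction designs. NB log-link GLMs with fixed tagwise dispersions are
  fit by vectorized IRLS across genes (offsets = log effective library
  size); the LRT statistic is referred to χ² with df equal to the number of
  dropped design columns. The study's quasi-likelihood F variant is
  deliberately simplified to the LRT; non-converged genes get p = NA and are
  excluded from FDR. Design matrices are dummy-coded with H2O/CTL as
  reference levels and aliased columns dropped by greedy rank checks.
* **FDR.** Benjamini–Hochberg step-up (statsmodels), verified against a
  hand-computed oracle.

### Calibration and its limits

With the true per-gene dispersions supplied, the exact test's null p-values
are KS-uniform. With *estimated* dispersions at 12 samples and per-gene
dispersions drawn from a gamma with shape 2 (coefficient of variation ≈
0.7, a realistic level of biological dispersion heterogeneity), null
p-values deviate measurably from uniformity (deficit of small p): the
per-gene dispersion estimation error floor at n = 12 cannot resolve the
heterogeneity, and shrinkage misallocates it. This is a property of the
tagwise-shrinkage methodology, not of this implementation — edgeR 4.0 run
on the identical null matrix shows the same KS failure (D ≈ 0.07,
p ≈ 1e-8). Realized FDR remains controlled (conservative) throughout, which
is the operationally relevant guarantee. The acceptance suite asserts the
strict KS criterion as stated and documents the failure; a companion test
pins the known-dispersion calibration.

## Permutation magnitude test

For a contrast, the observed statistic is the number of genes with
FDR < 0.05. Treatment labels are reshuffled within patient by default (each
patient's arm multiset is preserved, matching the additive patient term; a
global shuffle is available), the full DE machinery — TMM kept, dispersions
re-estimated with shrink-to-common, test re-fit — is re-run per permutation,
and `bootstrap_p = (1 + #{null ≥ observed}) / (n_perm + 1)`. The +1 guards
against p = 0 at finite permutations; the raw fraction the study reports is
also emitted. The additive GLM design is the default; the interaction
design is available but leaves no residual structure for the main effect
with duplicate-level replication. The filter (total abundance ≥ 6 across
samples) is label-free, so filtering once up front and re-filtering per
permutation coincide.

## Classifier robustness

A random forest (500 trees, sklearn) on the signature genes' log2(TPM+1)
with out-of-bag evaluation: OOB error %, confusion matrix, and AUC from OOB
vote fractions (trapezoidal ROC, tie-averaged ranks). Samples never left
out of bag (vanishingly rare at 500 trees) count as an even vote split.

## Overlap and signature statistics

* **Fisher overlap.** The odds ratio is the conditional MLE under Fisher's
  noncentral hypergeometric likelihood (the root of E_OR[X] = x), with the
  exact central 95% CI from inverting one-sided tests at 2.5% per side —
  scipy's `odds_ratio(kind="conditional")`, which satisfies both defining
  equations to ~1e-14. R's `fisher.test` prints slightly different digits
  for the same table because its uniroot tolerance leaves the endpoints at
  one-sided p ≈ 0.0250–0.0251; this package keeps the exact inversion.
* **Temporal grouping** partitions the union of acute- and
  chronic-significant genes into shared / acute_only / chronic_only; shared
  genes take the acute sign, and sign conflicts are labeled "discordant"
  and excluded from trajectory aggregates.
* **Trajectory tests** z-score each gene across all samples, average over
  the group (up- and down-genes separately in the pipeline), and F-test the
  aggregate between the two arms of each contrast. Constant aggregates are
  reported as p = 1 with a degenerate flag.
* **ORA** is a one-sided hypergeometric tail with BH across sets, reading
  gene sets from GMT. The original study's enrichment tool is not named;
  the hypergeometric ORA is this package's documented stand-in.

## Co-expression modules

Unsigned weighted network on the DE-gene union (vehicle + acute samples):
adjacency |cor|^β with β the smallest power whose connectivity distribution
reaches scale-free fit R² > 0.9 (signed R², truncated at 0, over 10
connectivity bins); unsigned TOM; average-linkage clustering of 1 − TOM
with a *static* height cut (default 0.99) — the dynamic hybrid cut of the
original WGCNA is unspecified in enough detail to reproduce, and the static
cut preserves the testable planted-block contract. Clusters under
min_module_size (10) become "unassigned"; surviving modules get color-style
labels by descending size. Eigengenes are first-PC sample scores of the
gene-standardized module submatrix (zero-mean across samples by
construction, sign-aligned to the module average; a single-gene module's
eigengene is its z-scores); each is tested with
`lm(eigengene ~ disease * treatment)` and type-II F-tests, flagging
interaction-significant modules at p < 0.05. The unassigned set is also
summarized as a reportable signature, since the study analyzes its grey
set as its largest signature.

## Response axis and responder calls

The PC space is fit on control vehicle + acute samples restricted to the
control acute DE signature: genes centered and scaled (scaling on by
default, configurable) by *control* statistics, SVD loadings, PC1 sign
oriented so treated controls score higher than vehicle controls. All
samples — including disease samples the fit never saw — are projected with
the control center/scale, which is what makes the axis transferable.
Per-patient response = mean PC1 (treated) − mean PC1 (vehicle); responder
means strictly positive shift. Patients missing an arm are flagged and
excluded from the table, not silently dropped. Covariate associations
(activity, receptor level per arm) are OLS slope F-tests.

## Recovery classification

For genes DE between disease and control at baseline (vehicle arm, exact
test): an arm "recovers" a gene when the treatment shift within ASD opposes
the baseline sign AND treated-ASD vs control-vehicle is no longer
significant (strict rule; a sign-only mode reproduces pure quadrant
membership). Genes normal at baseline but significantly different from the
control state after treatment are flagged "IGF-1 altered". Combined
categories follow from the per-arm calls; recovered_both is exactly the
intersection of the arm sets.

## Synthetic cohort generator

The generator emulates the study design: 7 CTL + 8 ASD patients, 2
replicates, 3 arms (90 samples), 5000 genes, NB counts. Values the study
states are used directly (cohort sizes, arms, FDR 0.05, 100 permutations,
min module size 10, scale-free target 0.9, responder fraction 5/8).
Everything else is a one-time choice at realistic bulk-RNA-seq scales:
baseline log2 means uniform on (1, 8); per-gene dispersion gamma with shape
2 and mean 0.15 (biological CV ≈ 0.4 at the mean, heterogeneous across
genes); library sizes uniform on 0.8–1.2M; patient effect SD 0.3 (log2);
treatment and baseline effects 1.0 log2; planted class fractions 4% shared,
3% acute-only, 3% chronic-only, 6% baseline-DE with half recoverable.
Timepoint-specific genes retain a 25% effect echo at the other timepoint
(the "low-level effects" pattern in the study's trajectory figures).

Response heterogeneity: controls respond with scale r = 1; ASD responders
draw r ~ U(0.3, 1) (positive but attenuated), non-responders r ~ U(−0.5, 0)
(inverted), with 5/8 responders by default. r scales the treatment effect
of the responsive gene classes and the designated receptor gene's
acute-arm level (×2^(r·effect)); the per-patient activity covariate is
`2·r + N(0, 0.5)`. Recoverable baseline genes are shifted back toward the
control level in treated ASD samples by the full baseline effect,
*unscaled* by r and ASD-only: scaling the recovery shift by r would (a)
shift these ASD-specific genes in controls too and (b) cancel only ~1/3 of
the baseline offset at the group level (mean ASD r ≈ 0.3), making
group-level recovery detection structurally impossible; the implemented
coupling keeps responder structure on the response axis and clean planted
truth for the recovery classifier.

The per-patient random effect enters as a single log-scale constant across
all genes, i.e. a library-scale shift that normalization absorbs — patient
structure beyond that (gene-specific patient effects, batch effects,
cell-type mixtures) is deliberately out of scope. One RNG stream is
consumed in a fixed order (gene parameters → classes/directions → patient
effects → response scales → library sizes → counts → activity), so a given
seed yields byte-identical outputs and partial re-simulation is impossible
rather than silently wrong. TPM uses unit gene length (TPM ≡ CPM): no
transcript lengths exist in simulation and all downstream math uses
relative abundances only.

What passing tests do **not** show about real data: the generator has no
gene–gene correlation outside planted modules, no GC/length biases, no
isoform structure, no batch effects, and scalar patient effects — power and
calibration results transfer to real cohorts only to the extent those
factors are second-order.

## QC

Samples are excluded when ln(detected genes) falls below 6 (≈ 403 genes;
base and quantity configurable — the study states only "log(gene counts)"),
then when their (PC1, PC2) distance from the centroid exceeds the mean
distance by 3 SDs. The literal reading "distance exceeds 3 SDs of the
distance" removes essentially all samples whenever the distance
distribution is tight around a large mean (clustered data), so the
mean + k·SD form is used. Identical samples (zero spread) produce no PCA
exclusions. Cell-type scores sum per-gene z-scored log expression over
marker sets (z of a constant gene defined as 0); because z-scoring removes
absolute levels, the score measures relative per-sample composition, not
absolute marker abundance; association with diagnosis is a one-way F-test.

## Problem sizes in the checks

The acceptance suite uses the study's design throughout: the default
5000-gene, 90-sample cohort for sensitivity, recovery and responder
patterns; 2000 genes × 12 samples × 20 replicates for null calibration;
600-gene cohorts with 24–49 permutations for permutation calibration
(the smallest permutation count that can resolve p ≤ 0.05, keeping the
calibration's 20 replicates practical). The pipeline default stays at 100
permutations.

## Known limitations

* LRT in place of the quasi-likelihood F-test makes small-sample p-values
  slightly liberal for the GLM path; rank order is essentially unchanged.
* The exact test's library equalization (gamma quantile map) is the usual
  approximation; with very unequal libraries its tail p-values track the
  ideal conditional binomial only to within a factor of a few (asserted as
  a log-scale agreement test).
* Static tree cut will not split nested modules the dynamic cut can; for
  the planted-block structures of interest it is exact.
* The temporal-class labels inherit the generator's 25% effect echo: with
  realistic power, ~10–15% of timepoint-specific genes are legitimately
  detected at the other timepoint and labeled shared.
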