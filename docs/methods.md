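# Methods

This note records the modeling choices, defaults, and limitations of the
package, stage by stage.

## Synthetic cohort: what it emulates, and what it does not

The generator produces the raw material of a regional folding GWAS with a
known causal chain: genotypes → latent shape factors → rendered skeleton
volumes, with covariate confounding on the side.

**Genotypes.** Dosages are sums of two Bernoulli haplotypes.  LD is
simulated at the haplotype level: within a block (default 5 SNPs, 5 kb
spacing, 1 Mb between blocks), the SNP at distance d from the block anchor
copies the anchor haplotype with probability (1 − ld_decay)^d (default
ld_decay = 0.05) and is redrawn at the block MAF otherwise.  Copying valid
haplotypes — rather than correlating dosages directly — guarantees dosages
in {0,1,2}, Hardy–Weinberg proportions, and a realistic r² decay (≈0.9 per
step here, typical of dense imputed panels at 5 kb spacing).  All SNPs of a
block share one MAF (uniform in [0.05, 0.5]) so copying preserves the
declared frequency exactly.

**Shape factors.** Four per-subject factors drive rendering:
`pcs_strength` (presence/length of the PCS-like fold), `cs_interruption`
(gap width in the CS-like fold), `depth_scale` (depth multiplier), `jitter`
(positional noise scale).  Each is a sum of additive SNP effects, covariate
terms, and Gaussian noise (default sd 1).  When a heritability target h² is
set, each causal SNP's effect is rescaled so that it explains h² of its
factor's variance *empirically in the generated cohort* (default h² = 0.01
per causal SNP; two causal SNPs, one on `pcs_strength`, one on
`cs_interruption`, at the anchors of two distant LD blocks).  Default
covariate confounding: age and site shift `depth_scale` (scanner/ageing
effects on apparent depth; site as additive per-site offsets only, leaving
topology untouched), and sex mildly shifts `pcs_strength` (reported sex
differences in PCS frequency).  Ageing deliberately does not alter fold
topology: the pattern is prenatally fixed; only depth is age-dependent.

**Rendering.** In a 16³ grid of 2 mm voxels, axis 0 is depth (superficial
face at index 0), axis 1 runs along the folds, axis 2 separates the two
fold planes.  The CS sheet is always present with a central gap of width
round(2 + 2·cs_interruption); the PCS sheet is rendered only when
`pcs_strength` > 0 with length round(6 + 3·pcs_strength) — a hard presence
threshold plus continuous length modulation, reproducing the mix of
categorical and continuous variability that makes the PCS notion ambiguous
in the first place.  Sheets are one voxel thick; integer jitter (scale
0.35·|jitter factor|, clipped to ±1 voxel) perturbs positions.  The
generator makes no claim to brain geometry beyond this: no T1 contrast, no
cortical surface, no curvature.  Tests passing on these cohorts show the
*pipeline machinery* recovers planted structure; they say nothing about
real segmentation quality, registration error, or population stratification.

## Preprocessing

The ROI mask is the voxelwise union of a labeled subset's skeletons dilated
by a Euclidean ball of 5 mm measured between voxel centers.  QC removes
subjects whose masked voxel count exceeds 1.2 × the 90th percentile
(linear-interpolation percentile — the one reading of "the last decile"
that yields a single scalar threshold); counts are taken *after* masking,
a choice the upstream description leaves open, and the QC report records
the threshold used.  Downsampling is block max-pooling (presence-preserving
for 1-voxel-thin skeletons, unlike averaging + thresholding); grids are
zero-padded to a multiple of the factor.

## Encoder

The desk-scale encoder is a 4-layer stride-2 3D CNN (channels 8-16-32-64)
with a dense map to a 32-d latent and a 64-64 projection head, trained with
Adam (lr 1e-3, batch 64, 20 epochs, one global seed) on the Barlow Twins
objective; the network and its backprop are implemented in numpy (im2col
convolutions) and verified against finite differences in the test suite.
The cross-correlation C uses batch-centered columns, making it a Pearson
correlation in [−1, 1]; denominators are floored at 1e-9 so zero-variance
columns cannot divide by zero (the floor is inactive on non-degenerate
batches, so exact-oracle tests see the textbook formula).  λ defaults to
5e-3.  Augmentation defaults: translations up to ±2 voxels, depth trimming
of a uniform fraction in [0, 0.3] of occupied depth levels along a fixed
config-declared depth axis (axis 0; the depth map of real pipelines is not
reproduced here), and one of cut-out (box ≤ 0.3 of each axis) or cut-in
(box ≥ 0.7 of each axis).  All augmentations are subtractive, so views are
always valid skeletons.  Embeddings are backbone outputs with no
augmentation at inference; PCA truncation keeps the minimal components
reaching 99.9% cumulative variance (typically 11–14 dims on the default
cohort).

With the cohort's intrinsic dimensionality (~4 factors) far below the
projector width, trained outputs are necessarily more mutually correlated
than random-init projections; the redundancy term's effect is therefore
demonstrated as a λ contrast (higher λ → lower off-diagonal |C|), not as an
absolute comparison to initialization.

## Linear probe

The pattern probe is a linear-kernel SVM with balanced class weights and
C = 0.01, fit on embedding columns standardized to unit variance (PCA
components differ in scale by orders of magnitude; C is only meaningful on
a fixed scale).  Decision values are mapped to probabilities by a logistic
(Platt) calibration fit on out-of-fold decision values from 5 internal
splits.  Cross-validation uses 10 folds stratified jointly on label × site
× sex, with strata under 10 members pooled so folds stay constructible.
Ranking for moving-average maps sorts by (score, subject index) — stable
and reproducible; batch starts are spaced evenly from rank 0 to n − batch
size (default 10 batches of 200).

## Multivariate association

Residualization regresses each embedding column on [intercept, 10 genetic
PCs, age, sex, age², site indicator contrasts] and keeps the residual,
variance-standardized so that the permutation-estimated R is a correlation
matrix (whether the reference method standardizes phenotypes or z-scores is
not documented; standardizing phenotypes makes the two coincide and is the
package default, exposed via `standardize=`).  A rank-deficient design
raises with the collinear columns named.

Per-SNP, per-dimension z-scores are simple-regression t-statistics computed
in closed form from the Pearson correlation, z = r·√((n−2)/(1−r²)), with
1 − r² floored at 1e-12 (a perfect fit yields a large finite z, not an
overflow) and zero-variance SNPs flagged with z = 0.  R is the correlation
of z-score columns across SNPs after subject-wise permutation of the
genotype matrix; eigenvalues are floored at 1e-6 × the largest (logged)
because tens of correlated dimensions can be ill-conditioned.  T = zᵀR⁻¹z
via Cholesky.

**Null model.** T's null distribution comes from the same permuted
z-scores: empirical below the 99th percentile, and above it a gamma fitted
by maximum likelihood (location 0) to all permuted T, rescaled to be
continuous at the junction — monotone by construction and able to reach
small p-values without astronomical permutation counts.  With 10⁴–5·10⁴
permuted statistics the fitted tail agrees with the analytic chi-square in
the independent-dimension case to within ~10% relative down to p = 1e-4;
requests below ~1/(N+1) rely on the gamma extrapolation and a warning names
the attainable empirical floor.  λ_GC is median(χ²₁ quantile of p)/0.4549;
on fully null cohorts it averages 0.97 with sampling sd ≈ 0.07 at 500 SNPs,
so single-run values up to ~1.15 are ordinary noise, and genuine planted
signal inflates it further (as in any GWAS with real associations).

**minP.** Two-sided per-dimension p combined as 1 − (1 − min p)^k (Šidák).
The power contrast between the two combiners is simulated at a per-SNP
variance share of 1% — the same effect size as the cohort's causal SNPs —
split either evenly over 5 of 10 dimensions or loaded on one.

**Genotype QC.** MAF > 0.05 and a Hardy–Weinberg exact test (Wigginton
recurrence) at p < 1e-15 are applied before association; synthetic data
passes both by construction, but the filters run regardless.  The X
chromosome concept does not arise (the generator emits autosomal labels
only).  LD for clumping is in-cohort dosage r²; no external reference panel
is consulted, so locus spans can only be as wide as the genotyped panel
allows.

## Interpretation

Dosage-on-embedding OLS uses the residualized embedding (the association
input); numerically collinear columns trigger a small ridge fallback with a
warning.  Extreme-batch averages take the 200 lowest- and highest-ranked
subjects by predicted dosage (ties broken by subject index).  All ranked
batches are available through the probe's moving-average machinery; the
extremes are the default view.  The 5%/35% display thresholds are rendering
metadata only.  For synthetic cohorts, a recovery metric maps the OLS
coefficient vector back to factor space through the empirical linear
factor-to-embedding fit and reports its cosine to the planted effect
direction.

## Problem sizes and statistical design

Default study conditions: n = 3000 subjects, 16³ grids, 200 SNPs, 20
training epochs — sized so the complete suite and the acceptance script
each run in minutes on one CPU.  A design-time power note: with a causal
SNP explaining h² = 1% of a factor, the omnibus non-centrality is bounded
by n·h²/(1 − h²) ≈ 30 regardless of encoder quality (the embedding sees the
factor only through the rendered volume), and the hard presence threshold
in PCS rendering keeps roughly two thirds of that for the PCS factor.
Against the chi-square-k 1e-5 quantile this leaves single-locus discovery
at these conditions near a coin flip — which is why end-to-end runs
sometimes report one locus and sometimes none, while the extreme-batch
interpretation maps (driven by the embedding's ranking, not by the SNP's
significance) separate the PCS zone robustly in every run.

## Known limitations

- No segmentation, registration, or surface modeling; volumes are born
  co-registered on a common grid.
- The encoder is orders of magnitude smaller than production regional
  encoders; its embeddings are not transferable features.
- The permutation null assumes exchangeable subjects (no relatedness, no
  population structure beyond the regressed-out PCs).
- Replication uses the p < 0.05/l gate plus a user-facing λ_GC report for
  the replication cohort; the "not inflated" condition has no canonical
  threshold and is left as a reported quantity (default guidance λ ≤ 1.1).
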