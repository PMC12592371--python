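# foldgene

Discovery of cortical folding patterns under genetic influence, at desk
scale: a self-supervised representation of regional sulcal skeletons, a
multivariate genome-wide association study (mvGWAS) on that representation,
locus definition and replication gating, and genotype-guided interpretation
of the latent space as folding-pattern transitions.  A synthetic cohort
generator with known ground truth stands in for biobank data, so every stage
is runnable and testable without any download.

## Who this is for

Researchers in imaging genetics who want a transparent, fully inspectable
implementation of the "embed the fold, associate the embedding" strategy for
regions — like the anterior cingulate cortex (ACC) with its sometimes-present
paracingulate sulcus (PCS) running parallel to the cingulate sulcus (CS) —
where categorical pattern labels are too coarse to capture folding
variability.

## The method

**Phenotype.** Each subject contributes a binary 3D sulcal skeleton (a
negative cast of the cortex), masked to a region of interest built as the
union of labeled subjects' skeletons plus a 5 mm dilation, quality-controlled
(subjects with more than 1.2x the 90th-percentile voxel count are dropped)
and downsampled to 2 mm.

**Representation.** An encoder f_θ is trained with the Barlow Twins
objective on pairs of augmented views (translations, fold-depth trimming,
cut-in, cut-out):

    L = Σ_i (1 − C_ii)² + λ Σ_i Σ_{j≠i} C_ij²,
    C_ij = Σ_b z^A_{b,i} z^B_{b,j} / (‖z^A_i‖ ‖z^B_j‖)   (batch-centered)

The embedding is the backbone output before the projection head, truncated
by PCA to the minimal set of components explaining ≥ 99.9% of variance.

**Association.** Embedding dimensions are pre-residualized on 10 genetic
PCs, age, sex, age², and site.  Per SNP i, per-dimension z-scores
z_i = (z_i1 … z_ik) from univariate regressions are combined into the
omnibus statistic

    T_i = z_iᵀ R⁻¹ z_i,

with R the dimension correlation matrix estimated from permuted genotypes
and T's null taken from the same permutations (empirical body, gamma tail).
A minP comparator, 1 − (1 − min_j p_ij)^k, is provided: the omnibus
statistic favors diffuse multi-dimensional signals, minP favors localized
ones.  Significant SNPs are pruned at LD r² ≥ 0.6 (independent significant
SNPs) then r² ≥ 0.1 (lead SNPs); a locus is the smallest interval containing
all SNPs with r² > 0.1 with its lead, loci within 250 kb merged.  A locus
replicates when its lead's replication p < 0.05/l for l discovery loci.

**Interpretation.** For an associated SNP, the minor-allele dosage is
regressed (OLS) on the residualized embedding; subjects ranked by predicted
dosage are averaged in extreme batches of 200, giving voxelwise occupancy
maps (displayed on a 5%–35% scale) that visualize the folding-pattern
transition the SNP tags.

## Worked example

The numbered drivers under `analysis/` run the whole study on the synthetic
cohort (≈6 minutes total on one CPU):

```bash
python analysis/01_simulate_cohort.py          # 3000 subjects, 200 SNPs
python analysis/02_preprocess_qc.py
python analysis/03_train_encoder.py
python analysis/04_probe_pcs.py
python analysis/05_mvgwas.py
python analysis/06_interpret_loci.py --snp rs100010
```

Output from one run of that chain:

```
QC threshold 217.2 voxels; kept 2968/3000 subjects
final twin loss 3.068 (from 22.906); PCA kept 11 dims at 99.9% variance
10-fold stratified CV AUC on 341 labeled subjects: 1.000
197/200 SNPs pass MAF>0.05 and HWE p>1e-15
lambda_GC = 1.273; min p_mv = 2.14e-08; 1 loci at p < 1e-05
lead_snp  chrom  span_start  span_end  p_discovery ind_sig_snps
rs100011      1     3050000   3070000 2.142327e-08     rs100011
rs100010: OLS R2 = 0.0188; extreme-batch maps -> results/interpret_rs100010
```

Reading this: QC removed 32 over-segmented subjects; the twin loss fell
7-fold over 20 epochs; the PCA-truncated embedding (11 dims) linearly
separates planted PCS/non-PCS subjects perfectly; the mvGWAS recovers the
LD block of the planted PCS-factor SNP (rs100010 sits inside the discovered
locus led by its block partner rs100011); λ_GC > 1 here reflects genuine
planted signal, not miscalibration (it is ≈1.0 on fully null cohorts).  The
OLS R² ≈ 0.019 matches the planted ~1% effect plus its LD partners, and the
extreme-batch maps differ almost entirely inside the PCS zone — the
transition from "CS only" to "double-parallel" folding.

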