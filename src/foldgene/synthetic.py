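"""Synthetic cohort generator: genotypes, covariates, latent shape factors,
and rendered sulcal-skeleton volumes with known ground truth.

The generator emulates the raw material of a folding-pattern GWAS at desk
scale: a box-shaped region containing two parametric folds — a cingulate-like
sulcus (CS) that is always present but may be interrupted, and a
paracingulate-like sulcus (PCS) that is present only in part of the
population — plus biallelic SNPs in LD blocks with additive effects on the
latent shape factors, and covariate confounding (age, sex, acquisition site).

Every stochastic step takes an explicit seed and is reproducible bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

FACTOR_NAMES = ("pcs_strength", "cs_interruption", "depth_scale", "jitter")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """Subjects x SNPs additive minor-allele dosages with SNP metadata."""

    dosages: np.ndarray          # (n_subjects, n_snps) int8 in {0,1,2}
    snp_id: np.ndarray           # str per SNP
    chrom: np.ndarray            # int per SNP
    bp: np.ndarray               # base-pair position, strictly increasing per chrom
    a1: np.ndarray               # minor-allele label
    maf: np.ndarray              # declared minor-allele frequency in (0, 0.5]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if not np.isin(self.dosages, (0, 1, 2)).all():
            raise ValueError("dosages must lie in {0,1,2}")
        for c in np.unique(self.chrom):
            bp_c = self.bp[self.chrom == c]
            if not (np.diff(bp_c) > 0).all():
                raise ValueError(f"bp not strictly increasing on chromosome {c}")

    @property
    def n_subjects(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def meta(self) -> pd.DataFrame:
        return pd.DataFrame({"snp_id": self.snp_id, "chrom": self.chrom,
                             "bp": self.bp, "a1": self.a1, "maf": self.maf})

    def empirical_maf(self) -> np.ndarray:
        f = self.dosages.mean(axis=0) / 2.0
        return np.minimum(f, 1.0 - f)


@dataclass
class CausalModel:
    """Ground truth: which SNPs are causal and how they load on the factors.

    ``effect_matrix`` has one row per causal SNP and one column per factor
    (order of :data:`FACTOR_NAMES`); units are factor units per minor allele.
    ``heritability_target`` rescales each causal SNP's row so the SNP explains
    that fraction of its target factor's variance (empirically, see
    :func:`gen_shape_factors`).
    """

    causal_snp_indices: list[int]
    effect_matrix: np.ndarray
    heritability_target: float | None = None

    def __post_init__(self) -> None:
        self.effect_matrix = np.atleast_2d(np.asarray(self.effect_matrix, dtype=float))
        if self.effect_matrix.shape[0] != len(self.causal_snp_indices):
            raise ValueError("effect_matrix rows must align with causal_snp_indices")
        if self.heritability_target is not None and not (0.0 <= self.heritability_target < 1.0):
            raise ValueError("heritability_target must be in [0, 1)")


@dataclass
class ShapeFactors:
    """Per-subject latent shape factors driving the rendered skeleton."""

    values: pd.DataFrame                       # columns = FACTOR_NAMES
    variance_components: dict = field(default_factory=dict)
    realized_effects: np.ndarray | None = None  # effect_matrix after h2 scaling

    def __post_init__(self) -> None:
        missing = set(FACTOR_NAMES) - set(self.values.columns)
        if missing:
            raise ValueError(f"missing factor columns: {sorted(missing)}")
        if not np.isfinite(self.values[list(FACTOR_NAMES)].to_numpy()).all():
            raise ValueError("factors must be finite")


def make_covariates(n_subjects: int, n_sites: int = 3, seed: int = 0) -> pd.DataFrame:
    """Covariate table: age (years), sex {0,1}, site label, 10 genetic PCs."""
    rng = np.random.default_rng(seed)
    df = pd.DataFrame({
        "age": rng.uniform(45.0, 82.0, n_subjects),
        "sex": rng.integers(0, 2, n_subjects),
        "site": [f"site{j}" for j in rng.integers(0, n_sites, n_subjects)],
    })
    for j in range(10):
        df[f"pc{j + 1}"] = rng.normal(size=n_subjects)
    return df


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def gen_genotypes(n_subjects: int, n_snps: int, maf_low: float = 0.05,
                  maf_high: float = 0.5, ld_block_size: int = 5,
                  ld_decay: float = 0.05, seed: int = 0) -> GenotypeMatrix:
    """Draw biallelic dosages as sums of two haplotypes with block LD.

    LD is simulated at the haplotype level: each block has an anchor SNP
    whose haplotypes are Bernoulli(maf); the SNP at distance ``d`` from the
    anchor copies the anchor haplotype with probability ``(1 - ld_decay)**d``
    and is otherwise redrawn independently at the same MAF.  All SNPs of a
    block share one MAF so copying preserves the declared frequency; r²
    between anchor and step-``d`` SNP decays roughly as ``(1 - ld_decay)**2d``.
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    if not (0.05 <= maf_low <= maf_high <= 0.5):
        raise ValueError("require 0.05 <= maf_low <= maf_high <= 0.5")
    if ld_block_size < 1:
        raise ValueError("ld_block_size must be >= 1")
    if not (0.0 <= ld_decay <= 1.0):
        raise ValueError("ld_decay must be in [0,1]")
    rng = np.random.default_rng(seed)

    n_blocks = int(np.ceil(n_snps / ld_block_size))
    block_maf = rng.uniform(maf_low, maf_high, n_blocks)
    haps = np.empty((2, n_subjects, n_snps), dtype=np.int8)
    maf = np.empty(n_snps)
    copy_p = 1.0 - ld_decay
    j = 0
    for b in range(n_blocks):
        size = min(ld_block_size, n_snps - j)
        p = block_maf[b]
        anchor = (rng.random((2, n_subjects)) < p).astype(np.int8)
        for d in range(size):
            if d == 0:
                haps[:, :, j] = anchor
            else:
                keep = rng.random((2, n_subjects)) < copy_p ** d
                fresh = (rng.random((2, n_subjects)) < p).astype(np.int8)
                haps[:, :, j] = np.where(keep, anchor, fresh)
            maf[j] = p
            j += 1

    dosages = haps.sum(axis=0, dtype=np.int8)
    # positions: 5 kb steps within a block, 1 Mb gaps between blocks, chrom 1
    bp = np.empty(n_snps, dtype=np.int64)
    j = 0
    pos = 1_000_000
    for b in range(n_blocks):
        size = min(ld_block_size, n_snps - j)
        for d in range(size):
            bp[j] = pos
            pos += 5_000
            j += 1
        pos += 1_000_000
    return GenotypeMatrix(
        dosages=dosages,
        snp_id=np.array([f"rs{100000 + i}" for i in range(n_snps)]),
        chrom=np.ones(n_snps, dtype=int),
        bp=bp,
        a1=np.array(["A"] * n_snps),
        maf=maf,
    )


# ---------------------------------------------------------------------------
# shape factors
# ---------------------------------------------------------------------------

def gen_shape_factors(G: GenotypeMatrix, causal_model: CausalModel | None,
                      covariates: pd.DataFrame | None = None,
                      covariate_effects: dict | None = None,
                      noise_sd: float = 1.0, seed: int = 0) -> ShapeFactors:
    """factor_j = sum_causal effect_ij * dosage_i + covariate terms + noise.

    ``covariate_effects`` maps factor name -> dict of covariate name -> slope
    (site uses per-site offsets: {"site": {"site0": off, ...}}).  Covariate
    columns age/pc* are standardized before applying slopes so slopes are per
    SD.  When ``causal_model.heritability_target`` is set, each causal SNP's
    effect row is rescaled so that, empirically in this cohort, the SNP
    explains that fraction of the variance of every factor it touches.
    """
    n = G.n_subjects
    rng = np.random.default_rng(seed)
    k = len(FACTOR_NAMES)
    genetic = np.zeros((n, k))
    realized = None
    if causal_model is not None and len(causal_model.causal_snp_indices) > 0:
        idx = np.asarray(causal_model.causal_snp_indices, dtype=int)
        if idx.min() < 0 or idx.max() >= G.n_snps:
            raise IndexError("causal SNP index out of range")
        eff = causal_model.effect_matrix.astype(float).copy()
        D = G.dosages[:, idx].astype(float)
        if causal_model.heritability_target is not None:
            h2 = causal_model.heritability_target
            # non-genetic variance of each factor in this cohort
            cov_part = _covariate_part(n, covariates, covariate_effects)
            base_var = noise_sd ** 2 + cov_part.var(axis=0)
            for i in range(len(idx)):
                dvar = D[:, i].var()
                for jf in range(k):
                    if eff[i, jf] != 0.0 and dvar > 0:
                        target_var = h2 / (1.0 - h2) * base_var[jf]
                        eff[i, jf] = np.sign(eff[i, jf]) * np.sqrt(target_var / dvar)
        genetic = D @ eff
        realized = eff
    cov_part = _covariate_part(n, covariates, covariate_effects)
    noise = rng.normal(scale=noise_sd, size=(n, k)) if noise_sd > 0 else np.zeros((n, k))
    total = genetic + cov_part + noise
    values = pd.DataFrame(total, columns=list(FACTOR_NAMES))
    vc = {
        "genetic": genetic.var(axis=0).tolist(),
        "covariate": cov_part.var(axis=0).tolist(),
        "noise": float(noise_sd) ** 2,
    }
    return ShapeFactors(values=values, variance_components=vc, realized_effects=realized)


def _covariate_part(n: int, covariates: pd.DataFrame | None,
                    covariate_effects: dict | None) -> np.ndarray:
    out = np.zeros((n, len(FACTOR_NAMES)))
    if covariates is None or not covariate_effects:
        return out
    for jf, fname in enumerate(FACTOR_NAMES):
        spec = covariate_effects.get(fname, {})
        for cov_name, slope in spec.items():
            if cov_name == "site":
                offs = covariates["site"].map(slope).fillna(0.0).to_numpy(float)
                out[:, jf] += offs
            else:
                x = covariates[cov_name].to_numpy(float)
                sd = x.std()
                xs = (x - x.mean()) / sd if sd > 0 else x - x.mean()
                out[:, jf] += slope * xs
    return out


DEFAULT_COVARIATE_EFFECTS = {
    # scanner/site and ageing act on apparent fold depth; a mild sex effect on
    # the paracingulate factor mirrors reported sex differences in PCS frequency
    "depth_scale": {"age": -0.35, "site": {"site0": 0.0, "site1": 0.25, "site2": -0.25}},
    "pcs_strength": {"sex": 0.2},
}


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

@dataclass
class SkeletonVolume:
    grid: np.ndarray               # 3D uint8 in {0,1}
    voxel_size_mm: float = 2.0
    affine: np.ndarray | None = None
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if not np.isin(self.grid, (0, 1)).all():
            raise ValueError("skeleton grid must be binary")
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel_size_mm must be positive")
        if self.affine is None:
            self.affine = np.diag([self.voxel_size_mm] * 3 + [1.0])

    def count(self) -> int:
        return int(self.grid.sum())


def _fold_geometry(grid_shape):
    """Shared geometric constants for a given grid: plane positions etc."""
    gx, gy, gz = grid_shape
    return {
        "z_cs": gz // 3,           # lateral plane of the CS sheet
        "z_pcs": (2 * gz) // 3,    # lateral plane of the PCS sheet
        "base_depth": max(4, gx // 2),
    }


def render_skeleton(factors_row, grid_shape=(16, 16, 16), voxel_size_mm: float = 2.0,
                    seed: int = 0, subject_id: str = "") -> SkeletonVolume:
    """Rasterize one subject's skeleton from its shape factors.

    Axis 0 is depth (index 0 = superficial face), axis 1 runs along the
    folds, axis 2 separates the CS plane from the PCS plane.  The CS sheet is
    always present with a central interruption whose width grows with
    ``cs_interruption``; the PCS sheet is rendered only when ``pcs_strength``
    exceeds 0, with length increasing in ``pcs_strength``.  Sheets are one
    voxel thick laterally; their depth extent scales with ``depth_scale`` and
    positions are perturbed by integer jitter.
    """
    if min(grid_shape) < 8:
        raise ValueError("grid_shape must be at least 8 per axis")
    geo = _fold_geometry(grid_shape)
    gx, gy, gz = grid_shape
    if geo["z_pcs"] - geo["z_cs"] < 3:
        raise ValueError("grid too small to separate the two folds")
    f = factors_row
    pcs_strength = float(f["pcs_strength"])
    cs_interruption = float(f["cs_interruption"])
    depth_scale = float(f["depth_scale"])
    # the jitter factor is a positional noise *scale*: interpret through |.|
    # so a zero factor renders deterministically
    jitter = 0.35 * abs(float(f["jitter"]))
    rng = np.random.default_rng(seed)

    grid = np.zeros(grid_shape, dtype=np.uint8)
    depth = int(np.clip(round(geo["base_depth"] * (1.0 + 0.25 * np.tanh(depth_scale))),
                        2, gx - 2))

    def jit() -> int:
        return int(np.clip(round(rng.normal(0.0, jitter)), -1, 1))

    # --- CS: full-length sheet with a central gap ----------------------------
    z_cs = int(np.clip(geo["z_cs"] + jit(), 1, gz - 2))
    y0, y1 = 1, gy - 1
    gap_w = int(np.clip(round(2.0 + 2.0 * cs_interruption), 0, gy - 6))
    gap_c = gy // 2 + jit()
    cs_cols = np.ones(gy, dtype=bool)
    cs_cols[:y0] = cs_cols[y1:] = False
    if gap_w > 0:
        g0 = max(y0, gap_c - gap_w // 2)
        cs_cols[g0:g0 + gap_w] = False
    grid[1:1 + depth, cs_cols, z_cs] = 1

    # --- PCS: present above threshold, length grows with strength ------------
    if pcs_strength > 0.0:
        z_pcs = int(np.clip(geo["z_pcs"] + jit(), geo["z_cs"] + 2, gz - 2))
        length = int(np.clip(round(6.0 + 3.0 * pcs_strength), 3, gy - 2))
        c = gy // 2 + jit()
        p0 = int(np.clip(c - length // 2, 1, gy - 2))
        p1 = int(np.clip(p0 + length, p0 + 1, gy - 1))
        pcs_depth = max(2, int(round(depth * 0.85)))
        grid[1:1 + pcs_depth, p0:p1, z_pcs] = 1

    return SkeletonVolume(grid=grid, voxel_size_mm=voxel_size_mm,
                          subject_id=subject_id)


def render_cohort(factors: ShapeFactors, grid_shape=(16, 16, 16),
                  voxel_size_mm: float = 2.0, seed: int = 0) -> list[SkeletonVolume]:
    """Render every subject; per-subject seeds derive from ``seed``."""
    rng = np.random.default_rng(seed)
    subseeds = rng.integers(0, 2 ** 31 - 1, len(factors.values))
    vols = []
    for i, (_, row) in enumerate(factors.values.iterrows()):
        vols.append(render_skeleton(row, grid_shape, voxel_size_mm,
                                    seed=int(subseeds[i]), subject_id=f"S{i:06d}"))
    return vols


def pcs_zone(grid_shape, tight: bool = False) -> np.ndarray:
    """Ground-truth mask of voxels the PCS sheet can occupy.

    ``tight=True`` restricts to the unjittered plane and the core extent the
    sheet always covers when present — the region used for occupancy metrics.
    """
    geo = _fold_geometry(grid_shape)
    gx, gy, gz = grid_shape
    mask = np.zeros(grid_shape, dtype=bool)
    if tight:
        d = max(2, int(round(geo["base_depth"] * 0.85)) - 1)
        c = gy // 2
        mask[1:1 + d, c - 2:c + 2, geo["z_pcs"]] = True
    else:
        mask[:, :, max(0, geo["z_pcs"] - 1):geo["z_pcs"] + 2] = True
    return mask


def cs_zone(grid_shape) -> np.ndarray:
    geo = _fold_geometry(grid_shape)
    mask = np.zeros(grid_shape, dtype=bool)
    mask[:, :, max(0, geo["z_cs"] - 1):geo["z_cs"] + 2] = True
    return mask


# ---------------------------------------------------------------------------
# cohort on disk
# ---------------------------------------------------------------------------

@dataclass
class CohortConfig:
    """Default study conditions for the synthetic ACC-like cohort."""

    n_subjects: int = 3000
    n_snps: int = 200
    maf_low: float = 0.05
    maf_high: float = 0.5
    ld_block_size: int = 5
    ld_decay: float = 0.05
    grid_shape: tuple = (16, 16, 16)
    voxel_size_mm: float = 2.0
    n_sites: int = 3
    noise_sd: float = 1.0
    heritability: float = 0.01
    # one causal SNP on the PCS factor, one on the CS-interruption factor,
    # placed at the anchors of two distinct LD blocks
    causal_snps: tuple = (10, 110)
    causal_factors: tuple = ("pcs_strength", "cs_interruption")
    covariate_effects: dict = field(default_factory=lambda: DEFAULT_COVARIATE_EFFECTS)
    seed: int = 0


def build_cohort(config: CohortConfig):
    """Generate the full in-memory cohort: (G, covariates, factors, volumes, causal)."""
    if config.n_subjects <= 0:
        raise ValueError("n_subjects must be positive")
    rng = np.random.default_rng(config.seed)
    s_geno, s_cov, s_fact, s_rend = rng.integers(0, 2 ** 31 - 1, 4)
    G = gen_genotypes(config.n_subjects, config.n_snps, config.maf_low,
                      config.maf_high, config.ld_block_size, config.ld_decay,
                      seed=int(s_geno))
    covariates = make_covariates(config.n_subjects, config.n_sites, seed=int(s_cov))
    eff = np.zeros((len(config.causal_snps), len(FACTOR_NAMES)))
    for i, fac in enumerate(config.causal_factors):
        eff[i, FACTOR_NAMES.index(fac)] = 1.0
    causal = CausalModel(causal_snp_indices=list(config.causal_snps),
                         effect_matrix=eff,
                         heritability_target=config.heritability)
    factors = gen_shape_factors(G, causal, covariates, config.covariate_effects,
                                noise_sd=config.noise_sd, seed=int(s_fact))
    volumes = render_cohort(factors, config.grid_shape, config.voxel_size_mm,
                            seed=int(s_rend))
    return G, covariates, factors, volumes, causal


def gen_cohort(config: CohortConfig, out_dir: str) -> dict:
    """Materialize a cohort on disk: NIfTI volumes, PLINK genotypes, TSVs.

    Returns a manifest dict of the paths written.
    """
    import nibabel as nib

    from . import plink

    G, covariates, factors, volumes, causal = build_cohort(config)
    os.makedirs(out_dir, exist_ok=True)
    vol_dir = os.path.join(out_dir, "volumes")
    os.makedirs(vol_dir, exist_ok=True)
    subject_ids = [v.subject_id for v in volumes]
    for v in volumes:
        img = nib.Nifti1Image(v.grid.astype(np.uint8), v.affine)
        nib.save(img, os.path.join(vol_dir, f"{v.subject_id}.nii.gz"))

    prefix = os.path.join(out_dir, "genotypes")
    plink.write_bed(prefix, G.dosages, G.meta(), subject_ids)
    plink.write_dosage_tsv(os.path.join(out_dir, "dosages.tsv"), G.dosages,
                           G.meta(), subject_ids)

    cov = covariates.copy()
    cov.insert(0, "subject_id", subject_ids)
    cov.to_csv(os.path.join(out_dir, "covariates.tsv"), sep="\t", index=False)

    gt = factors.values.copy()
    gt.insert(0, "subject_id", subject_ids)
    gt.to_csv(os.path.join(out_dir, "factors.tsv"), sep="\t", index=False)

    cm = pd.DataFrame(causal.effect_matrix if factors.realized_effects is None
                      else factors.realized_effects, columns=list(FACTOR_NAMES))
    cm.insert(0, "snp_index", causal.causal_snp_indices)
    cm.insert(1, "snp_id", [G.snp_id[i] for i in causal.causal_snp_indices])
    cm.to_csv(os.path.join(out_dir, "causal_model.tsv"), sep="\t", index=False)

    with open(os.path.join(out_dir, "config.json"), "w") as fh:
        json.dump({k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in dataclasses.asdict(config).items()
                   if not isinstance(v, dict)}, fh, indent=2)

    return {"volumes": vol_dir, "plink_prefix": prefix,
            "covariates": os.path.join(out_dir, "covariates.tsv"),
            "factors": os.path.join(out_dir, "factors.tsv"),
            "causal_model": os.path.join(out_dir, "causal_model.tsv")}


def load_cohort(out_dir: str):
    """Read back a cohort written by :func:`gen_cohort`.

    Returns (G, covariates, factors_df, volumes, causal_df); the declared
    MAF column is recomputed empirically on load.
    """
    import nibabel as nib

    from . import plink

    prefix = os.path.join(out_dir, "genotypes")
    dosages, meta, subject_ids = plink.read_bed(prefix)
    maf = dosages.mean(axis=0) / 2.0
    maf = np.minimum(maf, 1.0 - maf)
    G = GenotypeMatrix(dosages=dosages, snp_id=meta["snp_id"].to_numpy(),
                       chrom=meta["chrom"].to_numpy(), bp=meta["bp"].to_numpy(),
                       a1=meta["a1"].to_numpy(), maf=maf)
    covariates = pd.read_csv(os.path.join(out_dir, "covariates.tsv"), sep="\t")
    factors_df = pd.read_csv(os.path.join(out_dir, "factors.tsv"), sep="\t")
    causal_df = pd.read_csv(os.path.join(out_dir, "causal_model.tsv"), sep="\t")
    volumes = []
    for sid in subject_ids:
        img = nib.load(os.path.join(out_dir, "volumes", f"{sid}.nii.gz"))
        vox = float(img.header.get_zooms()[0])
        volumes.append(SkeletonVolume(grid=np.asarray(img.dataobj).astype(np.uint8),
                                      voxel_size_mm=vox, affine=img.affine,
                                      subject_id=sid))
    return G, covariates, factors_df, volumes, causal_df
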