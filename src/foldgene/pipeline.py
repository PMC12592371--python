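"""End-to-end orchestration: synthetic cohort -> preprocessing -> encoder ->
embedding -> multivariate association -> loci -> interpretation.

Used by the numbered analysis drivers, the acceptance script, and the
end-to-end tests; every stage is importable on its own.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import assoc, interpret, preprocess
from .augment import AugmentationConfig
from .encoder import EncoderConfig, EncoderState, embed, reduce_pca, train_encoder
from .synthetic import CohortConfig, build_cohort, pcs_zone


@dataclass
class PipelineResult:
    cohort: tuple
    encoder: EncoderState
    E_res: object
    result: assoc.MvAssocResult
    loci: assoc.LocusTable
    kept: np.ndarray
    qc_threshold: float
    extras: dict = field(default_factory=dict)


def run_pipeline(cohort_config: CohortConfig | None = None,
                 encoder_config: EncoderConfig | None = None,
                 augmentation_config: AugmentationConfig | None = None,
                 n_perm: int = 20, p_thresh: float = 1e-5,
                 seed: int = 0, verbose: bool = False) -> PipelineResult:
    """Run the full discovery pipeline on a synthetic cohort.

    ``seed`` drives cohort generation, encoder training and the permutation
    null (sub-seeds are derived from it).
    """
    rng = np.random.default_rng(seed)
    s_cohort, s_enc, s_perm = (int(x) for x in rng.integers(0, 2 ** 31 - 1, 3))

    ccfg = cohort_config or CohortConfig()
    ccfg = type(ccfg)(**{**ccfg.__dict__, "seed": s_cohort})
    G, covariates, factors, volumes, causal = build_cohort(ccfg)

    # QC on masked voxel counts (volumes are generated inside the ROI box)
    counts = [v.count() for v in volumes]
    kept, thr = preprocess.qc_filter(counts)
    volumes_k = [volumes[i] for i in kept]

    ecfg = encoder_config or EncoderConfig()
    ecfg = type(ecfg)(**{**ecfg.__dict__, "seed": s_enc})
    state = train_encoder(volumes_k, ecfg, augmentation_config, verbose=verbose)

    E_raw = embed(state, volumes_k)
    E_pca = reduce_pca(E_raw)
    cov_k = covariates.iloc[kept].reset_index(drop=True)
    E_res = assoc.residualize(E_pca, cov_k)

    from .synthetic import GenotypeMatrix
    G_k = GenotypeMatrix(dosages=G.dosages[kept], snp_id=G.snp_id,
                         chrom=G.chrom, bp=G.bp, a1=G.a1, maf=G.maf)
    G_f, snp_kept = assoc.filter_snps(G_k)
    res = assoc.run_mostest(E_res, G_f, n_perm=n_perm, seed=s_perm)
    ld = assoc.ld_r2_matrix(G_f)
    loci = assoc.clump_loci(res.summary, res.p_mv, ld, p_thresh=p_thresh)

    return PipelineResult(cohort=(G_f, cov_k, factors, volumes_k, causal),
                          encoder=state, E_res=E_res, result=res, loci=loci,
                          kept=kept, qc_threshold=thr,
                          extras={"snp_kept": snp_kept, "E_pca": E_pca,
                                  "ld": ld, "cohort_config": ccfg})


def causal_recovery(pr: PipelineResult) -> dict:
    """Which planted causal SNPs fall inside a discovered locus span."""
    G_f, _, factors, _, causal = pr.cohort
    snp_kept = pr.extras["snp_kept"]
    ccfg = pr.extras["cohort_config"]
    recovered = {}
    for orig_idx in causal.causal_snp_indices:
        pos = np.flatnonzero(snp_kept == orig_idx)
        if pos.size == 0:
            recovered[orig_idx] = False
            continue
        j = int(pos[0])
        bp, chrom = G_f.bp[j], G_f.chrom[j]
        hit = any((row["chrom"] == chrom and
                   row["span_start"] <= bp <= row["span_end"])
                  for _, row in pr.loci.loci.iterrows())
        recovered[orig_idx] = bool(hit)
    return recovered


def interpret_snp(pr: PipelineResult, snp_index: int, batch_size: int = 200):
    """Dosage OLS + extreme batch maps for one SNP of the filtered panel."""
    G_f, _, factors, volumes, causal = pr.cohort
    reg = interpret.dosage_ols(pr.E_res, G_f.dosages[:, snp_index].astype(float))
    low, high = interpret.extreme_batch_averages(volumes, reg.y_pred, batch_size)
    return reg, low, high


def pcs_occupancy_gap(pr: PipelineResult, low, high) -> float:
    """Mean occupancy difference (high - low) inside the tight PCS zone."""
    ccfg = pr.extras["cohort_config"]
    zone = pcs_zone(tuple(ccfg.grid_shape), tight=True)
    return float(high.values[zone].mean() - low.values[zone].mean())
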