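"""Multivariate genome-wide association on the latent embedding.

Per SNP, univariate association z-scores with each embedding dimension are
combined into the omnibus statistic

    T_i = z_i' R^{-1} z_i

where R is the phenotype correlation matrix estimated from z-scores under
permuted genotypes; T's null distribution is taken from the same permuted
statistics (empirical body, gamma-extrapolated tail).  The module also
provides the minP comparator, genomic control, FUMA-style two-stage LD
clumping into loci, and the per-locus replication gate p < 0.05 / l.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .encoder import EmbeddingMatrix
from .synthetic import GenotypeMatrix

_CHI2_MEDIAN_1DF = float(stats.chi2.ppf(0.5, 1))  # 0.454936...


# ---------------------------------------------------------------------------
# covariate residualization
# ---------------------------------------------------------------------------

def design_matrix(covariates: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """[intercept, genetic PCs, age, sex, age², site indicator contrasts]."""
    n = len(covariates)
    cols: list[np.ndarray] = [np.ones(n)]
    names = ["intercept"]
    for c in covariates.columns:
        if c.startswith("pc"):
            cols.append(covariates[c].to_numpy(float))
            names.append(c)
    age = covariates["age"].to_numpy(float)
    cols += [age, covariates["sex"].to_numpy(float), age ** 2]
    names += ["age", "sex", "age2"]
    sites = sorted(covariates["site"].astype(str).unique())
    for s in sites[1:]:  # drop-first contrast coding
        cols.append((covariates["site"].astype(str) == s).to_numpy(float))
        names.append(f"site[{s}]")
    return np.column_stack(cols), names


def residualize(E: EmbeddingMatrix, covariates: pd.DataFrame,
                standardize: bool = True) -> EmbeddingMatrix:
    """Least-squares residual of each embedding column on the covariate design.

    Raises on a rank-deficient design, naming the collinear columns.  After
    residualization each dimension is variance-standardized (so the
    permutation-based R is a correlation matrix); disable with
    ``standardize=False``.
    """
    X, names = design_matrix(covariates)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        _, R_qr = np.linalg.qr(X)
        bad = [names[j] for j in range(X.shape[1])
               if abs(R_qr[j, j]) < 1e-8 * abs(R_qr[0, 0])]
        raise ValueError(f"rank-deficient covariate design; collinear columns: {bad}")
    beta, *_ = np.linalg.lstsq(X, E.values, rcond=None)
    resid = E.values - X @ beta
    if standardize:
        sd = resid.std(axis=0)
        sd[sd == 0] = 1.0
        resid = resid / sd
    return EmbeddingMatrix(values=resid, subject_ids=E.subject_ids,
                           state="residualized")


# ---------------------------------------------------------------------------
# summary statistics
# ---------------------------------------------------------------------------

@dataclass
class SummaryStats:
    z: np.ndarray                 # (n_snps, k)
    meta: pd.DataFrame            # snp_id, chrom, bp, a1, maf, n
    zero_variance: np.ndarray | None = None


def _zscores(Y: np.ndarray, D: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized per-SNP x per-dimension simple-regression z-scores.

    For simple linear regression the coefficient t-statistic equals
    r * sqrt((n-2) / (1-r²)) with r the Pearson correlation; for zero-variance
    SNPs z is set to 0 and flagged.
    """
    n = Y.shape[0]
    Yc = Y - Y.mean(axis=0)
    Yn = Yc / np.maximum(np.sqrt((Yc ** 2).sum(axis=0)), 1e-300)
    Dc = D - D.mean(axis=0)
    dnorm = np.sqrt((Dc ** 2).sum(axis=0))
    zero_var = dnorm == 0
    Dn = Dc / np.where(zero_var, 1.0, dnorm)
    r = Dn.T @ Yn
    r2 = np.clip(r ** 2, 0.0, 1.0 - 1e-12)  # epsilon guard for perfect fits
    z = r * np.sqrt((n - 2) / (1.0 - r2))
    z[zero_var, :] = 0.0
    return z, zero_var


def univariate_z(E_res: EmbeddingMatrix, G: GenotypeMatrix) -> SummaryStats:
    """Standard per-dimension GWAS z-scores for every SNP."""
    if E_res.values.shape[0] != G.n_subjects:
        raise ValueError("embedding and genotypes have different subject counts")
    z, zero_var = _zscores(E_res.values, G.dosages.astype(float))
    meta = G.meta()
    meta["n"] = G.n_subjects
    return SummaryStats(z=z, meta=meta, zero_variance=zero_var)


# ---------------------------------------------------------------------------
# MOSTest statistic and permutation null
# ---------------------------------------------------------------------------

def permuted_zscores(E_res: EmbeddingMatrix, G: GenotypeMatrix, n_perm: int,
                     seed: int = 0) -> np.ndarray:
    """z-scores after subject-wise permutation of the genotype rows,
    stacked over ``n_perm`` permutations: shape (n_perm * n_snps, k)."""
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    Y = E_res.values
    D = G.dosages.astype(float)
    out = []
    for _ in range(n_perm):
        perm = rng.permutation(G.n_subjects)
        z, _ = _zscores(Y, D[perm])
        out.append(z)
    return np.vstack(out)


def estimate_R(E_res: EmbeddingMatrix, G: GenotypeMatrix, n_perm: int,
               seed: int = 0, z_perm: np.ndarray | None = None,
               eig_floor: float = 1e-6) -> np.ndarray:
    """Phenotype correlation matrix from permuted-genotype z-scores.

    Conditioned to be positive definite by flooring eigenvalues at
    ``eig_floor`` times the largest.
    """
    if z_perm is None:
        z_perm = permuted_zscores(E_res, G, n_perm, seed)
    k = z_perm.shape[1]
    if z_perm.shape[0] <= k:
        raise ValueError("need more permuted statistics than dimensions")
    R = np.corrcoef(z_perm, rowvar=False)
    R = np.atleast_2d(R)
    w, V = np.linalg.eigh(R)
    floor = eig_floor * w.max()
    if (w < floor).any():
        warnings.warn(f"R eigenvalues floored at {floor:.3e}")
        w = np.maximum(w, floor)
        R = (V * w) @ V.T
        d = np.sqrt(np.diag(R))
        R = R / np.outer(d, d)
    return R


def mostest_stat(z: np.ndarray, R: np.ndarray):
    """T = z' R^{-1} z for one z row (returns float) or a matrix of rows."""
    z_arr = np.asarray(z, dtype=float)
    single = z_arr.ndim == 1
    z2 = np.atleast_2d(z_arr)
    R = np.atleast_2d(np.asarray(R, dtype=float))
    try:
        L = np.linalg.cholesky(R)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError("R is not positive definite; condition it "
                                    "with estimate_R") from exc
    w = np.linalg.solve(L, z2.T)
    T = (w ** 2).sum(axis=0)
    return float(T[0]) if single else T


@dataclass
class NullModel:
    """Permutation null for T: empirical body, gamma tail above q99."""

    T_perm: np.ndarray
    gamma_shape: float = field(init=False)
    gamma_scale: float = field(init=False)
    q99: float = field(init=False)
    p_at_q99: float = field(init=False)

    def __post_init__(self) -> None:
        T = np.sort(np.asarray(self.T_perm, dtype=float))
        if T.size < 100:
            raise ValueError("too few permuted statistics for a null model")
        self.T_perm = T
        shape, _, scale = stats.gamma.fit(T, floc=0)
        self.gamma_shape, self.gamma_scale = float(shape), float(scale)
        self.q99 = float(np.quantile(T, 0.99))
        self.p_at_q99 = self._p_emp(np.array([self.q99]))[0]

    def _p_emp(self, T_obs: np.ndarray) -> np.ndarray:
        n = self.T_perm.size
        n_ge = n - np.searchsorted(self.T_perm, T_obs, side="right")
        return (1.0 + n_ge) / (n + 1.0)

    def pvalue(self, T_obs) -> np.ndarray:
        """p in (0,1]; monotone non-increasing in T by construction."""
        T_obs = np.atleast_1d(np.asarray(T_obs, dtype=float))
        p = self._p_emp(T_obs)
        tail = T_obs > self.q99
        if tail.any():
            sf = stats.gamma.sf(T_obs[tail], self.gamma_shape, scale=self.gamma_scale)
            sf99 = stats.gamma.sf(self.q99, self.gamma_shape, scale=self.gamma_scale)
            p[tail] = self.p_at_q99 * sf / max(sf99, 1e-300)
        return np.clip(p, np.finfo(float).tiny, 1.0)

    def attainable_floor(self) -> float:
        return 1.0 / (self.T_perm.size + 1.0)


def null_pvalue(T_obs, T_perm) -> np.ndarray:
    """Convenience wrapper: build the null model and evaluate p-values."""
    if np.asarray(T_perm).size < 10_000:
        warnings.warn("fewer than 1e4 permuted statistics; small p-values "
                      f"are floored near {1.0 / (np.asarray(T_perm).size + 1):.2e}")
    return NullModel(np.asarray(T_perm)).pvalue(T_obs)


def minp_stat(z, k: int | None = None) -> np.ndarray:
    """Šidák-combined best single-dimension p-value.

    Per-dimension two-sided p, then p = 1 - (1 - min_j p_j)^k; sensitive to
    signals localized in one dimension.
    """
    z = np.atleast_2d(np.asarray(z, dtype=float))
    k = k or z.shape[1]
    p_dim = 2.0 * stats.norm.sf(np.abs(z))
    pmin = p_dim.min(axis=1)
    p = -np.expm1(k * np.log1p(-np.clip(pmin, 0.0, 1.0 - 1e-16)))
    p[pmin >= 1.0] = 1.0
    return np.clip(p, np.finfo(float).tiny, 1.0)


def lambda_gc(pvals) -> float:
    """Genomic inflation: median 1-df chi-square quantile of the p-values
    over the null median 0.4549."""
    p = np.asarray(pvals, dtype=float)
    if p.size < 100:
        raise ValueError("need at least 100 p-values")
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    chi = stats.chi2.isf(p, 1)
    return float(np.median(chi) / _CHI2_MEDIAN_1DF)


# ---------------------------------------------------------------------------
# full MOSTest run
# ---------------------------------------------------------------------------

@dataclass
class MvAssocResult:
    summary: SummaryStats
    T: np.ndarray
    p_mv: np.ndarray
    p_minp: np.ndarray
    R: np.ndarray
    null: NullModel

    def table(self) -> pd.DataFrame:
        df = self.summary.meta.copy()
        for j in range(self.summary.z.shape[1]):
            df[f"z_{j + 1}"] = self.summary.z[:, j]
        df["T"] = self.T
        df["p_mv"] = self.p_mv
        df["p_minp"] = self.p_minp
        return df


def run_mostest(E_res: EmbeddingMatrix, G: GenotypeMatrix, n_perm: int = 20,
                seed: int = 0) -> MvAssocResult:
    """Residualized embedding + genotypes -> per-SNP omnibus statistics.

    One set of permuted genotypes supplies both the phenotype correlation R
    and the null distribution of T.
    """
    summary = univariate_z(E_res, G)
    z_perm = permuted_zscores(E_res, G, n_perm, seed)
    R = estimate_R(E_res, G, n_perm, seed, z_perm=z_perm)
    T_obs = np.atleast_1d(mostest_stat(summary.z, R))
    T_perm = np.atleast_1d(mostest_stat(z_perm, R))
    null = NullModel(T_perm)
    return MvAssocResult(summary=summary, T=T_obs, p_mv=null.pvalue(T_obs),
                         p_minp=minp_stat(summary.z), R=R, null=null)


# ---------------------------------------------------------------------------
# genotype QC filters
# ---------------------------------------------------------------------------

def hwe_exact_pvalue(n_het: int, n_hom_minor: int, n_hom_major: int) -> float:
    """Exact Hardy–Weinberg test (mid-less two-sided, Wigginton-style)."""
    n = n_het + n_hom_minor + n_hom_major
    n_rare = 2 * n_hom_minor + n_het
    if n_rare > n:  # ensure 'rare' really is the minor allele
        n_rare = 2 * n - n_rare
    probs = np.zeros(n_rare + 1)
    # feasible het counts share parity with n_rare
    mid = int(round(n_rare * (2.0 * n - n_rare) / (2.0 * n)))
    if mid % 2 != n_rare % 2:
        mid += 1
    mid = min(mid, n_rare)
    probs[mid] = 1.0
    # downward recurrence
    het, hom_r = mid, (n_rare - mid) // 2
    hom_c = n - het - hom_r
    while het >= 2:
        probs[het - 2] = probs[het] * het * (het - 1) / (4.0 * (hom_r + 1) * (hom_c + 1))
        het -= 2
        hom_r += 1
        hom_c += 1
    # upward recurrence
    het, hom_r = mid, (n_rare - mid) // 2
    hom_c = n - het - hom_r
    while het <= n_rare - 2:
        probs[het + 2] = probs[het] * 4.0 * hom_r * hom_c / ((het + 2.0) * (het + 1.0))
        het += 2
        hom_r -= 1
        hom_c -= 1
    probs /= probs.sum()
    obs = n_het if n_het <= n_rare else n_rare
    return float(min(1.0, probs[probs <= probs[obs] * (1 + 1e-12)].sum()))


def filter_snps(G: GenotypeMatrix, maf_min: float = 0.05,
                hwe_p: float = 1e-15) -> tuple[GenotypeMatrix, np.ndarray]:
    """MAF and Hardy–Weinberg filters; returns (filtered G, kept indices)."""
    maf = G.empirical_maf()
    keep = maf > maf_min
    for j in np.flatnonzero(keep):
        d = G.dosages[:, j]
        p = hwe_exact_pvalue(int((d == 1).sum()), int((d == 2).sum()),
                             int((d == 0).sum()))
        if p < hwe_p:
            keep[j] = False
    idx = np.flatnonzero(keep)
    Gf = GenotypeMatrix(dosages=G.dosages[:, idx], snp_id=G.snp_id[idx],
                        chrom=G.chrom[idx], bp=G.bp[idx], a1=G.a1[idx],
                        maf=G.maf[idx])
    return Gf, idx


# ---------------------------------------------------------------------------
# clumping, loci, replication
# ---------------------------------------------------------------------------

def ld_r2_matrix(G: GenotypeMatrix) -> np.ndarray:
    """In-cohort pairwise dosage r²."""
    D = G.dosages.astype(float)
    sd = D.std(axis=0)
    ok = sd > 0
    r = np.zeros((G.n_snps, G.n_snps))
    if ok.any():
        sub = np.corrcoef(D[:, ok], rowvar=False)
        r[np.ix_(ok, ok)] = np.atleast_2d(sub)
    np.fill_diagonal(r, 1.0)
    return r ** 2


@dataclass
class LocusTable:
    loci: pd.DataFrame  # lead_snp, chrom, span_start, span_end, p_discovery,
    #                     ind_sig_snps, p_replication, validated

    def __len__(self) -> int:
        return len(self.loci)


def clump_loci(summary: SummaryStats, p_mv: np.ndarray, ld_matrix: np.ndarray,
               p_thresh: float = 5e-8, r2_indep: float = 0.6,
               r2_lead: float = 0.1, merge_kb: float = 250.0) -> LocusTable:
    """FUMA-style two-stage greedy pruning and locus definition.

    1. SNPs with p < p_thresh, ascending by p, greedily pruned at
       r² >= r2_indep -> independent significant SNPs.
    2. Those pruned again at r² >= r2_lead -> lead SNPs.
    3. Each lead's locus is the smallest contiguous bp interval containing
       every same-chromosome SNP with r² > r2_lead with the lead.
    4. Same-chromosome loci closer than merge_kb kb are merged; the merged
       lead is the minimum-p lead.
    """
    meta = summary.meta
    p_mv = np.asarray(p_mv, dtype=float)
    sig = np.flatnonzero(p_mv < p_thresh)
    cols = ["lead_snp", "chrom", "span_start", "span_end", "p_discovery",
            "ind_sig_snps"]
    if sig.size == 0:
        return LocusTable(pd.DataFrame(columns=cols))
    sig = sig[np.lexsort((sig, p_mv[sig]))]  # ascending p, stable

    ind_sig: list[int] = []
    for i in sig:
        if all(ld_matrix[i, j] < r2_indep for j in ind_sig):
            ind_sig.append(i)
    leads: list[int] = []
    for i in ind_sig:
        if all(ld_matrix[i, j] < r2_lead for j in leads):
            leads.append(i)

    chrom = meta["chrom"].to_numpy()
    bp = meta["bp"].to_numpy()
    loci = []
    for lead in leads:
        partners = np.flatnonzero((chrom == chrom[lead]) &
                                  (ld_matrix[lead] > r2_lead))
        partners = np.union1d(partners, [lead])
        loci.append({"lead": lead, "chrom": int(chrom[lead]),
                     "start": int(bp[partners].min()),
                     "end": int(bp[partners].max()), "p": float(p_mv[lead])})

    # merge same-chromosome loci closer than merge_kb
    loci.sort(key=lambda d: (d["chrom"], d["start"]))
    merged = []
    for loc in loci:
        prev = merged[-1] if merged else None
        if (prev is not None and loc["chrom"] == prev["chrom"]
                and loc["start"] - prev["end"] < merge_kb * 1000.0):
            prev["end"] = max(prev["end"], loc["end"])
            prev["start"] = min(prev["start"], loc["start"])
            if loc["p"] < prev["p"]:
                prev["lead"], prev["p"] = loc["lead"], loc["p"]
        else:
            merged.append(dict(loc))

    rows = []
    for loc in merged:
        members = [i for i in ind_sig if chrom[i] == loc["chrom"]
                   and loc["start"] <= bp[i] <= loc["end"]]
        rows.append({
            "lead_snp": meta["snp_id"].iloc[loc["lead"]],
            "chrom": loc["chrom"],
            "span_start": loc["start"],
            "span_end": loc["end"],
            "p_discovery": loc["p"],
            "ind_sig_snps": ";".join(meta["snp_id"].iloc[i] for i in members),
        })
    df = pd.DataFrame(rows, columns=cols)
    return LocusTable(df.sort_values(["chrom", "span_start"]).reset_index(drop=True))


def replication_check(locus_table: LocusTable, p_repl_per_lead: dict,
                      alpha: float = 0.05) -> LocusTable:
    """Validated iff the lead's replication p < alpha / (number of loci)."""
    df = locus_table.loci.copy()
    n_loci = len(df)
    p_repl, validated, reason = [], [], []
    for _, row in df.iterrows():
        pr = p_repl_per_lead.get(row["lead_snp"])
        if pr is None:
            p_repl.append(np.nan)
            validated.append(False)
            reason.append("missing replication p-value")
        else:
            p_repl.append(float(pr))
            ok = pr < alpha / n_loci
            validated.append(bool(ok))
            reason.append("" if ok else f"p >= {alpha}/{n_loci}")
    df["p_replication"] = p_repl
    df["validated"] = validated
    df["reason"] = reason
    return LocusTable(df)
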