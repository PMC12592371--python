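import numpy as np
import pandas as pd
import pytest
from scipy import stats

from foldgene import assoc
from foldgene.encoder import EmbeddingMatrix
from foldgene.synthetic import GenotypeMatrix, gen_genotypes, make_covariates


def _emb(X, state="residualized"):
    return EmbeddingMatrix(X, [f"s{i}" for i in range(len(X))], state=state)


class TestResidualize:
    def test_orthogonal_column_unchanged(self):
        rng = np.random.default_rng(0)
        cov = make_covariates(200, seed=1)
        X, _ = assoc.design_matrix(cov)
        y = rng.normal(size=200)
        y_orth = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
        E = _emb(y_orth[:, None], state="pca")
        out = assoc.residualize(E, cov, standardize=False)
        assert np.allclose(out.values[:, 0], y_orth, atol=1e-10)

    def test_covariate_column_residual_zero(self):
        cov = make_covariates(150, seed=2)
        E = _emb(cov["age"].to_numpy()[:, None], state="pca")
        out = assoc.residualize(E, cov, standardize=False)
        assert np.abs(out.values).max() < 1e-8

    def test_matches_projection_oracle(self):
        """Residuals equal (I - X (X'X)^-1 X') y on a small fixture."""
        rng = np.random.default_rng(3)
        cov = make_covariates(20, seed=3)
        Y = rng.normal(size=(20, 3))
        X, _ = assoc.design_matrix(cov)
        P = np.eye(20) - X @ np.linalg.inv(X.T @ X) @ X.T
        out = assoc.residualize(_emb(Y, "pca"), cov, standardize=False)
        assert np.allclose(out.values, P @ Y, atol=1e-8)
        orth = np.abs(X.T @ out.values).max()
        assert orth < 1e-8 * np.abs(Y).max() * 20

    def test_rank_deficient_design_reported(self):
        cov = make_covariates(50, seed=4)
        cov["pc2"] = cov["pc1"]  # exact collinearity
        with pytest.raises(ValueError, match="collinear"):
            assoc.residualize(_emb(np.random.default_rng(0).normal(size=(50, 2)),
                                   "pca"), cov)


class TestUnivariateZ:
    def test_closed_form_oracle(self):
        """z equals r sqrt((n-2)/(1-r^2)) with r the Pearson correlation."""
        rng = np.random.default_rng(5)
        n = 80
        G = gen_genotypes(n, 6, ld_block_size=1, seed=5)
        Y = rng.normal(size=(n, 3))
        ss = assoc.univariate_z(_emb(Y), G)
        for i in range(6):
            for j in range(3):
                r = stats.pearsonr(G.dosages[:, i], Y[:, j]).statistic
                expected = r * np.sqrt((n - 2) / (1 - r ** 2))
                assert ss.z[i, j] == pytest.approx(expected, rel=1e-9)

    def test_perfect_fit_capped_not_infinite(self):
        n = 100
        G = gen_genotypes(n, 1, ld_block_size=1, seed=6)
        Y = 2.0 * G.dosages[:, :1].astype(float)
        ss = assoc.univariate_z(_emb(Y), G)
        assert np.isfinite(ss.z[0, 0]) and abs(ss.z[0, 0]) > 20

    def test_null_calibration(self):
        rng = np.random.default_rng(7)
        n = 2000
        G = gen_genotypes(n, 200, ld_block_size=1, seed=7)
        ss = assoc.univariate_z(_emb(rng.normal(size=(n, 2))), G)
        z = ss.z.ravel()
        assert abs(z.mean()) < 0.1
        assert abs(z.var() - 1.0) < 0.1
        # standard-normal under the null
        assert stats.kstest(z, "norm").pvalue > 0.001

    def test_zero_variance_snp_flagged(self):
        G = gen_genotypes(50, 2, ld_block_size=1, seed=8)
        d = G.dosages.copy()
        d[:, 1] = 1
        G2 = GenotypeMatrix(dosages=d, snp_id=G.snp_id, chrom=G.chrom,
                            bp=G.bp, a1=G.a1, maf=G.maf)
        ss = assoc.univariate_z(_emb(np.random.default_rng(1).normal(size=(50, 2))), G2)
        assert ss.zero_variance[1] and not ss.zero_variance[0]
        assert (ss.z[1] == 0).all()


class TestEstimateR:
    def test_independent_dimensions_near_identity(self):
        rng = np.random.default_rng(9)
        n = 5000  # large n: the empirical dimension correlation is near zero
        G = gen_genotypes(n, 250, ld_block_size=1, seed=9)
        E = _emb(rng.normal(size=(n, 4)))
        R = assoc.estimate_R(E, G, n_perm=20, seed=0)
        off = R - np.diag(np.diag(R))
        assert np.abs(off).max() < 0.05

    def test_duplicated_dimension_unit_correlation(self):
        rng = np.random.default_rng(10)
        n = 500
        y = rng.normal(size=n)
        E = _emb(np.column_stack([y, y, rng.normal(size=n)]))
        G = gen_genotypes(n, 100, ld_block_size=1, seed=10)
        R = assoc.estimate_R(E, G, n_perm=20, seed=1)
        assert R[0, 1] > 0.95

    def test_symmetric_unit_diagonal(self):
        rng = np.random.default_rng(11)
        E = _emb(rng.normal(size=(300, 5)) @ rng.normal(size=(5, 5)))
        G = gen_genotypes(300, 80, ld_block_size=1, seed=11)
        R = assoc.estimate_R(E, G, n_perm=10, seed=2)
        assert np.allclose(R, R.T)
        assert np.allclose(np.diag(R), 1.0, atol=1e-9)
        assert np.linalg.eigvalsh(R).min() > 0


class TestMostestStat:
    def test_k1_is_z_squared(self):
        assert assoc.mostest_stat(np.array([1.7]), np.eye(1)) == pytest.approx(1.7 ** 2)

    def test_identity_R_sum_of_squares(self):
        z = np.array([0.5, -2.0, 1.0])
        assert assoc.mostest_stat(z, np.eye(3)) == pytest.approx(float((z ** 2).sum()))

    def test_2x2_explicit_inversion_oracle(self):
        z = np.array([1.0, 2.0])
        R = np.array([[1.0, 0.5], [0.5, 1.0]])
        det = 1.0 - 0.25
        Rinv = np.array([[1.0, -0.5], [-0.5, 1.0]]) / det
        expected = z @ Rinv @ z
        assert assoc.mostest_stat(z, R) == pytest.approx(expected, rel=1e-12)

    def test_singular_R_rejected(self):
        with pytest.raises(np.linalg.LinAlgError):
            assoc.mostest_stat(np.ones(2), np.ones((2, 2)))


class TestNullPvalue:
    @pytest.fixture(scope="class")
    def chi2_null(self):
        rng = np.random.default_rng(12)
        return assoc.NullModel(rng.chisquare(3, 20000))

    def test_median_maps_to_half(self, chi2_null):
        med = float(np.median(chi2_null.T_perm))
        assert chi2_null.pvalue(med)[0] == pytest.approx(0.5, abs=0.02)

    def test_tail_matches_chi2_oracle(self, chi2_null):
        T = np.array([10.0, 15.0, 20.0, 25.0])
        p = chi2_null.pvalue(T)
        expected = stats.chi2.sf(T, 3)
        rel = np.abs(p - expected) / expected
        assert (rel < 0.1).all()

    def test_monotone(self, chi2_null):
        T = np.linspace(0, 40, 300)
        p = chi2_null.pvalue(T)
        assert (np.diff(p) <= 1e-15).all()

    def test_warns_below_1e4_permutations(self):
        with pytest.warns(UserWarning):
            assoc.null_pvalue([1.0], np.random.default_rng(0).chisquare(2, 500))


class TestMinp:
    def test_k1_equals_univariate(self):
        z = np.array([[2.3]])
        assert assoc.minp_stat(z)[0] == pytest.approx(2 * stats.norm.sf(2.3))

    def test_all_zero_gives_one(self):
        assert assoc.minp_stat(np.zeros((1, 4)))[0] == pytest.approx(1.0)

    def test_type_one_error_calibrated(self):
        """Šidák combination over independent dimensions holds its level."""
        rng = np.random.default_rng(13)
        z = rng.normal(size=(10000, 3))
        p = assoc.minp_stat(z)
        assert (p < 0.05).mean() == pytest.approx(0.05, abs=0.01)


class TestLambdaGc:
    def test_all_half_gives_one(self):
        assert assoc.lambda_gc(np.full(100, 0.5)) == pytest.approx(1.0)

    def test_uniform_null(self):
        p = np.random.default_rng(14).uniform(size=100000)
        assert 0.98 < assoc.lambda_gc(p) < 1.02

    def test_inflation_direction(self):
        p = np.random.default_rng(15).uniform(size=1000) / 2
        assert assoc.lambda_gc(p) > 1.0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            assoc.lambda_gc(np.full(200, 1.5))
        with pytest.raises(ValueError):
            assoc.lambda_gc([0.5] * 10)


class TestHweFilter:
    def test_hwe_exact_matches_reference_values(self):
        # equilibrium counts: large p; gross heterozygote excess: tiny p
        assert assoc.hwe_exact_pvalue(50, 25, 25) == pytest.approx(1.0)
        assert assoc.hwe_exact_pvalue(50, 12, 38) > 0.5
        assert assoc.hwe_exact_pvalue(90, 5, 5) < 1e-10
        assert assoc.hwe_exact_pvalue(1000, 0, 0) < 1e-100

    def test_filter_keeps_hwe_snps(self):
        G = gen_genotypes(2000, 30, ld_block_size=1, seed=16)
        Gf, idx = assoc.filter_snps(G)
        assert len(idx) == 30  # generator draws in HWE with MAF > 0.05

    def test_filter_drops_low_maf(self):
        G = gen_genotypes(2000, 5, ld_block_size=1, seed=17)
        d = G.dosages.copy()
        d[:, 2] = 0
        d[:3, 2] = 1  # MAF ~ 0.00075
        G2 = GenotypeMatrix(dosages=d, snp_id=G.snp_id, chrom=G.chrom,
                            bp=G.bp, a1=G.a1, maf=G.maf)
        _, idx = assoc.filter_snps(G2)
        assert 2 not in idx


def brute_force_clump(meta, p, r2, p_thresh, r2_indep, r2_lead, merge_kb):
    """Independent re-implementation of the two-stage pruning with plain
    loops, used as the clumping oracle."""
    order = sorted(range(len(p)), key=lambda i: (p[i], i))
    sig = [i for i in order if p[i] < p_thresh]
    ind = []
    for i in sig:
        if all(r2[i][j] < r2_indep for j in ind):
            ind.append(i)
    leads = []
    for i in ind:
        if all(r2[i][j] < r2_lead for j in leads):
            leads.append(i)
    loci = []
    for lead in leads:
        bps = [meta["bp"][j] for j in range(len(p))
               if meta["chrom"][j] == meta["chrom"][lead] and r2[lead][j] > r2_lead]
        bps.append(meta["bp"][lead])
        loci.append({"chrom": meta["chrom"][lead], "start": min(bps),
                     "end": max(bps), "lead": lead, "p": p[lead]})
    loci.sort(key=lambda d: (d["chrom"], d["start"]))
    merged = []
    for loc in loci:
        if merged and loc["chrom"] == merged[-1]["chrom"] and \
                loc["start"] - merged[-1]["end"] < merge_kb * 1000:
            m = merged[-1]
            m["end"] = max(m["end"], loc["end"])
            m["start"] = min(m["start"], loc["start"])
            if loc["p"] < m["p"]:
                m["lead"], m["p"] = loc["lead"], loc["p"]
        else:
            merged.append(dict(loc))
    for m in merged:
        m["ind_sig"] = [i for i in ind if meta["chrom"][i] == m["chrom"]
                        and m["start"] <= meta["bp"][i] <= m["end"]]
    return merged


def random_clump_fixture(seed, n_snps=None):
    rng = np.random.default_rng(seed)
    m = n_snps or int(rng.integers(5, 21))
    chrom = np.sort(rng.integers(1, 4, m))
    bp = np.zeros(m, dtype=int)
    for c in np.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        bp[idx] = np.sort(rng.integers(1, 2_000_000, idx.size))
        bp[idx] += np.arange(idx.size)  # strictly increasing
    # random but symmetric PSD-ish r2 in [0,1]
    A = rng.random((m, m))
    r2 = (A + A.T) / 2
    np.fill_diagonal(r2, 1.0)
    p = 10.0 ** (-rng.uniform(0, 12, m))
    meta = {"chrom": chrom.tolist(), "bp": bp.tolist()}
    return meta, p, r2


class TestClumpLoci:
    def _run(self, meta, p, r2, **kw):
        m = len(p)
        summary = assoc.SummaryStats(
            z=np.zeros((m, 1)),
            meta=pd.DataFrame({"snp_id": [f"rs{i}" for i in range(m)],
                               "chrom": meta["chrom"], "bp": meta["bp"],
                               "a1": "A", "maf": 0.2, "n": 100}))
        return assoc.clump_loci(summary, p, r2, **kw)

    def test_no_significant_snps_empty(self):
        meta, p, r2 = random_clump_fixture(0)
        out = self._run(meta, np.full(len(p), 0.5), r2, p_thresh=5e-8)
        assert len(out) == 0

    def test_single_snp_locus(self):
        meta = {"chrom": [1, 1], "bp": [100, 500_000_000]}
        r2 = np.eye(2)
        out = self._run(meta, np.array([1e-9, 0.5]), r2, p_thresh=5e-8)
        assert len(out) == 1
        row = out.loci.iloc[0]
        assert row["lead_snp"] == "rs0"
        assert row["span_start"] == row["span_end"] == 100

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_bruteforce_enumeration(self, seed):
        meta, p, r2 = random_clump_fixture(seed)
        kw = dict(p_thresh=1e-4, r2_indep=0.6, r2_lead=0.1, merge_kb=250)
        got = self._run(meta, p, r2, **kw)
        exp = brute_force_clump(meta, p.tolist(), r2.tolist(), **kw)
        assert len(got) == len(exp)
        for row, e in zip(got.loci.itertuples(), exp):
            assert row.lead_snp == f"rs{e['lead']}"
            assert row.span_start == e["start"] and row.span_end == e["end"]
            assert row.ind_sig_snps == ";".join(f"rs{i}" for i in e["ind_sig"])


class TestReplicationCheck:
    def _table(self, n, p_repl):
        df = pd.DataFrame({"lead_snp": [f"rs{i}" for i in range(n)],
                           "chrom": 1, "span_start": 0, "span_end": 1,
                           "p_discovery": 1e-9,
                           "ind_sig_snps": ""})
        return assoc.LocusTable(df), {f"rs{i}": p for i, p in enumerate(p_repl)}

    def test_bonferroni_over_loci(self):
        table, pr = self._table(10, [0.004] + [0.5] * 9)
        out = assoc.replication_check(table, pr)
        assert out.loci["validated"].tolist() == [True] + [False] * 9

    def test_above_threshold_fails(self):
        table, pr = self._table(10, [0.02] + [0.5] * 9)
        out = assoc.replication_check(table, pr)
        assert not out.loci["validated"].any()

    def test_single_locus_boundary(self):
        table, pr = self._table(1, [0.049])
        assert assoc.replication_check(table, pr).loci["validated"].iloc[0]

    def test_missing_replication_p_flagged(self):
        table, _ = self._table(2, [0.001, 0.001])
        out = assoc.replication_check(table, {"rs0": 0.001})
        assert out.loci["validated"].iloc[0]
        assert not out.loci["validated"].iloc[1]
        assert "missing" in out.loci["reason"].iloc[1]
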