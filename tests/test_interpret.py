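import numpy as np
import pytest

from foldgene import interpret
from foldgene.encoder import EmbeddingMatrix
from foldgene.synthetic import (CausalModel, ShapeFactors, FACTOR_NAMES,
                                gen_genotypes, gen_shape_factors, pcs_zone,
                                render_cohort)


def _emb(X):
    return EmbeddingMatrix(X, [f"s{i}" for i in range(len(X))],
                           state="residualized")


class TestDosageOls:
    def test_noiseless_recovery(self):
        rng = np.random.default_rng(0)
        E = rng.normal(size=(100, 4))
        E[:, 0] = np.repeat([0.0, 0.5, 1.0], [30, 40, 30])[:100]
        y = 2.0 * E[:, 0]
        reg = interpret.dosage_ols(_emb(E), y)
        assert np.allclose(reg.beta, [2.0, 0, 0, 0], atol=1e-8)
        assert reg.r2 == pytest.approx(1.0)

    def test_null_r2_small(self):
        rng = np.random.default_rng(1)
        E = rng.normal(size=(2000, 10))
        y = rng.integers(0, 3, 2000).astype(float)
        reg = interpret.dosage_ols(_emb(E), y)
        assert reg.r2 < 0.02

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(30, 4))
        y = rng.integers(0, 3, 30).astype(float)
        reg = interpret.dosage_ols(_emb(X), y)
        Xd = np.column_stack([np.ones(30), X])
        beta_full = np.linalg.inv(Xd.T @ Xd) @ Xd.T @ y
        assert reg.intercept == pytest.approx(beta_full[0], abs=1e-8)
        assert np.allclose(reg.beta, beta_full[1:], atol=1e-8)

    def test_invalid_dosage_rejected(self):
        with pytest.raises(ValueError):
            interpret.dosage_ols(_emb(np.zeros((10, 2))), np.full(10, 0.5))

    def test_collinear_columns_ridge_fallback(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(50, 3))
        X = np.column_stack([X, X[:, 0]])
        with pytest.warns(UserWarning, match="collinear"):
            reg = interpret.dosage_ols(_emb(X), rng.integers(0, 3, 50).astype(float))
        assert np.isfinite(reg.beta).all()


class TestExtremeBatchAverages:
    def test_identical_volumes_identical_binary_maps(self):
        rng = np.random.default_rng(4)
        v = (rng.random((6, 6, 6)) < 0.3).astype(np.uint8)
        low, high = interpret.extreme_batch_averages([v] * 50, rng.normal(size=50),
                                                     batch_size=20)
        assert (low.values == high.values).all()
        assert set(np.unique(low.values)).issubset({0.0, 1.0})

    def test_rank_invariance_to_constant_shift(self):
        rng = np.random.default_rng(5)
        vols = [(rng.random((5, 5, 5)) < 0.3).astype(np.uint8) for _ in range(60)]
        y = rng.normal(size=60)
        a = interpret.extreme_batch_averages(vols, y, batch_size=20)
        b = interpret.extreme_batch_averages(vols, y + 17.3, batch_size=20)
        assert np.allclose(a[0].values, b[0].values)
        assert np.allclose(a[1].values, b[1].values)

    def test_too_few_subjects(self):
        with pytest.raises(ValueError):
            interpret.extreme_batch_averages([np.zeros((4, 4, 4))] * 30,
                                             np.zeros(30), batch_size=20)

    def test_planted_effect_separates_pcs_zone(self):
        """Ranking by a score aligned with the PCS factor separates PCS
        occupancy between the extreme batches."""
        rng = np.random.default_rng(6)
        n = 400
        import pandas as pd
        vals = pd.DataFrame({
            "pcs_strength": rng.normal(0, 1.5, n),
            "cs_interruption": rng.normal(0, 1, n),
            "depth_scale": rng.normal(0, 0.5, n),
            "jitter": rng.normal(0, 1, n),
        })
        vols = render_cohort(ShapeFactors(values=vals), seed=7)
        score = vals["pcs_strength"] + rng.normal(0, 0.5, n)
        low, high = interpret.extreme_batch_averages(vols, score, batch_size=100)
        zone = pcs_zone((16, 16, 16), tight=True)
        assert high.values[zone].mean() - low.values[zone].mean() > 0.2


class TestZscoreCorrMap:
    def test_duplicated_snp_unit_correlation(self):
        rng = np.random.default_rng(8)
        z = rng.normal(size=(3, 6))
        z[1] = z[0]
        C = interpret.zscore_corr_map(z)
        assert C[0, 1] == pytest.approx(1.0)
        assert np.allclose(C, C.T)
        assert np.allclose(np.diag(C), 1.0)

    def test_block_structure_of_planted_effects(self):
        """SNPs within one LD block share z-score direction; SNPs of
        distinct blocks with independent effects do not."""
        rng = np.random.default_rng(9)
        k = 20
        dir_a, dir_b = np.zeros(k), np.zeros(k)
        dir_a[0] = 1.0
        dir_b[10] = 1.0
        z = np.vstack([6 * dir_a + rng.normal(0, 0.5, k) for _ in range(3)] +
                      [6 * dir_b + rng.normal(0, 0.5, k) for _ in range(3)])
        C = interpret.zscore_corr_map(z)
        within = np.concatenate([C[:3, :3][np.triu_indices(3, 1)],
                                 C[3:, 3:][np.triu_indices(3, 1)]])
        across = np.abs(C[:3, 3:]).ravel()
        assert within.min() > 0.5
        assert across.max() < 0.3

    def test_single_snp_warns_empty(self):
        with pytest.warns(UserWarning):
            C = interpret.zscore_corr_map(np.ones((1, 4)))
        assert C.size == 0


class TestRecoverEffectDirection:
    def _setup(self, n=3000, h2=0.05, seed=0, flip=False):
        G = gen_genotypes(n, 10, ld_block_size=1, seed=seed)
        eff = np.zeros((1, 4))
        eff[0, 0] = -1.0 if flip else 1.0
        cm = CausalModel([3], eff, heritability_target=h2)
        factors = gen_shape_factors(G, cm, noise_sd=1.0, seed=seed + 1)
        # embedding = linear mix of the true factors plus noise
        rng = np.random.default_rng(seed + 2)
        F = factors.values[list(FACTOR_NAMES)].to_numpy()
        M = rng.normal(size=(4, 6))
        E = _emb(F @ M + 0.3 * rng.normal(size=(n, 6)))
        cm_realized = CausalModel([3], factors.realized_effects)
        reg = interpret.dosage_ols(E, G.dosages[:, 3].astype(float))
        return reg, cm_realized, E, factors

    def test_high_snr_recovery(self):
        reg, cm, E, factors = self._setup()
        cos = interpret.recover_effect_direction(reg, cm, E, factors)
        assert cos >= 0.9

    def test_sign_flip_antisymmetry(self):
        reg, cm, E, factors = self._setup(flip=True)
        cos = interpret.recover_effect_direction(reg, cm, E, factors)
        assert cos >= 0.9  # direction matches the (negative) planted effect
        cm_pos = CausalModel([3], -cm.effect_matrix)
        assert interpret.recover_effect_direction(reg, cm_pos, E, factors) <= -0.9

    def test_null_snp_centered_on_zero(self):
        sims = []
        for rep in range(10):
            n = 800
            G = gen_genotypes(n, 10, ld_block_size=1, seed=100 + rep)
            factors = gen_shape_factors(G, None, noise_sd=1.0, seed=200 + rep)
            rng = np.random.default_rng(300 + rep)
            F = factors.values[list(FACTOR_NAMES)].to_numpy()
            E = _emb(F @ rng.normal(size=(4, 6)) + 0.3 * rng.normal(size=(n, 6)))
            reg = interpret.dosage_ols(E, G.dosages[:, 0].astype(float))
            cm = CausalModel([0], [[1.0, 0, 0, 0]])
            sims.append(interpret.recover_effect_direction(reg, cm, E, factors))
        assert abs(np.mean(sims)) < 0.25

    def test_requires_ground_truth(self):
        reg, cm, E, factors = self._setup(n=500)
        with pytest.raises(ValueError):
            interpret.recover_effect_direction(reg, None, E, factors)
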