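"""Genotype-guided interpretation of the embedding as folding-pattern
transitions.

For an associated SNP, the minor-allele dosage is regressed on the
pre-residualized embedding by ordinary least squares; subjects are ranked by
the model-predicted dosage and the extreme rank batches are averaged into
occupancy maps, visualizing the pattern transition the SNP tags.  A z-score
correlation map across significant SNPs summarizes whether lead SNPs
represent their LD blocks consistently.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .encoder import EmbeddingMatrix
from .probe import FrequencyMap
from .synthetic import CausalModel, ShapeFactors, FACTOR_NAMES


@dataclass
class DosageRegression:
    beta: np.ndarray
    intercept: float
    y_pred: np.ndarray
    r2: float


def dosage_ols(E_res: EmbeddingMatrix, dosage) -> DosageRegression:
    """OLS fit of minor-allele dosage on the embedding dimensions.

    Falls back to a small ridge penalty with a warning when the embedding
    columns are numerically collinear.
    """
    X = E_res.values if isinstance(E_res, EmbeddingMatrix) else np.asarray(E_res)
    y = np.asarray(dosage, dtype=float)
    n, k = X.shape
    if n <= k:
        raise ValueError("need more subjects than embedding dimensions")
    if not np.isin(y, (0.0, 1.0, 2.0)).all():
        raise ValueError("dosage must lie in {0,1,2}")
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    XtX = Xc.T @ Xc
    cond = np.linalg.cond(XtX)
    if cond > 1e12:
        warnings.warn(f"collinear embedding columns (cond={cond:.2e}); "
                      "adding ridge penalty")
        XtX = XtX + 1e-8 * np.trace(XtX) / k * np.eye(k)
    beta = np.linalg.solve(XtX, Xc.T @ yc)
    intercept = float(y.mean() - X.mean(axis=0) @ beta)
    y_pred = X @ beta + intercept
    ss_res = float(((y - y_pred) ** 2).sum())
    ss_tot = float((yc ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return DosageRegression(beta=beta, intercept=intercept, y_pred=y_pred, r2=r2)


def extreme_batch_averages(volumes, y_pred, batch_size: int = 200
                           ) -> tuple[FrequencyMap, FrequencyMap]:
    """Occupancy maps of the lowest- and highest-ranked ``batch_size``
    subjects under the predicted dosage (stable ties by subject index)."""
    n = len(volumes)
    y = np.asarray(y_pred, dtype=float)
    if n < 2 * batch_size:
        raise ValueError("need at least 2 x batch_size subjects")
    order = np.lexsort((np.arange(n), y))
    grids = np.stack([v.grid if hasattr(v, "grid") else v for v in volumes]).astype(float)
    low_idx, high_idx = order[:batch_size], order[-batch_size:]
    low = FrequencyMap(values=grids[low_idx].mean(axis=0),
                       batch_indices=low_idx, batch_size=batch_size)
    high = FrequencyMap(values=grids[high_idx].mean(axis=0),
                        batch_indices=high_idx, batch_size=batch_size)
    return low, high


def zscore_corr_map(z_significant: np.ndarray) -> np.ndarray:
    """SNP x SNP Pearson correlation of per-dimension z-score vectors."""
    z = np.atleast_2d(np.asarray(z_significant, dtype=float))
    if z.shape[0] < 2:
        warnings.warn("fewer than 2 significant SNPs; empty correlation map")
        return np.zeros((0, 0))
    C = np.corrcoef(z)
    np.fill_diagonal(C, 1.0)
    return C


def recover_effect_direction(regression: DosageRegression,
                             causal_model: CausalModel,
                             E_res: EmbeddingMatrix,
                             factors: ShapeFactors,
                             causal_row: int = 0) -> float:
    """Cosine similarity between the regression direction, mapped back to
    factor space through the empirical linear embedding/factor fit, and the
    planted effect direction.  Synthetic cohorts only (requires ground truth).
    """
    if causal_model is None or factors is None:
        raise ValueError("ground truth required")
    F = factors.values[list(FACTOR_NAMES)].to_numpy(float)
    X = E_res.values
    Fc = F - F.mean(axis=0)
    Xc = X - X.mean(axis=0)
    # linear relation between factor space and embedding space: X ~ F A
    A, *_ = np.linalg.lstsq(Fc, Xc, rcond=None)
    beta_fac = A @ regression.beta
    eff = causal_model.effect_matrix[causal_row]
    denom = np.linalg.norm(beta_fac) * np.linalg.norm(eff)
    if denom == 0:
        return 0.0
    return float(beta_fac @ eff / denom)
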