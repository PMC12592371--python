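"""Barlow Twins self-supervised encoder for binary skeleton volumes.

The objective drives the cross-correlation matrix C of two augmented views'
projector outputs toward the identity:

    L = sum_i (1 - C_ii)^2 + lambda * sum_i sum_{j!=i} C_ij^2

with C_ij the Pearson cross-correlation (columns batch-centered) between
dimension i of view A and dimension j of view B.  The *embedding* used by
all downstream analyses is the backbone output, taken before the projection
head, with no augmentation at inference time.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.decomposition import PCA

from . import nn
from .augment import AugmentationConfig, random_view

_EPS = 1e-9


@dataclass
class EncoderConfig:
    """Desk-scale stand-in for a deep regional encoder.

    The backbone is ``n_conv_layers`` stride-2 3D convolutions followed by a
    dense map to ``latent_dim``; the projection head is two dense layers.
    """

    n_conv_layers: int = 4
    channels: tuple = (8, 16, 32, 64)
    latent_dim: int = 32
    projector_dims: tuple = (64, 64)
    lambda_bt: float = 5e-3
    batch_size: int = 64
    epochs: int = 20
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.latent_dim < 2:
            raise ValueError("latent_dim must be >= 2")
        if self.lambda_bt <= 0:
            raise ValueError("lambda_bt must be positive")
        if len(self.channels) < self.n_conv_layers:
            raise ValueError("need one channel count per conv layer")


@dataclass
class EmbeddingMatrix:
    """Subjects x k latent coordinates with provenance flags."""

    values: np.ndarray
    subject_ids: list
    state: str = "raw"  # raw | pca | residualized
    explained_variance: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.isfinite(self.values).all():
            raise ValueError("embedding must be finite")
        if len(self.subject_ids) != self.values.shape[0]:
            raise ValueError("one subject id per row required")

    @property
    def k(self) -> int:
        return self.values.shape[1]


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------

def cross_correlation(ZA: np.ndarray, ZB: np.ndarray, eps: float = _EPS) -> np.ndarray:
    """Batch cross-correlation matrix of two view embeddings.

    Columns are mean-centered over the batch, making C a Pearson correlation
    with entries in [-1, 1]; an epsilon in the denominators guards
    zero-variance columns.
    """
    A = ZA - ZA.mean(axis=0)
    B = ZB - ZB.mean(axis=0)
    na = np.maximum(np.sqrt((A ** 2).sum(axis=0)), eps)
    nb = np.maximum(np.sqrt((B ** 2).sum(axis=0)), eps)
    return (A / na).T @ (B / nb)


def barlow_twins_loss(ZA: np.ndarray, ZB: np.ndarray, lambda_bt: float) -> float:
    """Invariance term on the diagonal, redundancy term off it; >= 0."""
    if ZA.shape != ZB.shape or ZA.shape[0] < 2:
        raise ValueError("views must share shape with batch >= 2")
    C = cross_correlation(ZA, ZB)
    on = float(((1.0 - np.diag(C)) ** 2).sum())
    off = float((C ** 2).sum() - (np.diag(C) ** 2).sum())
    return on + lambda_bt * off


def barlow_twins_loss_grad(ZA: np.ndarray, ZB: np.ndarray, lambda_bt: float):
    """Loss and its gradients w.r.t. both view matrices."""
    A = ZA - ZA.mean(axis=0)
    B = ZB - ZB.mean(axis=0)
    na = np.maximum(np.sqrt((A ** 2).sum(axis=0)), _EPS)
    nb = np.maximum(np.sqrt((B ** 2).sum(axis=0)), _EPS)
    Ah, Bh = A / na, B / nb
    C = Ah.T @ Bh
    d = np.diag(C)
    loss = float(((1.0 - d) ** 2).sum() + lambda_bt * ((C ** 2).sum() - (d ** 2).sum()))
    G = 2.0 * lambda_bt * C
    np.fill_diagonal(G, -2.0 * (1.0 - d))
    dAh = Bh @ G.T
    dBh = Ah @ G
    # backprop through the normalization x -> x/||x|| and the centering
    dA = (dAh - Ah * (dAh * Ah).sum(axis=0)) / na
    dB = (dBh - Bh * (dBh * Bh).sum(axis=0)) / nb
    dZA = dA - dA.mean(axis=0)
    dZB = dB - dB.mean(axis=0)
    return loss, dZA, dZB


# ---------------------------------------------------------------------------
# encoder
# ---------------------------------------------------------------------------

@dataclass
class EncoderState:
    backbone: nn.Sequential
    projector: nn.Sequential
    config: EncoderConfig
    grid_shape: tuple
    loss_history: list = field(default_factory=list)


def _build(config: EncoderConfig, grid_shape, rng) -> tuple[nn.Sequential, nn.Sequential]:
    layers: list = []
    c_in = 1
    side = np.array(grid_shape)
    for i in range(config.n_conv_layers):
        c_out = config.channels[i]
        layers += [nn.Conv3d(c_in, c_out, kernel=3, stride=2, pad=1, rng=rng), nn.ReLU()]
        c_in = c_out
        side = (side + 1) // 2
    flat = int(c_in * side.prod())
    layers += [nn.Flatten(), nn.Dense(flat, config.latent_dim, rng=rng)]
    backbone = nn.Sequential(layers)
    h, out = config.projector_dims
    projector = nn.Sequential([nn.Dense(config.latent_dim, h, rng=rng), nn.ReLU(),
                               nn.Dense(h, out, rng=rng)])
    return backbone, projector


def _stack(volumes) -> np.ndarray:
    grids = [v.grid if hasattr(v, "grid") else v for v in volumes]
    return np.stack(grids).astype(np.float64)


def train_encoder(volumes, encoder_config: EncoderConfig | None = None,
                  augmentation_config: AugmentationConfig | None = None,
                  verbose: bool = False) -> EncoderState:
    """Train with the twin objective on randomly augmented view pairs.

    Deterministic for a fixed config seed.  Raises on non-finite loss.
    """
    cfg = encoder_config or EncoderConfig()
    aug = augmentation_config or AugmentationConfig()
    if len(volumes) < 2 * cfg.batch_size:
        raise ValueError("need at least 2 x batch_size volumes")
    rng = np.random.default_rng(cfg.seed)
    grids = [v.grid if hasattr(v, "grid") else v for v in volumes]
    grid_shape = grids[0].shape
    backbone, projector = _build(cfg, grid_shape, rng)
    params = backbone.params + projector.params
    opt = nn.Adam(params, lr=cfg.learning_rate)
    state = EncoderState(backbone, projector, cfg, grid_shape)

    n = len(grids)
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n - cfg.batch_size + 1, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            va = np.stack([random_view(grids[i], aug, rng) for i in idx])
            vb = np.stack([random_view(grids[i], aug, rng) for i in idx])
            xa = va[:, None].astype(np.float64)
            xb = vb[:, None].astype(np.float64)
            za = projector.forward(backbone.forward(xa))
            # cache backbone/projector activations for view A before running B
            grads_a_closure = _capture_backward(backbone, projector)
            zb = projector.forward(backbone.forward(xb))
            loss, dza, dzb = barlow_twins_loss_grad(za, zb, cfg.lambda_bt)
            if not np.isfinite(loss):
                raise RuntimeError(f"non-finite twin loss at epoch {epoch}")
            # accumulate gradients from both views
            backbone.backward(projector.backward(dzb))
            grads_b = [g.copy() for g in backbone.grads + projector.grads]
            grads_a_closure(dza)
            grads = [ga + gb for ga, gb in
                     zip(backbone.grads + projector.grads, grads_b)]
            opt.step(grads)
            losses.append(loss)
        state.loss_history.append(float(np.mean(losses)))
        if verbose:
            print(f"epoch {epoch + 1}/{cfg.epochs}  twin loss {state.loss_history[-1]:.4f}")
    return state


def _capture_backward(backbone: nn.Sequential, projector: nn.Sequential):
    """Snapshot the forward caches of every layer so a second forward pass
    (for the twin view) does not clobber them before backprop of the first."""
    caches = []
    for layer in backbone.layers + projector.layers:
        caches.append({k: v for k, v in layer.__dict__.items() if k.startswith("_")})

    def run_backward(dz):
        for layer, cache in zip(backbone.layers + projector.layers, caches):
            layer.__dict__.update(cache)
        backbone.backward(projector.backward(dz))

    return run_backward


def evaluate_loss(state: EncoderState, volumes,
                  augmentation_config: AugmentationConfig | None = None,
                  seed: int = 0, n_batches: int | None = None) -> float:
    """Mean twin loss on a held-out set, with fresh random views."""
    aug = augmentation_config or AugmentationConfig()
    rng = np.random.default_rng(seed)
    grids = [v.grid if hasattr(v, "grid") else v for v in volumes]
    bs = state.config.batch_size
    losses = []
    starts = range(0, len(grids) - bs + 1, bs)
    if n_batches is not None:
        starts = list(starts)[:n_batches]
    for start in starts:
        batch = grids[start:start + bs]
        va = np.stack([random_view(g, aug, rng) for g in batch])[:, None].astype(float)
        vb = np.stack([random_view(g, aug, rng) for g in batch])[:, None].astype(float)
        za = state.projector.forward(state.backbone.forward(va, train=False), train=False)
        zb = state.projector.forward(state.backbone.forward(vb, train=False), train=False)
        losses.append(barlow_twins_loss(za, zb, state.config.lambda_bt))
    return float(np.mean(losses))


def embed(state: EncoderState, volumes, batch_size: int = 256) -> EmbeddingMatrix:
    """Backbone output per subject, no augmentation, deterministic."""
    grids = [v.grid if hasattr(v, "grid") else v for v in volumes]
    ids = [getattr(v, "subject_id", f"S{i:06d}") or f"S{i:06d}"
           for i, v in enumerate(volumes)]
    if grids and grids[0].shape != state.grid_shape:
        raise ValueError("volume grid does not match the training grid")
    rows = []
    for start in range(0, len(grids), batch_size):
        x = np.stack(grids[start:start + batch_size])[:, None].astype(np.float64)
        rows.append(state.backbone.forward(x, train=False))
    return EmbeddingMatrix(values=np.vstack(rows), subject_ids=ids, state="raw")


def reduce_pca(E: EmbeddingMatrix, variance_target: float = 0.999) -> EmbeddingMatrix:
    """Keep the minimal number of ranked components whose cumulative
    explained variance reaches ``variance_target``."""
    X = E.values
    if X.shape[0] <= X.shape[1]:
        raise ValueError("need more subjects than embedding dimensions")
    total_var = X.var(axis=0).sum()
    if total_var <= 0:
        import warnings
        warnings.warn("degenerate zero-variance embedding; returning one zero component")
        return EmbeddingMatrix(values=np.zeros((X.shape[0], 1)),
                               subject_ids=E.subject_ids, state="pca",
                               explained_variance=np.array([0.0]))
    pca = PCA(n_components=min(X.shape[0] - 1, X.shape[1]), svd_solver="full")
    Y = pca.fit_transform(X)
    frac = pca.explained_variance_ratio_
    cum = np.cumsum(frac)
    if variance_target >= 1.0:
        n_keep = int((pca.explained_variance_ > 1e-12 * pca.explained_variance_[0]).sum())
    else:
        n_keep = int(np.searchsorted(cum, variance_target) + 1)
    n_keep = max(1, min(n_keep, Y.shape[1]))
    return EmbeddingMatrix(values=Y[:, :n_keep], subject_ids=E.subject_ids,
                           state="pca", explained_variance=frac[:n_keep])


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------

def save_encoder(state: EncoderState, path: str) -> None:
    """Serialize weights + config into one .npz with the config as JSON."""
    arrays = {f"p{i}": p for i, p in
              enumerate(state.backbone.params + state.projector.params)}
    cfg = asdict(state.config)
    cfg["channels"] = list(cfg["channels"])
    cfg["projector_dims"] = list(cfg["projector_dims"])
    arrays["config_json"] = np.frombuffer(
        json.dumps({"config": cfg, "grid_shape": list(state.grid_shape),
                    "loss_history": state.loss_history}).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_encoder(path: str) -> EncoderState:
    data = np.load(path)
    meta = json.loads(bytes(data["config_json"]).decode())
    cfg_d = meta["config"]
    cfg_d["channels"] = tuple(cfg_d["channels"])
    cfg_d["projector_dims"] = tuple(cfg_d["projector_dims"])
    cfg = EncoderConfig(**cfg_d)
    backbone, projector = _build(cfg, tuple(meta["grid_shape"]),
                                 np.random.default_rng(cfg.seed))
    params = backbone.params + projector.params
    for i, p in enumerate(params):
        p[...] = data[f"p{i}"]
    state = EncoderState(backbone, projector, cfg, tuple(meta["grid_shape"]))
    state.loss_history = list(meta["loss_history"])
    return state
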