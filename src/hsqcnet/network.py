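"""The siamese convolutional embedding network.

The embedding function G_W maps a binary HSQC raster to a point in [-1, 1]^K
(K = 10 by default) through four 4x4 convolution + overlapping 4x4/stride-2
max-pool stages (8, 16, 16, 16 filters) and four fully connected layers
(128, 128, 128, K), with hyperbolic-tangent activations on every layer
including the output, batch normalization on all layers except the embedding
output, and dropout (p = 0.5) on the three hidden fully connected layers.

Two weight-sharing twins of this network are trained on pairs of spectra with
the contrastive (spring) energy

    L = 1/2 * max(0, d - m)^2      if the pair shares a family
    L = 1/2 * max(0, m - d)^2      otherwise,

where d = ||G_W(x_i) - G_W(x_j)|| and m is the margin: same-family pairs are
pulled inside the margin, different-family pairs pushed beyond it.  Note the
margin acts on BOTH branches of this energy.

Forward and backward passes are implemented directly on NumPy arrays; all
convolutions are lowered to matrix multiplications via sliding-window
im2col, so gradients are analytic and checkable against finite differences.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import dataclass, asdict
from typing import Mapping, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "ArchitectureSpec",
    "NetworkWeights",
    "PairBatch",
    "ArchitectureError",
    "init_weights",
    "embed",
    "embed_images",
    "pairwise_distance",
    "contrastive_loss",
    "batch_loss",
    "batch_loss_and_grads",
    "max_embedding_distance",
    "save_checkpoint",
    "load_checkpoint",
]

_BN_EPS = 1e-5
_BN_MOMENTUM = 0.9


class ArchitectureError(ValueError):
    """Infeasible architecture (e.g. a pooled feature map collapses)."""


@dataclass(frozen=True)
class ArchitectureSpec:
    """Shape of the convolutional embedding network.

    ``input_side`` is configurable (the reference resolution is 512; smaller
    sides keep the same four conv/pool stages and the flatten size adapts).
    """

    input_side: int = 512
    conv_channels: tuple[int, ...] = (8, 16, 16, 16)
    conv_kernel: int = 4
    pool_size: int = 4
    pool_stride: int = 2
    fc_sizes: tuple[int, ...] = (128, 128, 128)
    embedding_dim: int = 10
    dropout_p: float = 0.5
    batchnorm: bool = True

    def __post_init__(self) -> None:
        if self.embedding_dim < 2:
            raise ArchitectureError("embedding_dim must be >= 2")
        if self.conv_kernel < 1 or self.pool_size < 1 or self.pool_stride < 1:
            raise ArchitectureError("kernel/pool sizes must be positive")
        if not (0 <= self.dropout_p < 1):
            raise ArchitectureError("dropout_p must lie in [0, 1)")
        self.feature_map_sides()  # validates feasibility

    def feature_map_sides(self) -> list[int]:
        """Post-pool side length after each conv stage; errors on collapse."""
        sides = []
        s = self.input_side
        for i, _ in enumerate(self.conv_channels):
            # size-preserving convolution, then valid pooling
            if s < self.pool_size:
                raise ArchitectureError(
                    f"feature map of side {s} before pool stage {i + 1} is "
                    f"smaller than the {self.pool_size}-pixel pool window; "
                    f"input_side {self.input_side} is too small"
                )
            s = (s - self.pool_size) // self.pool_stride + 1
            sides.append(s)
        return sides

    def flat_features(self) -> int:
        side = self.feature_map_sides()[-1]
        return self.conv_channels[-1] * side * side

    def layer_dims(self) -> list[tuple[str, tuple[int, ...]]]:
        """(name, weight shape) for every trainable linear map."""
        dims: list[tuple[str, tuple[int, ...]]] = []
        in_ch = 1
        for i, ch in enumerate(self.conv_channels):
            dims.append((f"conv{i + 1}", (ch, in_ch, self.conv_kernel, self.conv_kernel)))
            in_ch = ch
        in_f = self.flat_features()
        for j, out_f in enumerate(self.fc_sizes):
            dims.append((f"fc{j + 1}", (out_f, in_f)))
            in_f = out_f
        dims.append(("emb", (self.embedding_dim, in_f)))
        return dims


@dataclass
class NetworkWeights:
    """All trainable parameters plus batch-norm running statistics."""

    spec: ArchitectureSpec
    params: dict[str, np.ndarray]
    running: dict[str, np.ndarray]

    def copy(self) -> "NetworkWeights":
        return NetworkWeights(
            self.spec,
            {k: v.copy() for k, v in self.params.items()},
            {k: v.copy() for k, v in self.running.items()},
        )

    def zeros_like_params(self) -> dict[str, np.ndarray]:
        return {k: np.zeros_like(v) for k, v in self.params.items()}


@dataclass
class PairBatch:
    """Aligned left/right image stacks with same-family flags.

    ``same_flags`` must derive from the family labels of the paired spectra,
    never be supplied independently of them.
    """

    left: np.ndarray  # (B, side, side)
    right: np.ndarray
    same: np.ndarray  # (B,) bool
    left_ids: tuple[str, ...] | None = None
    right_ids: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if not (len(self.left) == len(self.right) == len(self.same)):
            raise ValueError("left/right/same must be aligned")
        if len(self.left) == 0:
            raise ValueError("empty pair batch")
        self.same = np.asarray(self.same, dtype=bool)


def init_weights(
    spec: ArchitectureSpec, seed: int, dtype: np.dtype = np.float32
) -> NetworkWeights:
    """Xavier/Glorot-initialized weights (variance 2/(fan_in + fan_out)).

    Biases start at zero, batch-norm scale at one and offset at zero;
    running means/variances at 0/1.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    params: dict[str, np.ndarray] = {}
    running: dict[str, np.ndarray] = {}
    for name, shape in spec.layer_dims():
        if name.startswith("conv"):
            fan_in = shape[1] * shape[2] * shape[3]
            fan_out = shape[0] * shape[2] * shape[3]
            n_out = shape[0]
        else:
            fan_in, fan_out = shape[1], shape[0]
            n_out = shape[0]
        std = np.sqrt(2.0 / (fan_in + fan_out))
        params[f"{name}_W"] = rng.normal(0.0, std, size=shape).astype(dtype)
        params[f"{name}_b"] = np.zeros(n_out, dtype=dtype)
        if spec.batchnorm and name != "emb":
            params[f"{name}_gamma"] = np.ones(n_out, dtype=dtype)
            params[f"{name}_beta"] = np.zeros(n_out, dtype=dtype)
            running[f"{name}_mean"] = np.zeros(n_out, dtype=dtype)
            running[f"{name}_var"] = np.ones(n_out, dtype=dtype)
    return NetworkWeights(spec, params, running)


# ---------------------------------------------------------------------------
# layer primitives (im2col convolution, overlapping max pool, batch norm)
# ---------------------------------------------------------------------------


def _conv_same_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray):
    """Size-preserving stride-1 convolution as one channels-first matmul.

    Even kernels pad asymmetrically: (k-1)//2 before, the remainder after.
    The padded input is gathered into a (C*k*k, N*H*W) column matrix by
    per-offset slice copies (contiguous inner runs, so the gather is cheap),
    after which the convolution is a single BLAS matmul.
    """
    N, C, H, Wd = x.shape
    F, _, k, _ = W.shape
    pb = (k - 1) // 2
    pa = k - 1 - pb
    xp = np.pad(x, ((0, 0), (0, 0), (pb, pa), (pb, pa)))
    colsT = np.empty((C * k * k, N, H, Wd), dtype=x.dtype)
    i = 0
    for c in range(C):
        for u in range(k):
            for v in range(k):
                colsT[i] = xp[:, c, u:u + H, v:v + Wd]
                i += 1
    colsT = colsT.reshape(C * k * k, N * H * Wd)
    y = W.reshape(F, -1) @ colsT
    y = np.ascontiguousarray(y.reshape(F, N, H, Wd).transpose(1, 0, 2, 3))
    y += b[None, :, None, None]
    return y, colsT


def _conv_same_backward(dy: np.ndarray, colsT: np.ndarray, W: np.ndarray, x_shape,
                        need_dx: bool = True):
    N, C, H, Wd = x_shape
    F, _, k, _ = W.shape
    pb = (k - 1) // 2
    pa = k - 1 - pb
    db = dy.sum(axis=(0, 2, 3))
    dyr = np.ascontiguousarray(dy.transpose(1, 0, 2, 3)).reshape(F, -1)
    dW = (dyr @ colsT.T).reshape(W.shape)
    if not need_dx:
        return None, dW, db
    # input gradient, accumulated per kernel offset in channels-first layout
    dxp = np.zeros((C, N, H + k - 1, Wd + k - 1), dtype=dy.dtype)
    for u in range(k):
        for v in range(k):
            contrib = (W[:, :, u, v].T @ dyr).reshape(C, N, H, Wd)
            dxp[:, :, u:u + H, v:v + Wd] += contrib
    dx = np.ascontiguousarray(
        dxp[:, :, pb:pb + H, pb:pb + Wd].transpose(1, 0, 2, 3)
    )
    return dx, dW, db


def _maxpool_forward(x: np.ndarray, size: int, stride: int):
    """Overlapping max pool tracking the winning in-window offset per output.

    The 4x4-window / stride-2 case factorizes: each window is the union of
    four non-overlapping 2x2 blocks, so the pool is a block max followed by a
    stride-1 2x2 max over the block grid, which touches far less memory than
    sixteen strided passes.  Other geometries use the generic shift loop.
    """
    N, C, H, W = x.shape
    Ho = (H - size) // stride + 1
    Wo = (W - size) // stride + 1
    if size == 4 and stride == 2:
        Hp, Wp = H + (H % 2), W + (W % 2)
        if (Hp, Wp) != (H, W):
            xp = np.full((N, C, Hp, Wp), -np.inf, dtype=x.dtype)
            xp[:, :, :H, :W] = x
        else:
            xp = x
        xr = xp.reshape(N, C, Hp // 2, 2, Wp // 2, 2)
        m = xr[:, :, :, 0, :, 0].copy()
        arg1 = np.zeros(m.shape, dtype=np.uint8)
        for idx, (i, j) in enumerate(((0, 1), (1, 0), (1, 1)), start=1):
            sl = xr[:, :, :, i, :, j]
            better = sl > m
            np.copyto(m, sl, where=better)
            np.copyto(arg1, np.uint8(idx), where=better)
        y = np.ascontiguousarray(m[:, :, :Ho, :Wo])
        arg2 = np.zeros(y.shape, dtype=np.uint8)
        for idx, (du, dv) in enumerate(((0, 1), (1, 0), (1, 1)), start=1):
            sl = m[:, :, du:du + Ho, dv:dv + Wo]
            better = sl > y
            np.copyto(y, sl, where=better)
            np.copyto(arg2, np.uint8(idx), where=better)
        return y, (arg1, arg2)
    y = np.full((N, C, Ho, Wo), -np.inf, dtype=x.dtype)
    arg = np.zeros((N, C, Ho, Wo), dtype=np.uint8)
    for u in range(size):
        for v in range(size):
            sl = x[:, :, u:u + stride * (Ho - 1) + 1:stride,
                   v:v + stride * (Wo - 1) + 1:stride]
            better = sl > y
            np.copyto(y, sl, where=better)
            np.copyto(arg, np.uint8(u * size + v), where=better)
    return y, arg


def _maxpool_backward(dy: np.ndarray, arg, x_shape, size: int, stride: int):
    N, C, H, W = x_shape
    _, _, Ho, Wo = dy.shape
    if size == 4 and stride == 2:
        arg1, arg2 = arg
        Hm, Wm = arg1.shape[2], arg1.shape[3]
        dm = np.zeros((N, C, Hm, Wm), dtype=dy.dtype)
        for idx, (du, dv) in enumerate(((0, 0), (0, 1), (1, 0), (1, 1))):
            tgt = dm[:, :, du:du + Ho, dv:dv + Wo]
            np.add(tgt, dy * (arg2 == idx), out=tgt)
        dxr = np.zeros((N, C, Hm, 2, Wm, 2), dtype=dy.dtype)
        for idx, (i, j) in enumerate(((0, 0), (0, 1), (1, 0), (1, 1))):
            dxr[:, :, :, i, :, j] = dm * (arg1 == idx)
        return np.ascontiguousarray(
            dxr.reshape(N, C, 2 * Hm, 2 * Wm)[:, :, :H, :W]
        )
    dx = np.zeros(x_shape, dtype=dy.dtype)
    for u in range(size):
        for v in range(size):
            mask = arg == u * size + v
            tgt = dx[:, :, u:u + stride * (Ho - 1) + 1:stride,
                     v:v + stride * (Wo - 1) + 1:stride]
            np.add(tgt, dy * mask, out=tgt)
    return dx


def _bn_forward(x, gamma, beta, running_mean, running_var, axes, training, update_running):
    if training:
        mean = x.mean(axis=axes)
        var = x.var(axis=axes)
        if update_running:
            running_mean *= _BN_MOMENTUM
            running_mean += (1 - _BN_MOMENTUM) * mean.astype(running_mean.dtype)
            running_var *= _BN_MOMENTUM
            running_var += (1 - _BN_MOMENTUM) * var.astype(running_var.dtype)
    else:
        mean, var = running_mean, running_var
    shape = [1] * x.ndim
    shape[1 if x.ndim == 4 else -1] = -1
    inv_std = 1.0 / np.sqrt(var + _BN_EPS)
    xhat = (x - mean.reshape(shape)) * inv_std.reshape(shape)
    out = gamma.reshape(shape) * xhat + beta.reshape(shape)
    return out, (xhat, inv_std, shape)


def _bn_backward(dout, cache, gamma, axes):
    xhat, inv_std, shape = cache
    dgamma = (dout * xhat).sum(axis=axes)
    dbeta = dout.sum(axis=axes)
    m = dout.size // dgamma.size
    # dxhat = dout * gamma; since gamma is per-channel constant,
    # mean(dxhat) = gamma * dbeta / m and mean(dxhat * xhat) = gamma * dgamma / m,
    # so dx = gamma * inv_std * (dout - dbeta/m - xhat * dgamma/m).
    dx = dout - (dbeta / m).reshape(shape)
    dx -= xhat * (dgamma / m).reshape(shape)
    dx *= (gamma * inv_std).reshape(shape)
    return dx, dgamma, dbeta


# ---------------------------------------------------------------------------
# forward / backward through the whole network
# ---------------------------------------------------------------------------


def _forward(
    weights: NetworkWeights,
    X: np.ndarray,
    training: bool,
    rng: np.random.Generator | None = None,
    update_running: bool = True,
):
    """Run G_W on a stack of images; returns (embeddings, cache)."""
    spec = weights.spec
    p = weights.params
    r = weights.running
    if X.ndim != 3 or X.shape[1] != spec.input_side or X.shape[2] != spec.input_side:
        raise ValueError(
            f"input images must be (n, {spec.input_side}, {spec.input_side}), "
            f"got {X.shape}"
        )
    dtype = p["conv1_W"].dtype
    x = np.ascontiguousarray(X[:, None, :, :], dtype=dtype)
    cache: list = []
    for i in range(len(spec.conv_channels)):
        name = f"conv{i + 1}"
        x_shape = x.shape
        y, cols = _conv_same_forward(x, p[f"{name}_W"], p[f"{name}_b"])
        bn_cache = None
        if spec.batchnorm:
            y, bn_cache = _bn_forward(
                y, p[f"{name}_gamma"], p[f"{name}_beta"],
                r[f"{name}_mean"], r[f"{name}_var"],
                axes=(0, 2, 3), training=training, update_running=update_running,
            )
        # tanh is strictly increasing, so tanh(maxpool(y)) == maxpool(tanh(y));
        # pooling first applies the nonlinearity to a quarter of the values.
        z, arg = _maxpool_forward(y, spec.pool_size, spec.pool_stride)
        a = np.tanh(z)
        cache.append((name, x_shape, cols, bn_cache, a, arg, y.shape))
        x = a
    n = x.shape[0]
    flat_shape = x.shape
    x = x.reshape(n, -1)
    for j in range(len(spec.fc_sizes)):
        name = f"fc{j + 1}"
        x_in = x
        y = x @ p[f"{name}_W"].T + p[f"{name}_b"]
        bn_cache = None
        if spec.batchnorm:
            y, bn_cache = _bn_forward(
                y, p[f"{name}_gamma"], p[f"{name}_beta"],
                r[f"{name}_mean"], r[f"{name}_var"],
                axes=(0,), training=training, update_running=update_running,
            )
        a = np.tanh(y)
        mask = None
        if training and spec.dropout_p > 0:
            if rng is None:
                raise ValueError("training-mode forward with dropout needs an RNG")
            mask = (rng.random(a.shape) >= spec.dropout_p).astype(dtype) / (
                1.0 - spec.dropout_p
            )
            a = a * mask
        cache.append((name, x_in, bn_cache, a, mask))
        x = a
    e_lin = x @ p["emb_W"].T + p["emb_b"]
    emb = np.tanh(e_lin)
    cache.append(("emb", x, emb, flat_shape))
    return emb, cache


def _backward(weights: NetworkWeights, cache: list, demb: np.ndarray):
    """Backpropagate d(loss)/d(embeddings) into parameter gradients."""
    spec = weights.spec
    p = weights.params
    grads = {k: None for k in p}
    name, x_in, emb, flat_shape = cache[-1]
    dz = demb * (1.0 - emb * emb)
    grads["emb_W"] = dz.T @ x_in
    grads["emb_b"] = dz.sum(axis=0)
    dx = dz @ p["emb_W"]
    for j in range(len(spec.fc_sizes) - 1, -1, -1):
        name, x_in, bn_cache, a, mask = cache[len(spec.conv_channels) + j]
        da = dx
        if mask is not None:
            da = da * mask
            a_pre = a / np.where(mask == 0, 1.0, mask)  # activation before dropout
        else:
            a_pre = a
        dy = da * (1.0 - a_pre * a_pre)
        if spec.batchnorm:
            dy, dgamma, dbeta = _bn_backward(dy, bn_cache, p[f"{name}_gamma"], axes=(0,))
            grads[f"{name}_gamma"] = dgamma
            grads[f"{name}_beta"] = dbeta
        grads[f"{name}_W"] = dy.T @ x_in
        grads[f"{name}_b"] = dy.sum(axis=0)
        dx = dy @ p[f"{name}_W"]
    dx = dx.reshape(flat_shape)
    for i in range(len(spec.conv_channels) - 1, -1, -1):
        name, x_shape, cols, bn_cache, a, arg, y_shape = cache[i]
        dz = dx * (1.0 - a * a)  # tanh backward at pooled size
        dy = _maxpool_backward(dz, arg, y_shape, spec.pool_size, spec.pool_stride)
        if spec.batchnorm:
            dy, dgamma, dbeta = _bn_backward(
                dy, bn_cache, p[f"{name}_gamma"], axes=(0, 2, 3)
            )
            grads[f"{name}_gamma"] = dgamma
            grads[f"{name}_beta"] = dbeta
        dx, dW, db = _conv_same_backward(dy, cols, p[f"{name}_W"], x_shape, need_dx=(i > 0))
        grads[f"{name}_W"] = dW
        grads[f"{name}_b"] = db
    return grads


def embed(
    weights: NetworkWeights, image, training_mode: bool = False,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Embed a single spectrum: G_W(x) in [-1, 1]^K.

    With ``training_mode`` false (the default, and the mode used for all
    retrieval and evaluation) the map is deterministic: dropout is off and
    batch-norm running statistics are used.
    """
    pixels = image.pixels if hasattr(image, "pixels") else np.asarray(image)
    emb, _ = _forward(
        weights, pixels[None, :, :].astype(np.float64), training=training_mode, rng=rng
    )
    return emb[0]


def embed_images(
    weights: NetworkWeights, images: Sequence, batch_size: int = 64
) -> np.ndarray:
    """Evaluation-mode embeddings of a stack of images, in order."""
    arrs = [im.pixels if hasattr(im, "pixels") else np.asarray(im) for im in images]
    X = np.stack(arrs).astype(np.float32)
    out = []
    for i in range(0, len(X), batch_size):
        emb, _ = _forward(weights, X[i:i + batch_size], training=False)
        out.append(emb)
    return np.concatenate(out, axis=0)


def pairwise_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Euclidean distance between two embedding vectors."""
    a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"dimension mismatch: {a.shape} vs {b.shape}")
    return float(np.linalg.norm(a - b))


def contrastive_loss(d, same, m: float = 1.0):
    """Contrastive (spring) energy of a pair at embedding distance d.

    Same family: 1/2 * max(0, d - m)^2 — zero inside the margin.
    Different family: 1/2 * max(0, m - d)^2 — zero beyond the margin.
    """
    if m <= 0:
        raise ValueError(f"margin must be positive, got {m}")
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    same = np.asarray(same, dtype=bool)
    pull = 0.5 * np.maximum(0.0, d - m) ** 2
    push = 0.5 * np.maximum(0.0, m - d) ** 2
    out = np.where(same, pull, push)
    return float(out) if out.ndim == 0 else out


def max_embedding_distance(K: int) -> float:
    """Largest attainable distance: opposite corners of the tanh hypercube."""
    return 2.0 * np.sqrt(K)


def _loss_from_embeddings(el, er, same, m):
    diff = el - er
    d = np.sqrt((diff * diff).sum(axis=1))
    losses = contrastive_loss(d, same, m)
    B = len(d)
    # dL/dd, guarding the non-differentiable point d = 0 (direction undefined)
    g = np.where(same, np.maximum(0.0, d - m), -np.maximum(0.0, m - d))
    safe = np.where(d > 1e-12, d, 1.0)
    coef = (g / safe) / B
    coef = np.where(d > 1e-12, coef, 0.0)
    dl = coef[:, None] * diff
    return float(losses.mean()), dl, -dl, d


def batch_loss(
    weights: NetworkWeights, batch: PairBatch, m: float = 1.0,
    training: bool = False, rng: np.random.Generator | None = None,
) -> float:
    """Mean contrastive energy over a pair batch via one shared-weight pass.

    Left and right images are concatenated into a single forward pass, so the
    twins share both weights and (in training mode) batch-norm statistics;
    the loss is therefore invariant to swapping left and right inputs.
    """
    loss, _ = batch_loss_and_grads(
        weights, batch, m, training=training, rng=rng, want_grads=False
    )
    return loss


def batch_loss_and_grads(
    weights: NetworkWeights, batch: PairBatch, m: float = 1.0,
    training: bool = True, rng: np.random.Generator | None = None,
    want_grads: bool = True,
):
    """Loss and analytic parameter gradients for one pair batch."""
    B = len(batch.left)
    dtype = weights.params["conv1_W"].dtype
    X = np.concatenate(
        [np.asarray(batch.left, dtype=dtype), np.asarray(batch.right, dtype=dtype)]
    )
    emb, cache = _forward(weights, X, training=training, rng=rng)
    loss, dl, dr, _ = _loss_from_embeddings(
        emb[:B].astype(np.float64), emb[B:].astype(np.float64), batch.same, m
    )
    if not want_grads:
        return loss, None
    demb = np.concatenate([dl, dr]).astype(emb.dtype)
    grads = _backward(weights, cache, demb)
    return loss, grads


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------


def save_checkpoint(
    path, weights: NetworkWeights, config: Mapping | None = None
) -> None:
    """Write every parameter tensor, the architecture and an optional config
    to a single archive; sufficient to reload bit-exactly."""
    meta = {
        "architecture": asdict(weights.spec),
        "config": dict(config) if config else None,
        "param_keys": sorted(weights.params),
        "running_keys": sorted(weights.running),
    }
    with zipfile.ZipFile(path, "w", compression=zipfile.ZIP_DEFLATED) as zf:
        zf.writestr("meta.json", json.dumps(meta, indent=1))
        for group, tensors in (("params", weights.params), ("running", weights.running)):
            for k, v in tensors.items():
                buf = io.BytesIO()
                np.save(buf, v)
                zf.writestr(f"{group}/{k}.npy", buf.getvalue())


def load_checkpoint(path) -> tuple[NetworkWeights, dict | None]:
    """Reload a checkpoint written by :func:`save_checkpoint`."""
    with zipfile.ZipFile(path, "r") as zf:
        meta = json.loads(zf.read("meta.json"))
        arch = meta["architecture"]
        for key in ("conv_channels", "fc_sizes"):
            arch[key] = tuple(arch[key])
        spec = ArchitectureSpec(**arch)
        params = {
            k: np.load(io.BytesIO(zf.read(f"params/{k}.npy")))
            for k in meta["param_keys"]
        }
        running = {
            k: np.load(io.BytesIO(zf.read(f"running/{k}.npy")))
            for k in meta["running_keys"]
        }
    return NetworkWeights(spec, params, running), meta["config"]
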