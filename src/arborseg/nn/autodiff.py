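"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations the segmentation and confidence networks
need: 3D convolution ("same" padding), batch normalization, ReLU, dropout,
2x average pooling, 2x nearest-neighbor upsampling, channel concatenation,
channel softmax/sigmoid, and the (weighted) cross-entropy losses.

All activations are float32 arrays in channels-last layout ``(N, D, H, W, C)``:
with few channels and small cubic patches this keeps every convolution a
sequence of contiguous BLAS matmuls (one per kernel offset) instead of an
expensive im2col gather, which is the fastest pure-numpy formulation at the
problem sizes used here. Convolution weights are stored as
``(k, k, k, C_in, C_out)``.
"""

from __future__ import annotations

import numpy as np

EPS_LOG = 1e-7  # probability clamp so log terms stay finite at saturation


class Tensor:
    """Array node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward_fn")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward_fn=None):
        arr = np.asarray(data, dtype=np.float32)
        self.data = arr if arr.flags["C_CONTIGUOUS"] else np.ascontiguousarray(arr)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents = parents
        self._backward_fn = backward_fn

    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.asarray(g, dtype=np.float32).copy()
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: "Tensor") -> None:
            stack = [(t, iter(t._parents))]
            seen.add(id(t))
            while stack:
                node, it = stack[-1]
                advanced = False
                for p in it:
                    if id(p) not in seen and p.requires_grad:
                        seen.add(id(p))
                        stack.append((p, iter(p._parents)))
                        advanced = True
                        break
                if not advanced:
                    topo.append(node)
                    stack.pop()

        visit(self)
        self._accumulate(np.asarray(grad, dtype=np.float32))
        for node in reversed(topo):
            if node._backward_fn is not None and node.grad is not None:
                node._backward_fn(node.grad)
            if node is not self:
                node.grad = None if node._backward_fn is not None else node.grad


def _make(data, parents, backward_fn) -> Tensor:
    req = any(p.requires_grad for p in parents)
    return Tensor(
        data, requires_grad=req, parents=tuple(parents),
        backward_fn=backward_fn if req else None,
    )


# ---------------------------------------------------------------------------
# convolution

def conv3d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """3D convolution with "same" zero padding.

    ``x``: (N, D, H, W, C); ``w``: (k, k, k, C, O); ``b``: (O,).
    """
    k = w.data.shape[0]
    p = k // 2
    N, D, H, W, C = x.data.shape
    O = w.data.shape[-1]
    if k == 1:
        out = x.data @ w.data[0, 0, 0] + b.data

        def backward1(go: np.ndarray) -> None:
            if b.requires_grad:
                b._accumulate(go.sum(axis=(0, 1, 2, 3)))
            if w.requires_grad:
                dw = np.tensordot(x.data, go, axes=([0, 1, 2, 3], [0, 1, 2, 3]))
                w._accumulate(dw[None, None, None])
            if x.requires_grad:
                x._accumulate(go @ w.data[0, 0, 0].T)

        return _make(out, (x, w, b), backward1)

    xp = np.pad(x.data, ((0, 0), (p, p), (p, p), (p, p), (0, 0)))
    out = np.zeros((N, D, H, W, O), dtype=np.float32)
    for i in range(k):
        for j in range(k):
            for l in range(k):
                out += xp[:, i : i + D, j : j + H, l : l + W, :] @ w.data[i, j, l]
    out += b.data

    def backward(go: np.ndarray) -> None:
        gov = go.reshape(-1, O)
        if b.requires_grad:
            b._accumulate(gov.sum(axis=0))
        if w.requires_grad:
            dw = np.zeros_like(w.data)
            for i in range(k):
                for j in range(k):
                    for l in range(k):
                        xs = xp[:, i : i + D, j : j + H, l : l + W, :]
                        dw[i, j, l] = xs.reshape(-1, C).T @ gov
            w._accumulate(dw)
        if x.requires_grad:
            # dx is the "full" correlation of go with the flipped kernel:
            # accumulating into one contiguous array avoids 27 strided adds
            gp = np.pad(go, ((0, 0), (p, p), (p, p), (p, p), (0, 0)))
            dx = np.zeros_like(x.data)
            for i in range(k):
                for j in range(k):
                    for l in range(k):
                        dx += gp[:, i : i + D, j : j + H, l : l + W, :] @ (
                            w.data[k - 1 - i, k - 1 - j, k - 1 - l].T
                        )
            x._accumulate(dx)

    return _make(out, (x, w, b), backward)


# ---------------------------------------------------------------------------
# normalization / activations

def batch_norm(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    training: bool,
    momentum: float = 0.1,
    eps: float = 1e-5,
) -> Tensor:
    """Per-channel batch normalization over (N, D, H, W).

    In training mode the batch statistics are used and the running estimates
    are updated in place; in eval mode the running estimates are used.
    """
    axes = (0, 1, 2, 3)
    if training:
        flat = x.data.reshape(-1, x.data.shape[-1])
        mu = flat.mean(axis=0)
        var = np.einsum("nc,nc->c", flat, flat) / flat.shape[0] - mu * mu
        np.maximum(var, 0.0, out=var)
        running_mean *= 1.0 - momentum
        running_mean += momentum * mu
        running_var *= 1.0 - momentum
        running_var += momentum * var
    else:
        mu, var = running_mean, running_var
    inv = (1.0 / np.sqrt(var + eps)).astype(np.float32)
    xhat = (x.data - mu) * inv
    out = gamma.data * xhat + beta.data

    def backward(go: np.ndarray) -> None:
        if gamma.requires_grad:
            gamma._accumulate((go * xhat).sum(axis=axes))
        if beta.requires_grad:
            beta._accumulate(go.sum(axis=axes))
        if x.requires_grad:
            g = go * gamma.data
            if training:
                gm = g.mean(axis=axes)
                gxm = (g * xhat).mean(axis=axes)
                dx = inv * (g - gm - xhat * gxm)
            else:
                dx = g * inv
            x._accumulate(dx.astype(np.float32))

    return _make(out, (x, gamma, beta), backward)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    out = x.data * mask

    def backward(go: np.ndarray) -> None:
        if x.requires_grad:
            x._accumulate(go * mask)

    return _make(out, (x,), backward)


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-np.clip(x.data, -60, 60)))

    def backward(go: np.ndarray) -> None:
        if x.requires_grad:
            x._accumulate(go * s * (1.0 - s))

    return _make(s, (x,), backward)


def dropout(x: Tensor, p: float, rng: np.random.Generator, training: bool) -> Tensor:
    if not training or p <= 0:
        return x
    keep = 1.0 - p
    mask = (rng.random(x.data.shape) < keep).astype(np.float32) / keep
    out = x.data * mask

    def backward(go: np.ndarray) -> None:
        if x.requires_grad:
            x._accumulate(go * mask)

    return _make(out, (x,), backward)


# ---------------------------------------------------------------------------
# resolution changes / concatenation

def avg_pool2(x: Tensor) -> Tensor:
    N, D, H, W, C = x.data.shape
    if D % 2 or H % 2 or W % 2:
        raise ValueError(f"avg_pool2 requires even spatial dims, got {(D, H, W)}")
    r = x.data.reshape(N, D // 2, 2, H // 2, 2, W // 2, 2, C)
    out = r.mean(axis=(2, 4, 6))

    def backward(go: np.ndarray) -> None:
        if x.requires_grad:
            g = np.repeat(np.repeat(np.repeat(go, 2, 1), 2, 2), 2, 3) / 8.0
            x._accumulate(g)

    return _make(out, (x,), backward)


def upsample2(x: Tensor) -> Tensor:
    out = np.repeat(np.repeat(np.repeat(x.data, 2, 1), 2, 2), 2, 3)

    def backward(go: np.ndarray) -> None:
        if x.requires_grad:
            N, D, H, W, C = x.data.shape
            g = go.reshape(N, D, 2, H, 2, W, 2, C).sum(axis=(2, 4, 6))
            x._accumulate(g)

    return _make(out, (x,), backward)


def concat_channels(tensors: list[Tensor]) -> Tensor:
    out = np.concatenate([t.data for t in tensors], axis=-1)
    splits = np.cumsum([t.data.shape[-1] for t in tensors])[:-1]

    def backward(go: np.ndarray) -> None:
        parts = np.split(go, splits, axis=-1)
        for t, g in zip(tensors, parts):
            if t.requires_grad:
                t._accumulate(np.ascontiguousarray(g))

    return _make(out, tuple(tensors), backward)


# ---------------------------------------------------------------------------
# heads and losses

def softmax_channels(x: Tensor) -> Tensor:
    z = x.data - x.data.max(axis=-1, keepdims=True)
    e = np.exp(z)
    s = e / e.sum(axis=-1, keepdims=True)

    def backward(go: np.ndarray) -> None:
        if x.requires_grad:
            dot = (go * s).sum(axis=-1, keepdims=True)
            x._accumulate(s * (go - dot))

    return _make(s, (x,), backward)


def weighted_cross_entropy(
    probs: Tensor, onehot: np.ndarray, weights: np.ndarray | None = None
) -> Tensor:
    """Spatially-weighted multi-class cross-entropy on probability maps.

    ``probs`` and ``onehot`` are channels-last ``(N, D, H, W, C)``; ``weights``
    is per-voxel ``(N, D, H, W)``. With ``weights`` None this is the plain
    segmentation loss: the mean over voxels of ``-sum_i Y_i ln X_i``. With a
    weight map, each voxel's term is scaled by its weight and the sum is
    normalized by the number of voxels with positive weight. Probabilities
    are clamped to [EPS_LOG, 1] before the log.
    """
    p = probs.data
    onehot = np.asarray(onehot, dtype=np.float32)
    if onehot.shape != p.shape:
        raise ValueError(f"shape mismatch: probs {p.shape} vs target {onehot.shape}")
    pc = np.clip(p, EPS_LOG, 1.0)
    per_vox = -(onehot * np.log(pc)).sum(axis=-1)  # (N, D, H, W)
    if weights is None:
        norm = float(per_vox.size)
        loss = per_vox.sum() / norm
        wmap = None
    else:
        wmap = np.asarray(weights, dtype=np.float32)
        if wmap.shape != per_vox.shape:
            raise ValueError(f"weights shape {wmap.shape} does not match voxels {per_vox.shape}")
        n_pos = int((wmap > 0).sum())
        norm = float(max(n_pos, 1))
        loss = float((wmap * per_vox).sum()) / norm

    def backward(go: np.ndarray) -> None:
        if probs.requires_grad:
            g = float(np.asarray(go).reshape(-1)[0])
            active = (p >= EPS_LOG).astype(np.float32)
            dper = -(onehot / pc) * active
            if wmap is None:
                dp = dper * (g / norm)
            else:
                dp = dper * (wmap[..., None] * (g / norm))
            probs._accumulate(dp)

    return _make(np.float32(loss), (probs,), backward)


def confidence_cross_entropy(pred: Tensor, target: np.ndarray, a: float = 0.1) -> Tensor:
    """Class-balanced binary cross-entropy for the confidence model.

    Mean over voxels of ``-(Y ln X + a (1 - Y) ln(1 - X))`` where ``Y`` is the
    binary agreement target and ``X`` the predicted confidence, clamped to
    [EPS_LOG, 1 - EPS_LOG]. The constant ``a`` down-weights the (far more
    numerous) correctly-classified voxels' complement term, countering the
    volume bias between correct and misclassified voxels.
    """
    if a <= 0:
        raise ValueError("class-balance constant a must be > 0")
    y = np.asarray(target, dtype=np.float32)
    if y.shape != pred.data.shape:
        raise ValueError(f"shape mismatch: pred {pred.data.shape} vs target {y.shape}")
    xc = np.clip(pred.data, EPS_LOG, 1.0 - EPS_LOG)
    per_vox = -(y * np.log(xc) + a * (1.0 - y) * np.log(1.0 - xc))
    norm = float(per_vox.size)
    loss = per_vox.sum() / norm

    def backward(go: np.ndarray) -> None:
        if pred.requires_grad:
            g = float(np.asarray(go).reshape(-1)[0]) / norm
            in_range = ((pred.data > EPS_LOG) & (pred.data < 1.0 - EPS_LOG)).astype(np.float32)
            dp = (-(y / xc) + a * (1.0 - y) / (1.0 - xc)) * in_range * g
            pred._accumulate(dp)

    return _make(np.float32(loss), (pred,), backward)
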