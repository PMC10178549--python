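"""A small 2-D convolutional network for outer-product spectral matrices.

The network classifies a sample from the rank-1 matrix ``S = x x^T`` of its
selected-wavelength vector ``x``. Layer stack (side length n -> 3 class
scores):

    input 1 x n x n
    -> 3x3 conv, 96 kernels, same padding -> batch norm -> ReLU
    -> 2x2 max pool, stride 2
    -> 1x1 conv, 192 kernels -> batch norm -> ReLU
    -> 1x1 conv, 384 kernels -> batch norm -> ReLU
    -> flatten -> fully connected, 32 nodes -> ReLU
    -> fully connected, 3 nodes -> softmax

Training is plain mini-batch stochastic gradient descent (optional momentum,
off by default) on the softmax cross-entropy loss. Everything — forward
pass, batch-norm statistics, backpropagation — is implemented directly on
NumPy arrays; inputs are small (side 8-132), so no GPU or autograd framework
is needed and runs are bit-reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ovotrace.errors import ParameterError, ValidationError

_BN_EPS = 1e-5
_BN_MOMENTUM = 0.1


@dataclass(frozen=True)
class CNNSpec:
    """Layer widths of the network; defaults follow the reference stack."""

    conv1_kernels: int = 96
    conv1_size: int = 3
    conv2_kernels: int = 192
    conv3_kernels: int = 384
    fc1_nodes: int = 32
    n_classes: int = 3
    pool_size: int = 2
    pool_stride: int = 2


@dataclass(frozen=True)
class TrainConfig:
    """SGD schedule: learning rate 1e-4, mini-batch 4, up to 300 epochs."""

    learning_rate: float = 1e-4
    batch_size: int = 4
    max_epochs: int = 300
    momentum: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.batch_size < 1 or self.max_epochs < 1:
            raise ParameterError("learning_rate, batch_size, max_epochs must be > 0")


def outer_product(x: np.ndarray) -> np.ndarray:
    """Rank-1 matrix ``S = x x^T`` used as the 2-D network input.

    S is symmetric, positive semidefinite, rank <= 1, and
    ``trace(S) = sum(x_i^2)``.
    """
    x = np.asarray(x, dtype=float).ravel()
    if x.size < 2:
        raise ValidationError("outer_product needs a vector of length >= 2")
    return np.outer(x, x)


# ---------------------------------------------------------------------------
# layer primitives (forward returns cache for backward)


def _conv3x3_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray):
    """Same-padded 3x3 convolution via im2col. x: (B, C, H, W_)."""
    B, C, H, Wd = x.shape
    K = W.shape[0]
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    # im2col: columns of shape (C*9) for every output position
    cols = np.empty((B, C * 9, H * Wd))
    i = 0
    for dh in range(3):
        for dw in range(3):
            patch = xp[:, :, dh : dh + H, dw : dw + Wd]
            cols[:, i * C : (i + 1) * C, :] = patch.reshape(B, C, -1)
            i += 1
    # match the (dh, dw)-major, then channel, layout of the columns
    Wm = W.transpose(0, 2, 3, 1).reshape(K, -1)
    out = np.einsum("kc,bcp->bkp", Wm, cols).reshape(B, K, H, Wd)
    out += b[None, :, None, None]
    return out, (cols, x.shape, Wm)


def _conv3x3_backward(dout: np.ndarray, W: np.ndarray, cache):
    cols, xshape, Wm = cache
    B, C, H, Wd = xshape
    K = W.shape[0]
    d = dout.reshape(B, K, -1)
    dW = (
        np.einsum("bkp,bcp->kc", d, cols)
        .reshape(K, 3, 3, C)
        .transpose(0, 3, 1, 2)
    )
    db = d.sum(axis=(0, 2))
    dcols = np.einsum("kc,bkp->bcp", Wm, d)  # (B, C*9, H*Wd)
    dxp = np.zeros((B, C, H + 2, Wd + 2))
    i = 0
    for dh in range(3):
        for dw in range(3):
            dxp[:, :, dh : dh + H, dw : dw + Wd] += dcols[
                :, i * C : (i + 1) * C, :
            ].reshape(B, C, H, Wd)
            i += 1
    return dxp[:, :, 1:-1, 1:-1], dW, db


def _conv1x1_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray):
    """1x1 convolution = per-pixel linear map. W: (K, C)."""
    out = np.einsum("kc,bchw->bkhw", W, x) + b[None, :, None, None]
    return out, x


def _conv1x1_backward(dout: np.ndarray, W: np.ndarray, x: np.ndarray):
    dW = np.einsum("bkhw,bchw->kc", dout, x)
    db = dout.sum(axis=(0, 2, 3))
    dx = np.einsum("kc,bkhw->bchw", W, dout)
    return dx, dW, db


def _bn_forward(x, gamma, beta, running, training: bool):
    if training:
        mean = x.mean(axis=(0, 2, 3))
        var = x.var(axis=(0, 2, 3))
        running["mean"] = (1 - _BN_MOMENTUM) * running["mean"] + _BN_MOMENTUM * mean
        running["var"] = (1 - _BN_MOMENTUM) * running["var"] + _BN_MOMENTUM * var
    else:
        mean, var = running["mean"], running["var"]
    inv = 1.0 / np.sqrt(var + _BN_EPS)
    xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
    out = gamma[None, :, None, None] * xhat + beta[None, :, None, None]
    return out, (xhat, inv)


def _bn_backward(dout, gamma, cache):
    xhat, inv = cache
    m = dout.shape[0] * dout.shape[2] * dout.shape[3]
    dgamma = (dout * xhat).sum(axis=(0, 2, 3))
    dbeta = dout.sum(axis=(0, 2, 3))
    dxhat = dout * gamma[None, :, None, None]
    dx = (
        dxhat
        - dxhat.mean(axis=(0, 2, 3))[None, :, None, None]
        - xhat * (dxhat * xhat).mean(axis=(0, 2, 3))[None, :, None, None]
    ) * inv[None, :, None, None]
    return dx, dgamma, dbeta


def _maxpool_forward(x: np.ndarray, size: int, stride: int):
    B, C, H, W = x.shape
    Ho, Wo = H // stride, W // stride
    if Ho < 1 or Wo < 1:
        raise ParameterError("input too small for the pooling layer")
    xt = x[:, :, : Ho * stride, : Wo * stride]
    xt = xt.reshape(B, C, Ho, stride, Wo, stride)
    out = xt.max(axis=(3, 5))
    # ties share the gradient equally (counts-normalized in backward)
    mask = xt == out[:, :, :, None, :, None]
    return out, (mask, x.shape, (Ho, Wo))


def _maxpool_backward(dout: np.ndarray, stride: int, cache):
    mask, xshape, (Ho, Wo) = cache
    B, C, H, W = xshape
    counts = mask.sum(axis=(3, 5), keepdims=True)
    grad = mask / counts * dout[:, :, :, None, :, None]
    dx = np.zeros(xshape)
    dx[:, :, : Ho * stride, : Wo * stride] = grad.reshape(
        B, C, Ho * stride, Wo * stride
    )
    return dx


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class OuterProductCNN:
    """The classifier object: parameters, forward pass, and SGD training."""

    def __init__(self, side: int, spec: CNNSpec, seed: int = 0):
        if side < 2:
            raise ParameterError(
                "outer-product side must be >= 2 (need at least 2 selected "
                "wavelengths) for the pooling layer to produce output"
            )
        self.side = side
        self.spec = spec
        rng = np.random.default_rng(seed)
        s = spec
        self.pooled = side // s.pool_stride
        flat = s.conv3_kernels * self.pooled * self.pooled

        def he(shape, fan_in):
            return rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)

        self.params = {
            "W1": he((s.conv1_kernels, 1, 3, 3), 9),
            "b1": np.zeros(s.conv1_kernels),
            "g1": np.ones(s.conv1_kernels),
            "be1": np.zeros(s.conv1_kernels),
            "W2": he((s.conv2_kernels, s.conv1_kernels), s.conv1_kernels),
            "b2": np.zeros(s.conv2_kernels),
            "g2": np.ones(s.conv2_kernels),
            "be2": np.zeros(s.conv2_kernels),
            "W3": he((s.conv3_kernels, s.conv2_kernels), s.conv2_kernels),
            "b3": np.zeros(s.conv3_kernels),
            "g3": np.ones(s.conv3_kernels),
            "be3": np.zeros(s.conv3_kernels),
            "Wf1": he((flat, s.fc1_nodes), flat),
            "bf1": np.zeros(s.fc1_nodes),
            "Wf2": he((s.fc1_nodes, s.n_classes), s.fc1_nodes),
            "bf2": np.zeros(s.n_classes),
        }
        self.running = {
            f"bn{i}": {"mean": np.zeros(c), "var": np.ones(c)}
            for i, c in enumerate(
                (s.conv1_kernels, s.conv2_kernels, s.conv3_kernels), start=1
            )
        }
        self.loss_history: list[float] = []

    # -- forward -----------------------------------------------------------
    def forward(self, S: np.ndarray, training: bool = False):
        """Map a batch of outer-product matrices (B, side, side) to scores."""
        p, sp = self.params, self.spec
        x = S[:, None, :, :]
        cache: dict[str, object] = {}
        h, cache["c1"] = _conv3x3_forward(x, p["W1"], p["b1"])
        h, cache["bn1"] = _bn_forward(
            h, p["g1"], p["be1"], self.running["bn1"], training
        )
        cache["r1"] = h > 0
        h = h * cache["r1"]
        h, cache["pool"] = _maxpool_forward(h, sp.pool_size, sp.pool_stride)
        h, cache["c2"] = _conv1x1_forward(h, p["W2"], p["b2"])
        h, cache["bn2"] = _bn_forward(
            h, p["g2"], p["be2"], self.running["bn2"], training
        )
        cache["r2"] = h > 0
        h = h * cache["r2"]
        h, cache["c3"] = _conv1x1_forward(h, p["W3"], p["b3"])
        h, cache["bn3"] = _bn_forward(
            h, p["g3"], p["be3"], self.running["bn3"], training
        )
        cache["r3"] = h > 0
        h = h * cache["r3"]
        cache["flat_shape"] = h.shape
        f = h.reshape(h.shape[0], -1)
        cache["f"] = f
        a1 = f @ p["Wf1"] + p["bf1"]
        cache["rf1"] = a1 > 0
        a1 = a1 * cache["rf1"]
        cache["a1"] = a1
        scores = a1 @ p["Wf2"] + p["bf2"]
        return scores, cache

    # -- backward ----------------------------------------------------------
    def _backward(self, dscores: np.ndarray, cache) -> dict[str, np.ndarray]:
        p, sp = self.params, self.spec
        g: dict[str, np.ndarray] = {}
        g["Wf2"] = cache["a1"].T @ dscores
        g["bf2"] = dscores.sum(axis=0)
        da1 = dscores @ p["Wf2"].T
        da1 = da1 * cache["rf1"]
        g["Wf1"] = cache["f"].T @ da1
        g["bf1"] = da1.sum(axis=0)
        dh = (da1 @ p["Wf1"].T).reshape(cache["flat_shape"])
        dh = dh * cache["r3"]
        dh, g["g3"], g["be3"] = _bn_backward(dh, p["g3"], cache["bn3"])
        dh, g["W3"], g["b3"] = _conv1x1_backward(dh, p["W3"], cache["c3"])
        dh = dh * cache["r2"]
        dh, g["g2"], g["be2"] = _bn_backward(dh, p["g2"], cache["bn2"])
        dh, g["W2"], g["b2"] = _conv1x1_backward(dh, p["W2"], cache["c2"])
        dh = _maxpool_backward(dh, sp.pool_stride, cache["pool"])
        dh = dh * cache["r1"]
        dh, g["g1"], g["be1"] = _bn_backward(dh, p["g1"], cache["bn1"])
        _, g["W1"], g["b1"] = _conv3x3_backward(dh, p["W1"], cache["c1"])
        return g

    # -- training ----------------------------------------------------------
    def fit(self, S: np.ndarray, y: np.ndarray, cfg: TrainConfig) -> "OuterProductCNN":
        """Mini-batch SGD on softmax cross-entropy; records per-epoch loss."""
        n = S.shape[0]
        rng = np.random.default_rng(cfg.seed)
        velocity = {k: np.zeros_like(v) for k, v in self.params.items()}
        onehot = np.eye(self.spec.n_classes)[y]
        for _ in range(cfg.max_epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for lo in range(0, n, cfg.batch_size):
                idx = order[lo : lo + cfg.batch_size]
                scores, cache = self.forward(S[idx], training=True)
                prob = _softmax(scores)
                eps = 1e-12
                loss = -np.mean(
                    np.log(prob[np.arange(len(idx)), y[idx]] + eps)
                )
                epoch_loss += loss * len(idx)
                dscores = (prob - onehot[idx]) / len(idx)
                grads = self._backward(dscores, cache)
                for k, gk in grads.items():
                    velocity[k] = cfg.momentum * velocity[k] - cfg.learning_rate * gk
                    self.params[k] = self.params[k] + velocity[k]
            self.loss_history.append(epoch_loss / n)
            if not np.isfinite(self.loss_history[-1]):
                raise ArithmeticError("training loss diverged to non-finite value")
        return self

    def predict(self, S: np.ndarray) -> np.ndarray:
        scores, _ = self.forward(S, training=False)
        return np.argmax(scores, axis=1)

    def predict_scores(self, S: np.ndarray) -> np.ndarray:
        scores, _ = self.forward(S, training=False)
        return scores
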