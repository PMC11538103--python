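"""Minimal 3D convolutional network for center-voxel patch classification.

A compact, dependency-free CNN stack (3D convolution with kernel 3 and
stride 2, batch normalization, ReLU, 2x max pooling, dense layers, sigmoid
output) trained with Adam on a summed cross-entropy loss, with a
reduce-on-plateau learning-rate schedule.  Everything is plain numpy with
explicit forward/backward passes; gradients are checked against numerical
differentiation in the test suite.

The default architecture follows the small-patch design: stacked
(conv k3 s2 -> BN -> ReLU) blocks with one max-pool after the first block,
the feature-map count held constant through the down-sampling steps until
the dense layers, and a single sigmoid output unit.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from itertools import product

import numpy as np

__all__ = ["SPCNNConfig", "SPCNN", "build_spcnn", "train_spcnn", "bce_with_logits"]


@dataclass
class SPCNNConfig:
    """Architecture and optimisation settings for the small-patch CNN."""

    patch_size: int = 25
    conv_kernel: int = 3
    conv_stride: int = 2
    pool_kernel: int = 2
    initial_feature_maps: int = 128
    n_blocks: int = 3
    dense_width: int = 256
    initial_lr: float = 1e-4
    min_lr: float = 1e-8
    lr_factor: float = 0.1
    lr_patience: int = 10
    batch_size: int = 25
    max_epochs: int = 80
    early_stop_epoch: int = 40
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("patch_size", "conv_kernel", "conv_stride", "pool_kernel",
                     "initial_feature_maps", "n_blocks", "dense_width",
                     "lr_patience", "batch_size", "max_epochs", "early_stop_epoch"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.lr_factor < 1:
            raise ValueError("lr_factor must be in (0, 1)")


# ---------------------------------------------------------------------------
# layers

class _Conv3d:
    def __init__(self, c_in, c_out, kernel, stride, pad, rng):
        fan_in = c_in * kernel**3
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, c_in, kernel, kernel, kernel))
        self.b = np.zeros(c_out)
        self.k, self.s, self.p = kernel, stride, pad

    def out_size(self, n):
        return (n + 2 * self.p - self.k) // self.s + 1

    def forward(self, x, train):
        p = self.p
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))
        N, C = x.shape[:2]
        do, ho, wo = (self.out_size(n) for n in x.shape[2:])
        out = np.zeros((N, self.W.shape[0], do, ho, wo))
        for i, j, k in product(range(self.k), repeat=3):
            v = xp[:, :, i:i + self.s * (do - 1) + 1:self.s,
                   j:j + self.s * (ho - 1) + 1:self.s,
                   k:k + self.s * (wo - 1) + 1:self.s]
            out += np.einsum("ncdhw,fc->nfdhw", v, self.W[:, :, i, j, k], optimize=True)
        out += self.b[None, :, None, None, None]
        self._xp, self._xshape = xp, x.shape
        return out

    def backward(self, g):
        xp = self._xp
        do, ho, wo = g.shape[2:]
        self.dW = np.zeros_like(self.W)
        self.db = g.sum(axis=(0, 2, 3, 4))
        dxp = np.zeros_like(xp)
        for i, j, k in product(range(self.k), repeat=3):
            sl = (slice(None), slice(None),
                  slice(i, i + self.s * (do - 1) + 1, self.s),
                  slice(j, j + self.s * (ho - 1) + 1, self.s),
                  slice(k, k + self.s * (wo - 1) + 1, self.s))
            self.dW[:, :, i, j, k] = np.einsum("nfdhw,ncdhw->fc", g, xp[sl], optimize=True)
            dxp[sl] += np.einsum("nfdhw,fc->ncdhw", g, self.W[:, :, i, j, k], optimize=True)
        p = self.p
        D, H, W = self._xshape[2:]
        return dxp[:, :, p:p + D, p:p + H, p:p + W]

    def params(self):
        return [("W", self.W, "dW"), ("b", self.b, "db")]


class _BatchNorm3d:
    def __init__(self, c, eps=1e-5, momentum=0.9):
        self.gamma = np.ones(c)
        self.beta = np.zeros(c)
        self.run_mean = np.zeros(c)
        self.run_var = np.ones(c)
        self.eps, self.momentum = eps, momentum

    def forward(self, x, train):
        axes = (0, 2, 3, 4)
        if train:
            mu = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.run_mean = self.momentum * self.run_mean + (1 - self.momentum) * mu
            self.run_var = self.momentum * self.run_var + (1 - self.momentum) * var
        else:
            mu, var = self.run_mean, self.run_var
        ivstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu[None, :, None, None, None]) * ivstd[None, :, None, None, None]
        self._cache = (xhat, ivstd)
        return self.gamma[None, :, None, None, None] * xhat + self.beta[None, :, None, None, None]

    def backward(self, g):
        xhat, ivstd = self._cache
        axes = (0, 2, 3, 4)
        m = g.shape[0] * g.shape[2] * g.shape[3] * g.shape[4]
        self.dgamma = (g * xhat).sum(axis=axes)
        self.dbeta = g.sum(axis=axes)
        gxhat = g * self.gamma[None, :, None, None, None]
        dx = (ivstd[None, :, None, None, None] / m) * (
            m * gxhat
            - gxhat.sum(axis=axes, keepdims=True)
            - xhat * (gxhat * xhat).sum(axis=axes, keepdims=True)
        )
        return dx

    def params(self):
        return [("gamma", self.gamma, "dgamma"), ("beta", self.beta, "dbeta")]


class _ReLU:
    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, g):
        return g * self._mask

    def params(self):
        return []


class _MaxPool3d:
    """2x2x2 max pooling with stride 2; odd trailing voxels are cropped."""

    def forward(self, x, train):
        N, C, D, H, W = x.shape
        d, h, w = D // 2, H // 2, W // 2
        xc = x[:, :, :2 * d, :2 * h, :2 * w]
        r = xc.reshape(N, C, d, 2, h, 2, w, 2)
        out = r.max(axis=(3, 5, 7))
        mask = (r == out[:, :, :, None, :, None, :, None])
        # split gradient evenly across ties to keep backward exact
        self._mask = mask / mask.sum(axis=(3, 5, 7), keepdims=True)
        self._xshape = x.shape
        return out

    def backward(self, g):
        N, C, D, H, W = self._xshape
        d, h, w = D // 2, H // 2, W // 2
        gr = self._mask * g[:, :, :, None, :, None, :, None]
        dx = np.zeros(self._xshape)
        dx[:, :, :2 * d, :2 * h, :2 * w] = gr.reshape(N, C, 2 * d, 2 * h, 2 * w)
        return dx

    def params(self):
        return []


class _Flatten:
    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, g):
        return g.reshape(self._shape)

    def params(self):
        return []


class _Dense:
    def __init__(self, n_in, n_out, rng):
        self.W = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))
        self.b = np.zeros(n_out)

    def forward(self, x, train):
        self._x = x
        return x @ self.W + self.b

    def backward(self, g):
        self.dW = self._x.T @ g
        self.db = g.sum(axis=0)
        return g @ self.W.T

    def params(self):
        return [("W", self.W, "dW"), ("b", self.b, "db")]


def bce_with_logits(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Summed binary cross-entropy on logits; returns (loss, dloss/dlogits)."""
    z = logits.ravel()
    y = y.ravel().astype(float)
    loss = float(np.sum(np.logaddexp(0.0, z) - y * z))
    p = 1.0 / (1.0 + np.exp(-z))
    return loss, (p - y).reshape(logits.shape)


class _Adam:
    def __init__(self, beta1=0.9, beta2=0.999, eps=1e-8):
        self.b1, self.b2, self.eps = beta1, beta2, eps
        self.m: dict = {}
        self.v: dict = {}
        self.t = 0

    def step(self, layers, lr):
        self.t += 1
        for li, layer in enumerate(layers):
            for name, arr, gname in layer.params():
                key = (li, name)
                g = getattr(layer, gname)
                m = self.m.setdefault(key, np.zeros_like(arr))
                v = self.v.setdefault(key, np.zeros_like(arr))
                m[:] = self.b1 * m + (1 - self.b1) * g
                v[:] = self.b2 * v + (1 - self.b2) * g * g
                mhat = m / (1 - self.b1**self.t)
                vhat = v / (1 - self.b2**self.t)
                arr -= lr * mhat / (np.sqrt(vhat) + self.eps)


# ---------------------------------------------------------------------------
# network

class SPCNN:
    """Small-patch CNN: binary classifier over cubes of ``patch_size``^3 voxels."""

    def __init__(self, config: SPCNNConfig):
        self.config = config
        if self._simulate_sizes(config, config.patch_size) is None:
            smallest = next(s for s in range(3, 512)
                            if self._simulate_sizes(config, s) is not None)
            raise ValueError(f"patch_size {config.patch_size} too small for "
                             f"{config.n_blocks} down-sampling blocks; minimum is {smallest}")
        rng = np.random.default_rng(config.seed)
        F = config.initial_feature_maps
        pad = (config.conv_kernel - 1) // 2
        layers: list = []
        size = config.patch_size
        sizes = [size]
        c_in = 1
        for block in range(config.n_blocks):
            conv = _Conv3d(c_in, F, config.conv_kernel, config.conv_stride, pad, rng)
            size = conv.out_size(size)
            layers += [conv, _BatchNorm3d(F), _ReLU()]
            c_in = F
            if block == 0:
                layers.append(_MaxPool3d())
                size //= config.pool_kernel
            sizes.append(size)
        layers.append(_Flatten())
        layers.append(_Dense(F * size**3, config.dense_width, rng))
        layers.append(_ReLU())
        layers.append(_Dense(config.dense_width, 1, rng))
        self.layers = layers
        self.spatial_sizes = sizes

    @staticmethod
    def _simulate_sizes(config: SPCNNConfig, size: int):
        """Spatial size after all blocks, or None if the patch is too small."""
        pad = (config.conv_kernel - 1) // 2
        for block in range(config.n_blocks):
            size = (size + 2 * pad - config.conv_kernel) // config.conv_stride + 1
            if size < 1:
                return None
            if block == 0:
                if size < config.pool_kernel:
                    return None
                size //= config.pool_kernel
        return size

    # -- inference ----------------------------------------------------------
    def forward_logits(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if x.ndim == 4:
            x = x[:, None]
        out = np.asarray(x, dtype=np.float64)
        for layer in self.layers:
            out = layer.forward(out, train)
        return out

    def backward(self, g: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g

    def predict_proba(self, patches: np.ndarray, batch_size: int = 512) -> np.ndarray:
        """Sigmoid probabilities for patches (N, s, s, s); deterministic."""
        out = np.empty(len(patches))
        for i in range(0, len(patches), batch_size):
            z = self.forward_logits(patches[i:i + batch_size], train=False)
            out[i:i + batch_size] = 1.0 / (1.0 + np.exp(-z.ravel()))
        return out

    def n_parameters(self) -> int:
        return int(sum(arr.size for layer in self.layers for _, arr, _ in layer.params()))

    # -- persistence --------------------------------------------------------
    def save(self, path) -> None:
        blobs = {"config": np.frombuffer(json.dumps(asdict(self.config)).encode(), dtype=np.uint8)}
        for li, layer in enumerate(self.layers):
            for name, arr, _ in layer.params():
                blobs[f"{li}.{name}"] = arr
            if isinstance(layer, _BatchNorm3d):
                blobs[f"{li}.run_mean"] = layer.run_mean
                blobs[f"{li}.run_var"] = layer.run_var
        np.savez(path, **blobs)

    @classmethod
    def load(cls, path) -> "SPCNN":
        with np.load(path) as z:
            config = SPCNNConfig(**json.loads(bytes(z["config"]).decode()))
            model = cls(config)
            for li, layer in enumerate(model.layers):
                for name, arr, _ in layer.params():
                    arr[:] = z[f"{li}.{name}"]
                if isinstance(layer, _BatchNorm3d):
                    layer.run_mean[:] = z[f"{li}.run_mean"]
                    layer.run_var[:] = z[f"{li}.run_var"]
        return model


def build_spcnn(config: SPCNNConfig | None = None) -> SPCNN:
    """Construct the small-patch CNN classifier from its configuration."""
    return SPCNN(config or SPCNNConfig())


# ---------------------------------------------------------------------------
# training

def train_spcnn(model: SPCNN, data, config: SPCNNConfig | None = None):
    """Train with Adam on summed cross-entropy; plateau LR schedule; seeded.

    ``data`` is a :class:`~lsatrace.phantom.PatchDataset`.  The history
    records per-epoch train/test loss (mean per sample) and accuracy plus
    the learning rate in effect.  Training stops at
    ``early_stop_epoch`` (or ``max_epochs`` if smaller).
    """
    config = config or model.config
    Xtr = data.patches[data.train]
    ytr = data.labels[data.train].astype(float)
    Xte = data.patches[~data.train]
    yte = data.labels[~data.train].astype(float)
    if len(np.unique(ytr)) < 2:
        raise ValueError("training split must contain both classes")

    rng = np.random.default_rng(config.seed + 1)
    adam = _Adam()
    lr = config.initial_lr
    best_test = np.inf
    stall = 0
    history = {"train_loss": [], "test_loss": [], "train_acc": [], "test_acc": [], "lr": []}
    n_epochs = min(config.max_epochs, config.early_stop_epoch)

    for _epoch in range(n_epochs):
        order = rng.permutation(len(Xtr))
        total_loss = 0.0
        correct = 0
        for i in range(0, len(order), config.batch_size):
            sel = order[i:i + config.batch_size]
            z = model.forward_logits(Xtr[sel], train=True)
            loss, dz = bce_with_logits(z, ytr[sel])
            total_loss += loss
            correct += int(np.sum((z.ravel() > 0) == (ytr[sel] > 0.5)))
            model.backward(dz)
            adam.step(model.layers, lr)
        test_loss, test_acc = _evaluate(model, Xte, yte)
        history["train_loss"].append(total_loss / max(len(Xtr), 1))
        history["train_acc"].append(correct / max(len(Xtr), 1))
        history["test_loss"].append(test_loss)
        history["test_acc"].append(test_acc)
        history["lr"].append(lr)

        if test_loss < best_test - 1e-12:
            best_test = test_loss
            stall = 0
        else:
            stall += 1
            if stall >= config.lr_patience:
                lr = max(lr * config.lr_factor, config.min_lr)
                stall = 0
    return model, history


def _evaluate(model: SPCNN, X, y) -> tuple[float, float]:
    if len(X) == 0:
        return 0.0, 0.0
    total = 0.0
    correct = 0
    for i in range(0, len(X), 256):
        z = model.forward_logits(X[i:i + 256], train=False)
        loss, _ = bce_with_logits(z, y[i:i + 256])
        total += loss
        correct += int(np.sum((z.ravel() > 0) == (y[i:i + 256] > 0.5)))
    return total / len(X), correct / len(X)
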