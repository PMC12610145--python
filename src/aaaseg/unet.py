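"""U-Net segmentation: architecture, training protocol and dataset splitting.

The network is the standard symmetric encoder-decoder: each level applies
two 3x3 convolutions with batch normalization and ReLU; levels are joined
by 2x2 max pooling on the way down and 2x2 up-convolutions plus skip
concatenation on the way up, with a final 1x1 convolution and sigmoid so the
output is a per-pixel probability map in [0, 1]. Training minimizes mean
squared error between the probability map and the binary mask with Adam, no
data augmentation, and records per-epoch loss and PSNR (peak 1, so
PSNR = 10*log10(1/MSE) holds identically at every epoch).

Everything runs on the CPU in NumPy (forward and backward passes are
hand-vectorized), which keeps the package dependency-light and makes runs
bit-reproducible for a given seed. Three scale presets are provided: ``full``
(256-px input, channels 64..1024, 200 epochs — the full-fidelity protocol)
and ``desk`` (64-px input, channels 8..128, <= 50 epochs) which trains in
minutes on one core; a further ``micro`` preset (32-px, 3 levels) exists for
smoke-scale experiments.

Dataset splitting is patient-wise: all slices of a patient land in exactly
one of train/validation/test, preventing leakage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

DTYPE = np.float32


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class UNetConfig:
    """Architecture and training hyperparameters.

    ``encoder_channels`` must double strictly level to level and
    ``input_size`` must be divisible by 2**(levels - 1).
    """

    input_size: int = 256
    encoder_channels: tuple[int, ...] = (64, 128, 256, 512, 1024)
    learning_rate: float = 5e-4
    epochs: int = 200
    batch_size: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        ch = self.encoder_channels
        if len(ch) < 2:
            raise ValueError("need at least two channel widths")
        if any(b != 2 * a for a, b in zip(ch, ch[1:])):
            raise ValueError("encoder channels must double strictly")
        depth = len(ch) - 1
        if self.input_size % (2**depth) != 0:
            raise ValueError(
                f"input_size {self.input_size} not divisible by 2^{depth}"
            )
        if self.learning_rate <= 0 or self.epochs < 1 or self.batch_size < 1:
            raise ValueError("invalid training hyperparameters")


def full_config(**overrides) -> UNetConfig:
    """Full-scale protocol: 256-px input, channels 64..1024, 200 epochs."""
    return UNetConfig(**overrides)


def desk_config(**overrides) -> UNetConfig:
    """CPU-friendly preset: 64-px input, channels 8..128, 50 epochs."""
    defaults = dict(
        input_size=64, encoder_channels=(8, 16, 32, 64, 128), epochs=50
    )
    defaults.update(overrides)
    return UNetConfig(**defaults)


def micro_config(**overrides) -> UNetConfig:
    """Smoke-scale preset: 32-px input, three levels, 15 epochs."""
    defaults = dict(input_size=32, encoder_channels=(4, 8, 16), epochs=15)
    defaults.update(overrides)
    return UNetConfig(**defaults)


# ---------------------------------------------------------------------------
# layers (forward + hand-derived backward)
# ---------------------------------------------------------------------------


class _Conv2d:
    """Same-padding 2-D convolution (stride 1, odd kernel)."""

    def __init__(self, c_in: int, c_out: int, ksize: int, rng: np.random.Generator):
        fan_in = c_in * ksize * ksize
        self.w = (rng.standard_normal((c_out, c_in, ksize, ksize)) * math.sqrt(2.0 / fan_in)).astype(DTYPE)
        self.b = np.zeros(c_out, dtype=DTYPE)
        self.k = ksize

    def params(self):
        return [self.w, self.b]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        k, p = self.k, self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        if train:
            self._xp = xp
        n, _, hp, wp = xp.shape
        h, w = hp - 2 * p, wp - 2 * p
        out = np.zeros((n, self.w.shape[0], h, w), dtype=DTYPE)
        for a in range(k):
            for b in range(k):
                out += np.einsum(
                    "oc,nchw->nohw", self.w[:, :, a, b], xp[:, :, a : a + h, b : b + w],
                    optimize=True,
                )
        return out + self.b[None, :, None, None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        k, p = self.k, self.k // 2
        xp = self._xp
        n, c, hp, wp = xp.shape
        h, w = grad.shape[2], grad.shape[3]
        self.dw = np.zeros_like(self.w)
        dxp = np.zeros_like(xp)
        for a in range(k):
            for b in range(k):
                self.dw[:, :, a, b] = np.einsum(
                    "nohw,nchw->oc", grad, xp[:, :, a : a + h, b : b + w], optimize=True
                )
                dxp[:, :, a : a + h, b : b + w] += np.einsum(
                    "oc,nohw->nchw", self.w[:, :, a, b], grad, optimize=True
                )
        self.db = grad.sum(axis=(0, 2, 3))
        self._xp = None
        return dxp[:, :, p : hp - p, p : wp - p] if p else dxp

    def grads(self):
        return [self.dw, self.db]


class _BatchNorm2d:
    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(channels, dtype=DTYPE)
        self.beta = np.zeros(channels, dtype=DTYPE)
        self.run_mean = np.zeros(channels, dtype=DTYPE)
        self.run_var = np.ones(channels, dtype=DTYPE)
        self.momentum = momentum
        self.eps = eps

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.run_mean = (self.momentum * self.run_mean + (1 - self.momentum) * mean).astype(DTYPE)
            self.run_var = (self.momentum * self.run_var + (1 - self.momentum) * var).astype(DTYPE)
            inv = 1.0 / np.sqrt(var + self.eps)
            xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
            self._xhat, self._inv = xhat.astype(DTYPE), inv.astype(DTYPE)
        else:
            inv = 1.0 / np.sqrt(self.run_var + self.eps)
            xhat = (x - self.run_mean[None, :, None, None]) * inv[None, :, None, None]
        return (self.gamma[None, :, None, None] * xhat + self.beta[None, :, None, None]).astype(DTYPE)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, inv = self._xhat, self._inv
        m = grad.shape[0] * grad.shape[2] * grad.shape[3]
        self.dgamma = (grad * xhat).sum(axis=(0, 2, 3))
        self.dbeta = grad.sum(axis=(0, 2, 3))
        gxh = grad * self.gamma[None, :, None, None]
        dx = (
            gxh
            - gxh.mean(axis=(0, 2, 3), keepdims=True)
            - xhat * (gxh * xhat).mean(axis=(0, 2, 3), keepdims=True)
        ) * inv[None, :, None, None]
        self._xhat = self._inv = None
        return dx.astype(DTYPE)

    def grads(self):
        return [self.dgamma, self.dbeta]


class _ReLU:
    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._mask = x > 0
        return np.maximum(x, 0)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        out = grad * self._mask
        self._mask = None
        return out

    def grads(self):
        return []


class _MaxPool2:
    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        flat = xr.reshape(n, c, h // 2, w // 2, 4)
        idx = flat.argmax(axis=-1)
        out = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
        if train:
            self._idx, self._shape = idx, (n, c, h, w)
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        flat = np.zeros((n, c, h // 2, w // 2, 4), dtype=grad.dtype)
        np.put_along_axis(flat, self._idx[..., None], grad[..., None], axis=-1)
        out = (
            flat.reshape(n, c, h // 2, w // 2, 2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(n, c, h, w)
        )
        self._idx = None
        return out

    def grads(self):
        return []


class _UpConv2:
    """2x2 stride-2 transposed convolution (learned upsampling)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        fan_in = c_in * 4
        self.w = (rng.standard_normal((c_in, c_out, 2, 2)) * math.sqrt(2.0 / fan_in)).astype(DTYPE)
        self.b = np.zeros(c_out, dtype=DTYPE)

    def params(self):
        return [self.w, self.b]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._x = x
        n, c, h, w = x.shape
        tmp = np.einsum("nchw,coab->nohawb", x, self.w, optimize=True)
        out = tmp.reshape(n, self.w.shape[1], 2 * h, 2 * w)
        return out + self.b[None, :, None, None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x = self._x
        n, o, h2, w2 = grad.shape
        g6 = grad.reshape(n, o, h2 // 2, 2, w2 // 2, 2)  # nohawb
        self.dw = np.einsum("nohawb,nchw->coab", g6, x, optimize=True)
        self.db = grad.sum(axis=(0, 2, 3))
        dx = np.einsum("nohawb,coab->nchw", g6, self.w, optimize=True)
        self._x = None
        return dx.astype(DTYPE)

    def grads(self):
        return [self.dw, self.db]


class _Block:
    """conv-BN-ReLU twice."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        self.layers = [
            _Conv2d(c_in, c_out, 3, rng),
            _BatchNorm2d(c_out),
            _ReLU(),
            _Conv2d(c_out, c_out, 3, rng),
            _BatchNorm2d(c_out),
            _ReLU(),
        ]

    def forward(self, x, train):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def grads(self):
        return [g for l in self.layers for g in l.grads()]


class UNet:
    """The assembled network; build with :func:`build_unet`."""

    def __init__(self, config: UNetConfig):
        self.config = config
        rng = np.random.default_rng(int(config.seed) % (2**31))
        ch = config.encoder_channels
        depth = len(ch) - 1
        self.enc = []
        c_prev = 1
        for c in ch[:-1]:
            self.enc.append(_Block(c_prev, c, rng))
            c_prev = c
        self.pools = [_MaxPool2() for _ in range(depth)]
        self.bottleneck = _Block(ch[-2], ch[-1], rng)
        self.ups, self.dec = [], []
        c_prev = ch[-1]
        for c in reversed(ch[:-1]):
            self.ups.append(_UpConv2(c_prev, c, rng))
            self.dec.append(_Block(2 * c, c, rng))
            c_prev = c
        self.head = _Conv2d(ch[0], 1, 1, rng)

    # -- plumbing -----------------------------------------------------------
    def _modules(self):
        return [*self.enc, *self.pools, self.bottleneck, *self.ups, *self.dec, self.head]

    def params(self):
        return [p for m in self._modules() for p in m.params()]

    def grads(self):
        return [g for m in self._modules() for g in m.grads()]

    def n_parameters(self) -> int:
        return sum(p.size for p in self.params())

    # -- forward / backward -------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Map (n, H, W) images to (n, H, W) sigmoid probability maps."""
        x = np.asarray(x, dtype=DTYPE)
        if x.ndim == 2:
            x = x[None]
        size = self.config.input_size
        if x.shape[1] != size or x.shape[2] != size:
            raise ValueError(
                f"input is {x.shape[1]}x{x.shape[2]}, model expects {size}x{size}"
            )
        h = x[:, None]
        skips = []
        for block, pool in zip(self.enc, self.pools):
            h = block.forward(h, train)
            skips.append(h)
            h = pool.forward(h, train)
        h = self.bottleneck.forward(h, train)
        self._skip_channels = []
        for up, dec, skip in zip(self.ups, self.dec, reversed(skips)):
            h = up.forward(h, train)
            self._skip_channels.append(skip.shape[1])
            h = np.concatenate([skip, h], axis=1)
            h = dec.forward(h, train)
        z = self.head.forward(h, train)
        out = 1.0 / (1.0 + np.exp(-z.astype(np.float64)))
        if train:
            self._out = out
        return out[:, 0]

    def backward(self, grad_out: np.ndarray) -> None:
        """Backprop from d(loss)/d(probability map); call after a train forward."""
        out = self._out
        g = (grad_out[:, None] * out * (1.0 - out)).astype(DTYPE)
        g = self.head.backward(g)
        skip_grads = []
        for dec, up, c_skip in zip(
            reversed(self.dec), reversed(self.ups), reversed(self._skip_channels)
        ):
            g = dec.backward(g)
            skip_grads.append(g[:, :c_skip])
            g = up.backward(g[:, c_skip:])
        g = self.bottleneck.backward(g)
        # skip_grads were collected shallow-to-deep; the encoder unwinds deep-to-shallow
        for pool, block, gs in zip(
            reversed(self.pools), reversed(self.enc), reversed(skip_grads)
        ):
            g = pool.backward(g)
            g = g + gs
            g = block.backward(g)
        self._out = None


def build_unet(config: UNetConfig) -> UNet:
    """Construct a network with deterministic, seed-controlled initialization."""
    return UNet(config)


def _batchnorm_layers(model: UNet):
    for module in model._modules():
        for layer in getattr(module, "layers", []):
            if isinstance(layer, _BatchNorm2d):
                yield layer


def save_model(model: UNet, path) -> None:
    """Serialize parameters, batch-norm running statistics and the config."""
    import dataclasses
    import json

    arrays = {f"p{i}": p for i, p in enumerate(model.params())}
    for i, bn in enumerate(_batchnorm_layers(model)):
        arrays[f"bn{i}_mean"] = bn.run_mean
        arrays[f"bn{i}_var"] = bn.run_var
    arrays["config"] = np.frombuffer(
        json.dumps(dataclasses.asdict(model.config)).encode(), dtype=np.uint8
    )
    np.savez(path, **arrays)


def load_model(path) -> UNet:
    """Rebuild a network from :func:`save_model` output."""
    import json

    with np.load(path) as data:
        cfg = json.loads(bytes(data["config"]).decode())
        cfg["encoder_channels"] = tuple(cfg["encoder_channels"])
        config = UNetConfig(**cfg)
        model = UNet(config)
        for i, p in enumerate(model.params()):
            p[...] = data[f"p{i}"]
        for i, bn in enumerate(_batchnorm_layers(model)):
            bn.run_mean = data[f"bn{i}_mean"]
            bn.run_var = data[f"bn{i}_var"]
    return model


class _Adam:
    def __init__(self, params, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads):
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= (self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)).astype(p.dtype)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


def _mse(pred: np.ndarray, target: np.ndarray) -> float:
    return float(np.mean((pred - target) ** 2))


def _eval_loss(model: UNet, images: np.ndarray, masks: np.ndarray, batch: int) -> float:
    total, count = 0.0, 0
    for i in range(0, len(images), batch):
        pred = model.forward(images[i : i + batch], train=False)
        tgt = masks[i : i + batch]
        total += float(((pred - tgt) ** 2).sum())
        count += tgt.size
    return total / count


def train(
    model: UNet,
    train_set: tuple[np.ndarray, np.ndarray],
    val_set: tuple[np.ndarray, np.ndarray] | None,
    config: UNetConfig,
) -> tuple[UNet, pd.DataFrame]:
    """MSE/Adam training loop with per-epoch loss and PSNR monitoring.

    ``train_set`` / ``val_set`` are ``(images, masks)`` stacks of shape
    (n, H, W); masks are {0, 1}. No augmentation is applied. Returns the
    trained model and a history frame with one row per epoch.
    """
    x, y = np.asarray(train_set[0], dtype=DTYPE), np.asarray(train_set[1], dtype=DTYPE)
    if x.shape != y.shape:
        raise ValueError(f"image/mask shape mismatch: {x.shape} vs {y.shape}")
    if len(x) == 0:
        raise ValueError("empty training set")
    rng = np.random.default_rng((int(config.seed) + 1) % (2**31))
    opt = _Adam(model.params(), config.learning_rate)
    history = []
    for epoch in range(config.epochs):
        order = rng.permutation(len(x))
        for i in range(0, len(order), config.batch_size):
            sel = order[i : i + config.batch_size]
            pred = model.forward(x[sel], train=True)
            tgt = y[sel]
            grad = (2.0 / tgt.size) * (pred - tgt)
            model.backward(grad)
            opt.step(model.grads())
        train_loss = _eval_loss(model, x, y, config.batch_size)
        row = {
            "epoch": epoch,
            "train_loss": train_loss,
            "train_psnr": 10 * math.log10(1.0 / train_loss) if train_loss > 0 else math.inf,
        }
        if val_set is not None:
            val_loss = _eval_loss(
                model,
                np.asarray(val_set[0], dtype=DTYPE),
                np.asarray(val_set[1], dtype=DTYPE),
                config.batch_size,
            )
            row["val_loss"] = val_loss
            row["val_psnr"] = 10 * math.log10(1.0 / val_loss) if val_loss > 0 else math.inf
        history.append(row)
    return model, pd.DataFrame(history)


def predict(model: UNet, image: np.ndarray) -> np.ndarray:
    """Probability map(s) in [0, 1] for one image or an (n, H, W) stack."""
    arr = np.asarray(image, dtype=DTYPE)
    single = arr.ndim == 2
    out = model.forward(arr[None] if single else arr, train=False)
    return out[0] if single else out


def binarize(prob_map: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Threshold a probability map (>= threshold -> 1)."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    return (np.asarray(prob_map) >= threshold).astype(np.uint8)


# ---------------------------------------------------------------------------
# patient-wise splitting
# ---------------------------------------------------------------------------


def split_by_patient(
    cohort: Sequence, fractions: tuple[float, float, float], seed: int = 0
) -> tuple[list, list, list]:
    """Partition patients (never slices) into train/validation/test.

    ``cohort`` is a sequence of objects exposing ``patient_id`` and a spec
    with ``n_slices`` (e.g. :class:`aaaseg.phantom.PatientRecord`). Subset
    slice counts approximate ``fractions``; every subset receives at least
    one patient and no patient appears twice.
    """
    if len(fractions) != 3 or any(f <= 0 for f in fractions):
        raise ValueError("fractions must be three positive numbers")
    if abs(sum(fractions) - 1.0) > 1e-8:
        raise ValueError("fractions must sum to 1")
    if len(cohort) < 3:
        raise ValueError("need at least three patients (one per subset)")
    rng = np.random.default_rng(int(seed) % (2**31))
    order = rng.permutation(len(cohort))
    patients = [cohort[i] for i in order]

    def n_slices(rec) -> int:
        return getattr(getattr(rec, "spec", rec), "n_slices", 1)

    total = sum(n_slices(r) for r in patients)
    targets = [f * total for f in fractions]
    subsets: list[list] = [[], [], []]
    filled = [0.0, 0.0, 0.0]
    for rec in patients:
        # most-underfilled subset relative to its target
        deficits = [(filled[j] - targets[j]) / targets[j] for j in range(3)]
        j = int(np.argmin(deficits))
        subsets[j].append(rec)
        filled[j] += n_slices(rec)
    # guarantee non-empty subsets
    for j in range(3):
        if not subsets[j]:
            donor = max(range(3), key=lambda i: len(subsets[i]))
            subsets[j].append(subsets[donor].pop())
    ids = [set(r.patient_id for r in s) for s in subsets]
    assert not (ids[0] & ids[1] or ids[0] & ids[2] or ids[1] & ids[2])
    return subsets[0], subsets[1], subsets[2]


# ---------------------------------------------------------------------------
# sklearn-style wrapper
# ---------------------------------------------------------------------------


class UNetSegmenter(BaseEstimator):
    """fit/predict wrapper around the network and training loop.

    ``fit(X, y)`` trains on an (n, H, W) image stack against binary masks;
    ``predict(X)`` returns probability maps and ``predict_masks(X)``
    thresholded masks. Fitted attributes: ``model_``, ``history_``
    (per-epoch loss/PSNR frame) and ``config_``.
    """

    def __init__(
        self,
        input_size: int = 64,
        encoder_channels: tuple[int, ...] = (8, 16, 32, 64, 128),
        learning_rate: float = 5e-4,
        epochs: int = 50,
        batch_size: int = 3,
        seed: int = 0,
        threshold: float = 0.5,
    ):
        self.input_size = input_size
        self.encoder_channels = encoder_channels
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.batch_size = batch_size
        self.seed = seed
        self.threshold = threshold

    def _config(self) -> UNetConfig:
        return UNetConfig(
            input_size=self.input_size,
            encoder_channels=tuple(self.encoder_channels),
            learning_rate=self.learning_rate,
            epochs=self.epochs,
            batch_size=self.batch_size,
            seed=self.seed,
        )

    def fit(self, X, y, validation_data=None):
        cfg = self._config()
        model = build_unet(cfg)
        model, history = train(
            model, (np.asarray(X), np.asarray(y)), validation_data, cfg
        )
        self.config_ = cfg
        self.model_ = model
        self.history_ = history
        return self

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "model_"):
            raise RuntimeError("UNetSegmenter is not fitted")
        return predict(self.model_, np.asarray(X))

    def predict_masks(self, X) -> np.ndarray:
        return binarize(self.predict(X), self.threshold)
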