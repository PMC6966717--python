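"""A small convolutional network implemented on numpy.

Architecture (default): three conv blocks (32/64/128 filters, 5x5
kernels, stride 2, each followed by ReLU and 2x2 max pooling with
stride 2), four fully connected layers of width 500 with dropout 0.5,
a final two-way linear layer and softmax.  Spatial sizes follow
valid-padding floor arithmetic ``out = floor((in - k) / s) + 1``; with
the default 881 x 322 input the stage sizes are
(439,159) -> (219,79) -> (108,38) -> (54,19) -> (25,8) -> (12,4) and the
flattened width is 12*4*128 = 6144.

Training is plain SGD with momentum; the learning rate starts at 0.01
and is multiplied by 0.1 every 10 epochs.  Everything is seeded through
``numpy.random.Generator`` so a fixed seed reproduces training exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .exceptions import ShapeError

DTYPE = np.float64


@dataclass
class NetworkConfig:
    input_shape: tuple[int, int] = (881, 322)
    conv_filters: tuple[int, ...] = (32, 64, 128)
    kernel: tuple[int, int] = (5, 5)
    conv_stride: tuple[int, int] = (2, 2)
    pool_kernel: tuple[int, int] = (2, 2)
    pool_stride: tuple[int, int] = (2, 2)
    fc_widths: tuple[int, ...] = (500, 500, 500, 500)
    dropout_rate: float = 0.5
    n_classes: int = 2
    momentum: float = 0.9
    learning_rate: float = 0.01
    lr_drop_factor: float = 0.1
    lr_drop_every: int = 10
    max_epochs: int = 50
    batch_size: int = 128
    seed: int = 0

    def __post_init__(self) -> None:
        self.input_shape = tuple(self.input_shape)
        self.conv_filters = tuple(self.conv_filters)
        self.fc_widths = tuple(self.fc_widths)
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")
        if any(w <= 0 for w in self.fc_widths):
            raise ValueError("fully connected widths must be positive")
        layer_shapes(self)  # raises ShapeError on collapsing dimensions

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: tuple(v) if isinstance(v, list) else v
                      for k, v in d.items() if k in known})


def _out_dim(size: int, k: int, s: int) -> int:
    return (size - k) // s + 1


def layer_shapes(config: NetworkConfig) -> dict:
    """Closed-form spatial sizes per stage plus the flattened width.

    Returns {"stages": [(h, w) after each conv and each pool], "flat": n}.
    Raises :class:`ShapeError` naming the first layer whose output
    dimension is non-positive.
    """
    h, w = config.input_shape
    kh, kw = config.kernel
    sh, sw = config.conv_stride
    pk_h, pk_w = config.pool_kernel
    ps_h, ps_w = config.pool_stride
    stages: list[tuple[int, int]] = []
    for i, _f in enumerate(config.conv_filters, start=1):
        h, w = _out_dim(h, kh, sh), _out_dim(w, kw, sw)
        if h <= 0 or w <= 0:
            raise ShapeError(f"conv block {i}: output collapses to {h} x {w}")
        stages.append((h, w))
        h, w = _out_dim(h, pk_h, ps_h), _out_dim(w, pk_w, ps_w)
        if h <= 0 or w <= 0:
            raise ShapeError(f"pool after conv block {i}: output collapses to {h} x {w}")
        stages.append((h, w))
    flat = h * w * (config.conv_filters[-1] if config.conv_filters else 1)
    return {"stages": stages, "flat": flat}


def learning_rate_at(config: NetworkConfig, epoch: int) -> float:
    """Learning rate for a 1-based epoch index under the step schedule."""
    if epoch < 1:
        raise ValueError("epoch is 1-based")
    return config.learning_rate * config.lr_drop_factor ** ((epoch - 1) // config.lr_drop_every)


# -- primitive ops ------------------------------------------------------------

def _im2col(x, kh, kw, sh, sw, oh, ow):
    n, c, _h, _w = x.shape
    cols = np.empty((n, c, kh, kw, oh, ow), dtype=x.dtype)
    for i in range(kh):
        for j in range(kw):
            cols[:, :, i, j] = x[:, :, i:i + sh * oh:sh, j:j + sw * ow:sw]
    return cols.reshape(n, c * kh * kw, oh * ow)


def _col2im(dcols, x_shape, kh, kw, sh, sw, oh, ow):
    n, c, _h, _w = x_shape
    dcols = dcols.reshape(n, c, kh, kw, oh, ow)
    dx = np.zeros(x_shape, dtype=dcols.dtype)
    for i in range(kh):
        for j in range(kw):
            dx[:, :, i:i + sh * oh:sh, j:j + sw * ow:sw] += dcols[:, :, i, j]
    return dx


def _pool_forward(x, k, s):
    n, c, h, w = x.shape
    oh, ow = _out_dim(h, k, s), _out_dim(w, k, s)
    cols = np.empty((n, c, k * k, oh, ow), dtype=x.dtype)
    idx = 0
    for i in range(k):
        for j in range(k):
            cols[:, :, idx] = x[:, :, i:i + s * oh:s, j:j + s * ow:s]
            idx += 1
    arg = cols.argmax(axis=2)
    out = np.take_along_axis(cols, arg[:, :, None], axis=2)[:, :, 0]
    return out, (arg, x.shape, k, s, oh, ow)


def _pool_backward(dout, cache):
    arg, x_shape, k, s, oh, ow = cache
    n, c, _h, _w = x_shape
    dcols = np.zeros((n, c, k * k, oh, ow), dtype=dout.dtype)
    np.put_along_axis(dcols, arg[:, :, None], dout[:, :, None], axis=2)
    dx = np.zeros(x_shape, dtype=dout.dtype)
    idx = 0
    for i in range(k):
        for j in range(k):
            dx[:, :, i:i + s * oh:s, j:j + s * ow:s] += dcols[:, :, idx]
            idx += 1
    return dx


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(probs: np.ndarray, labels: np.ndarray) -> float:
    eps = 1e-12
    return float(-np.mean(np.log(probs[np.arange(len(labels)), labels] + eps)))


class Network:
    """Parameter store plus forward/backward passes for the architecture."""

    def __init__(self, config: NetworkConfig):
        self.config = config
        self.shapes = layer_shapes(config)
        rng = np.random.default_rng(config.seed)
        kh, kw = config.kernel
        self.params: dict[str, np.ndarray] = {}
        c_in = 1
        for i, f in enumerate(config.conv_filters):
            fan_in = c_in * kh * kw
            self.params[f"Wc{i}"] = rng.normal(
                0.0, np.sqrt(2.0 / fan_in), size=(f, c_in, kh, kw)
            ).astype(DTYPE)
            self.params[f"bc{i}"] = np.zeros(f, dtype=DTYPE)
            c_in = f
        widths = [self.shapes["flat"], *config.fc_widths, config.n_classes]
        for i in range(len(widths) - 1):
            self.params[f"Wf{i}"] = rng.normal(
                0.0, np.sqrt(2.0 / widths[i]), size=(widths[i + 1], widths[i])
            ).astype(DTYPE)
            self.params[f"bf{i}"] = np.zeros(widths[i + 1], dtype=DTYPE)
        self._velocity = {k: np.zeros_like(v) for k, v in self.params.items()}

    # -- forward / backward ---------------------------------------------------

    def forward(self, x: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None):
        """Logits for a batch of matrices shaped (N, H, W) or (N, 1, H, W)."""
        cfg = self.config
        if x.ndim == 3:
            x = x[:, None, :, :]
        if x.shape[2:] != cfg.input_shape:
            raise ShapeError(
                f"input spatial shape {x.shape[2:]} does not match "
                f"config.input_shape {cfg.input_shape}"
            )
        x = np.ascontiguousarray(x, dtype=DTYPE)
        kh, kw = cfg.kernel
        sh, sw = cfg.conv_stride
        cache: list = []
        for i in range(len(cfg.conv_filters)):
            w, b = self.params[f"Wc{i}"], self.params[f"bc{i}"]
            f = w.shape[0]
            oh = _out_dim(x.shape[2], kh, sh)
            ow = _out_dim(x.shape[3], kw, sw)
            cols = _im2col(x, kh, kw, sh, sw, oh, ow)
            wm = w.reshape(f, -1)
            out = np.matmul(wm[None], cols).reshape(x.shape[0], f, oh, ow)
            out += b[None, :, None, None]
            relu_mask = out > 0
            out *= relu_mask
            pooled, pcache = _pool_forward(out, cfg.pool_kernel[0], cfg.pool_stride[0])
            cache.append(("conv", x.shape, cols, relu_mask, pcache, i, (oh, ow)))
            x = pooled
        n = x.shape[0]
        flat_shape = x.shape
        h = x.reshape(n, -1)
        n_fc = len(cfg.fc_widths)
        for i in range(n_fc + 1):
            w, b = self.params[f"Wf{i}"], self.params[f"bf{i}"]
            z = h @ w.T + b
            if i < n_fc:
                relu_mask = z > 0
                z = z * relu_mask
                if train and cfg.dropout_rate > 0:
                    if rng is None:
                        raise ValueError("training forward pass needs an rng for dropout")
                    keep = (rng.random(z.shape) >= cfg.dropout_rate) / (1 - cfg.dropout_rate)
                    z = z * keep
                else:
                    keep = None
                cache.append(("fc", h, relu_mask, keep, i))
                h = z
            else:
                cache.append(("out", h, i))
                h = z
        cache.append(("flat", flat_shape))
        return h, cache

    def backward(self, cache: list, dlogits: np.ndarray) -> dict[str, np.ndarray]:
        cfg = self.config
        grads: dict[str, np.ndarray] = {}
        flat_shape = cache[-1][1]
        d = dlogits
        for entry in reversed(cache[:-1]):
            if entry[0] == "out":
                _, h, i = entry
                grads[f"Wf{i}"] = d.T @ h
                grads[f"bf{i}"] = d.sum(axis=0)
                d = d @ self.params[f"Wf{i}"]
            elif entry[0] == "fc":
                _, h, relu_mask, keep, i = entry
                if keep is not None:
                    d = d * keep
                d = d * relu_mask
                grads[f"Wf{i}"] = d.T @ h
                grads[f"bf{i}"] = d.sum(axis=0)
                d = d @ self.params[f"Wf{i}"]
            else:  # conv block
                _, x_shape, cols, relu_mask, pcache, i, (oh, ow) = entry
                if d.ndim == 2:
                    d = d.reshape(flat_shape)
                d = _pool_backward(d, pcache)
                d = d * relu_mask
                f = self.params[f"Wc{i}"].shape[0]
                dflat = d.reshape(d.shape[0], f, -1)
                grads[f"Wc{i}"] = np.einsum("nfl,nkl->fk", dflat, cols).reshape(
                    self.params[f"Wc{i}"].shape
                )
                grads[f"bc{i}"] = dflat.sum(axis=(0, 2))
                wm = self.params[f"Wc{i}"].reshape(f, -1)
                dcols = np.matmul(wm.T[None], dflat)
                kh, kw = cfg.kernel
                sh, sw = cfg.conv_stride
                d = _col2im(dcols, x_shape, kh, kw, sh, sw, oh, ow)
        return grads

    def loss_and_grads(self, x: np.ndarray, labels: np.ndarray,
                       rng: np.random.Generator):
        logits, cache = self.forward(x, train=True, rng=rng)
        probs = softmax(logits)
        loss = cross_entropy(probs, labels)
        dlogits = probs.copy()
        dlogits[np.arange(len(labels)), labels] -= 1.0
        dlogits /= len(labels)
        return loss, self.backward(cache, dlogits), probs

    def sgd_step(self, grads: dict[str, np.ndarray], lr: float) -> None:
        mu = self.config.momentum
        for k, g in grads.items():
            v = self._velocity[k]
            v *= mu
            v -= lr * g
            self.params[k] += v

    def predict_proba(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        """Class probabilities at inference (dropout disabled), order preserved."""
        out = []
        for start in range(0, len(x), batch_size):
            logits, _ = self.forward(x[start:start + batch_size], train=False)
            out.append(softmax(logits))
        return np.vstack(out) if out else np.empty((0, self.config.n_classes))
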