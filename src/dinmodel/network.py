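"""Convolutional digit-in-noise classifier, implemented directly in numpy.

Architecture (10 parameterized layers, 20 parameter tensors):

    C1 (5x5) -> LRN -> maxpool -> C2 (3x3) -> LRN -> maxpool
    -> C3 -> C4 -> C5 (all 3x3) -> maxpool -> F1 ... F5 -> 10 log-probabilities

Convolutional channel depths dilate and constrict by a factor of two
([C, 2C, 4C, 2C, C]); the five fully connected widths decrease geometrically
from the flattened convolutional output down to the 10 digit classes. Local
response normalization follows the first two convolutions; no other
regularization is applied beyond the z-scored input. Training uses Adam with
a cross-entropy objective (log-softmax + negative log-likelihood) and an L2
weight-decay term folded into the gradient.

Forward and backward passes are written out explicitly (im2col convolutions,
channel-window LRN, one-hot maxpool scatter); gradients are verified against
finite differences in the test suite. A ``trainable_mask`` restricts which of
the 20 parameter tensors a training step may touch — masked-out tensors are
bit-identical afterwards, which is the mechanism behind constrained
adaptation (final-layer-only learning).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "NetworkConfig",
    "NetworkState",
    "build_network",
    "forward",
    "train_step",
    "predict",
    "full_mask",
    "final_layer_mask",
    "PARAM_KEYS",
]

CONV_LAYERS = ("C1", "C2", "C3", "C4", "C5")
FC_LAYERS = ("F1", "F2", "F3", "F4", "F5")
LAYERS = CONV_LAYERS + FC_LAYERS
#: The 20 parameter tensors: weight and bias of each layer.
PARAM_KEYS = tuple((layer, p) for layer in LAYERS for p in ("weight", "bias"))


@dataclass(frozen=True)
class NetworkConfig:
    """Hyperparameters of the classifier."""

    input_shape: tuple  # (n_cf, n_frames)
    base_channels: int = 16
    conv_kernel_sizes: tuple = (5, 3, 3, 3, 3)
    n_classes: int = 10
    lrn_size: int = 5
    lrn_alpha: float = 1e-4
    lrn_beta: float = 0.75
    lrn_k: float = 2.0
    pool_size: int = 2
    batch_size: int = 256
    learning_rate: float = 1e-3
    weight_decay: float = 1e-3
    #: Fixed init scale for every tensor; None selects fan-in (He) scaling,
    #: std = sqrt(2 / fan_in), which keeps activations from vanishing through
    #: the ten-layer stack. Either way all parameters are normally distributed.
    init_std: float | None = None

    @property
    def conv_channels(self) -> tuple:
        c = self.base_channels
        return (c, 2 * c, 4 * c, 2 * c, c)


@dataclass
class NetworkState:
    """All mutable network state: parameters, optimizer moments, step count."""

    config: NetworkConfig
    params: dict            # layer -> {"weight": array, "bias": array}
    fc_widths: tuple
    conv_out_shape: tuple   # (channels, h, w) entering the flatten
    adam_m: dict = field(default_factory=dict)
    adam_v: dict = field(default_factory=dict)
    step: int = 0
    seed: int = 0

    def copy(self) -> "NetworkState":
        return NetworkState(
            config=self.config,
            params={l: {k: v.copy() for k, v in p.items()}
                    for l, p in self.params.items()},
            fc_widths=self.fc_widths,
            conv_out_shape=self.conv_out_shape,
            adam_m={l: {k: v.copy() for k, v in p.items()}
                    for l, p in self.adam_m.items()},
            adam_v={l: {k: v.copy() for k, v in p.items()}
                    for l, p in self.adam_v.items()},
            step=self.step,
            seed=self.seed,
        )


def full_mask() -> set:
    """Every parameter tensor trainable."""
    return set(PARAM_KEYS)


def final_layer_mask() -> set:
    """Only the final fully connected layer (F5) weight and bias trainable."""
    return {("F5", "weight"), ("F5", "bias")}


# ---------------------------------------------------------------------------
# Layer primitives (stride-1 'same' convolutions, odd kernels)
# ---------------------------------------------------------------------------

def _conv2d(x: np.ndarray, w: np.ndarray, b: np.ndarray | float) -> np.ndarray:
    """x: (N, Cin, H, W); w: (Cout, Cin, k, k) -> (N, Cout, H, W)."""
    k = w.shape[2]
    pad = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = sliding_window_view(xp, (k, k), axis=(2, 3))  # (N, Cin, H, W, k, k)
    n, cin, h, wd = x.shape
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * wd, cin * k * k)
    out = cols @ w.reshape(w.shape[0], -1).T
    out = out.reshape(n, h, wd, w.shape[0]).transpose(0, 3, 1, 2)
    return out + (b[None, :, None, None] if isinstance(b, np.ndarray) else b)


def _conv2d_backward(x: np.ndarray, w: np.ndarray, grad: np.ndarray):
    """Gradients of a stride-1 'same' convolution. Returns (dx, dw, db)."""
    k = w.shape[2]
    pad = k // 2
    n, cin, h, wd = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = sliding_window_view(xp, (k, k), axis=(2, 3))
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * wd, cin * k * k)
    g = grad.transpose(0, 2, 3, 1).reshape(n * h * wd, w.shape[0])
    dw = (g.T @ cols).reshape(w.shape)
    db = grad.sum(axis=(0, 2, 3))
    # input gradient = 'same' convolution of grad with channel-transposed,
    # spatially flipped weights
    w_flip = w[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)
    dx = _conv2d(grad, np.ascontiguousarray(w_flip), 0.0)
    return dx, dw, db


def _maxpool(x: np.ndarray, size: int):
    """Non-overlapping max pooling; trailing rows/cols beyond a multiple of
    ``size`` are dropped. Returns (out, argmax index array) for backward."""
    n, c, h, w = x.shape
    h2, w2 = h // size, w // size
    xc = x[:, :, : h2 * size, : w2 * size]
    win = xc.reshape(n, c, h2, size, w2, size).transpose(0, 1, 2, 4, 3, 5)
    flat = win.reshape(n, c, h2, w2, size * size)
    idx = flat.argmax(axis=4)
    out = np.take_along_axis(flat, idx[..., None], axis=4)[..., 0]
    return out, idx


def _maxpool_backward(grad: np.ndarray, idx: np.ndarray, x_shape: tuple,
                      size: int) -> np.ndarray:
    n, c, h, w = x_shape
    h2, w2 = h // size, w // size
    flat = np.zeros((n, c, h2, w2, size * size))
    np.put_along_axis(flat, idx[..., None], grad[..., None], axis=4)
    win = flat.reshape(n, c, h2, w2, size, size).transpose(0, 1, 2, 4, 3, 5)
    dx = np.zeros(x_shape)
    dx[:, :, : h2 * size, : w2 * size] = win.reshape(n, c, h2 * size, w2 * size)
    return dx


def _lrn_window_sum(x2: np.ndarray, size: int) -> np.ndarray:
    """Sliding sum of squared activations across the channel axis."""
    c = x2.shape[1]
    half = size // 2
    cs = np.concatenate([np.zeros_like(x2[:, :1]), np.cumsum(x2, axis=1)], axis=1)
    lo = np.maximum(np.arange(c) - half, 0)
    hi = np.minimum(np.arange(c) + half + 1, c)
    return cs[:, hi] - cs[:, lo]


def _lrn(x: np.ndarray, cfg: NetworkConfig):
    s = _lrn_window_sum(x * x, cfg.lrn_size)
    den = cfg.lrn_k + (cfg.lrn_alpha / cfg.lrn_size) * s
    out = x * den ** (-cfg.lrn_beta)
    return out, den


def _lrn_backward(x: np.ndarray, den: np.ndarray, grad: np.ndarray,
                  cfg: NetworkConfig) -> np.ndarray:
    # dx_m = g_m den_m^-b - (2ab/n) x_m sum_{c: m in win(c)} g_c x_c den_c^-(b+1)
    beta = cfg.lrn_beta
    inner = grad * x * den ** (-(beta + 1.0))
    backsum = _lrn_window_sum(inner, cfg.lrn_size)  # window symmetric: same sum
    return grad * den ** (-beta) \
        - (2.0 * cfg.lrn_alpha * beta / cfg.lrn_size) * x * backsum


def _log_softmax(z: np.ndarray) -> np.ndarray:
    zmax = z.max(axis=1, keepdims=True)
    return z - zmax - np.log(np.exp(z - zmax).sum(axis=1, keepdims=True))


# ---------------------------------------------------------------------------
# Network construction
# ---------------------------------------------------------------------------

def _plan_shapes(config: NetworkConfig) -> tuple[tuple, tuple, list[str]]:
    """Propagate spatial shapes through the stack; reject degenerate plans."""
    h, w = config.input_shape
    report = [f"input: 1 x {h} x {w}"]
    channels = config.conv_channels
    pool_after = {0, 1, 4}
    for i, layer in enumerate(CONV_LAYERS):
        report.append(f"{layer}: {channels[i]} x {h} x {w} "
                      f"(kernel {config.conv_kernel_sizes[i]})")
        if i in pool_after:
            h, w = h // config.pool_size, w // config.pool_size
            report.append(f"pool -> {channels[i]} x {h} x {w}")
            if h <= 0 or w <= 0:
                raise ValueError("pooling collapsed the feature map:\n"
                                 + "\n".join(report))
    flat = channels[-1] * h * w
    if flat < config.n_classes:
        raise ValueError("flattened dimension smaller than the class count:\n"
                         + "\n".join(report))
    widths = np.unique(np.round(np.geomspace(flat, config.n_classes, 6)
                                ).astype(int))[::-1]
    if len(widths) < 6:  # degenerate tiny nets: force strictly decreasing widths
        widths = np.linspace(flat, config.n_classes, 6).round().astype(int)
    fc_widths = tuple(int(v) for v in widths[1:])
    report.append(f"flatten: {flat} -> FC {fc_widths}")
    return (channels[-1], h, w), fc_widths, report


def build_network(config: NetworkConfig, seed: int) -> NetworkState:
    """Initialize all 20 parameter tensors ~ Normal(0, init_std), seeded."""
    conv_out, fc_widths, _ = _plan_shapes(config)
    rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, 0xD1])

    def _std(fan_in: int) -> float:
        if config.init_std is not None:
            return config.init_std
        return float(np.sqrt(2.0 / fan_in))

    params: dict = {}
    in_ch = 1
    for i, layer in enumerate(CONV_LAYERS):
        k = config.conv_kernel_sizes[i]
        out_ch = config.conv_channels[i]
        std = _std(in_ch * k * k)
        params[layer] = {
            "weight": rng.normal(0.0, std, (out_ch, in_ch, k, k)),
            "bias": rng.normal(0.0, std, out_ch),
        }
        in_ch = out_ch
    fan_in = conv_out[0] * conv_out[1] * conv_out[2]
    for layer, width in zip(FC_LAYERS, fc_widths):
        std = _std(fan_in)
        params[layer] = {
            "weight": rng.normal(0.0, std, (width, fan_in)),
            "bias": rng.normal(0.0, std, width),
        }
        fan_in = width
    zeros = {l: {k: np.zeros_like(v) for k, v in p.items()}
             for l, p in params.items()}
    return NetworkState(config=config, params=params, fc_widths=fc_widths,
                        conv_out_shape=conv_out,
                        adam_m=zeros,
                        adam_v={l: {k: np.zeros_like(v) for k, v in p.items()}
                                for l, p in params.items()},
                        step=0, seed=int(seed))


def _check_normalized(batch: np.ndarray) -> None:
    mean, sd = batch.mean(), batch.std()
    if abs(mean) > 0.25 or not (0.4 < sd < 2.5):
        warnings.warn("input batch does not look z-scored "
                      f"(mean {mean:.3f}, sd {sd:.3f}); the classifier is "
                      "trained on z-scored neurograms", stacklevel=3)


def _forward_pass(state: NetworkState, x: np.ndarray, keep_cache: bool):
    """Shared forward; returns (log_probs, cache or None)."""
    cfg = state.config
    cache: list = []
    a = x[:, None, :, :].astype(np.float64)  # (N, 1, H, W)
    pool_after = {0, 1, 4}
    for i, layer in enumerate(CONV_LAYERS):
        p = state.params[layer]
        pre = _conv2d(a, p["weight"], p["bias"])
        entry = {"layer": layer, "x": a, "pre": pre}
        a = np.maximum(pre, 0.0)
        if i in {0, 1}:
            entry["relu_out"] = a
            a, den = _lrn(a, cfg)
            entry["lrn_den"] = den
        if i in pool_after:
            entry["pool_in_shape"] = a.shape
            entry["pool_in"] = a
            a, idx = _maxpool(a, cfg.pool_size)
            entry["pool_idx"] = idx
        cache.append(entry)
    n = a.shape[0]
    a = a.reshape(n, -1)
    for j, layer in enumerate(FC_LAYERS):
        p = state.params[layer]
        pre = a @ p["weight"].T + p["bias"]
        cache.append({"layer": layer, "x": a, "pre": pre})
        a = np.maximum(pre, 0.0) if j < len(FC_LAYERS) - 1 else pre
    logp = _log_softmax(a)
    return logp, (cache if keep_cache else None)


def forward(state: NetworkState, batch: np.ndarray) -> np.ndarray:
    """Class log-probabilities for a batch of z-scored neurograms.

    ``batch``: (n, n_cf, n_frames). Rows of exp(output) sum to 1.
    """
    batch = np.asarray(batch, dtype=np.float64)
    if batch.ndim != 3 or batch.shape[1:] != tuple(state.config.input_shape):
        raise ValueError(f"batch shape {batch.shape} does not match input "
                         f"shape {state.config.input_shape}")
    _check_normalized(batch)
    logp, _ = _forward_pass(state, batch, keep_cache=False)
    return logp


def predict(state: NetworkState, batch: np.ndarray) -> np.ndarray:
    """Hard digit predictions (argmax of the log-probabilities)."""
    return np.argmax(forward(state, batch), axis=1)


def _backward_pass(state: NetworkState, cache: list, logp: np.ndarray,
                   labels: np.ndarray) -> dict:
    cfg = state.config
    n = logp.shape[0]
    probs = np.exp(logp)
    dlogits = probs.copy()
    dlogits[np.arange(n), labels] -= 1.0
    dlogits /= n

    grads: dict = {}
    g = dlogits
    for j in range(len(FC_LAYERS) - 1, -1, -1):
        entry = cache[len(CONV_LAYERS) + j]
        layer = entry["layer"]
        grads[layer] = {"weight": g.T @ entry["x"], "bias": g.sum(axis=0)}
        g = g @ state.params[layer]["weight"]
        if j > 0:
            g = g * (cache[len(CONV_LAYERS) + j - 1]["pre"] > 0)

    g = g.reshape((n, *state.conv_out_shape))
    for i in range(len(CONV_LAYERS) - 1, -1, -1):
        entry = cache[i]
        layer = entry["layer"]
        if "pool_idx" in entry:
            g = _maxpool_backward(g, entry["pool_idx"],
                                  entry["pool_in_shape"], cfg.pool_size)
        if "lrn_den" in entry:
            g = _lrn_backward(entry["relu_out"], entry["lrn_den"], g, cfg)
        g = g * (entry["pre"] > 0)
        g, dw, db = _conv2d_backward(entry["x"], state.params[layer]["weight"], g)
        grads[layer] = {"weight": dw, "bias": db}
    return grads


def train_step(state: NetworkState, batch: np.ndarray, labels: np.ndarray,
               trainable_mask: set | None = None) -> float:
    """One Adam step of cross-entropy training; returns the batch loss.

    Only tensors named in ``trainable_mask`` (default: all 20) are updated;
    every other tensor — parameters and optimizer moments — is left
    bit-identical. Weight decay is applied as an L2 gradient term, to the
    trainable tensors only.
    """
    batch = np.asarray(batch, dtype=np.float64)
    labels = np.asarray(labels)
    if batch.shape[0] == 0:
        raise ValueError("empty batch")
    if trainable_mask is None:
        trainable_mask = full_mask()
    _check_normalized(batch)

    logp, cache = _forward_pass(state, batch, keep_cache=True)
    loss = float(-logp[np.arange(len(labels)), labels].mean())
    grads = _backward_pass(state, cache, logp, labels)

    cfg = state.config
    state.step += 1
    t = state.step
    b1, b2, eps = 0.9, 0.999, 1e-8
    for layer, key in PARAM_KEYS:
        if (layer, key) not in trainable_mask:
            continue
        g = grads[layer][key] + cfg.weight_decay * state.params[layer][key]
        m = state.adam_m[layer][key]
        v = state.adam_v[layer][key]
        m[...] = b1 * m + (1 - b1) * g
        v[...] = b2 * v + (1 - b2) * g * g
        mhat = m / (1 - b1**t)
        vhat = v / (1 - b2**t)
        state.params[layer][key] -= cfg.learning_rate * mhat / (np.sqrt(vhat) + eps)
    return loss
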