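"""Three-block 1-D convolutional network for 128 x 1 x 3 windows.

Architecture (default spec): three blocks of valid stride-1 convolution
-> exclusive 2 x 1 max pooling -> ReLU, with filter banks
7 x 1 x 3 x 72, 6 x 1 x (.) x 144 and 5 x 1 x (.) x 108, followed by
flatten -> fully connected 256 -> dropout 0.5 -> fully connected 10 ->
softmax.  The spatial length chain is 128 -> 122 -> 61 -> 56 -> 28 ->
24 -> 12, giving a flattened length of 12 * 108 = 1296.

Two routes exist through every layer:

* the contract operations :func:`conv_layer`, :func:`max_pool`,
  :func:`relu`, :func:`softmax` act on single (H, W, D) tensors and follow
  the defining sums literally (they are cross-checked against brute-force
  nested-loop oracles in the test suite);
* the batched ``(N, L, C)`` fast path used by :func:`forward` and training
  (im2col + matrix multiply), which must agree with the contract route.

Convolution is valid (no padding), stride 1, cross-correlation indexing:

    y[i'', j'', d''] = b[d''] + sum_{i', j', d} f[i', j', d, d'']
                                * x[i'' + i' - 1, j'' + j' - 1, d]

Each block's filters span the full channel depth of the incoming tensor;
the unit third number in the published bank shapes is read as spatial
width.  Dropout is inverted (activations scaled by 1/keep at train time)
so inference needs no rescaling.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from triact.codes import ActivityCode, CANONICAL_CODES
from triact.signal_io import Window

#: Spatial lengths after each conv and pool of the default spec.
DEFAULT_SHAPE_CHAIN = (122, 61, 56, 28, 24, 12)


@dataclass(frozen=True)
class NetworkSpec:
    """Layer geometry of the network.

    ``conv_blocks`` lists ``(kernel_length, out_channels)`` per block; the
    filter depth of each block is the channel count of the incoming
    tensor (3 for block 1 under the default spec).
    """

    input_len: int = 128
    input_channels: int = 3
    conv_blocks: tuple[tuple[int, int], ...] = ((7, 72), (6, 144), (5, 108))
    pool_size: int = 2
    fc_width: int = 256
    dropout_rate: float = 0.5
    n_classes: int = 10

    def __post_init__(self) -> None:
        if self.input_len < 1 or self.input_channels < 1:
            raise ValueError("input dimensions must be positive")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")
        chain = self.shape_chain()
        if min(chain) < 1:
            raise ValueError(f"layer collapses to zero length: chain={chain}")
        default_geometry = (128, 3, ((7, 72), (6, 144), (5, 108)), 2)
        if (self.input_len, self.input_channels, self.conv_blocks,
                self.pool_size) == default_geometry:
            # published geometry: assert the documented shape chain
            assert chain == DEFAULT_SHAPE_CHAIN, chain

    def shape_chain(self) -> tuple[int, ...]:
        """Spatial length after each conv and each pool, in order."""
        chain = []
        length = self.input_len
        for kernel, _ in self.conv_blocks:
            length = length - kernel + 1  # valid convolution
            chain.append(length)
            length = length // self.pool_size  # exclusive pooling, floor
            chain.append(length)
        return tuple(chain)

    @property
    def flat_len(self) -> int:
        return self.shape_chain()[-1] * self.conv_blocks[-1][1]

    def channel_chain(self) -> tuple[int, ...]:
        return (self.input_channels,) + tuple(c for _, c in self.conv_blocks)


@dataclass
class NetworkParams:
    """Learned weights of the network, with the spec they instantiate.

    ``weights`` keys: ``conv{i}_w`` (K, C_in, C_out), ``conv{i}_b``
    (C_out,), ``fc_w`` (flat, fc_width), ``fc_b``, ``out_w``
    (fc_width, n_classes), ``out_b``.
    """

    spec: NetworkSpec
    weights: dict[str, np.ndarray]
    seed: int | None = None
    version: str = "1"

    def __post_init__(self) -> None:
        expected = _expected_shapes(self.spec)
        for name, shape in expected.items():
            if name not in self.weights:
                raise ValueError(f"missing parameter array {name!r}")
            got = self.weights[name].shape
            if got != shape:
                raise ValueError(
                    f"parameter {name!r} has shape {got}, expected {shape}"
                )

    def copy(self) -> "NetworkParams":
        return NetworkParams(
            spec=self.spec,
            weights={k: v.copy() for k, v in self.weights.items()},
            seed=self.seed,
            version=self.version,
        )


def _expected_shapes(spec: NetworkSpec) -> dict[str, tuple[int, ...]]:
    shapes: dict[str, tuple[int, ...]] = {}
    channels = spec.channel_chain()
    for i, (kernel, c_out) in enumerate(spec.conv_blocks, start=1):
        shapes[f"conv{i}_w"] = (kernel, channels[i - 1], c_out)
        shapes[f"conv{i}_b"] = (c_out,)
    shapes["fc_w"] = (spec.flat_len, spec.fc_width)
    shapes["fc_b"] = (spec.fc_width,)
    shapes["out_w"] = (spec.fc_width, spec.n_classes)
    shapes["out_b"] = (spec.n_classes,)
    return shapes


def init_params(spec: NetworkSpec, seed: int = 0) -> NetworkParams:
    """Variance-scaled (He) random initialization with a recorded seed."""
    rng = np.random.default_rng(seed)
    weights: dict[str, np.ndarray] = {}
    for name, shape in _expected_shapes(spec).items():
        if name.endswith("_b"):
            weights[name] = np.zeros(shape)
        else:
            fan_in = int(np.prod(shape[:-1]))
            weights[name] = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)
    return NetworkParams(spec=spec, weights=weights, seed=seed)


def save_params(params: NetworkParams, path: str | Path) -> None:
    """Serialize params to a versioned ``.npz`` container."""
    meta = {
        "version": params.version,
        "seed": params.seed,
        "spec": {
            "input_len": params.spec.input_len,
            "input_channels": params.spec.input_channels,
            "conv_blocks": [list(b) for b in params.spec.conv_blocks],
            "pool_size": params.spec.pool_size,
            "fc_width": params.spec.fc_width,
            "dropout_rate": params.spec.dropout_rate,
            "n_classes": params.spec.n_classes,
        },
    }
    np.savez(
        path, __meta__=np.array(json.dumps(meta)), **params.weights
    )


def load_params(path: str | Path) -> NetworkParams:
    """Load params written by :func:`save_params`; validates all shapes."""
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["__meta__"]))
        weights = {k: data[k] for k in data.files if k != "__meta__"}
    spec_d = meta["spec"]
    spec = NetworkSpec(
        input_len=spec_d["input_len"],
        input_channels=spec_d["input_channels"],
        conv_blocks=tuple(tuple(b) for b in spec_d["conv_blocks"]),
        pool_size=spec_d["pool_size"],
        fc_width=spec_d["fc_width"],
        dropout_rate=spec_d["dropout_rate"],
        n_classes=spec_d["n_classes"],
    )
    return NetworkParams(
        spec=spec, weights=weights, seed=meta["seed"], version=meta["version"]
    )


# ---------------------------------------------------------------------------
# Contract operations on single (H, W, D) tensors
# ---------------------------------------------------------------------------

def conv_layer(
    x: np.ndarray, filters: np.ndarray, biases: np.ndarray | None = None
) -> np.ndarray:
    """Valid, stride-1 correlation of one (H, W, D) tensor with a
    (H', W', D, D'') filter bank plus per-output-channel biases.

    Output shape is (H - H' + 1, W - W' + 1, D'').
    """
    x = np.asarray(x, dtype=float)
    filters = np.asarray(filters, dtype=float)
    if x.ndim != 3 or filters.ndim != 4:
        raise ValueError("conv_layer expects a 3-D input and a 4-D bank")
    h_f, w_f, depth, d_out = filters.shape
    if depth != x.shape[2]:
        raise ValueError(
            f"filter depth {depth} != input depth {x.shape[2]}"
        )
    if h_f > x.shape[0] or w_f > x.shape[1]:
        raise ValueError("filter spatial extent exceeds input extent")
    if biases is None:
        biases = np.zeros(d_out)
    biases = np.asarray(biases, dtype=float)
    if biases.shape != (d_out,):
        raise ValueError("bias vector must have one entry per output channel")
    patches = sliding_window_view(x, (h_f, w_f), axis=(0, 1))
    # patches: (H'', W'', D, H', W'); filters: (H', W', D, D'')
    return np.einsum("abdij,ijdk->abk", patches, filters) + biases


def max_pool(x: np.ndarray, pool_h: int = 2, pool_w: int = 1) -> np.ndarray:
    """Non-overlapping (exclusive) maxima over pool_h x pool_w areas per
    depth channel; trailing remainder rows/columns are dropped."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 3:
        raise ValueError("max_pool expects a 3-D tensor")
    if pool_h < 1 or pool_w < 1:
        raise ValueError("pool dimensions must be >= 1")
    h_out = x.shape[0] // pool_h
    w_out = x.shape[1] // pool_w
    cropped = x[: h_out * pool_h, : w_out * pool_w, :]
    return cropped.reshape(h_out, pool_h, w_out, pool_w, x.shape[2]).max(
        axis=(1, 3)
    )


def relu(x: np.ndarray) -> np.ndarray:
    """Elementwise max(0, x); shape preserved."""
    return np.maximum(0.0, np.asarray(x, dtype=float))


def softmax(scores: np.ndarray) -> np.ndarray:
    """Probability vector exp(x_k) / sum_t exp(x_t), computed with
    max-subtraction for numerical stability."""
    scores = np.asarray(scores, dtype=float)
    shifted = scores - scores.max(axis=-1, keepdims=True)
    exp = np.exp(shifted)
    return exp / exp.sum(axis=-1, keepdims=True)


# ---------------------------------------------------------------------------
# Batched fast path: tensors are (N, L, C)
# ---------------------------------------------------------------------------

def _conv1d(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Batched valid stride-1 correlation of (N, L, C_in) with
    (K, C_in, C_out), as a sum of K shifted matrix products."""
    kernel, c_in, c_out = w.shape
    l_out = x.shape[1] - kernel + 1
    y = np.zeros((x.shape[0], l_out, c_out))
    for k in range(kernel):
        y += x[:, k : k + l_out, :] @ w[k]
    return y + b


def _conv1d_backward(
    dy: np.ndarray, x: np.ndarray, w: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    kernel, c_in, c_out = w.shape
    l_out = dy.shape[1]
    dw = np.empty_like(w)
    dx = np.zeros_like(x)
    for k in range(kernel):
        x_slice = x[:, k : k + l_out, :]
        dw[k] = np.einsum("nlc,nlo->co", x_slice, dy, optimize=True)
        dx[:, k : k + l_out, :] += dy @ w[k].T
    db = dy.sum(axis=(0, 1))
    return dx, dw, db


def _maxpool1d(x: np.ndarray, pool: int) -> tuple[np.ndarray, np.ndarray, int]:
    n, length, c = x.shape
    l_out = length // pool
    xr = x[:, : l_out * pool, :].reshape(n, l_out, pool, c)
    idx = xr.argmax(axis=2)
    y = np.take_along_axis(xr, idx[:, :, None, :], axis=2)[:, :, 0, :]
    return y, idx, length


def _maxpool1d_backward(
    dy: np.ndarray, idx: np.ndarray, pool: int, input_len: int
) -> np.ndarray:
    n, l_out, c = dy.shape
    dxr = np.zeros((n, l_out, pool, c))
    np.put_along_axis(dxr, idx[:, :, None, :], dy[:, :, None, :], axis=2)
    dx = np.zeros((n, input_len, c))
    dx[:, : l_out * pool, :] = dxr.reshape(n, l_out * pool, c)
    return dx


def forward_batch(
    x: np.ndarray,
    params: NetworkParams,
    training_mode: bool = False,
    dropout_rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, dict]:
    """Run the full network on a batch (N, L, C) of windows.

    Returns class probabilities (N, n_classes) and a cache of
    intermediates for :func:`backward_batch`.  With ``training_mode`` an
    inverted-dropout mask is applied to the fully connected layer
    (``dropout_rng`` required when the rate is nonzero).
    """
    spec = params.spec
    if x.ndim != 3 or x.shape[1:] != (spec.input_len, spec.input_channels):
        raise ValueError(
            f"batch shape {x.shape} inconsistent with spec input "
            f"({spec.input_len}, {spec.input_channels})"
        )
    cache: dict = {"blocks": []}
    act = x
    for i in range(1, len(spec.conv_blocks) + 1):
        w = params.weights[f"conv{i}_w"]
        b = params.weights[f"conv{i}_b"]
        z = _conv1d(act, w, b)
        pooled, idx, z_len = _maxpool1d(z, spec.pool_size)
        out = np.maximum(0.0, pooled)
        cache["blocks"].append(
            {"x": act, "z_len": z_len, "idx": idx, "pooled": pooled}
        )
        act = out
    n = x.shape[0]
    flat = act.reshape(n, -1)
    hidden = flat @ params.weights["fc_w"] + params.weights["fc_b"]
    if training_mode and spec.dropout_rate > 0.0:
        if dropout_rng is None:
            raise ValueError("training_mode with dropout requires dropout_rng")
        keep = 1.0 - spec.dropout_rate
        mask = (dropout_rng.random(hidden.shape) < keep) / keep
        dropped = hidden * mask
    else:
        mask = None
        dropped = hidden
    scores = dropped @ params.weights["out_w"] + params.weights["out_b"]
    probs = softmax(scores)
    cache.update(
        flat=flat, hidden_shape=act.shape, mask=mask, dropped=dropped,
        probs=probs, n=n,
    )
    return probs, cache


def backward_batch(
    params: NetworkParams, cache: dict, y_idx: np.ndarray
) -> tuple[float, dict[str, np.ndarray]]:
    """Mean cross-entropy loss and its gradients w.r.t. every parameter.

    ``y_idx`` holds canonical class indices; gradients are averaged over
    the batch (no weight-decay term — the optimizer adds that).
    """
    spec = params.spec
    probs = cache["probs"]
    n = cache["n"]
    eps = 1e-12
    loss = float(-np.mean(np.log(probs[np.arange(n), y_idx] + eps)))
    dscores = probs.copy()
    dscores[np.arange(n), y_idx] -= 1.0
    dscores /= n
    grads: dict[str, np.ndarray] = {}
    grads["out_w"] = cache["dropped"].T @ dscores
    grads["out_b"] = dscores.sum(axis=0)
    ddropped = dscores @ params.weights["out_w"].T
    dhidden = ddropped * cache["mask"] if cache["mask"] is not None else ddropped
    grads["fc_w"] = cache["flat"].T @ dhidden
    grads["fc_b"] = dhidden.sum(axis=0)
    dflat = dhidden @ params.weights["fc_w"].T
    dact = dflat.reshape(cache["hidden_shape"])
    for i in range(len(spec.conv_blocks), 0, -1):
        blk = cache["blocks"][i - 1]
        dpooled = dact * (blk["pooled"] > 0.0)
        dz = _maxpool1d_backward(
            dpooled, blk["idx"], spec.pool_size, blk["z_len"]
        )
        dact, dw, db = _conv1d_backward(
            dz, blk["x"], params.weights[f"conv{i}_w"]
        )
        grads[f"conv{i}_w"] = dw
        grads[f"conv{i}_b"] = db
    return loss, grads


# ---------------------------------------------------------------------------
# Single-window interface
# ---------------------------------------------------------------------------

def forward(
    window: Window | np.ndarray,
    params: NetworkParams,
    training_mode: bool = False,
    dropout_rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Class-probability vector for one window (sums to 1)."""
    values = window.values if isinstance(window, Window) else np.asarray(window)
    probs, _ = forward_batch(
        values[None, :, :], params, training_mode=training_mode,
        dropout_rng=dropout_rng,
    )
    return probs[0]


def predict(window: Window | np.ndarray, params: NetworkParams) -> ActivityCode:
    """Argmax class; ties break toward the lowest canonical index."""
    probs = forward(window, params)
    return CANONICAL_CODES[int(np.argmax(probs))]


def predict_batch(x: np.ndarray, params: NetworkParams) -> np.ndarray:
    """Canonical class indices for a batch (N, L, C)."""
    probs, _ = forward_batch(x, params)
    return probs.argmax(axis=1)


def zero_one_loss(predicted: ActivityCode, truth: ActivityCode) -> int:
    """0 if the prediction equals the ground truth, else 1."""
    return 0 if predicted == truth else 1
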