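"""Convolutional multitask network mapping feature windows to per-site
log-TMRCA and recombination-breakpoint logits.

Architecture: input batch normalization -> ``n_blocks`` x (1-D convolution +
batch normalization + ReLU) -> final 1x1 convolution with two output
channels. Convolutions are stride-1, dilation-1 and *valid* (no padding), so
the window's flanking context is consumed exactly by the receptive field and
the output covers the ``L`` central sites. Because the coalescent with
recombination is well approximated by Markov processes along the genome, this
local connectivity is a natural model class for the task; kernel sizes are
chosen to give a large receptive field (to capture long shared haplotypes)
at a modest parameter count.

The implementation is pure NumPy with hand-written backward passes, which
keeps training, gradient-based interpretability (saliency), and checkpoints
free of any deep-learning runtime.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from .features import WindowSpec

__all__ = [
    "ModelConfig",
    "ConvNet",
    "build_model",
    "receptive_field",
    "desk_config",
    "full_config",
    "save_checkpoint",
    "load_checkpoint",
]


def receptive_field(kernels) -> int:
    """Receptive field in sites of a stride-1, dilation-1 stack (head is 1x1)."""
    return 1 + sum(int(k) - 1 for k in kernels)


@dataclass(frozen=True)
class ModelConfig:
    """Shape of the network; ``channels[i]``/``kernels[i]`` define block i."""

    window: WindowSpec
    in_channels: int = 6
    channels: tuple = (8, 16, 16)
    kernels: tuple = (11, 9, 9)

    def __post_init__(self):
        object.__setattr__(self, "channels", tuple(int(c) for c in self.channels))
        object.__setattr__(self, "kernels", tuple(int(k) for k in self.kernels))
        if len(self.channels) != len(self.kernels) or not self.channels:
            raise ValueError("channels and kernels must be equal-length, non-empty")
        if any(k < 1 for k in self.kernels) or any(c < 1 for c in self.channels):
            raise ValueError("kernel sizes and channel counts must be >= 1")
        rf = receptive_field(self.kernels)
        if rf > self.window.L1:
            raise ValueError(
                f"receptive field {rf} exceeds window length L1={self.window.L1}"
            )
        if rf - 1 != 2 * self.window.context:
            raise ValueError(
                f"context must equal (receptive_field - 1) / 2: got context="
                f"{self.window.context}, receptive field {rf}"
            )

    @property
    def receptive_field(self) -> int:
        return receptive_field(self.kernels)


def desk_config(L: int = 512, in_channels: int = 6) -> ModelConfig:
    """Small CPU-friendly preset (3 blocks, ~4K parameters, RF 27)."""
    kernels = (11, 9, 9)
    return ModelConfig(
        window=WindowSpec(L=L, context=(receptive_field(kernels) - 1) // 2),
        in_channels=in_channels,
        channels=(8, 16, 16),
        kernels=kernels,
    )


def full_config(L: int = 512, in_channels: int = 6) -> ModelConfig:
    """Full-scale preset: 5 blocks, first-block width 8, ~119K parameters,
    receptive field 71 sites."""
    kernels = (15, 15, 15, 15, 15)
    return ModelConfig(
        window=WindowSpec(L=L, context=(receptive_field(kernels) - 1) // 2),
        in_channels=in_channels,
        channels=(8, 16, 32, 64, 80),
        kernels=kernels,
    )


class Param:
    __slots__ = ("name", "value", "grad")

    def __init__(self, name: str, value: np.ndarray):
        self.name = name
        self.value = value
        self.grad = np.zeros_like(value)


class _BatchNorm1d:
    """Per-channel normalization over (batch, length) with affine transform."""

    def __init__(self, n_channels: int, name: str, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(f"{name}.gamma", np.ones(n_channels))
        self.beta = Param(f"{name}.beta", np.zeros(n_channels))
        self.running_mean = np.zeros(n_channels)
        self.running_var = np.ones(n_channels)
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            mu = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mu
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mu, var = self.running_mean, self.running_var
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu[None, :, None]) * invstd[None, :, None]
        self._cache = (xhat, invstd, training, x.shape[0] * x.shape[2])
        return self.gamma.value[None, :, None] * xhat + self.beta.value[None, :, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, invstd, training, m = self._cache
        self.gamma.grad += (dout * xhat).sum(axis=(0, 2))
        self.beta.grad += dout.sum(axis=(0, 2))
        dxhat = dout * self.gamma.value[None, :, None]
        if not training:
            return dxhat * invstd[None, :, None]
        s1 = dxhat.sum(axis=(0, 2), keepdims=True)
        s2 = (dxhat * xhat).sum(axis=(0, 2), keepdims=True)
        return (invstd[None, :, None] / m) * (m * dxhat - s1 - xhat * s2)


class _Conv1d:
    """Valid (unpadded) 1-D convolution, stride 1."""

    def __init__(self, c_in: int, c_out: int, k: int, name: str, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (c_in * k))
        self.W = Param(f"{name}.W", rng.normal(0.0, scale, size=(c_out, c_in, k)))
        self.b = Param(f"{name}.b", np.zeros(c_out))
        self.k = k
        self._cache = None

    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        xw = np.lib.stride_tricks.sliding_window_view(x, self.k, axis=2)
        self._cache = (xw, x.shape)
        out = np.einsum("nclk,ock->nol", xw, self.W.value, optimize=True)
        return out + self.b.value[None, :, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xw, x_shape = self._cache
        self.W.grad += np.einsum("nclk,nol->ock", xw, dout, optimize=True)
        self.b.grad += dout.sum(axis=(0, 2))
        k = self.k
        pad = np.pad(dout, ((0, 0), (0, 0), (k - 1, k - 1)))
        dw = np.lib.stride_tricks.sliding_window_view(pad, k, axis=2)
        return np.einsum("nolk,ock->ncl", dw, self.W.value[:, :, ::-1], optimize=True)


class _ReLU:
    def __init__(self):
        self._mask = None

    def params(self):
        return []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class ConvNet:
    """The multitask model. Output channel 0 is log-TMRCA (natural log,
    generations, floored at 1 before logging in the labels); channel 1 is the
    unscaled breakpoint probability (logit)."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        self.layers = [_BatchNorm1d(config.in_channels, "bn0")]
        c_prev = config.in_channels
        for i, (c, k) in enumerate(zip(config.channels, config.kernels)):
            self.layers.append(_Conv1d(c_prev, c, k, f"block{i}.conv", rng))
            self.layers.append(_BatchNorm1d(c, f"block{i}.bn"))
            self.layers.append(_ReLU())
            c_prev = c
        self.layers.append(_Conv1d(c_prev, 2, 1, "head", rng))
        self.last_normalized_input: np.ndarray | None = None
        self.last_normalized_grad: np.ndarray | None = None

    # -- parameter plumbing --------------------------------------------------

    def parameters(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params()]

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0.0

    @property
    def n_params(self) -> int:
        return int(sum(p.value.size for p in self.parameters()))

    def state_arrays(self) -> dict[str, np.ndarray]:
        state = {p.name: p.value for p in self.parameters()}
        for i, layer in enumerate(self.layers):
            if isinstance(layer, _BatchNorm1d):
                state[f"running_mean.{i}"] = layer.running_mean
                state[f"running_var.{i}"] = layer.running_var
        return state

    def load_state_arrays(self, state: dict[str, np.ndarray]) -> None:
        for p in self.parameters():
            p.value[...] = state[p.name]
        for i, layer in enumerate(self.layers):
            if isinstance(layer, _BatchNorm1d):
                layer.running_mean[...] = state[f"running_mean.{i}"]
                layer.running_var[...] = state[f"running_var.{i}"]

    def copy(self) -> "ConvNet":
        clone = ConvNet(self.config, seed=0)
        clone.load_state_arrays({k: v.copy() for k, v in self.state_arrays().items()})
        return clone

    # -- computation -----------------------------------------------------------

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """(N, C, L1) features -> (N, 2, L) outputs for the central sites."""
        x = np.asarray(x, dtype=np.float64)
        if x.ndim == 2:
            x = x[None]
        if np.isnan(x).any():
            raise ValueError("NaN in network input")
        if x.shape[1] != self.config.in_channels or x.shape[2] != self.config.window.L1:
            raise ValueError(
                f"expected input (N, {self.config.in_channels}, "
                f"{self.config.window.L1}), got {x.shape}"
            )
        out = self.layers[0].forward(x, training)
        self.last_normalized_input = out
        for layer in self.layers[1:]:
            out = layer.forward(out, training)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        """Backpropagate; accumulates parameter grads, returns grad w.r.t. the
        raw input. Also records the grad w.r.t. the normalized input (the
        output of the leading batch-norm layer)."""
        grad = dout
        for layer in reversed(self.layers[1:]):
            grad = layer.backward(grad)
        self.last_normalized_grad = grad
        return self.layers[0].backward(grad)

    def first_block_activations(self, x: np.ndarray) -> np.ndarray:
        """(N, channels[0], L2) output of the first conv block (eval mode)."""
        x = np.asarray(x, dtype=np.float64)
        if x.ndim == 2:
            x = x[None]
        out = x
        for layer in self.layers[:4]:  # bn0, conv0, bn, relu
            out = layer.forward(out, training=False)
        return out


def build_model(config: ModelConfig, seed: int = 0) -> ConvNet:
    """Instantiate the network; raises if the receptive field exceeds L1."""
    return ConvNet(config, seed=seed)


def _config_to_dict(config: ModelConfig) -> dict:
    d = asdict(config)
    d["window"] = {"L": config.window.L, "context": config.window.context}
    return d


def _config_from_dict(d: dict) -> ModelConfig:
    return ModelConfig(
        window=WindowSpec(**d["window"]),
        in_channels=d["in_channels"],
        channels=tuple(d["channels"]),
        kernels=tuple(d["kernels"]),
    )


def save_checkpoint(
    path,
    model: ConvNet,
    uncertainty: tuple[float, float] = (0.0, 0.0),
    provenance: dict | None = None,
) -> None:
    """Single-file checkpoint: weights + config + training provenance."""
    meta = {
        "config": _config_to_dict(model.config),
        "uncertainty": list(map(float, uncertainty)),
        "provenance": provenance or {},
    }
    np.savez(
        path,
        __meta__=np.frombuffer(json.dumps(meta, sort_keys=True).encode(), dtype=np.uint8),
        **model.state_arrays(),
    )


def load_checkpoint(path) -> tuple[ConvNet, dict]:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        state = {k: data[k] for k in data.files if k != "__meta__"}
    model = ConvNet(_config_from_dict(meta["config"]), seed=0)
    model.load_state_arrays(state)
    return model, meta
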