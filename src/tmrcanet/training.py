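"""Training: multitask loss, imbalance-aware pair sampling, epoch loop with
fresh simulations, recent-TMRCA-focused validation, and transfer learning.

Each training epoch draws a configurable number of independent coalescent
simulations (64 by default), takes a single haplotype pair from each, and
tiles that pair's sequence into fixed-length windows that form the epoch's
minibatches. Epochs alternate between uniform and relatedness-informed pair
sampling, which oversamples recent TMRCAs; the model with the minimum
validation score is kept.

The two tasks (log-TMRCA regression via Huber loss, breakpoint
classification via class-weighted binary cross-entropy) are balanced with
learned homoscedastic-uncertainty scalars:

    loss = exp(-s_reg) * Huber + exp(-s_cls) * weightedBCE + (s_reg + s_cls) / 2

The uncertainty scalars get their own, larger Adam step size: Adam's
scale-invariant updates would otherwise move two scalar parameters
imperceptibly over a short run.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .features import WindowSpec, full_feature_tracks, window_slice
from .network import ConvNet, ModelConfig, build_model
from .simulate import (
    EmptyRegionError,
    GeneticMap,
    SimulationConfig,
    TrueLabels,
    simulate_dataset,
)

__all__ = [
    "TaskUncertainty",
    "TrainConfig",
    "TrainState",
    "TrainResult",
    "Adam",
    "huber",
    "multitask_loss",
    "relatedness_pairing",
    "uniform_pairing",
    "make_epoch",
    "build_validation_set",
    "validation_score",
    "train",
    "finetune",
    "epochs_to_reach",
]


@dataclass
class TaskUncertainty:
    """Learned log-variance scalars for the two tasks."""

    s_reg: float = 0.0
    s_cls: float = 0.0

    def as_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        return np.array(self.s_reg, dtype=float), np.array(self.s_cls, dtype=float)


def huber(residual: np.ndarray, delta: float = 1.0) -> np.ndarray:
    """Elementwise Huber loss: quadratic within ``delta``, linear outside."""
    r = np.abs(residual)
    return np.where(r <= delta, 0.5 * r**2, delta * (r - 0.5 * delta))


def _huber_grad(residual: np.ndarray, delta: float = 1.0) -> np.ndarray:
    return np.clip(residual, -delta, delta)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _bce_with_logits(z: np.ndarray, y: np.ndarray) -> np.ndarray:
    # log(1 + e^z) - z*y, computed stably
    return np.maximum(z, 0.0) - z * y + np.log1p(np.exp(-np.abs(z)))


def class_weights_from_labels(b: np.ndarray) -> tuple[float, float]:
    """Inverse-frequency class weights (w0, w1): w_c = n / (2 * n_c)."""
    n = b.size
    n1 = int(b.sum())
    n0 = n - n1
    w0 = n / (2.0 * n0) if n0 > 0 else 0.0
    w1 = n / (2.0 * n1) if n1 > 0 else 0.0
    return w0, w1


def multitask_loss(
    output: np.ndarray,
    tmrca_true: np.ndarray,
    breakpoint_true: np.ndarray,
    uncertainty: TaskUncertainty,
    class_weights: Optional[tuple[float, float]] = None,
    delta: float = 1.0,
    return_grads: bool = False,
):
    """Homoscedastic-uncertainty-weighted Huber + class-weighted BCE.

    ``output`` is the network output (N, 2, L) (or (2, L)); channel 0 is
    predicted log-TMRCA, channel 1 the breakpoint logit. ``tmrca_true`` is in
    generations (> 0, floored at 1 before logging); ``breakpoint_true`` is
    binary. Both terms are averaged per site.

    With ``return_grads`` also returns ``(d_output, ds_reg, ds_cls)`` plus the
    two raw task means, enabling the caller to take an optimization step.
    """
    out = np.asarray(output, dtype=float)
    if out.ndim == 2:
        out = out[None]
    t = np.asarray(tmrca_true, dtype=float).reshape(out.shape[0], out.shape[2])
    b = np.asarray(breakpoint_true, dtype=float).reshape(out.shape[0], out.shape[2])
    if np.any(t <= 0):
        raise ValueError("TMRCA labels must be positive")
    log_t = np.log(np.maximum(t, 1.0))
    if class_weights is None:
        class_weights = class_weights_from_labels(b)
    w0, w1 = class_weights

    residual = out[:, 0, :] - log_t
    huber_mean = float(huber(residual, delta).mean())
    z = out[:, 1, :]
    w = np.where(b > 0.5, w1, w0)
    bce_mean = float((w * _bce_with_logits(z, b)).mean())

    s_reg, s_cls = float(uncertainty.s_reg), float(uncertainty.s_cls)
    loss = (
        np.exp(-s_reg) * huber_mean
        + np.exp(-s_cls) * bce_mean
        + 0.5 * s_reg
        + 0.5 * s_cls
    )
    if not return_grads:
        return float(loss)

    n = residual.size
    d_out = np.zeros_like(out)
    d_out[:, 0, :] = np.exp(-s_reg) * _huber_grad(residual, delta) / n
    d_out[:, 1, :] = np.exp(-s_cls) * w * (_sigmoid(z) - b) / n
    ds_reg = 0.5 - np.exp(-s_reg) * huber_mean
    ds_cls = 0.5 - np.exp(-s_cls) * bce_mean
    return float(loss), d_out, ds_reg, ds_cls, huber_mean, bce_mean


class Adam:
    """Adam over (array, grad-callback) pairs with per-group learning rates."""

    def __init__(self, groups, betas=(0.9, 0.999), eps=1e-8):
        # groups: list of (params, lr); params: list of objects with
        # .value / .grad ndarray attributes
        self.groups = [(list(params), float(lr)) for params, lr in groups]
        self.state = {}
        self.t = 0
        self.betas = betas
        self.eps = eps

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        for params, lr in self.groups:
            for p in params:
                key = id(p)
                if key not in self.state:
                    self.state[key] = (np.zeros_like(p.value), np.zeros_like(p.value))
                m, v = self.state[key]
                g = p.grad
                m[...] = b1 * m + (1 - b1) * g
                v[...] = b2 * v + (1 - b2) * g**2
                mhat = m / (1 - b1**self.t)
                vhat = v / (1 - b2**self.t)
                p.value -= lr * mhat / (np.sqrt(vhat) + self.eps)


class _ScalarParam:
    """Adapter making a python float trainable by :class:`Adam`."""

    def __init__(self, value: float = 0.0):
        self.value = np.array(float(value))
        self.grad = np.array(0.0)


# -- pair sampling ------------------------------------------------------------


def uniform_pairing(n_haplotypes: int, rng: np.random.Generator) -> list[tuple[int, int]]:
    """Uniformly random perfect matching of 0..n-1."""
    if n_haplotypes % 2:
        raise ValueError("need an even number of haplotypes")
    perm = rng.permutation(n_haplotypes)
    return [(int(perm[2 * i]), int(perm[2 * i + 1])) for i in range(n_haplotypes // 2)]


def relatedness_pairing(mean_tmrca: np.ndarray, seed: int) -> list[tuple[int, int]]:
    """Relatedness-informed perfect matching oversampling recent TMRCAs.

    The first pair is drawn uniformly. Each subsequent pair is formed by
    drawing an anchor uniformly from the already-paired haplotypes, taking
    the remaining haplotype with the smallest mean TMRCA to the anchor, and
    pairing it with the remaining haplotype closest to *it*. Ties break to
    the lowest index. Deterministic given the seed.
    """
    m = np.asarray(mean_tmrca, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("mean_tmrca must be a square matrix")
    n = m.shape[0]
    if n % 2:
        raise ValueError("need an even number of haplotypes")
    if n < 4:
        raise ValueError("need at least 4 haplotypes")
    rng = np.random.default_rng(seed)
    remaining = list(range(n))
    first = sorted(rng.choice(n, size=2, replace=False).tolist())
    pairs = [(int(first[0]), int(first[1]))]
    processed = [int(first[0]), int(first[1])]
    for h in processed:
        remaining.remove(h)
    while remaining:
        anchor = processed[int(rng.integers(len(processed)))]
        rem = np.array(remaining)
        h1 = int(rem[np.argmin(m[anchor, rem])])
        rem2 = rem[rem != h1]
        h2 = int(rem2[np.argmin(m[h1, rem2])])
        pairs.append((h1, h2))
        processed.extend([h1, h2])
        remaining.remove(h1)
        remaining.remove(h2)
    return pairs


# -- epoch construction --------------------------------------------------------


@dataclass(frozen=True)
class TrainConfig:
    """Single configuration driving :func:`train` / :func:`finetune`."""

    sim: SimulationConfig
    model: ModelConfig
    epochs: int = 15
    sims_per_epoch: int = 64
    batch_size: int = 64
    lr: float = 1e-3
    uncertainty_lr: float = 0.05
    val_sims: int = 4
    val_top_fraction: float = 0.05
    val_bins: int = 20
    huber_delta: float = 1.0
    raw_channels: bool = False
    shuffle_labels: Optional[str] = None  # diagnostic: 'tmrca' | 'breakpoint'
    seed: int = 0

    def __post_init__(self):
        if self.shuffle_labels not in (None, "tmrca", "breakpoint"):
            raise ValueError("shuffle_labels must be None, 'tmrca' or 'breakpoint'")
        expected = 6
        if self.model.in_channels != expected:
            raise ValueError("model.in_channels must match the 6 feature channels")


@dataclass
class TrainState:
    """Mutable state of a training run."""

    epoch: int = 0
    mode: str = "uniform"
    best_val: float = np.inf
    best_epoch: int = -1
    best_state: Optional[dict] = None
    best_uncertainty: tuple[float, float] = (0.0, 0.0)


@dataclass
class TrainResult:
    model: ConvNet
    uncertainty: TaskUncertainty
    history: pd.DataFrame
    best_val: float
    best_epoch: int
    config: TrainConfig


def _slice_map_region(gmap: GeneticMap, region_length: float, rng: np.random.Generator) -> GeneticMap:
    """Random sub-region of a non-constant map, rebased to position 0."""
    span = float(gmap.positions[-1] - gmap.positions[0])
    if span <= region_length:
        return gmap
    start = gmap.positions[0] + rng.uniform(0.0, span - region_length)
    end = start + region_length
    grid = np.concatenate(
        [[start], gmap.positions[(gmap.positions > start) & (gmap.positions < end)], [end]]
    )
    return GeneticMap(positions=grid - start, map_cM=gmap.cm_at(grid))


def pair_windows(
    panel,
    labels: TrueLabels,
    pair: tuple[int, int],
    window: WindowSpec,
    raw: bool = False,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Tile one pair's sequence into training windows.

    Returns ``(X, t, b)`` with shapes (n_windows, 6, L1), (n_windows, L),
    (n_windows, L). Windows are tiled at stride L from site 0; a trailing
    partial window is dropped (training only; inference stitches the tail).
    """
    tracks = full_feature_tracks(panel, pair, raw=raw)
    t_sites = labels.site_tmrca(pair)
    b_sites = labels.breakpoint_indicator(pair)
    n_sites = panel.n_sites
    offsets = [o for o in range(0, n_sites - window.L + 1, window.L)]
    if not offsets:
        return (
            np.zeros((0, tracks.shape[0], window.L1)),
            np.zeros((0, window.L)),
            np.zeros((0, window.L)),
        )
    X = np.stack([window_slice(tracks, window, o) for o in offsets])
    t = np.stack([t_sites[o : o + window.L] for o in offsets])
    b = np.stack([b_sites[o : o + window.L] for o in offsets])
    return X, t.astype(float), b.astype(float)


def make_epoch(
    config: TrainConfig,
    mode: str,
    sim_rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[int]]:
    """Fresh training data for one epoch: ``sims_per_epoch`` independent
    simulations, one pair each, tiled into windows.

    Returns (X, tmrca, breakpoints, simulation_seeds). With a non-constant
    genetic map each simulation samples a different sub-region of the map.
    """
    xs, ts, bs, seeds = [], [], [], []
    for _ in range(config.sims_per_epoch):
        sim_seed = int(sim_rng.integers(1, 2**31 - 1))
        seeds.append(sim_seed)
        sim = replace(config.sim, seed=sim_seed)
        if config.sim.genetic_map is not None:
            sim = replace(
                sim, genetic_map=_slice_map_region(config.sim.genetic_map, sim.region_length, sim_rng)
            )
        try:
            panel, labels = simulate_dataset(sim)
        except EmptyRegionError as e:
            raise EmptyRegionError(f"simulation with seed {sim_seed} failed: {e}") from e
        if mode == "relatedness":
            matching = relatedness_pairing(
                labels.mean_tmrca_matrix(), seed=int(sim_rng.integers(2**31 - 1))
            )
            pair = matching[int(sim_rng.integers(len(matching)))]
        else:
            pick = sim_rng.choice(panel.n_haplotypes, size=2, replace=False)
            pair = (int(pick[0]), int(pick[1]))
        X, t, b = pair_windows(panel, labels, pair, config.model.window, config.raw_channels)
        xs.append(X)
        ts.append(t)
        bs.append(b)
    return np.concatenate(xs), np.concatenate(ts), np.concatenate(bs), seeds


# -- validation ----------------------------------------------------------------


@dataclass
class ValidationSet:
    X: np.ndarray  # (n_windows, 6, L1)
    log_t: np.ndarray  # (n_windows, L)
    weights: np.ndarray  # per-site weights, same shape as log_t


def build_validation_set(config: TrainConfig, val_rng: np.random.Generator) -> ValidationSet:
    """Validation windows from held-out simulations, keeping only the
    top 5% closest pairs by mean *true* TMRCA (ascending), with inverse
    log-TMRCA-density site weights (clipped at 100x the median weight)."""
    candidates = []  # (mean_tmrca, panel, labels, pair)
    for _ in range(config.val_sims):
        sim = replace(config.sim, seed=int(val_rng.integers(1, 2**31 - 1)))
        panel, labels = simulate_dataset(sim)
        m = labels.mean_tmrca_matrix()
        n = panel.n_haplotypes
        for i in range(n):
            for j in range(i + 1, n):
                candidates.append((m[i, j], panel, labels, (i, j)))
    candidates.sort(key=lambda c: c[0])
    n_keep = int(np.floor(config.val_top_fraction * len(candidates)))
    if n_keep < 1:
        warnings.warn("fewer than 20 candidate pairs; using the single closest pair")
        n_keep = 1
    xs, ls = [], []
    for _, panel, labels, pair in candidates[:n_keep]:
        X, t, _ = pair_windows(panel, labels, pair, config.model.window, config.raw_channels)
        if X.shape[0] == 0:
            continue
        xs.append(X)
        ls.append(np.log(np.maximum(t, 1.0)))
    X = np.concatenate(xs)
    log_t = np.concatenate(ls)
    # inverse-density weights over equal-width bins of true log-TMRCA,
    # emphasizing under-represented recent and extremely old TMRCAs
    lo, hi = log_t.min(), log_t.max()
    if hi <= lo:
        weights = np.ones_like(log_t)
    else:
        edges = np.linspace(lo, hi, config.val_bins + 1)
        idx = np.clip(np.digitize(log_t, edges[1:-1]), 0, config.val_bins - 1)
        counts = np.bincount(idx.ravel(), minlength=config.val_bins).astype(float)
        w_bin = np.where(counts > 0, 1.0 / np.maximum(counts, 1.0), 0.0)
        occupied = w_bin[counts > 0]
        w_bin = np.minimum(w_bin, 100.0 * np.median(occupied))
        weights = w_bin[idx]
        weights /= weights.mean()
    return ValidationSet(X=X, log_t=log_t, weights=weights)


def validation_score(
    model: ConvNet, valset: ValidationSet, delta: float = 1.0, batch_size: int = 64
) -> float:
    """Weighted Huber loss on log-TMRCA over the validation windows."""
    total, norm = 0.0, 0.0
    for i in range(0, valset.X.shape[0], batch_size):
        out = model.forward(valset.X[i : i + batch_size], training=False)
        r = out[:, 0, :] - valset.log_t[i : i + batch_size]
        w = valset.weights[i : i + batch_size]
        total += float((w * huber(r, delta)).sum())
        norm += float(w.size)
    return total / max(norm, 1.0)


# -- training loop -------------------------------------------------------------


def _stream_rngs(seed: int) -> dict[str, np.random.Generator]:
    base = np.random.SeedSequence(seed)
    names = ("init", "train_sims", "validation", "batching", "diagnostic")
    children = base.spawn(len(names))
    return {name: np.random.default_rng(ss) for name, ss in zip(names, children)}


def train(
    config: TrainConfig,
    init_model: Optional[ConvNet] = None,
    init_uncertainty: Optional[TaskUncertainty] = None,
) -> TrainResult:
    """Run the full training loop; returns the best-validation checkpoint.

    All randomness derives from ``config.seed`` through named streams, so a
    repeated run is bit-identical. Training simulation seeds are drawn from a
    single stream across epochs (no reuse), and validation simulations use a
    disjoint stream.
    """
    rngs = _stream_rngs(config.seed)
    if init_model is None:
        model = build_model(config.model, seed=int(rngs["init"].integers(2**31 - 1)))
    else:
        if init_model.config != config.model:
            raise ValueError("checkpoint/window mismatch between donor model and config")
        model = init_model.copy()
    unc = init_uncertainty or TaskUncertainty()
    s_reg = _ScalarParam(unc.s_reg)
    s_cls = _ScalarParam(unc.s_cls)
    opt = Adam(
        groups=[
            (model.parameters(), config.lr),
            ([s_reg, s_cls], config.uncertainty_lr),
        ]
    )

    valset = build_validation_set(config, rngs["validation"])
    state = TrainState()
    rows = []
    warm_start = init_model is None
    for epoch in range(config.epochs):
        state.epoch = epoch
        state.mode = "uniform" if epoch % 2 == 0 else "relatedness"
        X, t, b = _epoch_data(config, state.mode, rngs)
        if warm_start:
            # output-bias initialization from the first epoch's labels: the
            # Huber gradient is clipped, so Adam alone would need thousands
            # of steps to move the regression output to the log-TMRCA scale
            head = model.layers[-1]
            head.b.value[0] = float(np.log(np.maximum(t, 1.0)).mean())
            rate = float(np.clip(b.mean(), 1e-4, 1 - 1e-4))
            head.b.value[1] = float(np.log(rate / (1 - rate)))
            warm_start = False
        order = rngs["batching"].permutation(X.shape[0])
        X, t, b = X[order], t[order], b[order]
        epoch_loss, n_batches = 0.0, 0
        for i in range(0, X.shape[0], config.batch_size):
            xb, tb, bb = X[i : i + config.batch_size], t[i : i + config.batch_size], b[i : i + config.batch_size]
            out = model.forward(xb, training=True)
            unc_now = TaskUncertainty(float(s_reg.value), float(s_cls.value))
            loss, d_out, dsr, dsc, *_ = multitask_loss(
                out, tb, bb, unc_now, delta=config.huber_delta, return_grads=True
            )
            model.zero_grad()
            model.backward(d_out)
            s_reg.grad = np.array(dsr)
            s_cls.grad = np.array(dsc)
            opt.step()
            epoch_loss += loss
            n_batches += 1
        score = validation_score(model, valset, delta=config.huber_delta)
        rows.append(
            {
                "epoch": epoch,
                "mode": state.mode,
                "train_loss": epoch_loss / max(n_batches, 1),
                "val_score": score,
                "s_reg": float(s_reg.value),
                "s_cls": float(s_cls.value),
            }
        )
        if score < state.best_val:
            state.best_val = score
            state.best_epoch = epoch
            state.best_state = {k: v.copy() for k, v in model.state_arrays().items()}
            state.best_uncertainty = (float(s_reg.value), float(s_cls.value))
    if state.best_state is not None:
        model.load_state_arrays(state.best_state)
    return TrainResult(
        model=model,
        uncertainty=TaskUncertainty(*state.best_uncertainty),
        history=pd.DataFrame(rows),
        best_val=state.best_val,
        best_epoch=state.best_epoch,
        config=config,
    )


def _epoch_data(config: TrainConfig, mode: str, rngs) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    X, t, b, _ = make_epoch(config, mode, rngs["train_sims"])
    if config.shuffle_labels == "tmrca":
        for i in range(t.shape[0]):
            rngs["diagnostic"].shuffle(t[i])
    elif config.shuffle_labels == "breakpoint":
        for i in range(b.shape[0]):
            rngs["diagnostic"].shuffle(b[i])
    return X, t, b


def finetune(
    donor: TrainResult | tuple[ConvNet, TaskUncertainty],
    config: TrainConfig,
) -> TrainResult:
    """Transfer learning: initialize every layer from a donor checkpoint and
    update all layers under the new configuration."""
    if isinstance(donor, TrainResult):
        model, unc = donor.model, donor.uncertainty
    else:
        model, unc = donor
    return train(config, init_model=model, init_uncertainty=unc)


def epochs_to_reach(history: pd.DataFrame, score: float) -> int:
    """1-based epoch count until val_score <= score; inf-like large if never."""
    hit = history.index[history["val_score"] <= score]
    return int(hit[0]) + 1 if len(hit) else len(history) + 1
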