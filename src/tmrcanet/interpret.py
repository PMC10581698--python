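"""Interpretability analyses of a trained model.

Three probes into what the network has learned:

* input x gradient saliency maps for a single target site, computed against
  the *normalized* input (the output of the leading batch-norm layer) so all
  six channels are on a comparable scale;
* MAF perturbation analyses, shifting the MAF channel at homozygous (AND=1)
  or heterozygous (XOR=1) sites and measuring the mean change in predicted
  TMRCA;
* correlation of first-block channel activations with the XOR/AND logic
  functions, for a model trained on raw haplotype channels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .network import ConvNet

__all__ = [
    "SaliencyMap",
    "saliency_map",
    "saliency_group_mean",
    "perturb_maf",
    "perturbed_maf_channel",
    "channel_logic_correlation",
]

#: Channel indices in the engineered feature layout.
XOR, AND, MAF = 0, 1, 2


@dataclass
class SaliencyMap:
    """Non-negative 6 x L1 attribution grid for one target site."""

    grid: np.ndarray
    target_site: int

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        if np.any(self.grid < 0) or not np.all(np.isfinite(self.grid)):
            raise ValueError("saliency grid must be finite and non-negative")


def saliency_map(
    model: ConvNet,
    features: np.ndarray,
    target_site: int,
    rescale: float = 1e6,
) -> SaliencyMap:
    """Input x gradient attribution of one site's TMRCA prediction.

    Forward pass; the predicted TMRCA at ``target_site`` (a central-window
    index in [0, L)) is rescaled by ``rescale`` to avoid vanishing gradients;
    the absolute gradient with respect to the normalized input is multiplied
    elementwise by the absolute normalized input.
    """
    window = model.config.window
    if not 0 <= target_site < window.L:
        raise ValueError(f"target_site must lie in the central window [0, {window.L})")
    x = np.asarray(features, dtype=float)
    if x.ndim == 2:
        x = x[None]
    out = model.forward(x, training=False)
    dout = np.zeros_like(out)
    # d(rescale * exp(y)) / dy = rescale * exp(y)
    dout[0, 0, target_site] = rescale * np.exp(np.clip(out[0, 0, target_site], -30.0, 30.0))
    model.zero_grad()
    model.backward(dout)
    grad = model.last_normalized_grad[0]
    normalized = model.last_normalized_input[0]
    return SaliencyMap(grid=np.abs(grad) * np.abs(normalized), target_site=target_site)


def saliency_group_mean(smap: SaliencyMap, site_mask: np.ndarray) -> np.ndarray:
    """Per-channel mean attribution over a boolean site selection (e.g.
    high-MAF heterozygous sites, or recent- vs deep-TMRCA strata)."""
    mask = np.asarray(site_mask, dtype=bool)
    if mask.shape != (smap.grid.shape[1],):
        raise ValueError("mask length must equal L1")
    if not mask.any():
        return np.full(smap.grid.shape[0], np.nan)
    return smap.grid[:, mask].mean(axis=1)


def perturbed_maf_channel(
    windows: np.ndarray, mode: str, n_haplotypes: int, magnitude: float = 0.05
) -> np.ndarray:
    """Apply the MAF perturbation rule; returns the perturbed windows.

    Lowering at AND=1 sites: MAF below 0.05 snaps to the singleton frequency
    1/n_haplotypes, otherwise ``maf - magnitude``. Raising at XOR=1 sites:
    MAF above 0.45 snaps to 0.5, otherwise ``maf + magnitude``. A zero
    magnitude returns the input unchanged.
    """
    if mode not in ("lower_and_sites", "raise_xor_sites"):
        raise ValueError("mode must be 'lower_and_sites' or 'raise_xor_sites'")
    X = np.asarray(windows, dtype=float)
    if X.ndim == 2:
        X = X[None]
    Xp = X.copy()
    if magnitude == 0.0:
        return Xp
    maf = X[:, MAF, :]
    if mode == "lower_and_sites":
        sel = X[:, AND, :] == 1
        new = np.where(maf < 0.05, 1.0 / n_haplotypes, maf - magnitude)
    else:
        sel = X[:, XOR, :] == 1
        new = np.where(maf > 0.45, 0.5, maf + magnitude)
    Xp[:, MAF, :] = np.where(sel, new, maf)
    return Xp


def perturb_maf(
    model: ConvNet,
    windows: np.ndarray,
    mode: str,
    n_haplotypes: int,
    magnitude: float = 0.05,
    batch_size: int = 64,
) -> float:
    """Mean change in predicted TMRCA under a MAF perturbation.

    ``mode='lower_and_sites'`` subtracts ``magnitude`` from the MAF at all
    homozygous-derived (AND=1) sites; ``mode='raise_xor_sites'`` adds it at
    all heterozygous (XOR=1) sites. MAF values below 0.05 (when lowering) are
    set to the singleton frequency 1/n_haplotypes, and values above 0.45
    (when raising) are set to 0.5. Returns the mean over windows and central
    sites of (perturbed - baseline) predicted TMRCA in generations.
    """
    X = np.asarray(windows, dtype=float)
    if X.ndim == 2:
        X = X[None]
    Xp = perturbed_maf_channel(X, mode, n_haplotypes, magnitude)
    deltas = []
    for i in range(0, X.shape[0], batch_size):
        base = model.forward(X[i : i + batch_size], training=False)
        pert = model.forward(Xp[i : i + batch_size], training=False)
        clip = lambda y: np.exp(np.clip(y, -30.0, 30.0))
        deltas.append(clip(pert[:, 0, :]) - clip(base[:, 0, :]))
    return float(np.concatenate(deltas).mean())


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a**2).sum() * (b**2).sum())
    if denom == 0:
        return np.nan
    return float((a * b).sum() / denom)


def channel_logic_correlation(
    model: ConvNet,
    dataset: Sequence[tuple[np.ndarray, np.ndarray, np.ndarray]],
) -> pd.DataFrame:
    """Correlate first-block channel activations with XOR/AND functions.

    ``dataset`` yields ``(raw_window, xor_track, and_track)`` per pair, where
    ``raw_window`` is an (in_channels, L1) feature window from the raw
    haplotype layout and the logic tracks have length L1. Activations have
    length L2 = L1 - (k0 - 1); only the L2 central sites of each logic track
    are used. Correlations are averaged over pairs; a constant channel
    yields NaN (undefined), not 0.

    Returns a DataFrame with per-channel ``r_xor``/``r_and`` plus the
    max-|r| gate assignment.
    """
    k0 = model.config.kernels[0]
    trim = (k0 - 1) // 2
    rs_xor, rs_and = [], []
    for raw_window, xor_track, and_track in dataset:
        acts = model.first_block_activations(raw_window)[0]  # (C1, L2)
        L2 = acts.shape[1]
        lo = (xor_track.size - L2) // 2
        x_c = np.asarray(xor_track, dtype=float)[lo : lo + L2]
        a_c = np.asarray(and_track, dtype=float)[lo : lo + L2]
        rs_xor.append([_pearson(acts[c], x_c) for c in range(acts.shape[0])])
        rs_and.append([_pearson(acts[c], a_c) for c in range(acts.shape[0])])
    import warnings

    with warnings.catch_warnings():
        # all-NaN channels (e.g. a constant logic track) stay NaN by design
        warnings.simplefilter("ignore", category=RuntimeWarning)
        r_xor = np.nanmean(np.asarray(rs_xor, dtype=float), axis=0)
        r_and = np.nanmean(np.asarray(rs_and, dtype=float), axis=0)
    df = pd.DataFrame(
        {
            "channel": np.arange(r_xor.size),
            "r_xor": r_xor,
            "r_and": r_and,
        }
    )
    df["assigned_gate"] = np.where(
        np.abs(df["r_xor"].fillna(0)) >= np.abs(df["r_and"].fillna(0)), "xor", "and"
    )
    return df
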