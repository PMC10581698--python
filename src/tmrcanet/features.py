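"""Per-pair, per-site input features for the convolutional model.

Six channels per site for a haplotype pair (h1, h2):

0. ``xor``      — alleles differ (heterozygous pair state)
1. ``and``      — both carry the derived allele
2. ``maf``      — minor allele frequency over the full panel
3. ``dist_bp``  — physical distance to the previous retained site (0 at the
                  panel's first site)
4. ``dist_cM``  — genetic distance to the previous retained site
5. ``ibs_run``  — length of the maximal run of constant XOR value containing
                  the site (counting the site itself), over the whole panel

Distances are left raw; standardization is the job of the network's leading
batch-normalization layer. A ``raw`` mode substitutes the two raw haplotype
channels for xor/and (used for representation-probing analyses).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .simulate import HaplotypePanel

__all__ = [
    "WindowSpec",
    "CHANNELS",
    "RAW_CHANNELS",
    "pair_features",
    "full_feature_tracks",
    "ibs_run_lengths",
    "ibs_run_oracle",
    "window_slice",
]

CHANNELS = ("xor", "and", "maf", "dist_bp", "dist_cM", "ibs_run")
RAW_CHANNELS = ("h1", "h2", "maf", "dist_bp", "dist_cM", "ibs_run")


@dataclass(frozen=True)
class WindowSpec:
    """Central window of ``L`` sites flanked by ``context`` sites each side."""

    L: int
    context: int

    def __post_init__(self):
        if self.L < 1:
            raise ValueError("L must be >= 1")
        if self.context < 0:
            raise ValueError("context must be >= 0")

    @property
    def L1(self) -> int:
        return self.L + 2 * self.context


def ibs_run_lengths(xor_track: np.ndarray) -> np.ndarray:
    """Length of the maximal constant-value run containing each site, O(n)."""
    x = np.asarray(xor_track)
    n = x.size
    if n == 0:
        return np.zeros(0, dtype=np.int64)
    change = np.flatnonzero(x[1:] != x[:-1]) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [n]])
    lengths = ends - starts
    return np.repeat(lengths, lengths)


def ibs_run_oracle(xor_track: np.ndarray) -> np.ndarray:
    """Literal O(n^2) left+right scan per site; test oracle only."""
    x = np.asarray(xor_track)
    n = x.size
    out = np.zeros(n, dtype=np.int64)
    for i in range(n):
        run = 1
        j = i - 1
        while j >= 0 and x[j] == x[i]:
            run += 1
            j -= 1
        j = i + 1
        while j < n and x[j] == x[i]:
            run += 1
            j += 1
        out[i] = run
    return out


def full_feature_tracks(
    panel: HaplotypePanel, pair: tuple[int, int], raw: bool = False
) -> np.ndarray:
    """(6, n_sites) feature array for one pair over the whole panel."""
    h1, h2 = pair
    if h1 == h2:
        raise ValueError("self-pair is not a valid feature target")
    a1 = panel.alleles[h1].astype(np.float64)
    a2 = panel.alleles[h2].astype(np.float64)
    xor = (panel.alleles[h1] ^ panel.alleles[h2]).astype(np.float64)
    and_ = (panel.alleles[h1] & panel.alleles[h2]).astype(np.float64)
    # error-injected panels may contain monomorphic sites; floor the MAF at
    # the singleton frequency so the channel stays in (0, 0.5]
    maf = np.maximum(panel.maf, 1.0 / panel.n_haplotypes)
    dbp = np.concatenate([[0.0], np.diff(panel.positions)])
    dcm = np.concatenate([[0.0], np.diff(panel.map_cM)])
    ibs = ibs_run_lengths(xor).astype(np.float64)
    if raw:
        return np.stack([a1, a2, maf, dbp, dcm, ibs])
    return np.stack([xor, and_, maf, dbp, dcm, ibs])


def window_slice(tracks: np.ndarray, window: WindowSpec, offset: int) -> np.ndarray:
    """Slice sites [offset - context, offset + L + context) with edge padding.

    ``offset`` indexes the first *central* site. Outside the panel, xor/and
    (or raw haplotype) channels are zero-padded, distances are padded with 0,
    and maf / ibs_run replicate the edge value — keeping shapes fixed for the
    convolutional contract.
    """
    n_sites = tracks.shape[1]
    lo = offset - window.context
    hi = offset + window.L + window.context
    pad_left = max(0, -lo)
    pad_right = max(0, hi - n_sites)
    body = tracks[:, max(lo, 0) : min(hi, n_sites)]
    if pad_left == 0 and pad_right == 0:
        return body.copy()
    if body.shape[1] == 0:
        raise ValueError("window lies entirely outside the panel")
    out = np.empty((tracks.shape[0], window.L1), dtype=tracks.dtype)
    out[:, pad_left : window.L1 - pad_right] = body
    for side, pad, edge in (("L", pad_left, 0), ("R", pad_right, -1)):
        if pad == 0:
            continue
        col = np.zeros(tracks.shape[0], dtype=tracks.dtype)
        col[2] = body[2, edge]  # maf replicates
        col[5] = body[5, edge]  # ibs_run replicates
        block = np.repeat(col[:, None], pad, axis=1)
        if side == "L":
            out[:, :pad] = block
        else:
            out[:, window.L1 - pad :] = block
    return out


def pair_features(
    panel: HaplotypePanel,
    pair: tuple[int, int],
    window: WindowSpec,
    offset: int = 0,
    raw: bool = False,
    pad: bool = True,
) -> np.ndarray:
    """(6, L1) feature window for one pair; ``offset`` = first central site."""
    tracks = full_feature_tracks(panel, pair, raw=raw)
    if not pad:
        lo, hi = offset - window.context, offset + window.L + window.context
        if lo < 0 or hi > panel.n_sites:
            raise ValueError(
                f"window [{lo}, {hi}) exceeds panel of {panel.n_sites} sites "
                "and padding is disabled"
            )
    return window_slice(tracks, window, offset)
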