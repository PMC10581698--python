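"""Piecewise-constant refinement of raw per-site predictions.

Pairwise TMRCAs are piecewise constant along the genome, with jumps at
historical recombination events, but the raw network output varies from site
to site. The postprocessing step segments the sequence at sites whose
predicted breakpoint probability exceeds a threshold and replaces each
segment's values by their arithmetic mean, which preserves the track mean
exactly and nests segmentations across thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace
from typing import Iterable, Sequence

import numpy as np

from .features import window_slice, full_feature_tracks
from .network import ConvNet
from .simulate import HaplotypePanel, TrueLabels

__all__ = [
    "TmrcaTrack",
    "PiecewiseTmrca",
    "predict_pair",
    "make_piecewise",
    "tune_threshold",
    "DEFAULT_THRESHOLDS",
]

#: Piecewise thresholds used when tuning is skipped, by data modality.
DEFAULT_THRESHOLDS = {"sequencing": 0.7, "array": 0.55}


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


@dataclass
class TmrcaTrack:
    """Raw per-site predictions for one pair: TMRCA in generations (>= 1)
    and breakpoint probability in [0, 1]."""

    tmrca: np.ndarray
    p_break: np.ndarray

    def __post_init__(self):
        self.tmrca = np.asarray(self.tmrca, dtype=float)
        self.p_break = np.asarray(self.p_break, dtype=float)
        if self.tmrca.shape != self.p_break.shape or self.tmrca.ndim != 1:
            raise ValueError("tmrca and p_break must be equal-length 1-D arrays")
        if np.any(self.tmrca < 1.0) or np.any((self.p_break < 0) | (self.p_break > 1)):
            raise ValueError("tmrca must be >= 1 and p_break in [0, 1]")

    @property
    def n_sites(self) -> int:
        return self.tmrca.size


@dataclass
class PiecewiseTmrca:
    """Half-open (start_site, end_site, tmrca) segments tiling a track."""

    segments: list[tuple[int, int, float]]

    @property
    def n_sites(self) -> int:
        return self.segments[-1][1] if self.segments else 0

    def site_values(self) -> np.ndarray:
        out = np.empty(self.n_sites, dtype=float)
        for a, b, t in self.segments:
            out[a:b] = t
        return out

    def boundaries(self) -> np.ndarray:
        return np.array([a for a, _, _ in self.segments if a > 0], dtype=np.int64)


def predict_pair(
    model: ConvNet,
    panel: HaplotypePanel,
    pair: tuple[int, int],
    raw: bool = False,
    batch_size: int = 64,
) -> TmrcaTrack:
    """Full-chromosome raw prediction for one pair by window tiling.

    Windows are tiled at stride L with context overlap so that every site is
    predicted exactly once, from the window in which it is central; the last
    window is edge-padded and its predictions past the sequence end are
    discarded.
    """
    window = model.config.window
    n_sites = panel.n_sites
    tracks = full_feature_tracks(panel, pair, raw=raw)
    offsets = list(range(0, n_sites, window.L))
    X = np.stack([window_slice(tracks, window, o) for o in offsets])
    log_t = np.empty(n_sites)
    logit = np.empty(n_sites)
    for i in range(0, X.shape[0], batch_size):
        out = model.forward(X[i : i + batch_size], training=False)
        for j, o in enumerate(offsets[i : i + batch_size]):
            take = min(window.L, n_sites - o)
            log_t[o : o + take] = out[j, 0, :take]
            logit[o : o + take] = out[j, 1, :take]
    # clip before exponentiating: e^30 generations is already far beyond any
    # coalescent time, and untrained models can emit arbitrary outputs
    return TmrcaTrack(
        tmrca=np.maximum(np.exp(np.clip(log_t, 0.0, 30.0)), 1.0), p_break=_sigmoid(logit)
    )


def make_piecewise(track: TmrcaTrack, threshold: float) -> PiecewiseTmrca:
    """Segment a raw track at sites with ``p_break`` strictly above the
    threshold; a flagged site *starts* its segment. Segment values are the
    arithmetic mean of the raw TMRCA over the segment's sites."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    n = track.n_sites
    starts = np.flatnonzero(track.p_break > threshold)
    starts = starts[starts > 0]
    edges = np.concatenate([[0], starts, [n]]).astype(int)
    segments = [
        (int(a), int(b), float(track.tmrca[a:b].mean()))
        for a, b in zip(edges[:-1], edges[1:])
        if b > a
    ]
    return PiecewiseTmrca(segments=segments)


def tune_threshold(
    model: ConvNet,
    heldout: Sequence[tuple[HaplotypePanel, TrueLabels, tuple[int, int]]],
    grid: Iterable[float],
    raw: bool = False,
) -> tuple[float, "np.ndarray"]:
    """Grid-search the piecewise threshold on labelled held-out pairs.

    Returns ``(best_threshold, curve)`` where ``curve[i]`` is the mean
    absolute TMRCA error of the piecewise output at ``grid[i]``; the best
    threshold is the grid argmin (first on ties).
    """
    grid = list(grid)
    if not grid:
        raise ValueError("threshold grid must be non-empty")
    tracks = []
    truths = []
    for panel, labels, pair in heldout:
        tracks.append(predict_pair(model, panel, pair, raw=raw))
        truths.append(labels.site_tmrca(pair))
    curve = np.empty(len(grid))
    for i, thr in enumerate(grid):
        errs = []
        for track, truth in zip(tracks, truths):
            piece = make_piecewise(track, thr).site_values()
            errs.append(np.abs(piece - truth))
        curve[i] = float(np.concatenate(errs).mean())
    best = int(np.argmin(curve))
    return float(grid[best]), curve
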