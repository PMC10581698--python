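"""MAF-adjusted, quantile-normalized allele-age genome annotations.

Allele age carries the signature of past negative selection, but it is
strongly confounded by allele frequency. The annotation therefore bins
common variants (MAF >= 0.05) into 10 equal-width MAF bins on [0.05, 0.5]
and quantile-normalizes the ages within each bin to a standard normal
distribution, yielding a continuous per-variant annotation suitable for
stratified LD-score regression.
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .dating import AlleleAgeEstimate, aggregate_groups

__all__ = [
    "DEFAULT_ANNOTATION_BIN_EDGES",
    "build_annotation",
    "aggregate_annotation_inputs",
    "quantile_normalize",
]

#: Equal-width MAF bin edges on [0.05, 0.5]; user-overridable.
DEFAULT_ANNOTATION_BIN_EDGES = np.linspace(0.05, 0.5, 11)


def quantile_normalize(values: np.ndarray) -> np.ndarray:
    """Rank-based inverse-normal transform with offset (rank - 0.5) / n.

    Ties receive the mean of their rank range, hence a shared normalized
    value; the map is rank-preserving and invariant to monotone transforms
    of the input.
    """
    v = np.asarray(values, dtype=float)
    n = v.size
    if n == 0:
        return np.zeros(0)
    if n == 1:
        return np.zeros(1)
    ranks = rankdata(v, method="average")
    return norm.ppf((ranks - 0.5) / n)


def build_annotation(
    ages: np.ndarray,
    mafs: np.ndarray,
    bin_edges: Optional[np.ndarray] = None,
) -> pd.DataFrame:
    """Quantile-normalized allele-age annotation over MAF bins.

    Variants with MAF < 0.05 are dropped; the rest are assigned to 10
    equal-width MAF bins (1-based ``maf_bin``; the last bin is right-closed
    at 0.5) and their ages are inverse-normal transformed within each bin.
    A bin containing a single variant gets normalized value 0 with a
    warning. Returns a DataFrame indexed like the retained inputs with
    columns ``maf_bin``, ``age``, ``maf``, ``normalized_age``.
    """
    ages = np.asarray(ages, dtype=float)
    mafs = np.asarray(mafs, dtype=float)
    if ages.shape != mafs.shape or ages.ndim != 1:
        raise ValueError("ages and mafs must be equal-length 1-D arrays")
    if np.any(ages <= 0):
        raise ValueError("ages must be positive")
    if np.any((mafs <= 0) | (mafs > 0.5)):
        raise ValueError("MAFs must lie in (0, 0.5]")
    edges = DEFAULT_ANNOTATION_BIN_EDGES if bin_edges is None else np.asarray(bin_edges, float)
    n_bins = edges.size - 1
    keep = np.flatnonzero(mafs >= edges[0])
    if keep.size == 0:
        return pd.DataFrame(
            columns=["variant_index", "maf", "age", "maf_bin", "normalized_age"]
        )
    maf_k = mafs[keep]
    age_k = ages[keep]
    bins = np.clip(np.searchsorted(edges[1:-1], maf_k, side="left"), 0, n_bins - 1)
    normalized = np.empty(keep.size)
    for b in range(n_bins):
        sel = bins == b
        cnt = int(sel.sum())
        if cnt == 0:
            continue
        if cnt == 1:
            warnings.warn(f"MAF bin {b + 1} holds a single variant; normalized to 0")
            normalized[sel] = 0.0
        else:
            normalized[sel] = quantile_normalize(age_k[sel])
    return pd.DataFrame(
        {
            "variant_index": keep,
            "maf": maf_k,
            "age": age_k,
            "maf_bin": bins + 1,
            "normalized_age": normalized,
        }
    )


def aggregate_annotation_inputs(
    per_population: Sequence[dict[str, AlleleAgeEstimate]],
) -> dict[str, AlleleAgeEstimate]:
    """Combine per-population age tables variant-by-variant for an
    annotation spanning all populations (weighted-bound aggregation)."""
    all_ids: list[str] = []
    seen = set()
    for table in per_population:
        for vid in table:
            if vid not in seen:
                seen.add(vid)
                all_ids.append(vid)
    combined = {}
    for vid in all_ids:
        ests = [t[vid] for t in per_population if vid in t]
        combined[vid] = aggregate_groups(ests)
    return combined
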