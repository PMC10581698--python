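"""Allele age estimation from pairwise TMRCAs.

For a variant with derived-allele carriers, every *concordant* pair (both
haplotypes carry the derived allele) coalesces below the mutation, so the
maximum concordant TMRCA ``tc`` bounds the allele age from below; every
*discordant* pair (exactly one carrier) coalesces above it, so the minimum
discordant TMRCA ``td`` bounds it from above. Noisy TMRCA estimates can
violate ``tc <= td``; outlier pairs are rejected with the threshold that
minimizes the total number of rejections, and the age estimate is
``(tc + td) / 2`` over the retained pairs. Singletons have no concordant
pair and are excluded. Estimates from multiple populations are combined by
weighted averages of the bounds, weighted by retained pair counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Callable, Optional, Sequence

import numpy as np

from .simulate import HaplotypePanel, TrueLabels

__all__ = [
    "VariantPairSet",
    "AlleleAgeEstimate",
    "UndatableVariantError",
    "collect_pairs",
    "reject_outliers",
    "date_variant",
    "aggregate_groups",
    "true_tmrca_source",
    "piecewise_tmrca_source",
]


class UndatableVariantError(ValueError):
    """Raised for variants that cannot be dated (e.g. singletons)."""


@dataclass
class VariantPairSet:
    """Concordant/discordant TMRCA observations for one variant."""

    variant_id: str
    concordant: np.ndarray
    discordant: np.ndarray
    derived_count: int

    def __post_init__(self):
        self.concordant = np.asarray(self.concordant, dtype=float)
        self.discordant = np.asarray(self.discordant, dtype=float)


@dataclass
class AlleleAgeEstimate:
    """Point age with coalescent bounds and filtering diagnostics.

    ``tc``/``td`` are the retained lower/upper bounds (one may be None when a
    side was emptied by filtering — ``degenerate`` is then set). ``flagged``
    marks estimates where filtering still left tc > td.
    """

    variant_id: str
    tc: Optional[float]
    td: Optional[float]
    age: float
    rejected_fraction: float
    n_concordant_kept: int
    n_discordant_kept: int
    degenerate: bool = False
    flagged: bool = False


def true_tmrca_source(labels: TrueLabels) -> Callable[[tuple[int, int], int], float]:
    """TMRCA lookup backed by the simulated genealogy."""

    cache: dict[tuple[int, int], np.ndarray] = {}

    def lookup(pair: tuple[int, int], site: int) -> float:
        key = (min(pair), max(pair))
        if key not in cache:
            cache[key] = labels.site_tmrca(key)
        return float(cache[key][site])

    return lookup


def piecewise_tmrca_source(tracks) -> Callable[[tuple[int, int], int], float]:
    """TMRCA lookup from per-pair piecewise tracks.

    ``tracks`` maps an (ordered low, high) haplotype tuple to either a
    :class:`~tmrcanet.postprocess.PiecewiseTmrca` or a per-site array.
    """

    site_cache: dict[tuple[int, int], np.ndarray] = {}

    def lookup(pair: tuple[int, int], site: int) -> float:
        key = (min(pair), max(pair))
        if key not in site_cache:
            obj = tracks[key]
            site_cache[key] = obj if isinstance(obj, np.ndarray) else obj.site_values()
        return float(site_cache[key][site])

    return lookup


def collect_pairs(
    panel: HaplotypePanel,
    tmrca_source: Callable[[tuple[int, int], int], float],
    site: int,
    max_pairs: int = 10_000,
    seed: int = 0,
    variant_id: Optional[str] = None,
) -> VariantPairSet:
    """Gather concordant/discordant TMRCAs at a variant's site.

    For derived count k among n haplotypes there are C(k, 2) concordant and
    k*(n-k) discordant pairs; each side is independently subsampled (uniform,
    seeded) when it exceeds ``max_pairs``. Singletons raise
    :class:`UndatableVariantError`.
    """
    carriers = np.flatnonzero(panel.alleles[:, site] == 1)
    noncarriers = np.flatnonzero(panel.alleles[:, site] == 0)
    k = carriers.size
    if k < 2:
        raise UndatableVariantError(f"undatable: singleton (site {site})")
    if noncarriers.size == 0:
        raise UndatableVariantError(f"undatable: no discordant pair (site {site})")
    rng = np.random.default_rng(seed)
    conc = [(int(a), int(b)) for a, b in combinations(carriers, 2)]
    disc = [(int(a), int(b)) for a in carriers for b in noncarriers]
    if len(conc) > max_pairs:
        idx = rng.choice(len(conc), size=max_pairs, replace=False)
        conc = [conc[i] for i in sorted(idx)]
    if len(disc) > max_pairs:
        idx = rng.choice(len(disc), size=max_pairs, replace=False)
        disc = [disc[i] for i in sorted(idx)]
    return VariantPairSet(
        variant_id=variant_id or f"site{site}",
        concordant=np.array([tmrca_source(p, site) for p in conc]),
        discordant=np.array([tmrca_source(p, site) for p in disc]),
        derived_count=int(k),
    )


def reject_outliers(
    pairset: VariantPairSet,
) -> tuple[VariantPairSet, float, float]:
    """Drop outlier pairs with the rejection-minimizing TMRCA threshold.

    Concordant pairs strictly above and discordant pairs strictly below the
    threshold are rejected. The rejection count is piecewise constant between
    observed TMRCA values, so the observed values are a sufficient candidate
    set. Ties are broken by the smallest rejected fraction, then the smallest
    threshold. Returns (filtered pairset, threshold, rejected_fraction).
    """
    c = pairset.concordant
    d = pairset.discordant
    if c.size == 0 or d.size == 0:
        raise ValueError("reject_outliers needs both concordant and discordant pairs")
    candidates = np.unique(np.concatenate([c, d]))
    # rejections(t) = #{concordant > t} + #{discordant < t}
    n_c_above = c.size - np.searchsorted(np.sort(c), candidates, side="right")
    n_d_below = np.searchsorted(np.sort(d), candidates, side="left")
    rejections = n_c_above + n_d_below
    best = int(np.argmin(rejections))  # ties: smallest threshold (sorted order)
    thr = float(candidates[best])
    kept = VariantPairSet(
        variant_id=pairset.variant_id,
        concordant=c[c <= thr],
        discordant=d[d >= thr],
        derived_count=pairset.derived_count,
    )
    frac = float(rejections[best]) / (c.size + d.size)
    return kept, thr, frac


def date_variant(pairset: VariantPairSet) -> AlleleAgeEstimate:
    """Outlier-filter a pair set and average the resulting bounds."""
    kept, _, frac = reject_outliers(pairset)
    tc = float(kept.concordant.max()) if kept.concordant.size else None
    td = float(kept.discordant.min()) if kept.discordant.size else None
    degenerate = tc is None or td is None
    if tc is None and td is None:
        raise UndatableVariantError(
            f"filtering removed every pair for {pairset.variant_id}"
        )
    if degenerate:
        age = tc if td is None else td
    else:
        age = 0.5 * (tc + td)
    return AlleleAgeEstimate(
        variant_id=pairset.variant_id,
        tc=tc,
        td=td,
        age=float(age),
        rejected_fraction=frac,
        n_concordant_kept=int(kept.concordant.size),
        n_discordant_kept=int(kept.discordant.size),
        degenerate=degenerate,
        flagged=(not degenerate) and tc > td,
    )


def aggregate_groups(estimates: Sequence[AlleleAgeEstimate]) -> AlleleAgeEstimate:
    """Combine per-population estimates of one variant into a group estimate.

    The lower bound is the average of per-population ``tc`` weighted by
    retained concordant pair counts; the upper bound the analogous average of
    ``td`` with discordant weights; the age is the mean of the two. A
    population with zero weight on a side drops out of that side's average.
    """
    ests = [e for e in estimates if e is not None]
    if not ests:
        raise UndatableVariantError("variant datable in no population")
    wc = np.array([e.n_concordant_kept for e in ests], dtype=float)
    wd = np.array([e.n_discordant_kept for e in ests], dtype=float)
    tc_vals = np.array([e.tc if e.tc is not None else np.nan for e in ests])
    td_vals = np.array([e.td if e.td is not None else np.nan for e in ests])
    cu = (wc > 0) & ~np.isnan(tc_vals)
    du = (wd > 0) & ~np.isnan(td_vals)
    if not cu.any() and not du.any():
        raise UndatableVariantError("no usable bound in any population")
    lower = float((wc[cu] * tc_vals[cu]).sum() / wc[cu].sum()) if cu.any() else None
    upper = float((wd[du] * td_vals[du]).sum() / wd[du].sum()) if du.any() else None
    if lower is None:
        age = upper
    elif upper is None:
        age = lower
    else:
        age = 0.5 * (lower + upper)
    tot = sum(e.n_concordant_kept + e.n_discordant_kept for e in ests)
    rej = sum(
        e.rejected_fraction * (e.n_concordant_kept + e.n_discordant_kept) / (1 - e.rejected_fraction)
        if e.rejected_fraction < 1
        else 0.0
        for e in ests
    )
    frac = rej / (tot + rej) if (tot + rej) > 0 else 0.0
    return AlleleAgeEstimate(
        variant_id=ests[0].variant_id,
        tc=lower,
        td=upper,
        age=float(age),
        rejected_fraction=float(frac),
        n_concordant_kept=int(wc.sum()),
        n_discordant_kept=int(wd.sum()),
        degenerate=lower is None or upper is None,
        flagged=(lower is not None and upper is not None and lower > upper),
    )
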