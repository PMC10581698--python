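"""Coalescent simulation of training/validation/test data with exact labels.

This module wraps msprime to generate phased haplotype panels together with
the ground-truth pairwise TMRCA along the sequence, extracted directly from
the simulated tree sequence. It owns everything around the raw genealogy
sampling: demography/map configuration, sequencing and SNP-array site
ascertainment, phasing/genotyping error injection, and label bookkeeping.

Conventions
-----------
* Haplotypes are numbered 0..n-1 and paired into diploids (2i, 2i+1).
* Site indices are 0-based, half-open; bp positions are 0-based internally
  (1-based only at VCF boundaries, handled by :mod:`tmrcanet.io`).
* Labels are extracted *before* error injection so they remain the truth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import msprime
import numpy as np
import tskit

__all__ = [
    "DemographicModel",
    "GeneticMap",
    "SimulationConfig",
    "HaplotypePanel",
    "TrueLabels",
    "EmptyRegionError",
    "simulate_dataset",
    "simulate_pairwise_tmrcas",
    "inject_errors",
    "ascertain_array",
    "DEFAULT_ARRAY_SPECTRUM",
    "MAF_BIN_EDGES",
]


class EmptyRegionError(RuntimeError):
    """Raised when a simulated region retains zero polymorphic sites."""


@dataclass(frozen=True)
class DemographicModel:
    """Piecewise-constant single-population demography.

    ``epochs`` is a sequence of ``(start_time_generations, diploid_Ne)``
    pairs with strictly increasing start times beginning at 0.
    """

    epochs: tuple[tuple[float, float], ...]

    def __post_init__(self):
        epochs = tuple((float(t), float(ne)) for t, ne in self.epochs)
        object.__setattr__(self, "epochs", epochs)
        if not epochs:
            raise ValueError("demographic model needs at least one epoch")
        if epochs[0][0] != 0.0:
            raise ValueError("first epoch must start at generation 0")
        times = [t for t, _ in epochs]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("epoch start times must be strictly increasing")
        if any(ne <= 0 for _, ne in epochs):
            raise ValueError("all Ne values must be positive")

    @classmethod
    def constant(cls, ne: float) -> "DemographicModel":
        return cls(epochs=((0.0, ne),))

    def to_msprime(self) -> msprime.Demography:
        demog = msprime.Demography()
        demog.add_population(name="pop0", initial_size=self.epochs[0][1])
        for t, ne in self.epochs[1:]:
            demog.add_population_parameters_change(time=t, initial_size=ne)
        return demog


@dataclass(frozen=True)
class GeneticMap:
    """Physical-to-genetic coordinate table.

    ``positions`` in bp strictly increasing; ``map_cM`` non-decreasing.
    """

    positions: np.ndarray
    map_cM: np.ndarray

    def __post_init__(self):
        pos = np.asarray(self.positions, dtype=float)
        cm = np.asarray(self.map_cM, dtype=float)
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "map_cM", cm)
        if pos.ndim != 1 or pos.shape != cm.shape or pos.size < 2:
            raise ValueError("map needs >= 2 (position, cM) rows of equal length")
        if np.any(np.diff(pos) <= 0):
            raise ValueError("map positions must be strictly increasing")
        if np.any(np.diff(cm) < 0):
            raise ValueError("map cM values must be non-decreasing")

    @classmethod
    def constant(cls, rate_per_bp: float, length: float) -> "GeneticMap":
        """Uniform crossover rate (per bp per generation) over [0, length]."""
        return cls(
            positions=np.array([0.0, float(length)]),
            map_cM=np.array([0.0, rate_per_bp * length * 100.0]),
        )

    def cm_at(self, positions_bp: np.ndarray) -> np.ndarray:
        return np.interp(np.asarray(positions_bp, dtype=float), self.positions, self.map_cM)

    def to_rate_map(self, length: float) -> msprime.RateMap:
        """msprime RateMap over [0, length], clipping/extending the table."""
        pos = self.positions
        cm = self.map_cM
        if pos[0] > 0:
            pos = np.concatenate([[0.0], pos])
            cm = np.concatenate([[cm[0]], cm])
        if pos[-1] < length:
            # extend with the last interval's rate
            last_rate = (cm[-1] - cm[-2]) / (pos[-1] - pos[-2])
            pos = np.concatenate([pos, [length]])
            cm = np.concatenate([cm, [cm[-1] + last_rate * (length - pos[-2])]])
        keep = pos <= length
        if pos[keep][-1] < length:
            keep_pos = np.concatenate([pos[keep], [length]])
            keep_cm = np.concatenate([cm[keep], [np.interp(length, pos, cm)]])
        else:
            keep_pos, keep_cm = pos[keep], cm[keep]
        rates = np.diff(keep_cm) / 100.0 / np.diff(keep_pos)
        return msprime.RateMap(position=keep_pos, rate=rates)

    @property
    def total_cm(self) -> float:
        return float(self.map_cM[-1] - self.map_cM[0])


#: Equal-width MAF bin edges on (0, 0.5] used for array ascertainment.
MAF_BIN_EDGES = np.linspace(0.0, 0.5, 11)

#: Built-in synthetic stand-in for a SNP-array target MAF spectrum: genotyping
#: arrays are strongly enriched for common variants relative to sequencing, so
#: mass increases toward high MAF. User-overridable everywhere it is consumed.
DEFAULT_ARRAY_SPECTRUM = np.array(
    [0.030, 0.045, 0.065, 0.085, 0.100, 0.115, 0.125, 0.135, 0.145, 0.155]
)


@dataclass(frozen=True)
class SimulationConfig:
    """Everything needed to draw one labelled dataset."""

    demographic_model: DemographicModel
    n_haplotypes: int
    region_length: float
    genetic_map: Optional[GeneticMap] = None
    recombination_rate: float = 1e-8  # used when genetic_map is None
    mutation_rate: float = 1.65e-8
    modality: str = "sequencing"
    polymorphism_reference_size: Optional[int] = None  # diploid count
    switch_error_rate: float = 0.0
    genotyping_error_rate: float = 0.0
    beta_alpha: Optional[float] = None  # Kingman when absent; else in (1, 2]
    ncgc_rate: float = 0.0
    ncgc_tract_length: float = 300.0
    array_spectrum: Optional[np.ndarray] = None
    array_density: Optional[float] = None  # retained sites per cM
    seed: int = 0

    def __post_init__(self):
        if self.n_haplotypes < 2 or self.n_haplotypes % 2 != 0:
            raise ValueError("n_haplotypes must be an even integer >= 2")
        if self.region_length <= 0:
            raise ValueError("region_length must be positive")
        for name in ("switch_error_rate", "genotyping_error_rate"):
            r = getattr(self, name)
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"{name} must be a probability")
        if self.beta_alpha is not None and not (1.0 < self.beta_alpha <= 2.0):
            raise ValueError("beta_alpha must lie in (1, 2]")
        if self.modality not in ("sequencing", "array"):
            raise ValueError("modality must be 'sequencing' or 'array'")
        if self.ncgc_rate < 0 or self.mutation_rate < 0 or self.recombination_rate < 0:
            raise ValueError("rates must be non-negative")


@dataclass
class HaplotypePanel:
    """Phased derived-allele matrix with physical and genetic coordinates.

    ``alleles``: (n_haplotypes, n_sites) uint8 matrix, 1 = derived.
    """

    alleles: np.ndarray
    positions: np.ndarray  # bp, strictly increasing
    map_cM: np.ndarray

    def __post_init__(self):
        self.alleles = np.ascontiguousarray(self.alleles, dtype=np.uint8)
        self.positions = np.asarray(self.positions, dtype=float)
        self.map_cM = np.asarray(self.map_cM, dtype=float)
        if self.alleles.ndim != 2:
            raise ValueError("alleles must be 2-D (haplotypes x sites)")
        if self.positions.shape != (self.alleles.shape[1],):
            raise ValueError("positions length must match site count")
        if self.n_sites > 1 and np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[1]

    @property
    def derived_counts(self) -> np.ndarray:
        return self.alleles.sum(axis=0).astype(np.int64)

    @property
    def maf(self) -> np.ndarray:
        dc = self.derived_counts
        return np.minimum(dc, self.n_haplotypes - dc) / self.n_haplotypes

    def subset_sites(self, idx: np.ndarray) -> "HaplotypePanel":
        idx = np.asarray(idx)
        return HaplotypePanel(self.alleles[:, idx], self.positions[idx], self.map_cM[idx])

    def copy(self) -> "HaplotypePanel":
        return HaplotypePanel(self.alleles.copy(), self.positions.copy(), self.map_cM.copy())

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, HaplotypePanel)
            and np.array_equal(self.alleles, other.alleles)
            and np.array_equal(self.positions, other.positions)
            and np.array_equal(self.map_cM, other.map_cM)
        )


class TrueLabels:
    """Ground-truth pairwise TMRCA segments bound to a panel's site grid.

    Holds the simulated tree sequence; per-pair piecewise TMRCA segments and
    breakpoint labels are extracted lazily (and cached) in site coordinates.
    """

    def __init__(
        self,
        ts: tskit.TreeSequence,
        positions: np.ndarray,
        sample_nodes: Optional[np.ndarray] = None,
        mutation_times: Optional[np.ndarray] = None,
    ):
        self.ts = ts
        self.positions = np.asarray(positions, dtype=float)
        if sample_nodes is None:
            sample_nodes = np.asarray(ts.samples())
        self.sample_nodes = np.asarray(sample_nodes)
        self.mutation_times = (
            None if mutation_times is None else np.asarray(mutation_times, dtype=float)
        )
        self._segment_cache: dict[tuple[int, int], list[tuple[int, int, float]]] = {}

    @property
    def n_sites(self) -> int:
        return self.positions.size

    @property
    def n_haplotypes(self) -> int:
        return self.sample_nodes.size

    def restrict(self, site_idx: np.ndarray) -> "TrueLabels":
        site_idx = np.asarray(site_idx)
        mt = None if self.mutation_times is None else self.mutation_times[site_idx]
        return TrueLabels(self.ts, self.positions[site_idx], self.sample_nodes, mt)

    def restrict_to_positions(self, positions: np.ndarray) -> "TrueLabels":
        idx = np.searchsorted(self.positions, positions)
        if not np.array_equal(self.positions[idx], positions):
            raise ValueError("requested positions are not a subset of labelled sites")
        return self.restrict(idx)

    # -- per-pair extraction ------------------------------------------------

    def segments(self, pair: tuple[int, int]) -> list[tuple[int, int, float]]:
        """Half-open (start_site, end_site, tmrca) segments tiling the sites."""
        h1, h2 = pair
        if h1 == h2:
            raise ValueError("self-pair has no TMRCA")
        key = (min(h1, h2), max(h1, h2))
        cached = self._segment_cache.get(key)
        if cached is not None:
            return cached
        u, v = self.sample_nodes[key[0]], self.sample_nodes[key[1]]
        segs: list[tuple[int, int, float]] = []
        for tree in self.ts.trees(sample_lists=False):
            t = tree.tmrca(u, v)
            a = int(np.searchsorted(self.positions, tree.interval.left, side="left"))
            b = int(np.searchsorted(self.positions, tree.interval.right, side="left"))
            if b <= a:
                continue
            if segs and segs[-1][2] == t:
                segs[-1] = (segs[-1][0], b, t)
            else:
                segs.append((a, b, t))
        if segs:
            # trees can start mid-way through sites only at the edges
            segs[0] = (0, segs[0][1], segs[0][2])
            segs[-1] = (segs[-1][0], self.n_sites, segs[-1][2])
        self._segment_cache[key] = segs
        return segs

    def site_tmrca(self, pair: tuple[int, int]) -> np.ndarray:
        out = np.empty(self.n_sites, dtype=float)
        for a, b, t in self.segments(pair):
            out[a:b] = t
        return out

    def breakpoint_sites(self, pair: tuple[int, int]) -> np.ndarray:
        """Site indices where the TMRCA segment changes (left edges except 0)."""
        return np.array([a for a, _, _ in self.segments(pair) if a > 0], dtype=np.int64)

    def breakpoint_indicator(self, pair: tuple[int, int]) -> np.ndarray:
        out = np.zeros(self.n_sites, dtype=np.uint8)
        out[self.breakpoint_sites(pair)] = 1
        return out

    def mean_tmrca_matrix(self) -> np.ndarray:
        """Span-weighted mean pairwise TMRCA over the region (branch mode)."""
        ids = [int(u) for u in self.sample_nodes]
        div = self.ts.divergence_matrix([[u] for u in ids], mode="branch")
        m = np.asarray(div, dtype=float) / 2.0
        np.fill_diagonal(m, 0.0)
        return m


def simulate_pairwise_tmrcas(config: SimulationConfig) -> np.ndarray:
    """Single-locus pairwise TMRCAs from one ancestry realization.

    Runs the coalescent (no mutations, no ascertainment) and returns the
    C(n, 2) pairwise coalescence times at the left-most tree, in
    generations. Useful for studying TMRCA distributions, e.g. the burst of
    recent coalescence under the Beta-coalescent.
    """
    rng = np.random.default_rng(config.seed)
    ts, _ = _simulate_tree_sequence(config, rng, mutations=False)
    tree = ts.first()
    samples = np.asarray(ts.samples())[: config.n_haplotypes]
    out = []
    for i in range(samples.size):
        for j in range(i + 1, samples.size):
            out.append(tree.tmrca(samples[i], samples[j]))
    return np.asarray(out, dtype=float)


def _simulate_tree_sequence(
    config: SimulationConfig, rng: np.random.Generator, mutations: bool = True
):
    ref_hap = 0
    if config.polymorphism_reference_size is not None:
        ref_hap = 2 * config.polymorphism_reference_size
    n_total = max(config.n_haplotypes, ref_hap)
    if n_total % 2:
        n_total += 1
    model = None
    if config.beta_alpha is not None:
        model = msprime.BetaCoalescent(alpha=config.beta_alpha)
    if config.genetic_map is not None:
        recomb = config.genetic_map.to_rate_map(config.region_length)
        kwargs = dict(recombination_rate=recomb)
    else:
        kwargs = dict(
            recombination_rate=config.recombination_rate,
            sequence_length=config.region_length,
        )
    if config.ncgc_rate > 0:
        kwargs["gene_conversion_rate"] = config.ncgc_rate
        kwargs["gene_conversion_tract_length"] = config.ncgc_tract_length
    anc_seed = int(rng.integers(1, 2**31 - 1))
    mut_seed = int(rng.integers(1, 2**31 - 1))
    ts = msprime.sim_ancestry(
        samples=n_total // 2,
        ploidy=2,
        demography=config.demographic_model.to_msprime(),
        model=model,
        random_seed=anc_seed,
        **kwargs,
    )
    if mutations:
        ts = msprime.sim_mutations(
            ts,
            rate=config.mutation_rate,
            model=msprime.BinaryMutationModel(),
            random_seed=mut_seed,
        )
    return ts, n_total


def simulate_dataset(config: SimulationConfig) -> tuple[HaplotypePanel, TrueLabels]:
    """Draw one coalescent-with-recombination realization with truth labels.

    Returns the haplotype panel after ascertainment and error injection, and
    :class:`TrueLabels` bound to the panel's retained sites. Labels are
    extracted before error injection, so they remain the genealogical truth.

    Raises :class:`EmptyRegionError` when no polymorphic site survives.
    """
    rng = np.random.default_rng(config.seed)
    ts, n_total = _simulate_tree_sequence(config, rng)
    n_hap = config.n_haplotypes

    # single-mutation sites only: clean ancestral/derived polarity and a
    # well-defined mutation time per site
    site_mut_count = np.bincount(
        [m.site for m in ts.mutations()], minlength=ts.num_sites
    )
    good_sites = site_mut_count == 1
    if ts.num_sites == 0 or not good_sites.any():
        raise EmptyRegionError("no usable polymorphic site in the simulated region")

    G = ts.genotype_matrix()  # (sites, samples)
    positions = ts.tables.sites.position
    mut_times = np.full(ts.num_sites, np.nan)
    for m in ts.mutations():
        if good_sites[m.site]:
            mut_times[m.site] = m.time

    panel_cols = np.arange(n_hap)
    poly_panel = (G[:, panel_cols].sum(axis=1) % n_hap) != 0
    keep = good_sites & poly_panel
    if config.polymorphism_reference_size is not None:
        ref_cols = rng.choice(n_total, size=2 * config.polymorphism_reference_size, replace=False)
        s = G[:, ref_cols].sum(axis=1)
        keep &= (s > 0) & (s < ref_cols.size)
    keep_idx = np.flatnonzero(keep)
    if keep_idx.size == 0:
        raise EmptyRegionError("no polymorphic site survives ascertainment")

    positions = positions[keep_idx]
    if config.genetic_map is not None:
        map_cm = config.genetic_map.cm_at(positions)
    else:
        map_cm = positions * config.recombination_rate * 100.0
    panel = HaplotypePanel(G[np.ix_(keep_idx, panel_cols)].T, positions, map_cm)
    labels = TrueLabels(
        ts,
        positions,
        sample_nodes=np.asarray(ts.samples())[:n_hap],
        mutation_times=mut_times[keep_idx],
    )

    if config.modality == "array":
        panel = ascertain_array(
            panel,
            target_spectrum=config.array_spectrum,
            target_density=config.array_density,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        labels = labels.restrict_to_positions(panel.positions)

    if config.switch_error_rate > 0 or config.genotyping_error_rate > 0:
        panel = inject_errors(
            panel,
            config.switch_error_rate,
            config.genotyping_error_rate,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
    return panel, labels


def inject_errors(
    panel: HaplotypePanel,
    switch_rate: float,
    genotyping_rate: float,
    seed: int,
) -> HaplotypePanel:
    """Apply phasing switch errors and genotyping flips to a panel.

    Haplotypes are paired into diploids (2i, 2i+1). A switch error occurs
    independently at each heterozygous site with probability ``switch_rate``
    and swaps the two haplotypes of that diploid from that site onward
    (until a further switch reverses it). Genotyping errors flip individual
    allele calls independently with probability ``genotyping_rate``.
    """
    if not 0 <= switch_rate <= 1 or not 0 <= genotyping_rate <= 1:
        raise ValueError("error rates must be probabilities")
    if switch_rate > 0 and panel.n_haplotypes % 2 != 0:
        raise ValueError("switch errors require an even number of haplotypes")
    if switch_rate == 0 and genotyping_rate == 0:
        return panel
    rng = np.random.default_rng(seed)
    alleles = panel.alleles.copy()
    if switch_rate > 0:
        for d in range(panel.n_haplotypes // 2):
            a, b = alleles[2 * d], alleles[2 * d + 1]
            het = a != b
            events = np.zeros(panel.n_sites, dtype=bool)
            het_idx = np.flatnonzero(het)
            events[het_idx] = rng.random(het_idx.size) < switch_rate
            swapped = (np.cumsum(events) % 2).astype(bool)
            tmp = a[swapped].copy()
            a[swapped] = b[swapped]
            b[swapped] = tmp
    if genotyping_rate > 0:
        flips = rng.random(alleles.shape) < genotyping_rate
        alleles ^= flips.astype(np.uint8)
    return HaplotypePanel(alleles, panel.positions.copy(), panel.map_cM.copy())


def _allocate_bin_counts(
    available: np.ndarray, mass: np.ndarray, n_target: int
) -> np.ndarray:
    """Largest-remainder allocation of n_target draws across MAF bins,
    capped at availability, redistributing infeasible mass with a warning."""
    mass = np.asarray(mass, dtype=float).copy()
    if mass.sum() <= 0:
        raise ValueError("target spectrum must have positive total mass")
    mass /= mass.sum()
    counts = np.zeros_like(available)
    remaining = n_target
    active = available > 0
    if np.any(mass[~active] > 0):
        warnings.warn(
            "target spectrum puts mass on empty MAF bins; renormalizing",
            stacklevel=3,
        )
    while remaining > 0 and np.any(active & (counts < available)):
        m = np.where(active, mass, 0.0)
        if m.sum() == 0:
            break
        m /= m.sum()
        want = m * remaining
        take = np.minimum(np.floor(want).astype(int), available - counts)
        if take.sum() == 0:
            # largest remainders, one at a time
            order = np.argsort(-(want - np.floor(want)))
            for b in order:
                if active[b] and counts[b] < available[b] and remaining > 0:
                    counts[b] += 1
                    remaining -= 1
            active &= counts < available
            continue
        counts += take
        remaining -= take.sum()
        active &= counts < available
    return counts


def ascertain_array(
    panel: HaplotypePanel,
    target_spectrum: Optional[np.ndarray] = None,
    target_density: Optional[float] = None,
    seed: int = 0,
) -> HaplotypePanel:
    """Subsample sites to a target MAF spectrum and per-cM density.

    Emulates SNP-array ascertainment: retained sites' MAF histogram matches
    ``target_spectrum`` over 10 equal-width bins on (0, 0.5] up to
    feasibility; site order is preserved. When ``target_density`` (sites/cM)
    is None the current site count is kept.
    """
    spectrum = DEFAULT_ARRAY_SPECTRUM if target_spectrum is None else np.asarray(target_spectrum, float)
    if spectrum.size != MAF_BIN_EDGES.size - 1:
        raise ValueError(f"target spectrum needs {MAF_BIN_EDGES.size - 1} bins")
    if not np.isclose(spectrum.sum(), 1.0, atol=1e-6):
        raise ValueError("target spectrum must sum to 1")
    rng = np.random.default_rng(seed)
    maf = panel.maf
    # right-closed bins: maf = 0.05 belongs to bin 1, 0.5 to bin 10
    bins = np.clip(np.searchsorted(MAF_BIN_EDGES[1:-1], maf, side="left"), 0, 9)
    if target_density is None:
        n_target = panel.n_sites
    else:
        total_cm = float(panel.map_cM[-1] - panel.map_cM[0])
        n_target = int(round(target_density * total_cm))
    n_target = min(n_target, panel.n_sites)
    available = np.bincount(bins, minlength=10)
    counts = _allocate_bin_counts(available, spectrum, n_target)
    keep: list[np.ndarray] = []
    for b in range(10):
        if counts[b] == 0:
            continue
        idx = np.flatnonzero(bins == b)
        keep.append(rng.choice(idx, size=counts[b], replace=False))
    if not keep:
        raise EmptyRegionError("array ascertainment retained no site")
    keep_idx = np.sort(np.concatenate(keep))
    return panel.subset_sites(keep_idx)
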