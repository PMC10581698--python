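"""Simulate a labelled coalescent dataset and inspect the ground truth.

Draws one coalescent-with-recombination realization under a constant
demography, prints summary statistics of the haplotype panel, and shows the
piecewise-constant true TMRCA of one haplotype pair. The mean pairwise
TMRCA should sit near 2*Ne = 20,000 generations and nucleotide diversity
near 4*Ne*mu per bp.
"""

import numpy as np

from tmrcanet import DemographicModel, SimulationConfig, simulate_dataset

config = SimulationConfig(
    demographic_model=DemographicModel.constant(10_000),
    n_haplotypes=20,
    region_length=1_000_000,  # 1 Mb at 1e-8 crossovers/bp/gen = 1 cM
    mutation_rate=1.65e-8,
    seed=7,
)
panel, labels = simulate_dataset(config)

dc = panel.derived_counts
n = panel.n_haplotypes
pi = (2 * dc * (n - dc) / (n * (n - 1))).sum() / config.region_length
print(f"panel: {panel.n_haplotypes} haplotypes x {panel.n_sites} sites")
print(f"nucleotide diversity pi = {pi:.2e} per bp (E[pi] = 4*Ne*mu = 6.6e-4)")

m = labels.mean_tmrca_matrix()
print(f"mean pairwise TMRCA = {m[np.triu_indices(n, 1)].mean():,.0f} generations "
      "(E = 2*Ne = 20,000)")

segments = labels.segments((0, 1))
print(f"\npair (0, 1) has {len(segments)} true TMRCA segments; the first five:")
for start, end, tmrca in segments[:5]:
    print(f"  sites [{start:5d}, {end:5d})  TMRCA = {tmrca:10,.0f} generations")
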