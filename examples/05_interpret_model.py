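"""Probe what a trained model has learned.

Computes an input-x-gradient saliency map for one target site (against the
normalized input, so channels are comparable) and runs the MAF perturbation
analysis: raising the MAF at heterozygous (XOR=1) sites should raise the
predicted TMRCA, because heterozygosity at common variants indicates a
distant common ancestor.
"""

import numpy as np

from tmrcanet import (
    DemographicModel,
    SimulationConfig,
    TrainConfig,
    desk_config,
    simulate_dataset,
    train,
)
from tmrcanet.features import CHANNELS, full_feature_tracks, window_slice
from tmrcanet.interpret import perturb_maf, saliency_map

sim = SimulationConfig(
    demographic_model=DemographicModel.constant(10_000),
    n_haplotypes=20,
    region_length=2_000_000,
    seed=0,
)
result = train(
    TrainConfig(sim=sim, model=desk_config(L=512), epochs=8, sims_per_epoch=32,
                val_sims=3, seed=11)
)
model = result.model
window = model.config.window

panel, _ = simulate_dataset(
    SimulationConfig(
        demographic_model=DemographicModel.constant(10_000),
        n_haplotypes=20,
        region_length=2_000_000,
        seed=555_000,
    )
)
tracks = full_feature_tracks(panel, (0, 1))
features = window_slice(tracks, window, offset=window.L)

smap = saliency_map(model, features, target_site=window.L // 2)
per_channel = smap.grid.sum(axis=1)
print("total saliency mass per input channel (target = central site):")
for name, mass in zip(CHANNELS, per_channel):
    print(f"  {name:8s} {mass:12.1f}")

windows = np.stack(
    [window_slice(tracks, window, o) for o in range(0, panel.n_sites - window.L, window.L)]
)
for mode in ("raise_xor_sites", "lower_and_sites"):
    delta = perturb_maf(model, windows, mode, panel.n_haplotypes)
    print(f"mean TMRCA change under {mode}: {delta:+,.1f} generations")
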