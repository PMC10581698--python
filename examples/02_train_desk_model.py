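"""Train the desk-preset network on freshly simulated data.

Each epoch simulates independent regions, takes one haplotype pair per
simulation (alternating uniform and relatedness-informed sampling), and
minimizes the homoscedastic-uncertainty-weighted Huber + class-weighted
cross-entropy loss. The validation score is a weighted Huber loss on the
closest pairs; the best-scoring model is kept. A few minutes on one CPU.
"""

from tmrcanet import DemographicModel, SimulationConfig, TrainConfig, desk_config, train
from tmrcanet.network import save_checkpoint

config = TrainConfig(
    sim=SimulationConfig(
        demographic_model=DemographicModel.constant(10_000),
        n_haplotypes=20,
        region_length=2_000_000,
        seed=0,
    ),
    model=desk_config(L=512),
    epochs=8,
    sims_per_epoch=32,
    val_sims=3,
    seed=11,
)
result = train(config)
print(result.history[["epoch", "mode", "train_loss", "val_score"]].to_string(index=False))
print(f"\nbest validation score {result.best_val:.3f} at epoch {result.best_epoch}")
save_checkpoint("desk_checkpoint.npz", result.model,
                uncertainty=(result.uncertainty.s_reg, result.uncertainty.s_cls))
print("checkpoint written to desk_checkpoint.npz")
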