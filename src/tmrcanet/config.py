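"""Run configuration: strict YAML schema and deterministic seed derivation.

Every stochastic stage derives its seed from the master seed and a stage
label, so a config file plus master seed pins the entire pipeline.
Unknown configuration keys are a hard failure — no silent defaults.
"""

from __future__ import annotations

import zlib
from pathlib import Path
from typing import Any, Optional

import numpy as np
import yaml

from .features import WindowSpec
from .network import ModelConfig, desk_config, full_config, receptive_field
from .simulate import DemographicModel, SimulationConfig
from .training import TrainConfig

__all__ = ["load_config", "stage_seed", "build_sim_config", "build_train_config"]

_SCHEMA: dict[str, Any] = {
    "seed": None,
    "output_dir": None,
    "simulation": {
        "ne": None,
        "demography_file": None,
        "n_haplotypes": None,
        "region_length": None,
        "recombination_rate": None,
        "genetic_map_file": None,
        "mutation_rate": None,
        "modality": None,
        "polymorphism_reference_size": None,
        "switch_error_rate": None,
        "genotyping_error_rate": None,
        "beta_alpha": None,
        "ncgc_rate": None,
        "ncgc_tract_length": None,
        "array_density": None,
    },
    "window": {"L": None},
    "model": {"preset": None, "channels": None, "kernels": None},
    "training": {
        "epochs": None,
        "sims_per_epoch": None,
        "batch_size": None,
        "lr": None,
        "uncertainty_lr": None,
        "val_sims": None,
    },
    "postprocess": {"threshold": None},
    "dating": {"max_pairs": None},
}


def _check_keys(cfg: dict, schema: dict, path: str = "") -> None:
    for key, value in cfg.items():
        if key not in schema:
            raise ValueError(f"unknown configuration key: {path}{key}")
        if isinstance(value, dict):
            if not isinstance(schema[key], dict):
                raise ValueError(f"{path}{key} must be a scalar, not a mapping")
            _check_keys(value, schema[key], path=f"{path}{key}.")


def load_config(path) -> dict:
    cfg = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(cfg, dict):
        raise ValueError("configuration must be a YAML mapping")
    _check_keys(cfg, _SCHEMA)
    return cfg


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    ss = np.random.SeedSequence(
        entropy=int(master_seed), spawn_key=(zlib.crc32(stage.encode()),)
    )
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def build_sim_config(cfg: dict, seed: int) -> SimulationConfig:
    from .io import read_demography, read_genetic_map

    sim = cfg.get("simulation", {})
    if sim.get("demography_file"):
        demog = read_demography(sim["demography_file"])
    else:
        demog = DemographicModel.constant(float(sim.get("ne", 10_000)))
    gmap = None
    if sim.get("genetic_map_file"):
        gmap = read_genetic_map(sim["genetic_map_file"])
    return SimulationConfig(
        demographic_model=demog,
        n_haplotypes=int(sim.get("n_haplotypes", 20)),
        region_length=float(sim.get("region_length", 2e6)),
        genetic_map=gmap,
        recombination_rate=float(sim.get("recombination_rate", 1e-8)),
        mutation_rate=float(sim.get("mutation_rate", 1.65e-8)),
        modality=sim.get("modality", "sequencing"),
        polymorphism_reference_size=sim.get("polymorphism_reference_size"),
        switch_error_rate=float(sim.get("switch_error_rate", 0.0)),
        genotyping_error_rate=float(sim.get("genotyping_error_rate", 0.0)),
        beta_alpha=sim.get("beta_alpha"),
        ncgc_rate=float(sim.get("ncgc_rate", 0.0)),
        ncgc_tract_length=float(sim.get("ncgc_tract_length", 300.0)),
        array_density=sim.get("array_density"),
        seed=int(seed),
    )


def build_model_config(cfg: dict) -> ModelConfig:
    L = int(cfg.get("window", {}).get("L", 512))
    model = cfg.get("model", {})
    preset = model.get("preset", "desk")
    if model.get("channels") or model.get("kernels"):
        kernels = tuple(int(k) for k in model["kernels"])
        return ModelConfig(
            window=WindowSpec(L=L, context=(receptive_field(kernels) - 1) // 2),
            channels=tuple(int(c) for c in model["channels"]),
            kernels=kernels,
        )
    if preset == "desk":
        return desk_config(L=L)
    if preset == "full":
        return full_config(L=L)
    raise ValueError(f"unknown model preset: {preset}")


def build_train_config(cfg: dict) -> TrainConfig:
    master = int(cfg.get("seed", 0))
    tr = cfg.get("training", {})
    return TrainConfig(
        sim=build_sim_config(cfg, seed=0),  # per-sim seeds are drawn in-loop
        model=build_model_config(cfg),
        epochs=int(tr.get("epochs", 15)),
        sims_per_epoch=int(tr.get("sims_per_epoch", 64)),
        batch_size=int(tr.get("batch_size", 64)),
        lr=float(tr.get("lr", 1e-3)),
        uncertainty_lr=float(tr.get("uncertainty_lr", 0.05)),
        val_sims=int(tr.get("val_sims", 4)),
        seed=stage_seed(master, "training"),
    )
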