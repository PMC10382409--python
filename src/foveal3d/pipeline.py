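"""Desk-scale end-to-end pipeline: simulate -> preprocess -> train -> predict
-> evaluate.

The clinical-scale system (217 scans, 2,000 GPU epochs) is out of reach on a
workstation CPU, so the end-to-end path runs the identical pipeline at a
reduced, fixed problem size: 20 synthetic 64^3 phantoms at 1 mm, a
two-level foveal geometry, and 300 minibatches of 12 patches. These sizes
are the package's own scaled-down study conditions; every stage (patch
sampling, augmentation, loss, AdaDelta, tiled inference, node-level
evaluation) is exercised unchanged.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

from . import evaluate as ev
from .core import NormalizationSpec, normalize_intensity
from .foveal_net import ModelGeometry
from .infer import predict_volume, threshold_probability
from .phantom import PhantomConfig, generate_phantom, replace_seed
from .train import AugmentConfig, TrainConfig, TrainingCase, train_model


@dataclass
class End2EndConfig:
    """Fixed problem sizes of the scaled-down run."""

    n_volumes: int = 20
    n_train: int = 14
    n_val: int = 3
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    geometry: ModelGeometry = field(default_factory=lambda: ModelGeometry(
        n_levels=2, convs_per_block=3, kernel=3, level_scale=2,
        channels=(16, 16), output_size=(16, 16, 16), finest_spacing=1.0,
    ))
    epochs: int = 20
    minibatches_per_epoch: int = 15      # 300 minibatches total
    minibatch_size: int = 12
    threshold: float = 0.5


def make_cases(cfg: End2EndConfig, seed: int
               ) -> tuple[list[TrainingCase], list[TrainingCase],
                          list[TrainingCase]]:
    """Generate and normalize the cohort; returns (train, val, test) splits."""
    spec = NormalizationSpec()
    cases = []
    for i in range(cfg.n_volumes):
        vol, truth = generate_phantom(replace_seed(cfg.phantom, seed + i))
        cases.append(TrainingCase(volume=normalize_intensity(vol, spec),
                                  labels=truth.label_map,
                                  name=f"case_{i:04d}"))
    n1, n2 = cfg.n_train, cfg.n_train + cfg.n_val
    return cases[:n1], cases[n1:n2], cases[n2:]


def _evaluate_split(net, cases: list[TrainingCase], threshold: float,
                    ecfg: ev.EvalConfig) -> dict:
    volumes = []
    for c in cases:
        pmap = predict_volume(net, c.volume)
        mask = threshold_probability(pmap, threshold)
        volumes.append((mask, c.labels, c.name))
    return ev.build_report(volumes, ecfg).summary


def run_strategy(cfg: End2EndConfig, strategy: str, seed: int,
                 splits=None, progress: bool = False) -> dict:
    """Train with one augmentation strategy and evaluate val + test splits."""
    if splits is None:
        splits = make_cases(cfg, seed)
    train_cases, val_cases, test_cases = splits
    tcfg = TrainConfig(
        minibatch_size=cfg.minibatch_size, epochs=cfg.epochs,
        minibatches_per_epoch=cfg.minibatches_per_epoch,
        augment=AugmentConfig(strategy=strategy), seed=seed,
    )
    net, log = train_model(train_cases, val_cases, cfg.geometry, tcfg,
                           progress=progress)
    ecfg = ev.EvalConfig()
    result = {
        "strategy": strategy,
        "best_val_dice": log.attrs["best_val_dice"],
        "best_epoch": log.attrs["best_epoch"],
        "final_train_loss": float(log.train_loss.iloc[-1]),
        "val": _evaluate_split(net, val_cases, cfg.threshold, ecfg),
        "test": _evaluate_split(net, test_cases, cfg.threshold, ecfg),
    }
    return result, net, log


def run_end2end(cfg_dict: dict, strategies: list[str], seed: int,
                out_dir: str | None = None, progress: bool = True) -> dict:
    """Run the pipeline for each strategy; returns (and writes) the summary."""
    overrides = dict(cfg_dict.get("end2end", {}))
    geometry = ModelGeometry(**cfg_dict["geometry"]) \
        if "geometry" in cfg_dict else End2EndConfig().geometry
    phantom_cfg = PhantomConfig(**cfg_dict.get("phantom", {}))
    cfg = End2EndConfig(geometry=geometry, phantom=phantom_cfg, **overrides)
    splits = make_cases(cfg, seed)
    summary = {"seed": seed, "config": {"n_volumes": cfg.n_volumes,
                                        "epochs": cfg.epochs,
                                        "minibatches_per_epoch":
                                            cfg.minibatches_per_epoch},
               "strategies": {}}
    for strategy in strategies:
        result, net, log = run_strategy(cfg, strategy, seed, splits=splits,
                                        progress=progress)
        summary["strategies"][strategy] = result
        if out_dir is not None:
            sdir = os.path.join(out_dir, strategy.replace("+", "_"))
            os.makedirs(sdir, exist_ok=True)
            net.save(os.path.join(sdir, "checkpoint.npz"))
            log.to_csv(os.path.join(sdir, "training_log.csv"), index=False)
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        with open(os.path.join(out_dir, "summary.json"), "w") as fh:
            json.dump(summary, fh, indent=2, default=float)
    return summary


__all__ = ["End2EndConfig", "make_cases", "run_strategy", "run_end2end"]
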