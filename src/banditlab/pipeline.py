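"""End-to-end experiment orchestration: simulate -> fit -> evaluate -> analyse.

An :class:`ExperimentConfig` fully determines an experiment; every output
artifact is stamped with the config hash and the global seed so reruns are
reproducible and attributable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import behaviour
from .cohort import CohortSpec, Dataset, build_dataset, save_dataset, simulate_block
from .fitting import TrainingConfig, evaluate_and_compare, train
from .hybrid_models import NetworkWeights, make_model, save_weights
from .interpret import closed_loop_latents, pca_states, decode_history

__all__ = ["ExperimentConfig", "run_experiment"]


@dataclass(frozen=True)
class ExperimentConfig:
    cohort: CohortSpec = field(default_factory=CohortSpec)
    models: tuple[str, ...] = ("simple_rl", "best_rl")
    training: TrainingConfig = field(default_factory=TrainingConfig)
    metrics: tuple[str, ...] = ("streaks", "cycles", "lzw")
    inspect_ops: tuple[str, ...] = ()
    seed: int = 0

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _provenance(config: ExperimentConfig) -> dict:
    return {"config_hash": config.config_hash(), "seed": config.seed}


def run_behaviour_metrics(blocks, metrics, seed: int = 0) -> dict:
    """Run the requested model-free metrics over a block list."""
    out: dict[str, object] = {}
    if "streaks" in metrics:
        out["mean_streak_length"] = behaviour.repeat_streaks(blocks)
    if "cycles" in metrics:
        out["mean_cyclic_responses"] = float(behaviour.cyclic_responses(blocks).mean())
    if "lzw" in metrics:
        ratios = [behaviour.compressibility_ratio(b, n_random=20, seed=seed + i).ratio
                  for i, b in enumerate(blocks)]
        out["mean_compressibility_ratio"] = float(np.mean(ratios))
    if "stay" in metrics:
        out["stay_table"] = behaviour.stay_vs_reward_change(blocks).to_dict("records")
    if "lagreg" in metrics:
        res = behaviour.lagged_choice_regression(blocks)
        out["lagged_regression"] = res.coefficients.to_dict("records")
    return out


def run_experiment(config: ExperimentConfig, outdir: str | Path) -> dict:
    """Execute the full pipeline, persisting every stage's outputs.

    Returns a report dict (also written to ``report.json``).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"provenance": _provenance(config), "stages": {}}
    stage_t0 = time.time()

    def mark(stage: str):
        nonlocal stage_t0
        report["stages"][stage] = round(time.time() - stage_t0, 2)
        stage_t0 = time.time()

    try:
        dataset = build_dataset(dataclasses.replace(config.cohort, seed=config.seed))
        save_dataset(dataset, outdir / "data")
        mark("simulate")

        fits = {}
        for name in config.models:
            model = make_model(name, hidden_size=config.training.hidden_size)
            cfg = dataclasses.replace(config.training, seed=config.seed)
            fit = train(model, dataset, cfg)
            fits[name] = (model, fit.params)
            save_weights(NetworkWeights(arch=name,
                                        hidden_size=config.training.hidden_size,
                                        params=fit.params, seed=config.seed),
                         outdir / f"weights_{name}.json")
        mark("fit")

        test_blocks = dataset.split_blocks("test")
        per_block, pairwise = evaluate_and_compare(fits, test_blocks)
        per_block.to_csv(outdir / "test_per_block.csv", index=False)
        pairwise.to_csv(outdir / "test_pairwise.csv", index=False)
        report["mean_test_accuracy"] = (
            per_block.groupby("model")["accuracy"].mean().to_dict())
        mark("evaluate")

        report["behaviour_data"] = run_behaviour_metrics(
            dataset.blocks, config.metrics, seed=config.seed)
        sim_metrics = {}
        for name, (model, params) in fits.items():
            sim_blocks = [simulate_block(model, params, dataset.schedules[b.block_id],
                                         seed=config.seed + i,
                                         participant_id=b.participant_id,
                                         block_id=b.block_id)
                          for i, b in enumerate(test_blocks)]
            sim_metrics[name] = run_behaviour_metrics(sim_blocks, config.metrics,
                                                      seed=config.seed)
        report["behaviour_simulated"] = sim_metrics
        mark("behaviour")

        if config.inspect_ops:
            for name, (model, params) in fits.items():
                if name != "memory_ann":
                    continue
                traj = closed_loop_latents(model, params, test_blocks)
                basis = pca_states(traj, min_explained=0.01)
                inspect_out: dict = {
                    "explained_variance_ratio":
                        basis.explained_variance_ratio.tolist()}
                if "decode" in config.inspect_ops:
                    inspect_out["history_coefficients"] = \
                        decode_history(traj, basis, max_lag=10).tolist()
                (outdir / f"inspect_{name}.json").write_text(
                    json.dumps(inspect_out))
            mark("inspect")
    except Exception as exc:
        report["error"] = {"stage": _next_stage(report), "message": str(exc)}
        (outdir / "report.json").write_text(json.dumps(report, indent=1, default=str))
        raise

    (outdir / "report.json").write_text(json.dumps(report, indent=1, default=str))
    return report


def _next_stage(report: dict) -> str:
    done = list(report["stages"])
    order = ["simulate", "fit", "evaluate", "behaviour", "inspect"]
    for stage in order:
        if stage not in done:
            return stage
    return "unknown"
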