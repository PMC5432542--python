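"""Evaluation protocols on synthetic scene batches.

These functions bundle the standard experiments used to characterise
the pipeline: an end-to-end density benchmark (train the counting
network on one batch of scenes, estimate densities on a disjoint batch,
score the mean relative error) and a per-object benchmark (held-out
RMSE of plants-per-object on low-density scenes).  Both are fully
seeded and run from scratch: scenes are rendered, segmented and
processed exactly as in production.
"""

from __future__ import annotations

import numpy as np

from .countmodel import (
    evaluate,
    predict_counts,
    recursive_feature_elimination,
    train_network,
)
from .density import aggregate_density, relative_error
from .objects import FEATURE_NAMES
from .pipeline import PipelineConfig
from .synth import batch_specs, generate_training_set

__all__ = [
    "default_config",
    "labeled_scene_batch",
    "end_to_end_density_benchmark",
    "per_object_rmse_benchmark",
    "oracle_density_check",
]

TRAIN_DENSITIES = (100.0, 200.0, 300.0, 400.0, 600.0)   # sowing ladder
LOW_DENSITIES = (100.0, 150.0, 200.0, 250.0, 300.0)


def default_config() -> PipelineConfig:
    """Pipeline configuration matching the generator's scene geometry."""
    return PipelineConfig(segment_length_mm=500.0)


def labeled_scene_batch(densities, seeds, config=None, **spec_overrides):
    """Render scenes, run the pipeline, and label objects with truth.

    Returns ``(table, records)`` from
    :func:`wheatdensity.synth.generate_training_set`.
    """
    config = config or default_config()
    specs = batch_specs(densities, seeds, **spec_overrides)
    return generate_training_set(specs, config)


def end_to_end_density_benchmark(
    seed: int,
    n_train: int = 50,
    n_test: int = 30,
    densities=TRAIN_DENSITIES,
    k_n: int = 2,
    rfe_reps: int = 5,
    config: PipelineConfig | None = None,
):
    """Train on one scene batch, score densities on a disjoint batch.

    The counting network (``k_n`` hidden nodes) is pruned by recursive
    feature elimination on the training objects, then applied to every
    test scene; per-scene density estimates are compared with the
    generator's exact plant density.  Returns a dict with the mean
    relative error (percent), per-scene details, the RFE trace and the
    final model.
    """
    config = config or default_config()
    rng = np.random.default_rng(seed)
    train_seeds = rng.integers(0, 2 ** 31, size=n_train)
    test_seeds = rng.integers(0, 2 ** 31, size=n_test)

    table_tr, _ = labeled_scene_batch(densities, train_seeds, config)
    train = table_tr[~table_tr["border_flag"]]   # border objects: predict only
    trace, model = recursive_feature_elimination(
        train[FEATURE_NAMES], train["true_count"], k_n=k_n,
        reps=rfe_reps, seed=int(rng.integers(0, 2 ** 31)),
    )

    table_te, records = labeled_scene_batch(densities, test_seeds, config)
    scenes = []
    for rec in records:
        sub = table_te[table_te.image_id == rec["image_id"]].copy()
        sub["pred_count"] = predict_counts(model, sub)
        est = aggregate_density(
            sub, config, n_rows=rec["result"].row_model.n_rows
        )
        err = relative_error(est.plants_per_m2, rec["density_true"])
        scenes.append(
            {
                "image_id": rec["image_id"],
                "sowing_density": rec["sowing_density"],
                "density_true": rec["density_true"],
                "density_est": est.plants_per_m2,
                "rel_err_pct": err,
                "n_rows": est.n_rows_counted,
            }
        )
    mean_err = float(np.mean([s["rel_err_pct"] for s in scenes]))
    return {
        "mean_rel_err_pct": mean_err,
        "scenes": scenes,
        "trace": trace,
        "model": model,
        "n_train_objects": int(len(table_tr)),
    }


def per_object_rmse_benchmark(
    seed: int,
    n_scenes: int = 40,
    densities=LOW_DENSITIES,
    k_n: int = 2,
    rfe_reps: int = 5,
    n_splits: int = 5,
    config: PipelineConfig | None = None,
):
    """Held-out plants-per-object RMSE on low-density scenes.

    Objects from the scene batch are pooled; features are pruned by RFE;
    then over ``n_splits`` random 90/10 splits the network is retrained
    on the 90 % and scored on the held-out 10 %.  Returns the mean RMSE
    and per-split reports.
    """
    config = config or default_config()
    rng = np.random.default_rng(seed)
    scene_seeds = rng.integers(0, 2 ** 31, size=n_scenes)
    table, _ = labeled_scene_batch(densities, scene_seeds, config)
    table = table[~table["border_flag"]].reset_index(drop=True)

    trace, _ = recursive_feature_elimination(
        table[FEATURE_NAMES], table["true_count"], k_n=k_n, reps=rfe_reps,
        seed=int(rng.integers(0, 2 ** 31)),
    )
    feats = trace.chosen_features
    X = table[feats].reset_index(drop=True)
    y = table["true_count"].to_numpy(dtype=float)

    reports = []
    n = len(y)
    n_test = max(1, int(round(0.1 * n)))
    for s in range(n_splits):
        perm = rng.permutation(n)
        te, tr = perm[:n_test], perm[n_test:]
        model = train_network(X.iloc[tr], y[tr], k_n=k_n,
                              seed=int(rng.integers(0, 2 ** 31)))
        reports.append(evaluate(model, X.iloc[te], y[te]))
    return {
        "rmse_mean": float(np.mean([r.rmse for r in reports])),
        "r2_mean": float(np.mean([r.r2 for r in reports])),
        "bias_mean": float(np.mean([r.bias for r in reports])),
        "reports": reports,
        "chosen_features": feats,
        "n_objects": n,
    }


def oracle_density_check(
    seed: int,
    densities=TRAIN_DENSITIES,
    n_scenes: int = 5,
    config: PipelineConfig | None = None,
):
    """Estimated vs true density with ground-truth counts substituted.

    With perfect per-object counts, aggregation must reproduce the
    generator density to floating-point precision whenever no plant is
    lost by segmentation or row detection.  Returns per-scene pairs.
    """
    config = config or default_config()
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2 ** 31, size=n_scenes)
    table, records = labeled_scene_batch(densities, seeds, config)
    out = []
    for rec in records:
        sub = table[table.image_id == rec["image_id"]].copy()
        sub["pred_count"] = sub["true_count"]
        est = aggregate_density(
            sub, config, n_rows=rec["result"].row_model.n_rows
        )
        out.append(
            {
                "image_id": rec["image_id"],
                "density_true": rec["density_true"],
                "density_oracle": est.plants_per_m2,
                "n_lost_plants": rec["n_lost_plants"],
                "n_rows": est.n_rows_counted,
            }
        )
    return out
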