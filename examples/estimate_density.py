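"""End-to-end plant density estimation on a held-out synthetic scene.

Trains the counting network on one batch of scenes, then runs the full
pipeline (segmentation, row detection, object features, per-object
counts, aggregation) on a new scene and compares the estimated
plants/m2 against the generator's exact ground truth.
"""

from wheatdensity import (
    FEATURE_NAMES,
    SceneSpec,
    generate_scene,
    relative_error,
    run_pipeline,
    train_network,
)
from wheatdensity.benchmarks import default_config, labeled_scene_batch

config = default_config()
table, _ = labeled_scene_batch(densities=(100.0, 250.0, 400.0),
                               seeds=(31, 32, 33, 34), config=config)
model = train_network(table[FEATURE_NAMES], table["true_count"],
                      k_n=2, seed=0)
print(f"counting network trained on {len(table)} labelled objects")

spec = SceneSpec(sowing_density_seeds_m2=300.0, row_angle_deg=89.0, seed=99)
rgb, truth = generate_scene(spec)
est, objects, result = run_pipeline(rgb, model, config,
                                    resolution_mm=truth.resolution_mm)
print(f"held-out scene: {truth.n_plants} plants on {est.n_rows_counted} rows")
print(f"objects found: {est.n_objects}; summed continuous counts: "
      f"{est.sum_counts:.1f}")
print(f"estimated density: {est.plants_per_m2:.1f} plants/m2")
print(f"true density:      {truth.density_true:.1f} plants/m2")
print(f"relative error:    "
      f"{relative_error(est.plants_per_m2, truth.density_true):.1f} % "
      "(|estimate - truth| / truth)")
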