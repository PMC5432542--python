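import numpy as np
import pytest

from wheatdensity.pipeline import PipelineConfig, process_image
from wheatdensity.synth import SceneSpec, generate_scene, match_counts


@pytest.fixture(scope="session")
def scene300():
    """One mid-density scene with slightly tilted rows, plus its truth."""
    spec = SceneSpec(sowing_density_seeds_m2=300.0, row_angle_deg=88.5, seed=3)
    rgb, truth = generate_scene(spec)
    return rgb, truth


@pytest.fixture(scope="session")
def processed300(scene300):
    """The scene run through the geometric pipeline, with truth counts."""
    rgb, truth = scene300
    config = PipelineConfig(segment_length_mm=500.0)
    result = process_image(rgb, config, aux_label=truth.label,
                           resolution_mm=truth.resolution_mm)
    counts, lost = match_counts(result.aux_label, result.object_labels)
    for obj in result.objects:
        obj.true_count = counts.get(obj.object_id, 0)
    return {"rgb": rgb, "truth": truth, "result": result,
            "counts": counts, "n_lost": lost, "config": config}


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
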