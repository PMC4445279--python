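import numpy as np
import pytest

from puncta3d.pipeline import run_pipeline, train_chain_model
from puncta3d.synth import SceneParams, generate_scene, sample_training_rois


@pytest.fixture(scope="session")
def tiny_scene():
    """A small scene that keeps per-test generation cheap."""
    params = SceneParams(shape=(10, 96, 96), n_synapses=12, clump_fraction=0.25,
                         artifact_count=2, seed=7)
    syn, morph, scene = generate_scene(params)
    return syn, morph, scene


@pytest.fixture(scope="session")
def benchmark_scene():
    """The default benchmark scene: 256x256x16, 150 puncta, 30 % clumped."""
    syn, morph, scene = generate_scene(SceneParams())
    return syn, morph, scene


@pytest.fixture(scope="session")
def benchmark_model(benchmark_scene):
    _, _, scene = benchmark_scene
    rois = sample_training_rois(scene, 25, 25, seed=1)
    return train_chain_model(rois, seed=1)


@pytest.fixture(scope="session")
def benchmark_result(benchmark_scene, benchmark_model):
    syn, morph, scene = benchmark_scene
    return run_pipeline(syn, morphology=morph, model=benchmark_model,
                        reference=scene.true_centers)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
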