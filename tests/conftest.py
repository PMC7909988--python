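import pytest

from cgom.mapping import MappingConfig, map_recording
from cgom.segmentation import OracleSegmenter
from cgom.synthetic import GazeSimConfig, default_scene_spec, render_scene, simulate_gaze


@pytest.fixture(scope="session")
def small_scene():
    """A short default scene (5 syringes + 1 bottle) with its dataset."""
    spec = default_scene_spec(n_frames=1800, seed=7)
    source, dataset = render_scene(spec)
    return spec, source, dataset


@pytest.fixture(scope="session")
def noiseless_recording(small_scene):
    """100 zero-noise fixations plus their ground-truth mapping."""
    spec, _, dataset = small_scene
    config = GazeSimConfig(n_fixations=100, noise_sd_px=0.0, seed=11)
    events, truth = simulate_gaze(spec, dataset, config)
    return events, truth


@pytest.fixture(scope="session")
def oracle_mapping(small_scene, noiseless_recording):
    spec, source, dataset = small_scene
    events, _ = noiseless_recording
    config = MappingConfig(aoi_labels=spec.label_set)
    return map_recording(events, OracleSegmenter(dataset), source, config, spec.meta)
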