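import numpy as np
import pytest

from cytoiex import pipeline, stainseg, synthgen

SCENE_POOL_SEEDS = tuple(range(101, 111))
SCENE_NUCLEI = 20
SCENE_CANVAS = (1024, 1024)


@pytest.fixture(scope="session")
def scene_pool():
    """Ten mixed-class scenes at the default study conditions."""
    return [
        synthgen.generate_scene("mixed", SCENE_NUCLEI, SCENE_CANVAS, seed)
        for seed in SCENE_POOL_SEEDS
    ]


@pytest.fixture(scope="session")
def segmented_pool(scene_pool):
    """(scene, stain, roi, nuclei) tuples for the scene pool."""
    out = []
    for scene in scene_pool:
        stain, roi, nuclei = stainseg.segment_image(scene.image)
        out.append((scene, stain, roi, nuclei))
    return out


@pytest.fixture(scope="session")
def pooled_feature_table(scene_pool):
    """Labeled feature table over all segmented, truth-matched cells."""
    import pandas as pd

    config = pipeline.PipelineConfig()
    tables = [pipeline.scene_feature_table(s, config) for s in scene_pool]
    return pd.concat([t for t in tables if not t.empty], ignore_index=True)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
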