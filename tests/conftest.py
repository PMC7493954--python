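import dataclasses

import pytest
from hypothesis import settings

from cornsoy.pipeline import default_config, run
from cornsoy.synth import SceneLayout

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")

#: Fixed seed for the full-scale study-condition runs shared across tests.
STUDY_SEED = 7


def tiny_config(seed=0, **layout_overrides):
    """A scaled-down configuration for fast unit tests: 24x24 pixels,
    3 years, 50 trees. Study-condition tests use ``default_config``."""
    cfg = default_config(seed=seed)
    layout = dataclasses.replace(
        cfg.scene.layout, width=24, height=24, **layout_overrides
    )
    scene = dataclasses.replace(cfg.scene, layout=layout)
    return dataclasses.replace(
        cfg,
        scene=scene,
        years=(2016, 2017, 2018),
        train_years=(2017, 2018),
        test_years=(2016,),
        mask_years=(2016,),
        n_trees=50,
    )


@pytest.fixture(scope="session")
def study_config():
    """The default study conditions with a fixed seed."""
    return default_config(seed=STUDY_SEED)


@pytest.fixture(scope="session")
def study_report(study_config):
    """One full run under the default study conditions, shared across tests."""
    return run(study_config)
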