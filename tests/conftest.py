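import numpy as np
import pytest

from stabeam.pipeline import RunConfig, acquire, beamform_regions, evaluate


@pytest.fixture(scope="session")
def toy_run():
    """One full toy-phantom pipeline run shared across the suite.

    Returns the cube, the study setup, the per-region complex images /
    weight maps, and the metrics report.
    """
    cfg = RunConfig(preset="toy", rng_seed=1)
    setup = cfg.resolved_setup()
    cube = acquire(cfg)
    images, wmaps, counters = beamform_regions(
        cube, setup.regions, setup.beamformer, cfg.methods
    )
    report = evaluate(images, setup.rois, depth_compensation=True)
    return {
        "cube": cube,
        "setup": setup,
        "images": images,
        "weight_maps": wmaps,
        "counters": counters,
        "report": report,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
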