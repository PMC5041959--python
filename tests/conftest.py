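import numpy as np
import pytest

from emtscreen.simulate import ImagingParams, SimulationConfig, simulate_screen


@pytest.fixture(scope="session")
def small_screen():
    """A 12-compound simulated screen shared by the slower tests."""
    cfg = SimulationConfig(n_compounds=12, rng_seed=7)
    truth, layouts, features = simulate_screen(cfg)
    return cfg, truth, layouts, features


@pytest.fixture(scope="session")
def rendered_site():
    """One rendered mesenchymal-state site with its drawn-object truth."""
    from emtscreen.simulate import render_well_images

    rng = np.random.default_rng(11)
    (mset, truth), = render_well_images(8, 30.0, 24.0, 18.0,
                                        ImagingParams(), rng=rng)
    return mset, truth
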