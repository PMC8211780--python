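import pytest
from hypothesis import settings

import gsvfuse as g

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_config():
    """Study-condition generator settings on a small grid."""
    return g.LandscapeConfig(grid_rows=60, grid_cols=60, seed=11)


@pytest.fixture(scope="session")
def landscape(default_config):
    return g.generate_landscape(default_config)


@pytest.fixture(scope="session")
def plots(landscape, default_config):
    return g.sample_plots(landscape, 1500, default_config, seed=12)


@pytest.fixture(scope="session")
def records(plots, landscape):
    """Screened calibration table under default rules."""
    matched = g.match_plots_to_pixels(plots, landscape)
    kept, _ = g.screen(matched, g.ScreeningRules(), map_epoch=landscape.map_epoch)
    return kept


@pytest.fixture(scope="session")
def clean_setup():
    """Noiseless landscape + plots: records satisfy the model mean exactly."""
    cfg = g.noiseless_config(grid_rows=50, grid_cols=50, seed=5)
    L = g.generate_landscape(cfg)
    plots = g.sample_plots(L, 800, cfg, seed=6)
    matched = g.match_plots_to_pixels(plots, L)
    return cfg, L, matched
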