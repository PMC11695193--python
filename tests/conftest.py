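import pytest

from wheatcast.containers import FEATURE_ORDER
from wheatcast.model import BCBLConfig
from wheatcast.preprocess import build_samples
from wheatcast.scene import SceneConfig, simulate_county_dataset


@pytest.fixture(scope="session")
def fit_config():
    """Training configuration used for all model fits in the suite."""
    return BCBLConfig(max_epochs=100, patience=12)


@pytest.fixture(scope="session")
def mini_scene():
    """Miniature study region: 12 counties x 4 years with a drought year."""
    cfg = SceneConfig(
        n_years=4, n_counties=12, grid_rows=20, grid_cols=20,
        drought_years=(0,), drought_severity=0.7, seed=7,
    )
    return simulate_county_dataset(cfg)


@pytest.fixture(scope="session")
def mini_samples(mini_scene):
    return build_samples(mini_scene.county_series, mini_scene.yields, FEATURE_ORDER)


@pytest.fixture(scope="session")
def skill_scene():
    """40 counties x 10 years with a drought year routed through SIF."""
    cfg = SceneConfig(
        n_years=10, n_counties=40, grid_rows=32, grid_cols=32,
        drought_years=(0,), drought_severity=0.7, seed=1,
    )
    return simulate_county_dataset(cfg)


@pytest.fixture(scope="session")
def skill_samples(skill_scene):
    return build_samples(skill_scene.county_series, skill_scene.yields, FEATURE_ORDER)
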