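import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from aarspatial import AARPatternModel, simulate_study

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

#: a fast, small study used by unit tests (not the acceptance conditions)
SMALL_SIM = dict(
    n_genes=300,
    grid_rows=12,
    grid_cols=14,
    n_aar_genes=10,
    n_marker_genes_per_region=5,
    mito_fraction=0.02,
    n_bad_spots=6,
    seed=42,
)


@pytest.fixture(scope="session")
def small_bundle():
    return simulate_study(**SMALL_SIM)


@pytest.fixture(scope="session")
def default_bundle():
    """One study at the generator's default conditions."""
    return simulate_study(seed=11)


@pytest.fixture(scope="session")
def default_fit(default_bundle):
    """Fitted AAR model on the default study (hippocampal regions)."""
    model = AARPatternModel.from_samples(
        default_bundle.samples, default_bundle.regions
    )
    results = model.fit(regions=["dendritic", "somatic"])
    return model, results


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
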