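import numpy as np
import pytest

try:
    from hypothesis import HealthCheck, settings

    settings.register_profile(
        "repro",
        deadline=None,
        derandomize=True,
        max_examples=50,
        suppress_health_check=[HealthCheck.too_slow],
    )
    settings.load_profile("repro")
except ImportError:  # pragma: no cover
    pass

from phantom_oracles import clean_design, exact_config, make_grid


@pytest.fixture(scope="session")
def small_clean():
    """One clean 5-cell phantom with foci, plus its exact protocol."""
    design = clean_design(seed=3, cells=5)
    stacks, truth = make_grid(design)
    (_, grid), = stacks.items()
    return design, grid, truth, exact_config(design)


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
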