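import numpy as np
import pytest

from acornhrd import RunConfig, baseline_from_counts
from acornhrd import simulate as sim
from acornhrd.genome import GenomeLayout, build_window_grid, mask_windows


@pytest.fixture(scope="session")
def tiny_layout():
    """One 40 Mb chromosome split at 20 Mb, no exclusions."""
    return sim.toy_layout(n_chromosomes=1, chromosome_length=40_000_000, arm_split=20_000_000)


@pytest.fixture(scope="session")
def tiny_config(tiny_layout):
    return sim.SimulationConfig(layout=tiny_layout, depth=100.0, n_baseline=8)


@pytest.fixture(scope="session")
def tiny_grid(tiny_config):
    return sim.make_simulation_grid(tiny_config, seed=11)


@pytest.fixture(scope="session")
def tiny_panel(tiny_config, tiny_grid):
    return sim.simulate_baseline_panel(tiny_config, tiny_grid, seed=12)


@pytest.fixture(scope="session")
def tiny_baseline(tiny_panel, tiny_grid):
    return baseline_from_counts(tiny_panel, tiny_grid, RunConfig())


@pytest.fixture
def three_window_grid():
    """Minimal 3-window stepped grid (200 kb chromosome, 100 kb / 50 kb)."""
    layout = GenomeLayout((("chr1", 200_000),), {}, frozenset())
    return mask_windows(build_window_grid(layout, 100_000, 50_000))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
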