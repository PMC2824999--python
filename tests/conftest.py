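import numpy as np
import pytest

from brachymc import engine
from brachymc.transport import RunConfig

# Session-scoped simulation runs shared by the statistical and acceptance
# tests.  History counts trade statistical resolution against wall time:
# the transverse-axis quantities they feed have sub-1% statistical
# uncertainty, well inside the tolerances asserted on them.


@pytest.fixture(scope="session")
def air_run():
    """Point-detector air-kerma run in the 5 m air sphere."""
    return engine.run(RunConfig(mode="airkerma", phantom="air",
                                n_histories=1_000_000, seed=20251))


@pytest.fixture(scope="session")
def vacuum_run():
    """Same scoring with a vacuum sphere (scatter-free reference)."""
    return engine.run(RunConfig(mode="airkerma", phantom="vacuum",
                                n_histories=500_000, seed=20254))


@pytest.fixture(scope="session")
def water_run():
    """Dose run in the 100 cm water cylinder."""
    return engine.run(RunConfig(mode="dose", phantom="water",
                                n_histories=4_000_000, seed=20252))


@pytest.fixture(scope="session")
def pmma_run():
    """Dose run in the 100 cm PMMA cylinder."""
    return engine.run(RunConfig(mode="dose", phantom="pmma",
                                n_histories=2_500_000, seed=20253))


@pytest.fixture
def rng():
    return np.random.default_rng(987654321)
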