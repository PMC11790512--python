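import numpy as np
import pytest

from earbench import (CochleaModel, CoupledEar, ProsthesisSpec,
                      build_default_config, reconstruct)

#: the default analysis grid (60 log-spaced points, 100 Hz - 10 kHz)
FREQS = build_default_config().frequency.frequencies()


@pytest.fixture()
def config():
    """A fresh default configuration (mutable per test)."""
    return build_default_config()


@pytest.fixture(scope="session")
def default_config():
    """Shared immutable default configuration (do not mutate)."""
    return build_default_config()


@pytest.fixture(scope="session")
def natural_sweep(default_config):
    """Coupled natural-ear sweep on the default grid (shared, read-only)."""
    return CoupledEar(default_config).sweep(FREQS)


@pytest.fixture(scope="session")
def sealed06_sweep(default_config):
    spec = ProsthesisSpec(piston_diameter_m=0.6e-3, gap_state="sealed")
    return reconstruct(default_config, spec).sweep(FREQS)


@pytest.fixture(scope="session")
def sealed07_sweep(default_config):
    spec = ProsthesisSpec(piston_diameter_m=0.7e-3, gap_state="sealed")
    return reconstruct(default_config, spec).sweep(FREQS)


@pytest.fixture(scope="session")
def open06_sweep(default_config):
    spec = ProsthesisSpec(piston_diameter_m=0.6e-3, gap_state="open")
    return reconstruct(default_config, spec).sweep(FREQS)


@pytest.fixture(scope="session")
def small_cochlea(default_config):
    """Coarse standalone cochlea for cheap per-frequency checks."""
    return CochleaModel(default_config, n_sections=160)
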