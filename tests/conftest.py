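import numpy as np
import pytest

from fabprofile import (
    PipelineConfig,
    SimulatedClone,
    SimulationParams,
    render_run,
)


@pytest.fixture(scope="session")
def default_config() -> PipelineConfig:
    """The published timsTOF processing settings."""
    return PipelineConfig()


@pytest.fixture(scope="session")
def small_config() -> PipelineConfig:
    """A reduced grid (narrower mass window, envelope-matched charges) that
    keeps per-test deconvolutions fast without changing the algorithms."""
    return PipelineConfig(
        mz_low=1000.0,
        mz_high=2400.0,
        mass_low=46000.0,
        mass_high=50000.0,
        charge_min=22,
        charge_max=42,
        roi_start=10.0,
        roi_end=10.6,
    )


def single_clone_spectrum(mass: float, config: PipelineConfig, seed: int = 0,
                          abundance: float = 1e5):
    """Noiseless apex-scan spectrum of one clone (shared fixture helper)."""
    clone = SimulatedClone(true_mass=mass, rt_center=10.05, rt_sigma=0.1,
                           abundance=abundance)
    params = SimulationParams(n_clones=1, seed=seed, rt_start=10.0, rt_end=10.1)
    run = render_run([clone], params, config)
    return run.scans[3]  # scan at the elution apex


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240425)
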