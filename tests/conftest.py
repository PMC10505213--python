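import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")

from doct.phantom import (
    LABELS,
    PhantomSpec,
    RegionDynamics,
    generate_phantom,
    scenario_library,
)
from doct.metrics import compute_dynamics_volume
from doct.protocol import ScanProtocol
from doct.volume import to_db


def tiny_protocol(n_repeats: int = 32, dt_ms: float = 204.8, ny: int = 8) -> ScanProtocol:
    return ScanProtocol(
        n_regions=1,
        locations_per_region=ny,
        n_repeats=n_repeats,
        frame_repeat_time_ms=dt_ms,
        pixel_size_x_mm=0.02,
        pixel_size_y_mm=0.02,
        pixel_size_z_mm=0.02,
    )


@pytest.fixture(scope="session")
def control_phantom():
    """One mcf7_control phantom run through the full dynamics pipeline."""
    spec = scenario_library("mcf7_control", seed=11)
    volume, labels = generate_phantom(spec)
    maps = compute_dynamics_volume(to_db(volume))
    return spec, labels, maps


@pytest.fixture
def two_region_spec():
    """Small core+rim phantom factory with overridable region dynamics."""

    def make(core: RegionDynamics, rim: RegionDynamics, seed: int = 0, **kwargs):
        defaults = dict(
            grid_shape=(16, 32, 32),
            core_radius_mm=0.12,
            rim_radius_mm=0.2,
            regions=(core, rim),
            plate_thickness_vox=0,
            noise_floor_db=None,
            protocol=tiny_protocol(ny=16),
            seed=seed,
        )
        defaults.update(kwargs)
        return PhantomSpec(**defaults)

    return make
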