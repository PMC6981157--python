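import numpy as np
import pytest

from callusmech.phantom import (
    HealingLoading,
    HealingRule,
    PhantomGeometry,
    build_phantom,
    simulate_healing,
)


@pytest.fixture(scope="session")
def small_geom():
    # ~0.5 x 0.5 x 0.67 mm grid; gap of 20 slices (0.21 mm)
    return PhantomGeometry(
        grid_shape=(48, 48, 64),
        voxel_size=10.5,
        outer_major_axis=0.42,
        outer_minor_axis=0.32,
        cortical_thickness=0.10,
        gap_length=0.21,
    )


@pytest.fixture(scope="session")
def small_phantom(small_geom):
    return build_phantom(small_geom)


@pytest.fixture(scope="session")
def fast_loading():
    return HealingLoading(
        mode="displacement", axial_displacement=0.09, fe_coarsen=4, fe_tolerance=1e-6
    )


@pytest.fixture(scope="session")
def sim_series(small_phantom, fast_loading):
    """Three healing steps with mild flip noise and unlimited conduction."""
    rule = HealingRule(
        strain_threshold_form=0.30,
        flip_noise=0.02,
        conduction_radius=np.inf,
        maturation_rate=150.0,  # lets early deposits cross the 720 rung by frame 3
        rng_seed=11,
    )
    frames, log = simulate_healing(small_phantom, rule, fast_loading, n_steps=3)
    return frames, log, rule
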