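import numpy as np
import pytest

from fetalflow import (
    PhantomConfig,
    generate_pseudo_spiral_trajectory,
    make_phantom,
    simulate_acquisition,
    simulate_triggers,
)


@pytest.fixture(scope="session")
def scene16():
    """Small multi-frame scene for operator/recon tests."""
    return make_phantom(PhantomConfig(matrix_size=(16, 16, 16), n_coils=2))


@pytest.fixture(scope="session")
def static_scene16():
    """Single-frame (static flow) scene: full sampling is possible per frame."""
    return make_phantom(
        PhantomConfig(matrix_size=(16, 16, 16), n_coils=2, n_frames=1,
                      waveform=np.array([1.0]))
    )


@pytest.fixture(scope="session")
def full_ks16(static_scene16):
    """Fully sampled, noiseless, motionless acquisition of the static scene."""
    traj = generate_pseudo_spiral_trajectory((16, 16, 16), r=1, tr=0.001)
    trig = simulate_triggers(150, 0.0, traj.time[-1] + 1.0, seed=0)
    return simulate_acquisition(static_scene16, traj, None, trig, noise_sd=0.0)
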