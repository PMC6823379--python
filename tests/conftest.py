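import numpy as np
import pytest

from poreflux import BoxGeometry, Frame, IonSpecies, Trajectory


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def salt_species():
    return (IonSpecies("K+", +1, 2.54, 2),
            IonSpecies("CL-", -1, 2.45, 2))


def make_scripted_trajectory(z_paths, box_z=10.0, dt=0.1, species=None,
                             species_index=None, velocities=False):
    """Trajectory from explicit per-particle z paths (list of arrays).

    x, y are held at box center; positions get wrapped by the Frame
    constructor.  Used to script exact crossing / occupancy scenarios.
    """
    z = np.asarray(z_paths, dtype=float)  # (n_particles, n_frames)
    n, f = z.shape
    box = BoxGeometry(5.0, 5.0, box_z)
    if species is None:
        species = (IonSpecies("K+", +1, 2.54, n),)
        species_index = np.zeros(n, dtype=int)
    frames = []
    for k in range(f):
        pos = np.column_stack([np.full(n, 2.5), np.full(n, 2.5), z[:, k]])
        vel = None
        if velocities:
            prev = z[:, k - 1] if k else z[:, k]
            vel = np.column_stack([np.zeros(n), np.zeros(n),
                                   (z[:, k] - prev) / dt])
        frames.append(Frame(time=(k + 1) * dt, box=box,
                            species_index=np.asarray(species_index),
                            position=pos, velocity=vel))
    return Trajectory(species, frames)
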