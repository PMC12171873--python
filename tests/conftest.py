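import numpy as np
import pytest

from nmsm.trajectory_io import Atom, Trajectory


@pytest.fixture
def three_atom_traj():
    """3 atoms, 5 identical frames."""
    atoms = [
        Atom("N", "GLY", 1, "A", "N"),
        Atom("CA", "GLY", 1, "A", "C"),
        Atom("C", "GLY", 1, "A", "C"),
    ]
    frame = np.array([[0.0, 0.0, 0.0], [1.5, 0.0, 0.0], [2.1, 1.2, 0.0]])
    coords = np.repeat(frame[None], 5, axis=0)
    return Trajectory(atoms, coords, frame_interval=0.1)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
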