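import warnings

import numpy as np
import pandas as pd
import pytest

from loopdyn.trajectory import TrajectoryEnsemble

warnings.filterwarnings("ignore", module="MDAnalysis")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_ensemble(coords, names, resids, resnames=None, times=None,
                  elements=None):
    """Build a TrajectoryEnsemble from raw arrays (test scaffolding)."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim == 2:
        coords = coords[None, :, :]
    n_atoms = coords.shape[1]
    if resnames is None:
        resnames = ["ALA"] * n_atoms
    if elements is None:
        elements = [n[0] for n in names]
    from loopdyn.trajectory import ATOMIC_MASSES
    atoms = pd.DataFrame({
        "name": names, "resid": resids, "resname": resnames,
        "element": elements,
        "mass": [ATOMIC_MASSES.get(e, 12.0) for e in elements],
    })
    if times is None:
        times = np.arange(coords.shape[0], dtype=float)
    return TrajectoryEnsemble(atoms=atoms, frames=coords, times=times)


@pytest.fixture
def hexagon_ensemble():
    """A PHE-like residue: regular hexagon ring centred at the origin plus a
    target S atom at (0, 0, 4)."""
    ring = [[np.cos(k * np.pi / 3), np.sin(k * np.pi / 3), 0.0] for k in range(6)]
    coords = ring + [[0.0, 0.0, 4.0]]
    names = ["CG", "CD1", "CE1", "CZ", "CE2", "CD2", "SG"]
    resids = [70] * 6 + [109]
    resnames = ["PHE"] * 6 + ["CYS"]
    elements = ["C"] * 6 + ["S"]
    return make_ensemble(coords, names, resids, resnames, elements=elements)


def random_rigid_motion(rng):
    """A uniformly random proper rotation matrix and a random translation."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    rot = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])
    return rot, rng.normal(0.0, 20.0, 3)
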