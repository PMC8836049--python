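"""Shared fixtures: small synthetic structures and trajectories."""

from __future__ import annotations

import numpy as np
import pytest

from crysdyn.io_model import MAINCHAIN_ATOMS, Atom, Structure, Trajectory


def chains_to_structure(chains, resname="ALA"):
    """Mainchain-only Structure from build_chain-style dicts (one per segment)."""
    atoms, coords = [], []
    serial = 0
    res = 0
    for chain in chains:
        for i in range(chain["N"].shape[0]):
            res += 1
            for name in MAINCHAIN_ATOMS:
                serial += 1
                atoms.append(Atom(serial, name, name[0], res, resname, "A", res))
                coords.append(chain[name][i])
    return Structure(atoms, [np.array(coords)])


def point_structure(positions, resname="GLY", atom_name="CA"):
    """One single-atom residue per position."""
    positions = np.asarray(positions, dtype=float)
    atoms = [
        Atom(i + 1, atom_name, "C", i + 1, resname, "A", i + 1)
        for i in range(len(positions))
    ]
    return Structure(atoms, [positions])


def static_trajectory(structure, n_frames=5, dt_ns=0.25):
    coords = np.repeat(structure.coords(0)[None], n_frames, axis=0)
    return Trajectory(structure, np.arange(n_frames) * dt_ns, coords)


@pytest.fixture
def toy_two_domain():
    from crysdyn.synthetic_data import build_toy_two_domain

    return build_toy_two_domain(4, 6)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
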