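"""Shared fixtures: expensive detections are computed once per session."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from rnapocket.fixtures import make_shell_structure, make_toy_complex
from rnapocket.pocket_detection import detect_pockets
from rnapocket.structure_io import AtomRecord


@pytest.fixture(scope="session")
def shell_fixture():
    """Open-mouth shell pseudo-structure with its analytic cavity volume."""
    model, analytic = make_shell_structure(cavity_radius=8.0, mouth_width=2.0)
    return model, analytic


@pytest.fixture(scope="session")
def shell_pockets(shell_fixture):
    """Pockets detected on the shell fixture at the default 0.5 Å grid."""
    model, _ = shell_fixture
    return detect_pockets(model, spacing=0.5)


@pytest.fixture(scope="session")
def shell_pockets_coarse(shell_fixture):
    model, _ = shell_fixture
    return detect_pockets(model, spacing=1.0)


@pytest.fixture(scope="session")
def toy_complex():
    return make_toy_complex(n_nucleotides=12, ligand_size=5, seed=3)


@pytest.fixture()
def shell_with_ligand(shell_fixture):
    """Shell fixture with one ligand atom embedded at the cavity center."""
    model, analytic = shell_fixture
    lig = AtomRecord(
        serial=10_000,
        element="C",
        atom_name="C1",
        coords=np.zeros(3),
        residue_name="LIG",
        residue_index=5000,
        chain_id="B",
        is_hetero=True,
        vdw_radius=1.7,
    )
    return (
        dataclasses.replace(model, atoms=model.atoms + [lig], ligand_atoms=[lig]),
        analytic,
    )


def random_triangle_points(n: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform points in the NPR triangle (rod (0,1), sphere (1,1), disc (.5,.5))."""
    a = np.array([0.0, 1.0])
    b = np.array([1.0, 1.0])
    c = np.array([0.5, 0.5])
    u = rng.random((n, 2))
    flip = u.sum(axis=1) > 1.0
    u[flip] = 1.0 - u[flip]
    return a + u[:, :1] * (b - a) + u[:, 1:] * (c - a)
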