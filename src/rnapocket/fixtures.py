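"""Synthetic test fixtures with analytically known answers.

Three families of fixtures make every pipeline stage testable without any
external data:

* **analytic voxel shapes** (ball, rod/cuboid, disc/cylinder, ellipsoid)
  whose expected NPR coordinates come from closed-form solid-body moments,
  e.g. a cuboid with sides (a, b, c) has moments ∝ (b²+c², a²+c², a²+b²)/12;
* **shell pseudo-structures**: carbon pseudo-atoms on a sphere with a
  circular mouth, enclosing a cavity of known analytic volume — a
  ground-truth pocket for the two-probe detector;
* **toy RNA–ligand complexes**: minimal pseudo-nucleotides (one P, one N
  atom each) with a ligand placed so the true < 4 Å binding set is known at
  construction time.

All expected values are computed here from closed forms or brute-force
scans; nothing is derived from the detection/descriptor code under test.
The pseudo-structures are deliberately non-physical (no nucleotide
geometry): they exercise distance and voxel logic only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .pocket_detection import VoxelGrid
from .structure_io import AtomRecord, MolecularModel, vdw_radius

__all__ = [
    "ShapeFixture",
    "FixtureIntegrityError",
    "make_ball",
    "make_rod",
    "make_disc",
    "make_ellipsoid",
    "make_shell_structure",
    "make_toy_complex",
    "write_all_fixtures",
]

_CARBON_R = vdw_radius("C")


class FixtureIntegrityError(ValueError):
    """A generated fixture violates its own construction guarantees."""


@dataclass
class ShapeFixture:
    """A voxel mask plus its closed-form expected values."""

    name: str
    mask: VoxelGrid
    expected_npr: tuple[float, float]
    analytic_volume: float | None  # Å³, None where not meaningful
    tolerance: float  # |computed − expected| bound for NPR components


def _grid_for(dims: tuple[int, int, int], spacing: float = 1.0) -> np.ndarray:
    return np.zeros(dims, dtype=bool)


def _centered_coords(dims: tuple[int, int, int]) -> tuple[np.ndarray, ...]:
    """Voxel-center coordinates relative to the box center, in voxel units."""
    return np.meshgrid(
        *(np.arange(d) + 0.5 - d / 2.0 for d in dims), indexing="ij"
    )


def _npr_from_moments(moments: tuple[float, float, float]) -> tuple[float, float]:
    m = sorted(moments)
    return m[0] / m[2], m[1] / m[2]


def make_ball(radius: int, spacing: float = 1.0) -> ShapeFixture:
    """Solid ball of the given radius in voxels; expected NPR (1, 1)."""
    if radius < 1:
        raise ValueError("radius must be >= 1 voxel")
    dims = (2 * radius + 3,) * 3
    x, y, z = _centered_coords(dims)
    occ = x**2 + y**2 + z**2 <= radius**2
    vol = 4.0 / 3.0 * math.pi * (radius * spacing) ** 3
    return ShapeFixture("ball", VoxelGrid(np.zeros(3), spacing, occ), (1.0, 1.0), vol, 0.02)


def make_rod(a: int, b: int, c: int, spacing: float = 1.0) -> ShapeFixture:
    """Solid cuboid a×b×c voxels; expected NPR from (b²+c², a²+c², a²+b²)."""
    if min(a, b, c) < 1:
        raise ValueError("all cuboid sides must be >= 1 voxel")
    occ = np.ones((a, b, c), dtype=bool)
    pad = np.pad(occ, 1)
    expected = _npr_from_moments((b * b + c * c, a * a + c * c, a * a + b * b))
    vol = a * b * c * spacing**3
    return ShapeFixture("rod", VoxelGrid(np.zeros(3), spacing, pad), expected, vol, 0.02)


def make_disc(radius: int, height: int, spacing: float = 1.0) -> ShapeFixture:
    """Solid cylinder; moments ∝ (R²/2, (3R²+h²)/12, (3R²+h²)/12)."""
    if radius < 1 or height < 1:
        raise ValueError("radius and height must be >= 1 voxel")
    dims = (2 * radius + 3, 2 * radius + 3, height + 2)
    x, y, z = _centered_coords(dims)
    occ = (x**2 + y**2 <= radius**2) & (np.abs(z) <= height / 2.0)
    iz = radius**2 / 2.0
    ixy = (3.0 * radius**2 + height**2) / 12.0
    expected = _npr_from_moments((iz, ixy, ixy))
    vol = math.pi * radius**2 * height * spacing**3
    return ShapeFixture("disc", VoxelGrid(np.zeros(3), spacing, occ), expected, vol, 0.05)


def make_ellipsoid(a: int, b: int, c: int, spacing: float = 1.0) -> ShapeFixture:
    """Solid ellipsoid with semi-axes (a, b, c) voxels."""
    if min(a, b, c) < 1:
        raise ValueError("all semi-axes must be >= 1 voxel")
    dims = (2 * a + 3, 2 * b + 3, 2 * c + 3)
    x, y, z = _centered_coords(dims)
    occ = (x / a) ** 2 + (y / b) ** 2 + (z / c) ** 2 <= 1.0
    expected = _npr_from_moments((b * b + c * c, a * a + c * c, a * a + b * b))
    vol = 4.0 / 3.0 * math.pi * a * b * c * spacing**3
    return ShapeFixture(
        "ellipsoid", VoxelGrid(np.zeros(3), spacing, occ), expected, vol, 0.02
    )


# ---------------------------------------------------------------------------
# shell pseudo-structure


def _fibonacci_sphere(n: int) -> np.ndarray:
    """n approximately equidistributed unit vectors (golden-angle spiral)."""
    k = np.arange(n) + 0.5
    phi = math.pi * (1.0 + math.sqrt(5.0)) * k
    z = 1.0 - 2.0 * k / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)


def make_shell_structure(
    cavity_radius: float = 8.0,
    mouth_width: float = 2.0,
    atom_spacing: float = 1.0,
    center: np.ndarray | None = None,
    solvent_probe: float = 3.0,
    check_integrity: bool = True,
) -> tuple[MolecularModel, float]:
    """Carbon pseudo-atom shell enclosing a spherical cavity.

    Atom centers sit on a sphere of radius ``cavity_radius + r_C`` so the
    inner van der Waals surface is at ``cavity_radius``; a cone around +z is
    cleared to leave a mouth of free width ``mouth_width`` (0 closes the
    cavity completely).  Returns the model and the analytic cavity volume
    (4/3)π·cavity_radius³.

    Pseudo-atoms are written as single-atom cytosine polymer residues so the
    model satisfies the sequence invariant; the fixture is non-physical.

    When ``check_integrity`` is on and the mouth is narrower than the
    solvent-probe diameter, a flood fill verifies that the probe-dilated
    shell actually seals the cavity (no accidental probe-sized holes).
    """
    if atom_spacing > 1.5:
        raise ValueError("atom_spacing must be <= 1.5 Å for a probe-tight shell")
    if mouth_width < 0:
        raise ValueError("mouth_width must be >= 0")
    shell_r = cavity_radius + _CARBON_R
    n = max(int(math.ceil(4.0 * math.pi * shell_r**2 / atom_spacing**2)), 12)
    dirs = _fibonacci_sphere(n)
    if mouth_width > 0:
        half = mouth_width / 2.0 + _CARBON_R
        cos_alpha = math.cos(math.asin(min(half / shell_r, 1.0)))
        dirs = dirs[dirs[:, 2] < cos_alpha]
    if center is None:
        center = np.zeros(3)
    coords = center + shell_r * dirs

    atoms = [
        AtomRecord(
            serial=i + 1,
            element="C",
            atom_name="C1",
            coords=xyz,
            residue_name="C",
            residue_index=i + 1,
            chain_id="A",
            is_hetero=False,
            vdw_radius=_CARBON_R,
        )
        for i, xyz in enumerate(coords)
    ]
    model = MolecularModel(
        atoms=atoms, sequence="C" * len(atoms), ligand_atoms=[], name="shell"
    )
    if check_integrity and mouth_width < 2.0 * solvent_probe:
        _check_shell_seals(coords, center, cavity_radius, solvent_probe)
    analytic_volume = 4.0 / 3.0 * math.pi * cavity_radius**3
    return model, analytic_volume


def _check_shell_seals(
    coords: np.ndarray, center: np.ndarray, cavity_radius: float, probe: float
) -> None:
    """Flood-fill self-check: the probe-dilated shell must enclose the cavity."""
    spacing = 0.8
    margin = _CARBON_R + probe + 2 * spacing
    lo = coords.min(axis=0) - margin
    hi = coords.max(axis=0) + margin
    dims = np.ceil((hi - lo) / spacing).astype(int)
    grids = np.meshgrid(
        *(lo[d] + spacing * (np.arange(dims[d]) + 0.5) for d in range(3)),
        indexing="ij",
    )
    pts = np.stack(grids, axis=-1)
    occ = np.zeros(tuple(dims), dtype=bool)
    r = _CARBON_R + probe
    for xyz in coords:
        d2 = ((pts - xyz) ** 2).sum(axis=-1)
        occ |= d2 <= r * r
    free = ~occ
    labels, _ = ndimage.label(free)
    ci = np.floor((center - lo) / spacing).astype(int)
    cavity_label = labels[tuple(ci)]
    if cavity_label == 0:
        raise FixtureIntegrityError("cavity center swallowed by dilated shell")
    boundary_labels = set(np.unique(labels[0, :, :])) | set(
        np.unique(labels[-1, :, :])
    ) | set(np.unique(labels[:, 0, :])) | set(np.unique(labels[:, -1, :])) | set(
        np.unique(labels[:, :, 0])
    ) | set(np.unique(labels[:, :, -1]))
    if cavity_label in boundary_labels:
        raise FixtureIntegrityError(
            "shell leaks: a solvent probe can reach the cavity from outside"
        )


# ---------------------------------------------------------------------------
# toy RNA–ligand complex


def make_toy_complex(
    n_nucleotides: int = 12,
    ligand_size: int = 5,
    seed: int = 0,
    cutoff: float = 4.0,
) -> tuple[MolecularModel, set[tuple[str, int]]]:
    """Pseudo-RNA chain plus a ligand with a known < cutoff binding set.

    Each residue contributes a P and an N atom along a gentle helix; the
    ligand (residue LIG, carbon atoms) is dropped near the middle of the
    chain.  The ground-truth binding set is computed here by a brute-force
    all-pairs distance scan at construction time.

    Returns ``(model, truth)`` with ``truth`` a set of
    ``(chain_id, residue_index)``.
    """
    if n_nucleotides < 4:
        raise ValueError("need at least 4 nucleotides")
    rng = np.random.default_rng(seed)
    bases = rng.choice(list("ACGU"), size=n_nucleotides)
    atoms: list[AtomRecord] = []
    serial = 0
    backbone = []
    for i in range(n_nucleotides):
        t = i * 0.6
        pos = np.array([6.0 * math.cos(t), 6.0 * math.sin(t), 2.2 * i])
        pos = pos + rng.normal(scale=0.15, size=3)
        backbone.append(pos)
        for name, element, offset in (
            ("P", "P", np.zeros(3)),
            ("N1", "N", rng.normal(scale=0.4, size=3) + np.array([1.5, 0, 0])),
        ):
            serial += 1
            atoms.append(
                AtomRecord(
                    serial=serial,
                    element=element,
                    atom_name=name,
                    coords=pos + offset,
                    residue_name=str(bases[i]),
                    residue_index=i + 1,
                    chain_id="A",
                    is_hetero=False,
                    vdw_radius=vdw_radius(element),
                )
            )
    anchor = backbone[n_nucleotides // 2]
    lig_atoms: list[AtomRecord] = []
    for k in range(ligand_size):
        serial += 1
        xyz = anchor + np.array([3.0, 0.0, 0.0]) + rng.normal(scale=1.0, size=3)
        rec = AtomRecord(
            serial=serial,
            element="C",
            atom_name=f"C{k + 1}",
            coords=xyz,
            residue_name="LIG",
            residue_index=n_nucleotides + 1,
            chain_id="A",
            is_hetero=True,
            vdw_radius=_CARBON_R,
        )
        atoms.append(rec)
        lig_atoms.append(rec)
    model = MolecularModel(
        atoms=atoms,
        sequence="".join(bases),
        ligand_atoms=lig_atoms,
        name=f"toy{seed}",
    )
    truth: set[tuple[str, int]] = set()
    lig_xyz = np.stack([a.coords for a in lig_atoms])
    for a in atoms:
        if a.is_hetero:
            continue
        d = np.linalg.norm(lig_xyz - a.coords, axis=1).min()
        if d < cutoff:
            truth.add((a.chain_id, a.residue_index))
    return model, truth


def write_all_fixtures(outdir: str | Path) -> list[Path]:
    """Write the standard fixture set (PDB + MRC + expected-value JSON)."""
    import json

    from .pocket_detection import write_mask
    from .structure_io import write_pdb

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    expected: dict[str, dict] = {}
    for fx in (
        make_ball(10),
        make_rod(10, 10, 100),
        make_disc(25, 1),
        make_ellipsoid(30, 40, 50),
    ):
        p = outdir / f"{fx.name}.mrc"
        write_mask(p, fx.mask)
        written.append(p)
        expected[fx.name] = {
            "npr": list(fx.expected_npr),
            "analytic_volume": fx.analytic_volume,
            "tolerance": fx.tolerance,
        }
    shell, vol = make_shell_structure()
    p = outdir / "shell.pdb"
    write_pdb(shell, p)
    written.append(p)
    expected["shell"] = {"analytic_cavity_volume": vol}
    toy, truth = make_toy_complex(seed=0)
    p = outdir / "toy_complex.pdb"
    write_pdb(toy, p)
    written.append(p)
    expected["toy_complex"] = {"binding_set": sorted([c, i] for c, i in truth)}
    j = outdir / "expected.json"
    j.write_text(json.dumps(expected, indent=2))
    written.append(j)
    return written
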