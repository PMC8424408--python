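"""Two-probe rolling-probe pocket detection on a voxel grid.

The RNA is voxelized onto a cubic grid at spacing ``δ`` (a voxel is occupied
when its center lies inside an atom's van der Waals sphere).  Two probe
spheres are then "rolled" over the van der Waals surface:

* the **shell probe** (default radius 10 Å) defines a coarse molecular
  envelope — everything it cannot reach is part of the molecule-plus-pockets
  region;
* the **solvent probe** (default radius 3 Å) defines the fine molecular
  (solvent-excluded) volume.

Rolling a probe of radius *r* is computed as Euclidean morphological closing
of the occupancy by a ball of radius *r*: a voxel belongs to the probe-excluded
region when no clash-free probe placement covers it.  Probe placements are
*all* non-overlapping positions, including placements inside internal
cavities, which is what makes a fully enclosed void solvent-accessible in
the small-probe map while the large probe seals it.

Pockets are the 26-connected components of (shell-excluded minus
solvent-excluded), each carrying discrete volume/area metrics:

* ``V_p`` = occupied voxels × δ³,
* ``A_p`` = exposed 6-neighbour faces × δ²,
* effective radius ``r_eff = 3 V_p / A_p``,
* sphericity ``Ψ = π^(1/3) (6 V_p)^(2/3) / A_p`` (1 for a perfect sphere),
* centroid = mean of occupied voxel centers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import gemmi
import numpy as np
from scipy import ndimage

from .structure_io import MolecularModel

__all__ = [
    "VoxelGrid",
    "Pocket",
    "voxelize",
    "close_grid",
    "excluded_volume",
    "detect_pockets",
    "filter_volume_outliers",
    "effective_radius",
    "sphericity",
    "exposed_face_count",
    "write_mask",
    "read_mask",
]

_CONN26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class VoxelGrid:
    """A boolean occupancy map on a cubic grid.

    Voxel ``(i, j, k)`` has center ``origin + spacing * (i+0.5, j+0.5, k+0.5)``.
    """

    origin: np.ndarray  # (3,) Å, corner of voxel (0,0,0)
    spacing: float  # δ, Å
    occupancy: np.ndarray  # bool, shape (nx, ny, nz)

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        if self.origin.shape != (3,):
            raise ValueError("origin must be a 3-vector")
        if not self.spacing > 0:
            raise ValueError("spacing must be > 0")
        self.occupancy = np.asarray(self.occupancy, dtype=bool)
        if self.occupancy.ndim != 3:
            raise ValueError("occupancy must be 3-dimensional")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.occupancy.shape  # type: ignore[return-value]

    @property
    def n_occupied(self) -> int:
        return int(self.occupancy.sum())

    @property
    def volume(self) -> float:
        """Occupied volume in Å³ (voxel count × δ³)."""
        return self.n_occupied * self.spacing**3

    def voxel_centers(self) -> np.ndarray:
        """Centers of occupied voxels, shape (n, 3), Å."""
        idx = np.argwhere(self.occupancy)
        return self.origin + self.spacing * (idx + 0.5)

    def with_occupancy(self, occupancy: np.ndarray) -> "VoxelGrid":
        return VoxelGrid(self.origin.copy(), self.spacing, occupancy)

    def index_of(self, points: np.ndarray) -> np.ndarray:
        """Voxel indices containing each point (may fall outside the box)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return np.floor((pts - self.origin) / self.spacing).astype(int)


@dataclass
class Pocket:
    """A pocket: one connected voxel component with derived metrics."""

    pocket_id: str
    mask: VoxelGrid
    volume: float  # V_p, Å³
    area: float  # A_p, Å²
    r_eff: float  # Å
    sphericity: float  # Ψ, dimensionless
    centroid: np.ndarray  # r_c, Å
    extras: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# metric formulas (formula-level, independent of any grid)


def effective_radius(volume: float, area: float) -> float:
    """r_eff = 3 V / A: the radius of a sphere with the same V/A ratio."""
    return 3.0 * volume / area


def sphericity(volume: float, area: float) -> float:
    """Ψ = π^(1/3) (6 V)^(2/3) / A: area of equal-volume sphere over area."""
    return np.pi ** (1.0 / 3.0) * (6.0 * volume) ** (2.0 / 3.0) / area


def exposed_face_count(occupancy: np.ndarray) -> int:
    """Count voxel faces adjacent to an empty voxel or the box boundary."""
    occ = np.asarray(occupancy, dtype=bool)
    n = int(occ.sum())
    internal = 0
    for axis in range(3):
        a = np.swapaxes(occ, 0, axis)
        internal += int(np.count_nonzero(a[:-1] & a[1:]))
    return 6 * n - 2 * internal


# ---------------------------------------------------------------------------
# voxelization and probe rolling


def voxelize(
    model: MolecularModel,
    spacing: float = 0.5,
    inflate: float = 0.0,
    pad: float = 0.0,
) -> VoxelGrid:
    """Occupancy of the (optionally inflated) van der Waals volume.

    A voxel is occupied iff its center lies within ``vdw_radius + inflate``
    of some atom center.  The box extends ``max(vdw) + inflate + pad + 2δ``
    beyond the atom bounding box on every side; detection passes
    ``pad = shell`` so that probes can always be placed fully outside.
    """
    if not spacing > 0:
        raise ValueError("spacing must be > 0")
    if inflate < 0:
        raise ValueError("inflate must be >= 0")
    atoms = model.atoms
    if not atoms:
        raise ValueError("model has no atoms")
    coords = model.coords_of(atoms)
    radii = np.array([a.vdw_radius for a in atoms]) + inflate
    margin = radii.max() + pad + 2.0 * spacing
    lo = coords.min(axis=0) - margin
    hi = coords.max(axis=0) + margin
    dims = np.ceil((hi - lo) / spacing).astype(int)
    occ = np.zeros(dims, dtype=bool)

    # per-atom local boxes: cheap and exact for the center-inside test
    for xyz, r in zip(coords, radii):
        i0 = np.floor((xyz - r - lo) / spacing - 0.5).astype(int)
        i1 = np.ceil((xyz + r - lo) / spacing - 0.5).astype(int) + 1
        i0 = np.clip(i0, 0, dims)
        i1 = np.clip(i1, 0, dims)
        sl = tuple(slice(a, b) for a, b in zip(i0, i1))
        if any(s.start >= s.stop for s in sl):
            continue
        axes = [
            lo[d] + spacing * (np.arange(i0[d], i1[d]) + 0.5) - xyz[d]
            for d in range(3)
        ]
        d2 = (
            axes[0][:, None, None] ** 2
            + axes[1][None, :, None] ** 2
            + axes[2][None, None, :] ** 2
        )
        occ[sl] |= d2 <= r * r
    return VoxelGrid(lo, spacing, occ)


def close_grid(grid: VoxelGrid, probe: float) -> VoxelGrid:
    """Morphological closing of the occupancy by a Euclidean ball.

    Returns the probe-excluded region: voxels not covered by any clash-free
    probe placement.  Computed with two Euclidean distance transforms
    (dilate: distance-to-occupied ≤ probe; erode: distance-to-outside-of-
    dilation > probe), so the closing is by a true Euclidean ball rather
    than a structuring-element approximation.  The result always contains
    the input occupancy.
    """
    if probe < 0:
        raise ValueError("probe must be >= 0")
    occ = grid.occupancy
    if probe == 0 or not occ.any():
        return grid.with_occupancy(occ.copy())
    if probe < grid.spacing:
        warnings.warn(
            f"probe {probe} Å below grid spacing {grid.spacing} Å: "
            "rolling degenerates to the van der Waals region",
            stacklevel=2,
        )
    s = grid.spacing
    dist_to_occ = ndimage.distance_transform_edt(~occ, sampling=s)
    dilated = dist_to_occ <= probe
    dist_to_out = ndimage.distance_transform_edt(dilated, sampling=s)
    closed = dist_to_out > probe
    closed |= occ  # extensivity, guards voxel-center discretisation edge cases
    return grid.with_occupancy(closed)


def excluded_volume(
    model: MolecularModel, probe: float, spacing: float = 0.5
) -> VoxelGrid:
    """Probe-excluded (molecular) region for a single probe radius."""
    grid = voxelize(model, spacing=spacing, pad=probe)
    return close_grid(grid, probe)


# ---------------------------------------------------------------------------
# pocket extraction


def _component_pocket(
    grid: VoxelGrid, labels: np.ndarray, lab: int, pocket_id: str
) -> Pocket:
    comp = labels == lab
    idx = np.argwhere(comp)
    lo = np.maximum(idx.min(axis=0) - 1, 0)
    hi = np.minimum(idx.max(axis=0) + 2, comp.shape)
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    sub = comp[sl]
    origin = grid.origin + grid.spacing * lo
    mask = VoxelGrid(origin, grid.spacing, sub)
    d = grid.spacing
    vol = float(sub.sum()) * d**3
    area = exposed_face_count(sub) * d**2
    return Pocket(
        pocket_id=pocket_id,
        mask=mask,
        volume=vol,
        area=area,
        r_eff=effective_radius(vol, area),
        sphericity=sphericity(vol, area),
        centroid=mask.voxel_centers().mean(axis=0),
    )


def detect_pockets(
    model: MolecularModel,
    shell: float = 10.0,
    solvent: float = 3.0,
    spacing: float = 0.5,
    min_volume: float = 50.0,
    stem: str | None = None,
) -> list[Pocket]:
    """Detect pockets as the two-probe excluded-volume difference.

    The ligand (and all hetero atoms) are stripped first: pockets are a
    property of the RNA alone.  Components smaller than ``min_volume`` (Å³)
    are dropped; survivors are sorted by volume descending and named
    ``<stem>_<rank>`` with rank starting at 1.
    """
    if not shell > solvent:
        raise ValueError("shell probe must be larger than solvent probe")
    if solvent < 0:
        raise ValueError("solvent probe must be >= 0")
    rna = model.without_ligand()
    grid = voxelize(rna, spacing=spacing, pad=shell)
    shell_ex = close_grid(grid, shell)
    solv_ex = close_grid(grid, solvent)
    region = shell_ex.occupancy & ~solv_ex.occupancy
    labels, n = ndimage.label(region, structure=_CONN26)
    if n == 0:
        return []
    counts = np.bincount(labels.ravel())[1:]  # label 0 is background
    d3 = spacing**3
    order = [
        (lab + 1)
        for lab in np.argsort(-counts, kind="stable")
        if counts[lab] * d3 >= min_volume
    ]
    stem = stem if stem is not None else model.name
    return [
        _component_pocket(grid, labels, lab, f"{stem}_{rank}")
        for rank, lab in enumerate(order, start=1)
    ]


def filter_volume_outliers(
    pockets: Sequence[Pocket],
) -> tuple[list[Pocket], list[Pocket], float, float]:
    """Drop pockets with volume above mean + 3·σ (population σ).

    Returns ``(kept, removed, m, sigma)``.  With fewer than two pockets the
    input is returned unchanged with ``sigma = 0``.
    """
    pockets = list(pockets)
    if len(pockets) < 2:
        m = pockets[0].volume if pockets else 0.0
        return pockets, [], m, 0.0
    vols = np.array([p.volume for p in pockets])
    m = float(vols.mean())
    sigma = float(vols.std(ddof=0))
    thresh = m + 3.0 * sigma
    kept = [p for p in pockets if p.volume <= thresh]
    removed = [p for p in pockets if p.volume > thresh]
    return kept, removed, m, sigma


# ---------------------------------------------------------------------------
# MRC mask I/O (MRC2014 via gemmi)


def write_mask(path: str | Path, grid: VoxelGrid) -> None:
    """Write a boolean mask as an MRC2014 volume (values 0/1).

    The voxel size is δ on every axis and the grid origin is recorded in
    the MRC origin header words, so a round-trip restores the frame exactly.
    """
    nx, ny, nz = grid.dims
    g = gemmi.FloatGrid(nx, ny, nz)
    g.spacegroup = gemmi.SpaceGroup("P 1")
    g.set_unit_cell(
        gemmi.UnitCell(nx * grid.spacing, ny * grid.spacing, nz * grid.spacing,
                       90.0, 90.0, 90.0)
    )
    arr = np.array(g, copy=False)
    arr[...] = grid.occupancy.astype(np.float32)
    m = gemmi.Ccp4Map()
    m.grid = g
    m.update_ccp4_header()
    for word, value in zip((50, 51, 52), grid.origin):
        m.set_header_float(word, float(value))
    m.write_ccp4_map(str(path))


def read_mask(path: str | Path, expected_spacing: float | None = None) -> VoxelGrid:
    """Read an MRC mask back into a :class:`VoxelGrid`.

    Values > 0.5 count as occupied.  Anisotropic voxel sizes, or a mismatch
    with ``expected_spacing``, emit a metadata warning and fall back to the
    mean axis spacing.
    """
    m = gemmi.read_ccp4_map(str(path))
    g = m.grid
    dims = np.array([g.nu, g.nv, g.nw], dtype=float)
    cell = np.array([g.unit_cell.a, g.unit_cell.b, g.unit_cell.c])
    spacings = cell / dims
    if np.ptp(spacings) > 1e-6 * spacings.mean():
        warnings.warn(
            f"{path}: anisotropic voxel size {spacings}; using the mean",
            stacklevel=2,
        )
    spacing = float(spacings.mean())
    if expected_spacing is not None and abs(spacing - expected_spacing) > 1e-6:
        warnings.warn(
            f"{path}: voxel size {spacing} Å differs from expected "
            f"{expected_spacing} Å",
            stacklevel=2,
        )
    origin = np.array([m.header_float(w) for w in (50, 51, 52)])
    occ = np.array(g, copy=True) > 0.5
    return VoxelGrid(origin, spacing, occ)
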