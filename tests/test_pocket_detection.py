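"""Voxelization, probe closing, pocket extraction and metric algebra.

The independent reference for probe rolling is a brute-force oracle that
enumerates every clash-free probe placement on the voxel centers and marks
everything such a probe covers; the implementation under test uses distance
transforms instead.
"""

import math

import numpy as np
import pytest
from scipy.spatial import cKDTree

from rnapocket.fixtures import make_shell_structure
from rnapocket.pocket_detection import (
    VoxelGrid,
    close_grid,
    detect_pockets,
    effective_radius,
    excluded_volume,
    exposed_face_count,
    filter_volume_outliers,
    read_mask,
    sphericity,
    voxelize,
    write_mask,
)
from rnapocket.structure_io import AtomRecord, MolecularModel


def _atom(xyz, serial=1, element="C", r=1.7):
    return AtomRecord(
        serial=serial,
        element=element,
        atom_name="C1",
        coords=np.asarray(xyz, dtype=float),
        residue_name="C",
        residue_index=serial,
        chain_id="A",
        is_hetero=False,
        vdw_radius=r,
    )


def _model(coords, r=1.7):
    atoms = [_atom(x, serial=i + 1, r=r) for i, x in enumerate(coords)]
    return MolecularModel(atoms=atoms, sequence="C" * len(atoms), name="test")


def brute_force_closing(grid: VoxelGrid, probe: float) -> np.ndarray:
    """Oracle: closing via explicit probe placements on voxel centers."""
    occ = grid.occupancy
    idx = np.indices(occ.shape).reshape(3, -1).T
    centers = grid.origin + grid.spacing * (idx + 0.5)
    occupied_centers = centers[occ.ravel()]
    if occupied_centers.size == 0:
        return occ.copy()
    d_occ = cKDTree(occupied_centers).query(centers)[0]
    probe_ok = d_occ > probe  # clash-free probe placements
    placements = centers[probe_ok]
    if placements.size:
        d_place = cKDTree(placements).query(centers)[0]
        covered = d_place <= probe
    else:
        covered = np.zeros(len(centers), dtype=bool)
    closed = (~covered).reshape(occ.shape)
    return closed | occ


class TestVoxelize:
    def test_single_atom_volume_matches_sphere(self):
        model = _model([[0.0, 0.0, 0.0]])
        grid = voxelize(model, spacing=0.5)
        analytic = 4.0 / 3.0 * math.pi * 1.7**3
        assert grid.volume == pytest.approx(analytic, rel=0.10)

    def test_inflate_strictly_grows_the_region(self):
        model = _model([[0.0, 0.0, 0.0]])
        # pad the un-inflated grid extra so both boxes coincide exactly
        base = voxelize(model, spacing=0.5, inflate=0.0, pad=7.0)
        big = voxelize(model, spacing=0.5, inflate=3.0, pad=4.0)
        assert base.dims == big.dims
        assert np.all(big.occupancy[base.occupancy])
        assert big.n_occupied > base.n_occupied

    def test_two_distant_atoms_give_two_components(self):
        from scipy import ndimage

        model = _model([[0.0, 0.0, 0.0], [100.0, 0.0, 0.0]])
        grid = voxelize(model, spacing=1.0)
        _, n = ndimage.label(grid.occupancy)
        assert n == 2
        # brute-force check: every occupied center is inside some atom
        centers = grid.voxel_centers()
        coords = np.array([[0.0, 0.0, 0.0], [100.0, 0.0, 0.0]])
        d = cKDTree(coords).query(centers)[0]
        assert np.all(d <= 1.7)


class TestClosing:
    def test_probe_zero_is_identity(self):
        model = _model([[0.0, 0.0, 0.0], [3.0, 0.0, 0.0]])
        grid = voxelize(model, spacing=0.5, pad=2.0)
        closed = close_grid(grid, 0.0)
        assert np.array_equal(closed.occupancy, grid.occupancy)

    def test_narrow_mouth_concavity_filled_matches_oracle(self):
        # hollow shell with a 2 Å mouth and a cavity smaller than the probe:
        # a 3 Å probe fits neither through the mouth nor inside, so the
        # interior becomes part of the probe-excluded region
        model, _ = make_shell_structure(
            cavity_radius=2.5, mouth_width=2.0, check_integrity=False
        )
        grid = voxelize(model, spacing=1.0, pad=3.0)
        closed = close_grid(grid, 3.0)
        oracle = brute_force_closing(grid, 3.0)
        assert np.array_equal(closed.occupancy, oracle)
        i0 = grid.index_of(np.zeros(3))[0]
        assert closed.occupancy[tuple(i0)]
        assert not grid.occupancy[tuple(i0)]

    @pytest.mark.parametrize("probe", [0.0, 1.0, 2.0, 3.0])
    def test_matches_brute_force_oracle_on_random_clusters(self, probe):
        rng = np.random.default_rng(7)
        coords = rng.uniform(-3, 3, size=(5, 3))
        model = _model(list(coords))
        grid = voxelize(model, spacing=1.0, pad=probe + 1.0)
        closed = close_grid(grid, probe)
        assert np.array_equal(closed.occupancy, brute_force_closing(grid, probe))

    def test_monotone_in_probe_radius(self):
        rng = np.random.default_rng(11)
        coords = rng.uniform(-4, 4, size=(8, 3))
        model = _model(list(coords))
        grid = voxelize(model, spacing=1.0, pad=7.0)
        prev = close_grid(grid, 0.0).occupancy
        for probe in (1.0, 2.0, 4.0, 6.0):
            cur = close_grid(grid, probe).occupancy
            # continuum closing is monotone in the probe radius; the
            # voxel-center sampling may flip isolated boundary voxels
            violations = int(np.count_nonzero(prev & ~cur))
            assert violations <= 2, f"closing shrank at probe {probe}"
            assert cur.sum() + violations >= prev.sum()
            prev = cur

    def test_closing_contains_vdw_region(self):
        model = _model([[0.0, 0.0, 0.0], [4.0, 0.0, 0.0]])
        grid = voxelize(model, spacing=0.5, pad=3.0)
        closed = close_grid(grid, 3.0)
        assert np.all(closed.occupancy[grid.occupancy])

    def test_subvoxel_probe_warns(self):
        model = _model([[0.0, 0.0, 0.0]])
        grid = voxelize(model, spacing=1.0, pad=1.0)
        with pytest.warns(UserWarning, match="spacing"):
            close_grid(grid, 0.5)

    def test_excluded_volume_entry_point(self):
        model = _model([[0.0, 0.0, 0.0]])
        out = excluded_volume(model, probe=0.0, spacing=0.5)
        assert out.n_occupied > 0


class TestDetectPockets:
    def test_shell_cavity_found_with_analytic_volume(self, shell_fixture, shell_pockets):
        _, analytic = shell_fixture
        assert len(shell_pockets) == 1
        assert shell_pockets[0].volume == pytest.approx(analytic, rel=0.15)
        # the pocket must not overlap the van der Waals occupancy
        model, _ = shell_fixture
        p = shell_pockets[0]
        centers = p.mask.voxel_centers()
        coords = model.coords_of(model.atoms)
        d = cKDTree(coords).query(centers)[0]
        radii = max(a.vdw_radius for a in model.atoms)
        assert np.all(d > radii * 0.999)  # no pocket voxel inside an atom

    def test_volume_error_shrinks_with_finer_grid(
        self, shell_fixture, shell_pockets, shell_pockets_coarse
    ):
        _, analytic = shell_fixture
        err_fine = abs(shell_pockets[0].volume - analytic)
        err_coarse = abs(shell_pockets_coarse[0].volume - analytic)
        assert err_fine <= err_coarse

    def test_closed_shell_cavity_still_detected(self):
        model, analytic = make_shell_structure(cavity_radius=6.0, mouth_width=0.0)
        pockets = detect_pockets(model, spacing=0.5)
        assert len(pockets) == 1
        assert pockets[0].volume == pytest.approx(analytic, rel=0.15)

    def test_solid_block_has_no_pockets(self):
        coords = [
            [2.0 * i, 2.0 * j, 2.0 * k]
            for i in range(3)
            for j in range(3)
            for k in range(3)
        ]
        model = _model(coords)
        assert detect_pockets(model, spacing=0.5, min_volume=50.0) == []

    def test_pockets_sorted_and_named_by_rank(self):
        m1, _ = make_shell_structure(cavity_radius=8.0, mouth_width=2.0)
        m2, _ = make_shell_structure(
            cavity_radius=5.0, mouth_width=2.0, center=np.array([60.0, 0.0, 0.0])
        )
        both = MolecularModel(
            atoms=m1.atoms + m2.atoms,
            sequence=m1.sequence + m2.sequence,
            name="twin",
        )
        pockets = detect_pockets(both, spacing=1.0)
        assert [p.pocket_id for p in pockets] == ["twin_1", "twin_2"]
        assert pockets[0].volume > pockets[1].volume

    def test_shell_must_exceed_solvent(self):
        model = _model([[0.0, 0.0, 0.0]])
        with pytest.raises(ValueError):
            detect_pockets(model, shell=3.0, solvent=3.0)


class TestMetricAlgebra:
    def test_sphere_effective_radius_and_sphericity(self):
        R = 4.6
        V = 4.0 / 3.0 * math.pi * R**3
        A = 4.0 * math.pi * R**2
        assert effective_radius(V, A) == pytest.approx(R, rel=1e-12)
        assert sphericity(V, A) == pytest.approx(1.0, rel=1e-12)

    def test_cube_sphericity_closed_form(self):
        L = 3.0
        psi = sphericity(L**3, 6 * L**2)
        assert psi == pytest.approx((math.pi / 6.0) ** (1.0 / 3.0), rel=1e-12)
        assert psi == pytest.approx(0.8060, abs=5e-4)

    def test_single_voxel_area_and_volume(self):
        occ = np.zeros((3, 3, 3), dtype=bool)
        occ[1, 1, 1] = True
        d = 0.7
        grid = VoxelGrid(np.zeros(3), d, occ)
        assert grid.volume == pytest.approx(d**3)
        assert exposed_face_count(occ) * d**2 == pytest.approx(6 * d**2)

    def test_two_voxel_bar_area(self):
        occ = np.zeros((4, 3, 3), dtype=bool)
        occ[1, 1, 1] = occ[2, 1, 1] = True
        assert exposed_face_count(occ) == 10


class TestOutlierFilter:
    def _pocket(self, vol, pid="p"):
        occ = np.ones((1, 1, 1), dtype=bool)
        from rnapocket.pocket_detection import Pocket

        return Pocket(
            pocket_id=pid,
            mask=VoxelGrid(np.zeros(3), 1.0, occ),
            volume=vol,
            area=6.0,
            r_eff=vol / 2.0,
            sphericity=0.8,
            centroid=np.zeros(3),
        )

    def test_constructed_outlier_removed(self):
        # a single extreme value among many ordinary ones; the direct
        # m + 3σ computation is the oracle for what must be removed
        vols = np.array([100.0 + i for i in range(30)] + [10000.0])
        pockets = [self._pocket(v, f"p{i}") for i, v in enumerate(vols)]
        kept, removed, m, sigma = filter_volume_outliers(pockets)
        assert m == pytest.approx(vols.mean())
        assert sigma == pytest.approx(vols.std(ddof=0))
        expected_removed = sorted(vols[vols > vols.mean() + 3 * vols.std(ddof=0)])
        assert expected_removed == [10000.0]
        assert [p.volume for p in removed] == expected_removed
        assert len(kept) == 30

    def test_equal_volumes_nothing_removed(self):
        pockets = [self._pocket(500.0, f"p{i}") for i in range(5)]
        kept, removed, m, sigma = filter_volume_outliers(pockets)
        assert sigma == 0.0
        assert removed == []
        assert len(kept) == 5

    def test_single_pocket_identity(self):
        pockets = [self._pocket(321.0)]
        kept, removed, m, sigma = filter_volume_outliers(pockets)
        assert kept == pockets and removed == [] and sigma == 0.0

    def test_threshold_at_published_scale(self):
        m, sigma = 1440.9, 2329.4
        assert m + 3 * sigma == pytest.approx(8429.1, abs=0.05)


class TestMaskIO:
    def test_round_trip_preserves_occupancy(self, tmp_path):
        rng = np.random.default_rng(5)
        occ = rng.random((20, 20, 20)) < 0.3
        grid = VoxelGrid(np.array([1.5, -2.0, 3.25]), 0.5, occ)
        p = tmp_path / "mask.mrc"
        write_mask(p, grid)
        back = read_mask(p)
        assert np.array_equal(back.occupancy, occ)
        assert back.spacing == pytest.approx(0.5)
        np.testing.assert_allclose(back.origin, grid.origin, atol=1e-5)

    def test_voxel_size_recorded_in_header(self, tmp_path):
        import gemmi

        occ = np.zeros((8, 8, 8), dtype=bool)
        occ[2:5, 2:5, 2:5] = True
        grid = VoxelGrid(np.zeros(3), 1.0, occ)
        p = tmp_path / "unit.mrc"
        write_mask(p, grid)
        m = gemmi.read_ccp4_map(str(p))
        for axis_len, n in zip(
            (m.grid.unit_cell.a, m.grid.unit_cell.b, m.grid.unit_cell.c),
            (m.grid.nu, m.grid.nv, m.grid.nw),
        ):
            assert axis_len / n == pytest.approx(1.0)

    def test_empty_mask_round_trips(self, tmp_path):
        grid = VoxelGrid(np.zeros(3), 1.0, np.zeros((5, 5, 5), dtype=bool))
        p = tmp_path / "empty.mrc"
        write_mask(p, grid)
        back = read_mask(p)
        assert back.n_occupied == 0

    def test_spacing_mismatch_warns(self, tmp_path):
        grid = VoxelGrid(np.zeros(3), 0.5, np.ones((4, 4, 4), dtype=bool))
        p = tmp_path / "m.mrc"
        write_mask(p, grid)
        with pytest.warns(UserWarning, match="differs"):
            read_mask(p, expected_spacing=1.0)
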