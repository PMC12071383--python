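import numpy as np
import pytest
from scipy.spatial import cKDTree

from mutpocket.depth import (
    DepthParams,
    ResidueDepth,
    compute_atom_depths,
    residue_depth_profile,
    voxelize,
)
from mutpocket.structure_io import Atom, ProteinStructure, Residue
from mutpocket.synthetic_data import (
    make_lattice_ball,
    make_shell_with_cavity,
    make_single_atom,
    make_slab,
    _carbon_structure,
)

CARBON = 1.70


class TestAnalyticOracles:
    def test_isolated_atom(self):
        s, gt = make_single_atom()
        d = compute_atom_depths(s)[1]
        assert d == pytest.approx(gt["expected_depth"], abs=0.02)
        assert d == pytest.approx(2 * (1 - (CARBON / 10) ** 3), abs=0.02)

    def test_solid_ball_center(self):
        s, gt = make_lattice_ball(radius=5.0, spacing=1.0)
        d = compute_atom_depths(s, serials={gt["probe_serial"]})[gt["probe_serial"]]
        assert d == pytest.approx(1.75, abs=0.05)

    def test_fully_enclosed_atom(self):
        # ball larger than the reference sphere: nothing exposed
        s, gt = make_lattice_ball(radius=12.0, spacing=1.2)
        d = compute_atom_depths(s, serials={gt["probe_serial"]})[gt["probe_serial"]]
        assert d <= 0.02

    def test_slab_face_atom(self):
        s, gt = make_slab(half_extent=25.0)
        d = compute_atom_depths(s, serials={gt["probe_serial"]})[gt["probe_serial"]]
        assert d == pytest.approx(1.0, abs=0.05)


class TestVoxelize:
    def test_single_atom_occupied_volume(self):
        s, _ = make_single_atom()
        grid = voxelize(s, DepthParams())
        analytic = 4 / 3 * np.pi * CARBON**3
        assert grid.occupied_volume() == pytest.approx(analytic, rel=0.10)

    @pytest.mark.parametrize("fill,expected", [(True, True), (False, False)])
    def test_cavity_filling_flag(self, fill, expected):
        s, gt = make_shell_with_cavity(cavity_radius=2.0)
        grid = voxelize(s, DepthParams(fill_cavities=fill))
        idx = tuple(grid.world_to_index(gt["cavity_center"]))
        assert bool(grid.occupancy[idx]) is expected

    def test_cavity_fill_uses_flood_fill_oracle(self):
        # independent oracle: BFS over non-blocked voxels from the boundary
        from collections import deque
        from scipy import ndimage

        s, _ = make_shell_with_cavity(cavity_radius=2.0, shell_thickness=3.0,
                                      spacing=1.2)
        params = DepthParams(fill_cavities=False)
        grid = voxelize(s, params)
        occ = grid.occupancy
        # oracle with probe 0: free = ~occ, reachable from border, 6-connected
        reachable = np.zeros_like(occ)
        seeds = np.argwhere(~occ)
        border = seeds[
            (seeds == 0).any(axis=1)
            | (seeds == np.array(occ.shape) - 1).any(axis=1)
        ]
        queue = deque(map(tuple, border))
        for voxel in queue:
            reachable[voxel] = True
        shape = occ.shape
        while queue:
            x, y, z = queue.popleft()
            for dx, dy, dz in ((1,0,0),(-1,0,0),(0,1,0),(0,-1,0),(0,0,1),(0,0,-1)):
                n = (x+dx, y+dy, z+dz)
                if (0 <= n[0] < shape[0] and 0 <= n[1] < shape[1]
                        and 0 <= n[2] < shape[2]
                        and not occ[n] and not reachable[n]):
                    reachable[n] = True
                    queue.append(n)
        expected = ~reachable
        filled = voxelize(s, DepthParams(fill_cavities=True, probe_radius=0.0))
        assert np.array_equal(filled.occupancy, expected)

    def test_memory_budget_error_suggests_spacing(self):
        s, _ = make_single_atom()
        with pytest.raises(MemoryError, match="grid_spacing"):
            voxelize(s, DepthParams(max_voxels=1000))

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            DepthParams(grid_spacing=2.0)  # h > r/10
        with pytest.raises(ValueError):
            DepthParams(reference_radius=1.0)
        with pytest.raises(ValueError):
            DepthParams(probe_radius=-0.1)


class TestDepthProperties:
    def test_depth_range(self, bundle):
        structure, _ = bundle
        depths = compute_atom_depths(structure)
        values = np.array(list(depths.values()))
        assert np.all(values >= 0) and np.all(values <= 2)

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(42)
        coords = rng.uniform(-4, 4, (25, 3))
        s1 = _carbon_structure(coords, "cluster")
        d1 = compute_atom_depths(s1)
        # random rotation + translation
        q = rng.normal(size=(3, 3))
        rot, _ = np.linalg.qr(q)
        moved = coords @ rot.T + np.array([13.7, -8.1, 5.3])
        s2 = _carbon_structure(moved, "cluster_moved")
        d2 = compute_atom_depths(s2)
        deltas = [abs(d1[i] - d2[i]) for i in d1]
        assert max(deltas) <= 0.05

    def test_adding_atoms_never_increases_depth(self):
        rng = np.random.default_rng(7)
        base = rng.uniform(-4, 4, (20, 3))
        extra = rng.uniform(-6, 6, (15, 3))
        s_small = _carbon_structure(base, "small")
        s_big = _carbon_structure(np.vstack([base, extra]), "big")
        d_small = compute_atom_depths(s_small)
        d_big = compute_atom_depths(s_big)
        for serial in d_small:
            assert d_big[serial] <= d_small[serial] + 1e-12

    def test_grid_convergence_on_single_atom_and_slab(self):
        s, _ = make_single_atom()
        d_coarse = compute_atom_depths(s, DepthParams(grid_spacing=0.5))[1]
        d_fine = compute_atom_depths(s, DepthParams(grid_spacing=0.25))[1]
        assert abs(d_coarse - d_fine) <= 0.02

        s, gt = make_slab(half_extent=18.0)
        probe = {gt["probe_serial"]}
        d_coarse = compute_atom_depths(s, DepthParams(grid_spacing=0.5),
                                       serials=probe)[1]
        d_fine = compute_atom_depths(s, DepthParams(grid_spacing=0.25),
                                     serials=probe)[1]
        assert abs(d_coarse - d_fine) <= 0.02

    def test_monte_carlo_oracle_agreement(self):
        """Voxel integration vs. independent Monte-Carlo point-in-union test."""
        s, _ = make_lattice_ball(radius=3.5, spacing=1.0)
        assert s.n_atoms <= 200
        params = DepthParams(grid_spacing=0.25, fill_cavities=False)
        coords = s.coordinates()
        tree = cKDTree(coords)
        rng = np.random.default_rng(2024)
        n_samples = 100_000
        r = params.reference_radius
        # center atom and one surface atom
        test_serials = [1, s.n_atoms]
        depths = compute_atom_depths(s, params, serials=set(test_serials))
        atom_coords = {a.serial: a.coords for a in s.atoms()}
        for serial in test_serials:
            center = atom_coords[serial]
            direction = rng.normal(size=(n_samples, 3))
            direction /= np.linalg.norm(direction, axis=1)[:, None]
            radius = r * rng.random(n_samples) ** (1 / 3)
            pts = center + direction * radius[:, None]
            dist, _ = tree.query(pts, k=1)
            p_exposed = float(np.mean(dist > CARBON))
            d_mc = 2 * p_exposed
            sigma = 2 * np.sqrt(p_exposed * (1 - p_exposed) / n_samples)
            assert abs(depths[serial] - d_mc) <= 3 * sigma + 1e-9, (
                f"serial {serial}: voxel {depths[serial]:.4f} vs MC {d_mc:.4f} "
                f"(3 sigma = {3 * sigma:.4f})"
            )


class TestResidueDepth:
    def _residue(self, resname, names_serials):
        atoms = [
            Atom(serial=serial, name=name, element="C", coords=[0, 0, serial],
                 vdw_radius=1.7)
            for name, serial in names_serials
        ]
        return Residue(chain="A", resseq=1, icode="", resname=resname, atoms=atoms)

    def test_glycine_convention(self):
        res = self._residue("GLY", [("N", 1), ("CA", 2), ("C", 3), ("O", 4)])
        rd = residue_depth_profile({1: 0.5, 2: 0.4, 3: 0.5, 4: 0.5}, res)
        assert rd.d_alpha == 0.4 and rd.d_sidechain == 0.4
        assert rd.ratio == pytest.approx(1.0)

    def test_sidechain_mean_and_ratio(self):
        res = self._residue(
            "VAL", [("N", 1), ("CA", 2), ("C", 3), ("O", 4),
                    ("CB", 5), ("CG1", 6), ("CG2", 7)]
        )
        depths = {1: 0.2, 2: 0.3, 3: 0.2, 4: 0.2, 5: 0.8, 6: 1.0, 7: 1.2}
        rd = residue_depth_profile(depths, res)
        assert rd.d_sidechain == pytest.approx(1.0)
        assert rd.ratio == pytest.approx(1.0 / 0.3)

    def test_missing_ca_is_error(self):
        res = self._residue("VAL", [("N", 1), ("CB", 5)])
        with pytest.raises(ValueError, match="CA"):
            residue_depth_profile({1: 0.2, 5: 0.5}, res)

    def test_partial_sidechain_warns_and_averages(self):
        res = self._residue(
            "VAL", [("N", 1), ("CA", 2), ("C", 3), ("O", 4),
                    ("CB", 5), ("CG1", 6), ("CG2", 7)]
        )
        depths = {1: 0.2, 2: 0.3, 3: 0.2, 4: 0.2, 5: 0.8, 6: 1.0}  # CG2 missing
        with pytest.warns(UserWarning, match="side-chain"):
            rd = residue_depth_profile(depths, res)
        assert rd.d_sidechain == pytest.approx(0.9)

    def test_ratio_undefined_at_zero_ca_depth(self):
        assert ResidueDepth(d_alpha=0.0, d_sidechain=0.3).ratio is None
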