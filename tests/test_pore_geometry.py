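"""Pore-pathway geometry: axis, profile, rings, tilts, superposition."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from porephys import pore_geometry as pg
from porephys.structure_io import AtomRecord, StructureModel
from porephys.synthetic_structures import IdealPoreSpec, build_ideal_pore

from conftest import random_rigid_transform


def carbon_ring(n=12, radius=5.0, z=0.0, chain="A"):
    atoms = [
        AtomRecord(
            chain_id=chain, residue_number=i + 1, residue_name="RNG",
            atom_name="C", element="C",
            position=[radius * np.cos(2 * np.pi * i / n),
                      radius * np.sin(2 * np.pi * i / n), z],
        )
        for i in range(n)
    ]
    return StructureModel(atoms, name="ring")


def z_axis(point=(0.0, 0.0, 0.0)):
    # direction extracellular->intracellular = -z, so "up" is +z
    return pg.PoreAxis(point=np.array(point), direction=np.array([0.0, 0.0, -1.0]))


def grid_search_radius(model, z, radii_set="hole-default", extent=4.0,
                       grid=0.01):
    """Independent dense-grid oracle for the maximal in-plane sphere."""
    xyz = np.array([a.position for a in model.atoms])
    rad = np.array([pg.vdw_radius(a.element, radii_set) for a in model.atoms])
    xs = np.arange(-extent, extent + grid / 2, grid)
    best = -np.inf
    for x in xs:
        centers = np.stack(
            [np.full_like(xs, x), xs, np.full_like(xs, z)], axis=1
        )
        d = np.linalg.norm(
            xyz[None, :, :] - centers[:, None, :], axis=2
        ) - rad[None, :]
        best = max(best, d.min(axis=1).max())
    return best


class TestPoreAxis:
    def test_ideal_pore_axis_is_z(self, ideal_pore):
        model, truth = ideal_pore
        axis = pg.fit_pore_axis(model)
        assert abs(abs(axis.direction[2]) - 1.0) < 1e-6
        np.testing.assert_allclose(axis.up, truth["axis_up"], atol=1e-6)

    def test_axis_equivariance_under_rotation(self, ideal_pore, rng):
        model, _ = ideal_pore
        R, t = random_rigid_transform(rng)
        axis0 = pg.fit_pore_axis(model)
        axis1 = pg.fit_pore_axis(model.transformed(R, t))
        np.testing.assert_allclose(
            axis1.direction, R @ axis0.direction, atol=1e-6
        )

    def test_axis_robust_to_jitter(self):
        """Per-atom jitter sigma = 0.3 A: recovered axis within 1 degree of
        the construction axis (Monte Carlo over seeds)."""
        worst = 0.0
        for seed in range(100):
            model, _ = build_ideal_pore(
                IdealPoreSpec(ring_radius=6.84, jitter_sigma=0.3, seed=seed)
            )
            axis = pg.fit_pore_axis(model)
            ang = np.degrees(np.arccos(abs(axis.direction[2])))
            worst = max(worst, ang)
        assert worst < 1.0

    def test_too_few_rings_errors(self, ideal_pore):
        model, _ = ideal_pore
        with pytest.raises(ValueError, match=">= 2"):
            pg.fit_pore_axis(model, ring_indices=[9])


class TestPoreProfile:
    def test_analytic_cylinder(self):
        """12 carbons (vdW 1.85) on a 5 A ring: maximal sphere radius
        5 - 1.85 = 3.15 A at the ring plane."""
        model = carbon_ring()
        prof = pg.pore_profile(model, z_axis(), z_range=(-0.5, 0.5))
        assert prof.radius_at(0.0) == pytest.approx(3.15, abs=1e-3)

    def test_off_axis_seed_converges(self):
        """Axis displaced 1 A off the ring centre: the in-plane search still
        finds the centred 3.15 A sphere."""
        model = carbon_ring()
        prof = pg.pore_profile(
            model, z_axis(point=(1.0, 0.0, 0.0)), z_range=(0.0, 0.0)
        )
        assert prof.radius_at(0.0) == pytest.approx(3.15, abs=5e-3)

    def test_matches_grid_search_oracle(self):
        """Nelder-Mead station radii agree with a dense 0.01 A grid search
        on an irregular small fixture."""
        rng = np.random.default_rng(7)
        atoms = []
        for i in range(30):
            phi = rng.uniform(0, 2 * np.pi)
            r = rng.uniform(4.0, 7.0)
            atoms.append(
                AtomRecord(
                    chain_id="A", residue_number=i + 1, residue_name="RNG",
                    atom_name="C", element="C",
                    position=[r * np.cos(phi), r * np.sin(phi),
                              rng.uniform(-2, 2)],
                )
            )
        model = StructureModel(atoms)
        prof = pg.pore_profile(model, z_axis(), z_range=(-1.0, 1.0), step=0.5)
        for _i, row in prof.stations.iterrows():
            oracle = grid_search_radius(model, row.axial_coord)
            assert row.radius == pytest.approx(oracle, abs=0.05)

    def test_radius_cap_in_vestibule(self):
        model = carbon_ring(radius=30.0)
        prof = pg.pore_profile(model, z_axis(), z_range=(0.0, 0.0))
        assert prof.radius_at(0.0) == pytest.approx(10.0)

    def test_empty_selection_errors(self):
        znonly = StructureModel(
            [AtomRecord(chain_id="A", residue_number=1, residue_name="ZN",
                        atom_name="ZN", element="ZN", position=[0, 0, 0],
                        is_hetero=True)]
        )
        with pytest.raises(ValueError, match="empty"):
            pg.pore_profile(znonly, z_axis(), z_range=(0.0, 0.0))

    def test_blocker_ion_narrows_pore_when_included(self, ideal_pore):
        """A hetero ion on the axis blocks the pathway only when hetero
        atoms are profiled (blocked-pore mode)."""
        model, truth = ideal_pore
        blocked = model.copy()
        blocked.atoms.append(
            AtomRecord(chain_id="X", residue_number=1, residue_name="ZN",
                       atom_name="ZN", element="ZN",
                       position=[0.0, 0.0, 16.5], is_hetero=True)
        )
        axis = pg.fit_pore_axis(blocked)
        open_prof = pg.pore_profile(blocked, axis, include_het=False)
        blocked_prof = pg.pore_profile(blocked, axis, include_het=True)
        assert open_prof.min_radius() == pytest.approx(
            truth["min_pore_radius_ca_only"], abs=0.05
        )
        # a centred ion forces the sphere off-axis into the pentagon gap:
        # the pathway narrows substantially, but only when the ion is seen
        assert blocked_prof.min_radius() < open_prof.min_radius() - 1.5
        near_ion = blocked_prof.stations.query("14.5 <= axial_coord <= 18.5")
        assert near_ion["radius"].min() < open_prof.radius_at(16.5) - 1.5


class TestGateDiameter:
    def test_cylinder_closed_form(self, ideal_pore):
        model, truth = ideal_pore
        axis = pg.fit_pore_axis(model)
        prof = pg.pore_profile(model, axis)
        d = pg.gate_diameter(prof, model, 9)
        assert d == pytest.approx(
            2 * (truth["ring_radius"]["9"] - 1.85), abs=0.02
        )

    def test_window_outside_profile_errors(self, ideal_pore):
        model, _ = ideal_pore
        axis = pg.fit_pore_axis(model)
        prof = pg.pore_profile(model, axis, z_range=(0.0, 2.0))
        with pytest.raises(ValueError, match="outside"):
            pg.gate_diameter(prof, model, 20)

    def test_monotone_in_ring_dilation(self):
        """Dilating the 9' ring never shrinks the 9' gate diameter."""
        diams = []
        for r in (6.0, 6.5, 7.0, 7.5):
            model, _ = build_ideal_pore(IdealPoreSpec(ring_radius=r))
            axis = pg.fit_pore_axis(model)
            prof = pg.pore_profile(model, axis)
            diams.append(pg.gate_diameter(prof, model, 9))
        assert all(b >= a - 1e-9 for a, b in zip(diams, diams[1:]))


class TestRingMetrics:
    def test_regular_pentagon_closed_form(self, ideal_pore):
        """ring radius 6.84 A: perimeter 5 * 2 * 6.84 * sin(36 deg) = 40.2 A."""
        model, truth = ideal_pore
        axis = pg.fit_pore_axis(model)
        rm = pg.ring_metrics(model, 9, axis)
        assert rm.perimeter == pytest.approx(40.2045, abs=1e-3)
        assert rm.perimeter == pytest.approx(
            truth["ring_perimeter"]["9"], abs=1e-9
        )

    def test_matches_brute_force_on_jittered_ring(self):
        """Perimeter equals the direct distance sum over the azimuth-sorted
        closed polygon for an irregular pentagon."""
        model, _ = build_ideal_pore(
            IdealPoreSpec(ring_radius=6.84, jitter_sigma=0.5, seed=3)
        )
        axis = z_axis()
        rm = pg.ring_metrics(model, 9, axis)
        pts = np.array(
            [model.prime_ca(ch, 9).position for ch in model.subunit_chains()]
        )
        az = np.arctan2(pts[:, 1], pts[:, 0])
        ordered = pts[np.argsort(az)]
        oracle = sum(
            np.linalg.norm(ordered[(i + 1) % 5] - ordered[i]) for i in range(5)
        )
        assert rm.perimeter == pytest.approx(oracle, abs=1e-9)

    def test_cyclic_relabeling_invariance(self, ideal_pore, rng):
        """Perimeter is unchanged by rigid rotation about the axis (which
        cyclically permutes the azimuthal order)."""
        model, _ = ideal_pore
        axis = pg.fit_pore_axis(model)
        base = pg.ring_metrics(model, 9, axis).perimeter
        Rz = Rotation.from_euler("z", 100, degrees=True).as_matrix()
        rot = model.transformed(Rz, np.zeros(3))
        assert pg.ring_metrics(rot, 9, pg.fit_pore_axis(rot)).perimeter == \
            pytest.approx(base, abs=1e-9)

    def test_missing_ca_names_chain(self, ideal_pore):
        model, _ = ideal_pore
        broken = model.copy()
        drop = broken.prime_maps["C"].residue_number(9)
        broken.atoms = [
            a for a in broken.atoms
            if not (a.chain_id == "C" and a.residue_number == drop)
        ]
        axis = z_axis()
        with pytest.raises(KeyError, match="C"):
            pg.ring_metrics(broken, 9, axis)


class TestHelixTilt:
    def test_constructed_tilt_recovered(self, tilted_pore):
        model, truth = tilted_pore
        axis = pg.fit_pore_axis(model)
        res = pg.mean_m2_tilt(model, axis)
        for ch, ang in res.per_chain:
            assert ang == pytest.approx(truth["helix_tilt"][ch], abs=0.2)

    def test_parallel_helix_is_zero(self, ideal_pore):
        model, _ = ideal_pore
        axis = pg.fit_pore_axis(model)
        assert pg.helix_tilt(model, "A", axis=axis) == pytest.approx(
            0.0, abs=0.2
        )

    def test_mean_is_arithmetic_mean(self, tilted_pore):
        model, _ = tilted_pore
        axis = pg.fit_pore_axis(model)
        res = pg.mean_m2_tilt(model, axis)
        assert res.mean_angle == pytest.approx(
            np.mean([a for _c, a in res.per_chain]), abs=0.0
        )

    def test_too_few_atoms_errors(self, ideal_pore):
        model, _ = ideal_pore
        axis = pg.fit_pore_axis(model)
        with pytest.raises(ValueError, match=">= 6"):
            pg.helix_tilt(model, "A", segment=(9, 12), axis=axis)


class TestSuperposition:
    def test_identical_copies_rmsd_zero(self, ideal_pore):
        model, _ = ideal_pore
        res = pg.superpose(model.copy(), model)
        assert res.rmsd < 1e-8
        np.testing.assert_allclose(res.rotation, np.eye(3), atol=1e-8)

    def test_rigid_motion_invariance(self, ideal_pore, rng):
        model, _ = ideal_pore
        R, t = random_rigid_transform(rng)
        res = pg.superpose(model.transformed(R, t), model)
        assert res.rmsd < 1e-6
        np.testing.assert_allclose(res.rotation, R.T, atol=1e-6)

    def test_agrees_with_independent_kabsch_oracle(self, rng):
        """rmsd matches scipy's independent Kabsch (align_vectors) on noisy
        10-atom pairs."""
        P = rng.normal(size=(10, 3)) * 5
        R, t = random_rigid_transform(rng)
        Q = P @ R.T + t + rng.normal(scale=0.5, size=(10, 3))
        Rk, tk = pg.kabsch(P, Q)
        rmsd = float(np.sqrt(np.mean(np.sum((P @ Rk.T + tk - Q) ** 2, axis=1))))
        rot, oracle_rssd = Rotation.align_vectors(
            Q - Q.mean(0), P - P.mean(0)
        )
        oracle_rmsd = oracle_rssd / np.sqrt(10)
        assert rmsd == pytest.approx(oracle_rmsd, abs=1e-6)
        np.testing.assert_allclose(Rk, rot.as_matrix(), atol=1e-6)

    def test_degenerate_selection_errors(self):
        P = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3.0, 0, 0]])
        with pytest.raises(ValueError, match="degenerate"):
            pg.kabsch(P, P)


class TestDisplacement:
    def test_identical_models_zero(self, ideal_pore):
        model, _ = ideal_pore
        sel = {"chain": "B", "resnum": 259, "atom": "CA"}
        assert pg.displacement(model, model.copy(), sel) == pytest.approx(0.0)

    def test_translated_atom_measured_after_alignment(self, ideal_pore):
        """Move one chain by 2 A along x, align on the other four chains:
        displacement of the moved atom is exactly 2 A."""
        model, _ = ideal_pore
        moved = model.copy()
        for a in moved.atoms:
            if a.chain_id == "B":
                a.position = a.position + np.array([2.0, 0.0, 0.0])
        align = lambda a: a.atom_name == "CA" and a.chain_id != "B"  # noqa: E731
        d = pg.displacement(
            model, moved, {"chain": "B", "resnum": 259, "atom": "CA"},
            align_selection=align,
        )
        assert d == pytest.approx(2.0, abs=1e-9)

    def test_absent_atom_errors(self, ideal_pore):
        model, _ = ideal_pore
        with pytest.raises(ValueError, match="exactly one"):
            pg.displacement(model, model.copy(),
                            {"chain": "B", "resnum": 1, "atom": "CA"})


class TestCoordination:
    def make_site(self, dist=2.6, n=3):
        atoms = [
            AtomRecord(chain_id="X", residue_number=1, residue_name="ZN",
                       atom_name="ZN", element="ZN", position=[0, 0, 0],
                       is_hetero=True)
        ]
        for i in range(n):
            phi = 2 * np.pi * i / n
            atoms.append(
                AtomRecord(chain_id=chr(65 + i), residue_number=267,
                           residue_name="HIS", atom_name="NE2", element="N",
                           position=[dist * np.cos(phi),
                                     dist * np.sin(phi), 0.0])
            )
        return StructureModel(atoms)

    def test_trigonal_site(self):
        model = self.make_site()
        geo = pg.coordination(model, {"element": "ZN"}, {"atom": "NE2"})
        np.testing.assert_allclose(geo.distances, [2.6] * 3, atol=1e-9)
        np.testing.assert_allclose(geo.inter_ligand_angles, [120.0] * 3,
                                   atol=1e-6)

    def test_cutoff_below_min_distance_empty(self):
        model = self.make_site()
        geo = pg.coordination(model, {"element": "ZN"}, {"atom": "NE2"},
                              cutoff=2.0)
        assert geo.ligand_atoms == ()

    def test_multiple_metals_error(self):
        model = self.make_site()
        model.atoms.append(
            AtomRecord(chain_id="Y", residue_number=2, residue_name="ZN",
                       atom_name="ZN", element="ZN", position=[9, 9, 9],
                       is_hetero=True)
        )
        with pytest.raises(ValueError, match="matched 2"):
            pg.coordination(model, {"element": "ZN"}, {"atom": "NE2"})


class TestContactMap:
    def test_single_pair_at_cutoff(self):
        atoms = [
            AtomRecord(chain_id="T", residue_number=33, residue_name="ARG",
                       atom_name="O", element="O", position=[0, 0, 0]),
            AtomRecord(chain_id="B", residue_number=202, residue_name="THR",
                       atom_name="OG1", element="O", position=[2.7, 0, 0]),
        ]
        model = StructureModel(atoms)
        pairs = pg.contact_map(model, {"chain": "T"}, {"chain": "B"},
                               cutoff=3.5)
        assert len(pairs) == 1
        assert pairs[0][2] == pytest.approx(2.7)
        assert pg.contact_map(model, {"chain": "T"}, {"chain": "B"},
                              cutoff=2.0) == []


class TestRigidMotionInvariance:
    def test_all_metrics_invariant(self, tilted_pore, rng):
        """Perimeter, tilt, gate diameter and coordination distances are
        unchanged by a common rigid transform of the coordinates."""
        model, _ = tilted_pore
        R, t = random_rigid_transform(rng)
        moved = model.transformed(R, t)
        ax0, ax1 = pg.fit_pore_axis(model), pg.fit_pore_axis(moved)
        assert pg.ring_metrics(moved, 9, ax1).perimeter == pytest.approx(
            pg.ring_metrics(model, 9, ax0).perimeter, abs=1e-6
        )
        assert pg.mean_m2_tilt(moved, ax1).mean_angle == pytest.approx(
            pg.mean_m2_tilt(model, ax0).mean_angle, abs=1e-6
        )
        p0 = pg.pore_profile(model, ax0, z_range=(0.0, 5.0), step=1.0)
        p1 = pg.pore_profile(moved, ax1, z_range=(0.0, 5.0), step=1.0)
        np.testing.assert_allclose(
            p1.stations["radius"], p0.stations["radius"], atol=1e-5
        )
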