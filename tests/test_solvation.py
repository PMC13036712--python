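"""RDF/coordination, hydrogen-bond geometry and droplet extraction."""

import math

import numpy as np
import pytest

from hostguest import solvation as sv
from hostguest.solvation import HBondCriteria, Trajectory, first_shell, hbond_partners, rdf
from hostguest.synthetic import PlantedWater, gen_solvation_frames


def single_pair_traj(distance=3.0, box=20.0):
    coords = np.array([[10.0, 10.0, 10.0], [10.0, 10.0, 10.0 + distance]])
    return Trajectory(("A", "B"), coords[None], np.full(3, box))


class TestRDF:
    def test_single_pair_lands_in_one_bin(self):
        traj = single_pair_traj(3.0)
        res = rdf(traj, np.array([0]), np.array([1]), r_max=5.0, bin_width=0.1)
        hot = res.g > 0
        assert hot.sum() == 1
        assert abs(res.r_centers[hot][0] - 3.0) <= 0.05

    def test_ideal_gas_is_flat_at_unity(self):
        rng = np.random.default_rng(3)
        frames = rng.uniform(0, 20, size=(20, 400, 3))
        traj = Trajectory(tuple("X" * 400), frames, np.full(3, 20.0))
        res = rdf(traj, np.arange(200), np.arange(200, 400), r_max=9.0, bin_width=0.2)
        far = res.r_centers > 2.0
        assert np.abs(res.g[far] - 1.0).max() < 0.05

    def test_binning_conserves_shell_integral(self):
        rng = np.random.default_rng(5)
        frames = rng.uniform(0, 18, size=(10, 300, 3))
        traj = Trajectory(tuple("X" * 300), frames, np.full(3, 18.0))
        A, B = np.arange(150), np.arange(150, 300)
        lo, hi = 2.0, 7.0  # edges shared by both binnings

        def shell_integral(res, width):
            edges = np.arange(0.0, 8.0 + width, width)
            vols = np.diff(edges**3)  # proportional to int g r^2 dr per bin
            m = (edges[:-1] >= lo) & (edges[1:] <= hi)
            return (res.g[m] * vols[m]).sum() / 3.0

        r1 = rdf(traj, A, B, r_max=8.0, bin_width=0.1)
        r2 = rdf(traj, A, B, r_max=8.0, bin_width=0.2)
        assert shell_integral(r2, 0.2) == pytest.approx(
            shell_integral(r1, 0.1), rel=0.01
        )

    def test_histogram_counts_conserved(self):
        rng = np.random.default_rng(9)
        frames = rng.uniform(0, 16, size=(4, 100, 3))
        traj = Trajectory(tuple("X" * 100), frames, np.full(3, 16.0))
        A, B = np.arange(50), np.arange(50, 100)
        res = rdf(traj, A, B, r_max=7.9, bin_width=0.05)
        # reconstruct raw counts and compare with direct pair counting
        shell_vol = 4 / 3 * math.pi * np.diff(
            np.arange(0, 7.9 + 0.05, 0.05) ** 3
        )
        hist = res.g * traj.n_frames * len(A) * res.number_density_B * shell_vol
        direct = 0
        for f in traj.frames:
            d = f[A][:, None] - f[B][None, :]
            d -= traj.box * np.round(d / traj.box)
            direct += (np.linalg.norm(d, axis=-1) < 7.9).sum()
        assert hist.sum() == pytest.approx(direct, abs=1.5)

    def test_matches_mdanalysis_reference(self):
        """Independent cross-check against MDAnalysis InterRDF."""
        MDAnalysis = pytest.importorskip("MDAnalysis")
        from MDAnalysis.analysis.rdf import InterRDF

        rng = np.random.default_rng(17)
        n_frames, nA, nB, L = 6, 60, 60, 18.0
        frames = rng.uniform(0, L, size=(n_frames, nA + nB, 3))
        traj = Trajectory(tuple("X" * (nA + nB)), frames, np.full(3, L))
        ours = rdf(traj, np.arange(nA), np.arange(nA, nA + nB),
                   r_max=8.0, bin_width=0.2)

        u = MDAnalysis.Universe.empty(nA + nB, trajectory=True)
        coords = [f.copy() for f in frames]
        u.load_new(np.array(coords), format="memory",
                   dimensions=np.array([[L, L, L, 90, 90, 90]] * n_frames))
        ref = InterRDF(u.atoms[:nA], u.atoms[nA:], nbins=40, range=(0.0, 8.0))
        ref.run()
        assert np.allclose(ours.g, ref.results.rdf, atol=1e-6)

    def test_r_max_beyond_half_box_rejected(self):
        traj = single_pair_traj()
        with pytest.raises(ValueError):
            rdf(traj, np.array([0]), np.array([1]), r_max=10.5)


class TestFirstShell:
    def test_planted_two_water_shell(self):
        scene = gen_solvation_frames(
            n_waters=40,
            box=24.0,
            planted_shell=(PlantedWater(1.95, 10.0, 0.0), PlantedWater(2.0, 20.0, 180.0)),
            n_frames=5,
            seed=3,
        )
        traj = scene.trajectory
        res = rdf(traj, np.array([scene.solute_donor]), traj.select("O"),
                  r_max=8.0, bin_width=0.05)
        r_peak, r_min, n_coord = first_shell(res)
        assert 1.8 < r_peak < 2.2
        assert n_coord == pytest.approx(2.0, abs=0.05)

    def test_monotone_g_has_no_shell(self):
        res = sv.RDFResult(
            r_centers=np.linspace(0.1, 5.0, 50),
            g=np.linspace(0.0, 1.0, 50),
            number_density_B=0.033,
        )
        with pytest.raises(ValueError):
            first_shell(res)

    def test_similarity_rescaling(self):
        scene = gen_solvation_frames(
            n_waters=25, box=24.0,
            planted_shell=(PlantedWater(2.0, 15.0, 0.0),), n_frames=1, seed=8,
        )
        traj = scene.trajectory
        c = 1.5
        scaled = Trajectory(traj.labels, traj.frames * c, traj.box * c)
        a = first_shell(rdf(traj, np.array([0]), traj.select("O"), 8.0, 0.05))
        b = first_shell(rdf(scaled, np.array([0]), scaled.select("O"), 8.0 * c, 0.05 * c))
        assert b[0] == pytest.approx(c * a[0], rel=0.05)
        assert b[2] == pytest.approx(a[2], abs=0.05)


class TestHBonds:
    def setup_method(self):
        self.crit = HBondCriteria()

    def test_linear_contact_accepted(self):
        frame = np.array([[0, 0, 0], [0, 0, 1.0], [0, 0, 2.8]], float)
        assert hbond_partners(frame, [0], [1], [2], self.crit) == [(0, 1, 2)]

    def test_long_contact_rejected(self):
        frame = np.array([[0, 0, 0], [0, 0, 1.0], [0, 0, 3.6]], float)
        assert hbond_partners(frame, [0], [1], [2], self.crit) == []

    def test_bent_contact_rejected(self):
        th = math.radians(40.0)
        frame = np.array(
            [[0, 0, 0], [0, 0, 1.0], [2.8 * math.sin(th), 0, 2.8 * math.cos(th)]]
        )
        assert hbond_partners(frame, [0], [1], [2], self.crit) == []

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(11)
        frame = np.array([[0, 0, 0], [0, 0, 1.0], [0.5, 0, 2.7], [3.0, 3.0, 3.0]])
        res0 = hbond_partners(frame, [0], [1], [2, 3], self.crit)
        # random rotation + translation
        q = np.linalg.qr(rng.normal(size=(3, 3)))[0]
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        moved = frame @ q.T + np.array([1.7, -2.2, 0.4])
        assert hbond_partners(moved, [0], [1], [2, 3], self.crit) == res0

    def test_unmapped_hydrogen_rejected(self):
        frame = np.zeros((3, 3))
        with pytest.raises(ValueError):
            hbond_partners(frame, [0, 1], [2], [0], self.crit)

    def test_planted_scene_counts_match_construction(self):
        scene = gen_solvation_frames(
            n_waters=30, box=24.0,
            planted_shell=(
                PlantedWater(2.9, 5.0, 0.0),
                PlantedWater(3.0, 10.0, 120.0),
                PlantedWater(3.2, 20.0, 240.0),
                PlantedWater(2.9, 45.0, 60.0),   # misangled
                PlantedWater(3.0, 50.0, 300.0),  # misangled
            ),
            n_frames=1, seed=9,
        )
        traj = scene.trajectory
        acceptors = np.array([g[0] for g in scene.water_groups])
        triples = hbond_partners(
            traj.frames[0], [scene.solute_donor], [scene.solute_hydrogen],
            acceptors, self.crit, traj.box,
        )
        assert len(triples) == 3


class TestNanodroplet:
    def make_scene(self):
        return gen_solvation_frames(
            n_waters=50, box=46.0,
            planted_shell=(
                PlantedWater(2.9, 5.0, 0.0),
                PlantedWater(3.0, 12.0, 120.0),
                PlantedWater(3.1, 18.0, 240.0),
            ),
            n_frames=1, seed=13,
        )

    def test_partition_is_exact(self):
        scene = self.make_scene()
        traj = scene.trajectory
        qm, mm = sv.extract_nanodroplet(
            traj, 0, scene.solute_indices, list(scene.water_groups), radius=20.0,
            solute_donors=np.array([scene.solute_donor]),
            solute_hydrogens=np.array([scene.solute_hydrogen]),
        )
        retained = {g for g in qm} | {g for g in mm}
        assert len(qm) + len(mm) == len(retained)  # disjoint
        assert set(qm).isdisjoint(mm)
        # every retained water is within the cutoff; dropped ones outside
        frame = traj.frames[0]
        center = frame[scene.solute_indices].mean(axis=0)
        mass = np.array([15.999, 1.008, 1.008])
        for g in scene.water_groups:
            com = (mass[:, None] * frame[list(g)]).sum(0) / mass.sum()
            d = np.linalg.norm(com - center)
            assert (g in retained) == (d <= 20.0)

    def test_hbonded_waters_are_tagged_qm(self):
        scene = self.make_scene()
        traj = scene.trajectory
        qm, _ = sv.extract_nanodroplet(
            traj, 0, scene.solute_indices, list(scene.water_groups), radius=20.0,
            solute_donors=np.array([scene.solute_donor]),
            solute_hydrogens=np.array([scene.solute_hydrogen]),
        )
        assert set(qm) == set(scene.planted)

    def test_apolar_solute_has_empty_qm_set(self):
        scene = self.make_scene()
        qm, mm = sv.extract_nanodroplet(
            scene.trajectory, 0, scene.solute_indices, list(scene.water_groups),
            radius=20.0,  # no donors/hydrogens/acceptors declared
        )
        assert qm == [] and len(mm) > 0

    def test_cutoff_boundary(self):
        # one water just inside, one just outside the 20 A sphere
        box = np.full(3, 60.0)
        center = box / 2
        coords = [center, center + [0, 0, 1.0]]
        labels = ["N", "H"]
        for d in (19.9, 20.1):
            o = center + np.array([d, 0.0, 0.0])
            coords += [o, o + [0.6, 0.6, 0], o + [0.6, -0.6, 0]]
            labels += ["O", "H", "H"]
        traj = Trajectory(tuple(labels), np.array(coords)[None], box)
        groups = [(2, 3, 4), (5, 6, 7)]
        qm, mm = sv.extract_nanodroplet(traj, 0, np.array([0, 1]), groups, radius=20.0)
        retained = qm + mm
        assert (2, 3, 4) in retained and (5, 6, 7) not in retained


class TestOccupancyMap:
    def test_static_atom_fills_one_voxel(self):
        coords = np.tile(np.array([[3.3, 4.4, 5.5]]), (7, 1, 1))
        traj = Trajectory(("O",), coords, np.full(3, 10.0))
        grid, _ = sv.occupancy_map(traj, np.array([0]), voxel=0.5)
        assert grid.sum() == 7
        assert grid.max() == 7

    def test_counts_total_and_additivity(self):
        rng = np.random.default_rng(21)
        frames = rng.uniform(0, 12, size=(5, 30, 3))
        traj = Trajectory(tuple("O" * 30), frames, np.full(3, 12.0))
        g1, _ = sv.occupancy_map(traj, np.arange(15), voxel=0.5)
        g2, _ = sv.occupancy_map(traj, np.arange(15, 30), voxel=0.5)
        gall, _ = sv.occupancy_map(traj, np.arange(30), voxel=0.5)
        assert gall.sum() == 5 * 30
        assert np.array_equal(g1 + g2, gall)

    def test_planted_cloud_argmax_location(self):
        rng = np.random.default_rng(2)
        center = np.array([6.0, 6.0, 6.0])
        pts = center + rng.normal(0, 0.2, size=(40, 1, 3))
        traj = Trajectory(("O",), pts, np.full(3, 12.0))
        grid, _ = sv.occupancy_map(traj, np.array([0]), voxel=0.5)
        idx = np.unravel_index(np.argmax(grid), grid.shape)
        assert np.abs((np.array(idx) + 0.5) * 0.5 - center).max() <= 0.5
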