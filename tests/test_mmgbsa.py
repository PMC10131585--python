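"""GB/SASA oracles and the single-trajectory MM-GBSA screen."""

import numpy as np
import pytest
from scipy import integrate

from cycbind.mmgbsa import (
    GBParameters,
    born_radii,
    gb_energy,
    mmgbsa_score,
    sasa,
    sasa_energy,
    screen_trajectory,
)
from cycbind.structure import ParamStructure
from cycbind.thermo import COULOMB_CONSTANT
from cycbind.trajectory import Trajectory
from conftest import make_atoms

PARAMS = GBParameters()


def _hct_integral_quadrature(d, rho_i, s_radius):
    """Independent descreening integral: (1/4pi) int_{sphere_j} |r|^-4 dV.

    Shell decomposition around atom i: the part of the sphere of radius r
    (centered on i) lying inside the descreening sphere is a cap of solid
    angle 2 pi (1 - cos(alpha)).
    """
    def cap(r):
        cos_a = (r**2 + d**2 - s_radius**2) / (2 * r * d)
        return 0.5 * (1.0 - cos_a) / r**2

    lo = max(d - s_radius, rho_i)
    value, _ = integrate.quad(cap, lo, d + s_radius, limit=200)
    return value


class TestBornRadii:
    def test_isolated_atom_closed_form(self):
        s = make_atoms([[0, 0, 0]], radii=[1.5])
        radius = born_radii(s, PARAMS)[0]
        assert radius == pytest.approx(1.5 - PARAMS.born_offset, abs=1e-12)

    def test_far_separated_pair_isolated_limit(self):
        s = make_atoms([[0, 0, 0], [500.0, 0, 0]], radii=[1.5, 2.0])
        radii = born_radii(s, PARAMS)
        np.testing.assert_allclose(radii, [1.41, 1.91], atol=1e-6)

    def test_contact_pair_larger_than_far_pair(self):
        near = make_atoms([[0, 0, 0], [3.0, 0, 0]], radii=[1.5, 2.0])
        far = make_atoms([[0, 0, 0], [50.0, 0, 0]], radii=[1.5, 2.0])
        assert np.all(born_radii(near, PARAMS) > born_radii(far, PARAMS))

    def test_pair_descreening_matches_quadrature_oracle(self):
        d = 3.0
        radii = np.array([1.5, 2.0])
        s = make_atoms([[0, 0, 0], [d, 0, 0]], radii=radii)
        rho = radii - PARAMS.born_offset
        effective = born_radii(s, PARAMS)
        for i, j in ((0, 1), (1, 0)):
            integral = _hct_integral_quadrature(d, rho[i], PARAMS.descreen_scale * rho[j])
            psi = integral * rho[i]
            tanh_term = np.tanh(PARAMS.obc_alpha * psi - PARAMS.obc_beta * psi**2
                                + PARAMS.obc_gamma * psi**3)
            expected = 1.0 / (1.0 / rho[i] - tanh_term / radii[i])
            assert effective[i] == pytest.approx(expected, rel=1e-6)

    def test_nonpositive_intrinsic_radius_rejected(self):
        s = make_atoms([[0, 0, 0]], radii=[0.05])
        with pytest.raises(ValueError, match="Born offset"):
            born_radii(s, PARAMS)


class TestGBEnergy:
    def test_single_ion_born_formula(self):
        # effective radius 2.0 requires intrinsic 2.09 with the 0.09 offset
        s = make_atoms([[0, 0, 0]], charges=[1.0], radii=[2.09])
        expected = -0.5 * (1 - 1 / 78.5) * COULOMB_CONSTANT / 2.0
        assert gb_energy(s, params=PARAMS) == pytest.approx(expected, abs=1e-6)
        assert expected == pytest.approx(-81.96, abs=5e-3)

    def test_zero_charges_zero_energy(self, toy_complex):
        neutral = make_atoms(toy_complex.coord, radii=toy_complex.gb_radius)
        assert gb_energy(neutral, params=PARAMS) == 0.0

    def test_fused_ion_limit(self):
        # r -> 0: f_GB -> sqrt(a_i a_j); the pair behaves as one fused ion
        radii_int = np.array([2.09, 2.09])
        s = make_atoms([[0, 0, 0], [1e-7, 0, 0]], charges=[1.0, -1.0], radii=radii_int)
        a = born_radii(s, PARAMS)
        prefac = -0.5 * COULOMB_CONSTANT * (1 - 1 / 78.5)
        expected = prefac * (1 / a[0] + 1 / a[1] + 2 * (-1.0) / np.sqrt(a[0] * a[1]))
        assert gb_energy(s, params=PARAMS) == pytest.approx(expected, rel=1e-6)

    def test_rigid_motion_invariance(self, toy_complex):
        base = gb_energy(toy_complex, params=PARAMS)
        rng = np.random.default_rng(0)
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        moved = toy_complex.with_coord(toy_complex.coord @ q.T + 100.0)
        assert gb_energy(moved, params=PARAMS) == pytest.approx(base, rel=1e-9)


class TestSasa:
    def test_isolated_sphere(self):
        s = make_atoms([[0, 0, 0]], radii=[1.6])
        _, total = sasa(s, PARAMS, 960)
        assert total == pytest.approx(4 * np.pi * 3.0**2, rel=0.01)

    def test_separated_atoms_additive(self):
        s = make_atoms([[0, 0, 0], [100.0, 0, 0]], radii=[1.6, 2.0])
        per_atom, total = sasa(s, PARAMS, 960)
        assert per_atom[0] == pytest.approx(4 * np.pi * 3.0**2, rel=0.01)
        assert per_atom[1] == pytest.approx(4 * np.pi * 3.4**2, rel=0.01)
        assert total == pytest.approx(per_atom.sum())

    def test_two_overlapping_spheres_cap_formula(self):
        radius, d = 1.6, 2.5
        s = make_atoms([[0, 0, 0], [d, 0, 0]], radii=[radius, radius])
        _, total = sasa(s, PARAMS, 1920)
        r_ext = radius + PARAMS.probe_radius
        cap_height = r_ext - d / 2.0
        expected = 2 * (4 * np.pi * r_ext**2 - 2 * np.pi * r_ext * cap_height)
        assert total == pytest.approx(expected, rel=0.02)

    def test_point_count_convergence(self, toy_complex):
        _, t1 = sasa(toy_complex, PARAMS, 480)
        _, t2 = sasa(toy_complex, PARAMS, 960)
        assert abs(t2 - t1) / t2 < 0.005

    def test_too_few_points_rejected(self, toy_complex):
        with pytest.raises(ValueError, match="32"):
            sasa(toy_complex, PARAMS, 16)


class TestMmgbsaScore:
    def test_inert_far_ligand_scores_zero(self):
        coords = [[0, 0, 0], [3, 0, 0], [0, 3, 0], [200.0, 0, 0]]
        s = make_atoms(coords, charges=[0.5, -0.5, 0.0, 0.0],
                       radii=[1.5, 1.5, 1.5, 1.5],
                       lj_eps=[0.1, 0.1, 0.1, 0.0],
                       chains=["A", "A", "A", "B"])
        bd = mmgbsa_score(s, s.chain_id == "A", s.chain_id == "B", PARAMS, n_points=480)
        assert abs(bd.total) < 1e-6

    def test_two_atom_complex_term_by_term(self):
        d = 5.0
        q = np.array([1.0, -1.0])
        radii = np.array([1.5, 2.0])
        eps = np.array([0.1, 0.2])
        rmh = np.array([1.7, 1.9])
        s = make_atoms([[0, 0, 0], [d, 0, 0]], charges=q, radii=radii,
                       lj_eps=eps, lj_rmin_half=rmh, chains=["A", "B"])
        bd = mmgbsa_score(s, s.chain_id == "A", s.chain_id == "B", PARAMS, n_points=960)

        # independent term-by-term evaluation
        e_coul = COULOMB_CONSTANT * q[0] * q[1] / d
        eps_ij = np.sqrt(eps[0] * eps[1])
        rmin = rmh.sum()
        e_lj = eps_ij * ((rmin / d) ** 12 - 2 * (rmin / d) ** 6)
        rho = radii - PARAMS.born_offset
        a = np.empty(2)
        for i, j in ((0, 1), (1, 0)):
            integral = _hct_integral_quadrature(d, rho[i], PARAMS.descreen_scale * rho[j])
            psi = integral * rho[i]
            t = np.tanh(PARAMS.obc_alpha * psi - PARAMS.obc_beta * psi**2
                        + PARAMS.obc_gamma * psi**3)
            a[i] = 1.0 / (1.0 / rho[i] - t / radii[i])
        prefac = -0.5 * COULOMB_CONSTANT * (1 - 1 / 78.5)
        f01 = np.sqrt(d**2 + a[0] * a[1] * np.exp(-(d**2) / (4 * a[0] * a[1])))
        g_complex = prefac * (q[0]**2 / a[0] + q[1]**2 / a[1] + 2 * q[0] * q[1] / f01)
        g_parts = prefac * (q[0]**2 / rho[0] + q[1]**2 / rho[1])
        g_gb = g_complex - g_parts

        assert bd.e_coulomb == pytest.approx(e_coul, rel=1e-9)
        assert bd.e_lj == pytest.approx(e_lj, rel=1e-9)
        assert bd.g_gb == pytest.approx(g_gb, rel=1e-6)
        # probe-extended spheres (2.9, 3.4 A) overlap at d = 5: buried area
        # from the exact lens (spherical cap) formula
        r1, r2 = radii + PARAMS.probe_radius
        x1 = (d**2 + r1**2 - r2**2) / (2 * d)
        h1, h2 = r1 - x1, r2 - (d - x1)
        buried = 2 * np.pi * (r1 * h1 + r2 * h2)
        assert bd.g_sasa == pytest.approx(-PARAMS.surface_tension * buried, rel=0.02)

    def test_role_swap_symmetry(self, toy_complex):
        a = mmgbsa_score(toy_complex, toy_complex.chain_id == "A",
                         toy_complex.chain_id == "B", PARAMS, n_points=240)
        b = mmgbsa_score(toy_complex, toy_complex.chain_id == "B",
                         toy_complex.chain_id == "A", PARAMS, n_points=240)
        assert a.total == pytest.approx(b.total, rel=1e-12)

    def test_buried_area_nonnegative(self, toy_complex):
        receptor = toy_complex.subset(toy_complex.chain_id == "A")
        ligand = toy_complex.subset(toy_complex.chain_id == "B")
        _, t_c = sasa(toy_complex, PARAMS, 480)
        _, t_r = sasa(receptor, PARAMS, 480)
        _, t_l = sasa(ligand, PARAMS, 480)
        assert t_c <= t_r + t_l + 1e-9

    def test_vanishes_at_200A_separation(self, toy_complex):
        coords = toy_complex.coord.copy()
        coords[toy_complex.chain_id == "B"] += np.array([200.0, 0.0, 0.0])
        apart = toy_complex.with_coord(coords)
        bd = mmgbsa_score(apart, apart.chain_id == "A", apart.chain_id == "B",
                          PARAMS, n_points=480)
        assert abs(bd.total) < 1e-3

    def test_overlapping_masks_rejected(self, toy_complex):
        mask = toy_complex.chain_id == "A"
        with pytest.raises(ValueError, match="overlap"):
            mmgbsa_score(toy_complex, mask, mask, PARAMS)


def _screen_fixture():
    coords = [
        [0, 0, 0], [3, 0, 0], [0, 3, 0], [0, 0, 3],   # receptor chain A
        [8.0, 0, 0], [9.5, 0, 0],                      # ligand chain B
    ]
    return make_atoms(coords, charges=[0.2, -0.2, 0.1, -0.1, 0.3, -0.3],
                      chains=["A", "A", "A", "A", "B", "B"],
                      names=["X0", "X1", "X2", "X3", "CA", "CB"],
                      res_ids=[1, 2, 3, 4, 1, 1])


class TestScreenTrajectory:
    def test_never_dissociates_full_duration(self):
        top = _screen_fixture()
        frames = [top.coord.copy() for _ in range(10)]
        traj = Trajectory(frames=frames, frame_interval=0.2)
        res = screen_trajectory(traj, top, top.chain_id == "A", top.chain_id == "B",
                                PARAMS, n_points=120)
        assert res.time_bound == pytest.approx(2.0)
        assert res.n_bound == 10
        # identical frames: constant energy, zero SEM
        assert res.sem == pytest.approx(0.0, abs=1e-12)
        assert res.mean == pytest.approx(res.per_frame[0].total)

    def test_dissociation_at_frame_six(self):
        top = _screen_fixture()
        frames = []
        for i in range(10):
            f = top.coord.copy()
            if i >= 6:
                f[top.chain_id == "B"] += np.array([0.0, 30.0, 0.0])
            frames.append(f)
        traj = Trajectory(frames=frames, frame_interval=0.2)
        res = screen_trajectory(traj, top, top.chain_id == "A", top.chain_id == "B",
                                PARAMS, n_points=120)
        assert res.time_bound == pytest.approx(1.2)
        assert res.n_bound == 6
        assert len(res.per_frame) == 6
        assert np.isfinite(res.mean)

    def test_zero_bound_frames_flagged_not_raised(self):
        # a stop threshold below any attainable displacement unbinds frame 0
        top = _screen_fixture()
        traj = Trajectory(frames=[top.coord.copy(), top.coord.copy()], frame_interval=0.2)
        res = screen_trajectory(traj, top, top.chain_id == "A", top.chain_id == "B",
                                PARAMS, rmsd_stop=-1.0, n_points=120)
        assert res.time_bound == 0.0
        assert res.n_bound == 0
        assert np.isnan(res.mean)
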