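"""Coupled-dipole solver: closed-form solves, symmetries, substrate images.

The heavier oracle-equivalence checks against Mie live in the acceptance
suite; here each property is exercised on the smallest scene that shows it.
"""

import numpy as np
import pytest

from plasmonsense.dda import (PlaneWave, SolverSettings, cross_sections,
                              dipole_polarizability, green_tensor,
                              image_factor, quasistatic_image_field,
                              solve_dda, compute_spectrum)
from plasmonsense.geometry import (DipoleGrid, MoleculeSpec,
                                   NanorodGeometry, ShellSpec, build_scene,
                                   voxelize)
from plasmonsense.materials import MaterialSet
from plasmonsense.synthetic import make_toy_grid

LAM = 600.0
N_W = 1.33
EPS_W = N_W**2


def single_voxel_grid(scene, z=10.0, h=1.0):
    return DipoleGrid(
        voxel_size=h, origin=np.array([0.0, 0.0, z]), shape=(1, 1, 1),
        indices=np.array([[0, 0, 0]]),
        material_id=np.array([1], dtype=np.int8), scene=scene)


@pytest.fixture(scope="module")
def water_scene():
    return build_scene(NanorodGeometry(10.0, 1.0), ShellSpec(0.0),
                       substrate_enabled=False)


class TestPolarizability:
    def test_no_contrast_gives_zero(self):
        a = dipole_polarizability(EPS_W, EPS_W, 1.0, LAM)
        assert a == 0

    def test_static_limit_matches_clausius_mossotti(self):
        eps = 2.5 + 0.1j
        a_cm = 3.0 / (4 * np.pi) * (eps / EPS_W - 1) / (eps / EPS_W + 2)
        for model in ("clausius_mossotti_rr", "lattice_dispersion"):
            a = dipole_polarizability(eps, EPS_W, 1.0, 1e9, model)
            assert a == pytest.approx(a_cm, rel=1e-6)

    def test_ldr_close_to_cm_rr_at_small_kd(self):
        eps = -10.0 + 1.5j  # |m| k d ~ 0.08 for 2 nm voxel at 620 nm
        a1 = dipole_polarizability(eps, EPS_W, 2.0, 620.0,
                                   "clausius_mossotti_rr")
        a2 = dipole_polarizability(eps, EPS_W, 2.0, 620.0,
                                   "lattice_dispersion")
        assert abs(a1 - a2) / abs(a1) < 0.05


class TestTinySystems:
    def test_single_voxel_closed_form(self, water_scene):
        grid = single_voxel_grid(water_scene)
        sol = solve_dda(grid, PlaneWave(LAM),
                        SolverSettings(substrate_model="none"))
        assert sol.residual == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(sol.P[0], sol.alpha[0] * sol.E_inc[0])

    def test_two_voxel_brute_force(self, water_scene):
        """Solver equals a direct 6x6 inversion built from the dyadic."""
        h = 1.0
        grid = DipoleGrid(
            voxel_size=h, origin=np.array([0.0, 0.0, 10.0]),
            shape=(2, 1, 1), indices=np.array([[0, 0, 0], [1, 0, 0]]),
            material_id=np.array([1, 1], dtype=np.int8), scene=water_scene)
        wave = PlaneWave(LAM)
        sol = solve_dda(grid, wave, SolverSettings(substrate_model="none"))

        # independent dense construction
        k = 2 * np.pi * N_W / LAM
        eps = water_scene.materials.permittivity("gold", LAM)
        alpha = dipole_polarizability(eps, EPS_W, h, LAM,
                                      "lattice_dispersion")
        r12 = grid.centers[0] - grid.centers[1]
        G = green_tensor(r12[None, :], k)[0]
        A = np.zeros((6, 6), dtype=complex)
        A[:3, :3] = np.eye(3) / alpha
        A[3:, 3:] = np.eye(3) / alpha
        A[:3, 3:] = -G
        A[3:, :3] = -G
        b = sol.E_inc.ravel()
        P_direct = np.linalg.solve(A, b).reshape(2, 3)
        np.testing.assert_allclose(sol.P, P_direct, rtol=1e-10)

    def test_lossless_dielectric_has_no_absorption(self, water_scene):
        from dataclasses import replace
        from plasmonsense.materials import DielectricTable

        nk = np.sqrt(2.25)
        mats = MaterialSet(gold=DielectricTable(
            np.array([300.0, 1600.0]), np.full(2, nk), np.zeros(2)))
        scene = replace(water_scene, materials=mats)
        grid = voxelize(scene, 1.0)
        sol = solve_dda(grid, PlaneWave(LAM),
                        SolverSettings(substrate_model="none"))
        cs = cross_sections(sol)
        assert abs(cs.C_abs_um2) < 1e-3 * cs.C_ext_um2


class TestSymmetries:
    def test_mirror_symmetric_polarization(self):
        """x-polarized field on a y-symmetric rod gives a y-mirror field."""
        grid = make_toy_grid("rod_coarse")
        sol = solve_dda(grid, PlaneWave(700.0),
                        SolverSettings(substrate_model="none",
                                       tolerance=1e-6))
        c = grid.centers
        order = {tuple(np.round(p, 6)): i for i, p in enumerate(c)}
        mirrored = np.array([order[tuple(np.round(p * [1, -1, 1], 6))]
                             for p in c])
        # P_x, P_z even in y; P_y odd
        np.testing.assert_allclose(sol.P[:, 0], sol.P[mirrored, 0],
                                   atol=2e-5 * np.abs(sol.P[:, 0]).max())
        np.testing.assert_allclose(sol.P[:, 1], -sol.P[mirrored, 1],
                                   atol=2e-5 * np.abs(sol.P[:, 0]).max())

    def test_translation_invariance(self, water_scene):
        """Cross sections are unchanged by a rigid shift in the host."""
        settings = SolverSettings(substrate_model="none")
        grid = voxelize(water_scene, 1.0)
        cs1 = cross_sections(solve_dda(grid, PlaneWave(LAM), settings))
        shifted = DipoleGrid(
            voxel_size=grid.voxel_size,
            origin=grid.origin + np.array([3.7, -1.2, 8.9]),
            shape=grid.shape, indices=grid.indices,
            material_id=grid.material_id, scene=water_scene)
        cs2 = cross_sections(solve_dda(shifted, PlaneWave(LAM), settings))
        assert cs2.C_ext_um2 == pytest.approx(cs1.C_ext_um2, rel=1e-4)
        assert cs2.C_abs_um2 == pytest.approx(cs1.C_abs_um2, rel=1e-4)

    def test_determinism(self, water_scene):
        grid = voxelize(water_scene, 1.0)
        s = SolverSettings(substrate_model="none")
        a = solve_dda(grid, PlaneWave(LAM), s)
        b = solve_dda(grid, PlaneWave(LAM), s)
        np.testing.assert_array_equal(a.P, b.P)


class TestSubstrate:
    def test_index_matched_substrate_is_inert(self, water_scene):
        from dataclasses import replace

        scene_sub = replace(water_scene, substrate_enabled=True,
                            materials=MaterialSet(n_glass=1.33))
        grid_h = voxelize(water_scene, 1.0)
        grid_s = voxelize(scene_sub, 1.0)
        cs_h = cross_sections(solve_dda(
            grid_h, PlaneWave(LAM), SolverSettings(substrate_model="none")))
        cs_s = cross_sections(solve_dda(grid_s, PlaneWave(LAM),
                                        SolverSettings()))
        assert image_factor(1.33, 1.33) == 0.0
        assert cs_s.C_ext_um2 == pytest.approx(cs_h.C_ext_um2, rel=1e-6)

    def test_image_dipole_closed_form(self):
        """Textbook quasi-static image of a dipole above the interface."""
        n1, n2 = 1.33, 1.52
        beta = (n2**2 - n1**2) / (n2**2 + n1**2)
        p = np.array([1.0, 0.0, 0.0])
        zpos = 5.0
        obs = np.array([[0.0, 0.0, zpos]])
        E = quasistatic_image_field(obs, np.array([0.0, 0.0, zpos]), p,
                                    n1, n2)
        # horizontal dipole: image -beta*p at distance 2z below, on-axis
        # static field of a transverse dipole: E = -p'/r^3
        expected = beta * p / (2 * zpos) ** 3
        np.testing.assert_allclose(E[0], expected, rtol=1e-12)

    def test_substrate_redshifts_rod_resonance(self):
        """Glass below the rod pulls the longitudinal peak to the red."""
        from dataclasses import replace

        scene = build_scene(NanorodGeometry(10.0, 3.0), ShellSpec(0.0),
                            substrate_enabled=False)
        grid_h = voxelize(scene, 1.25)
        grid_s = voxelize(replace(scene, substrate_enabled=True), 1.25)
        lam = np.linspace(660.0, 780.0, 7)
        s_h = SolverSettings(substrate_model="none", tolerance=3e-4,
                             single_precision=True)
        s_s = SolverSettings(tolerance=3e-4, single_precision=True)
        df_h = compute_spectrum(grid_h, lam, s_h)
        df_s = compute_spectrum(grid_s, lam, s_s)

        def peak(df):
            v = df["C_scat_um2"].to_numpy()
            i = int(np.argmax(v))
            y = np.log(v[i - 1:i + 2])
            return lam[i] + 0.5 * (lam[1] - lam[0]) * (y[0] - y[2]) / (
                y[0] - 2 * y[1] + y[2])

        assert peak(df_s) > peak(df_h) + 1.0


class TestCrossSections:
    def test_rayleigh_absorption_closed_form(self, water_scene):
        """Tiny lossy sphere: C_abs matches 4 pi k Im(alpha_CM) to 2%."""
        from dataclasses import replace
        from plasmonsense.materials import DielectricTable

        eps = 2.56 + 0.06j
        nk = np.sqrt(eps)
        mats = MaterialSet(gold=DielectricTable(
            np.array([300.0, 1600.0]), np.full(2, nk.real),
            np.full(2, nk.imag)))
        scene = replace(water_scene, materials=mats,
                        rod=NanorodGeometry(4.0, 1.0))
        grid = voxelize(scene, 0.25)
        sol = solve_dda(grid, PlaneWave(LAM),
                        SolverSettings(substrate_model="none"))
        cs = cross_sections(sol)
        k = 2 * np.pi * N_W / LAM
        # radius of the sphere actually represented by the voxel set
        a3 = 3.0 * grid.material_volume("gold") / (4.0 * np.pi)
        alpha = a3 * (eps / EPS_W - 1) / (eps / EPS_W + 2)
        expected = 4 * np.pi * k * alpha.imag * 1e-6
        assert cs.C_abs_um2 == pytest.approx(expected, rel=0.02)

    def test_point_dipole_molecule_perturbs_spectrum(self):
        scene = build_scene(NanorodGeometry(16.0, 2.0),
                            molecule=MoleculeSpec(),
                            substrate_enabled=False)
        s = SolverSettings(substrate_model="none", tolerance=1e-4,
                           single_precision=True)
        g0 = voxelize(scene.without_molecule(), 2.0)
        g1 = voxelize(scene, 2.0, molecule_representation="point_dipole")
        lam = 620.0
        c0 = cross_sections(solve_dda(g0, PlaneWave(lam), s))
        c1 = cross_sections(solve_dda(g1, PlaneWave(lam), s))
        rel = c1.C_scat_um2 / c0.C_scat_um2 - 1.0
        assert rel != 0.0
        assert abs(rel) < 0.2


def test_empty_grid_raises(water_scene):
    grid = DipoleGrid(voxel_size=1.0, origin=np.zeros(3), shape=(1, 1, 1),
                      indices=np.empty((0, 3), dtype=int),
                      material_id=np.empty(0, dtype=np.int8),
                      scene=water_scene)
    with pytest.raises(ValueError):
        solve_dda(grid, PlaneWave(LAM))


def test_plane_wave_validation():
    with pytest.raises(ValueError):
        PlaneWave(600.0, polarization=(0.0, 0.0, 1.0))  # parallel to prop
    with pytest.raises(ValueError):
        PlaneWave(600.0, propagation=(0.0, 0.0, -2.0))
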