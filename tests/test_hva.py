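"""Vibration FEM: assembly oracles, modal reduction, loads, sweeps."""

import numpy as np
import pytest
import scipy.sparse as sp

import skullvibe as sv
from skullvibe import hva, press
from skullvibe.materials import Material
from skullvibe.phantom import SensorSpec


class TestAssembly:
    def test_element_stiffness_energy_oracle(self):
        """For any affine displacement u = G x the strain energy is
        (1/2) V eps:C:eps in closed form; the assembled K must
        reproduce it on a one-element mesh."""
        from skullvibe.hva import _element_stiffness, _elasticity_matrix

        rng = np.random.default_rng(3)
        coords = np.array([[[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1.0]]])
        coords = coords + 0.1 * rng.standard_normal(coords.shape)
        E, nu = 7.3e6, 0.29
        D = _elasticity_matrix(E, nu)
        Ke, vol = _element_stiffness(coords, D)
        G = rng.standard_normal((3, 3))
        u = (coords[0] @ G.T).ravel()  # u_a = G x_a
        energy_fem = 0.5 * u @ Ke[0] @ u
        eps = 0.5 * (G + G.T)
        voigt = np.array([eps[0, 0], eps[1, 1], eps[2, 2],
                          2 * eps[0, 1], 2 * eps[1, 2], 2 * eps[2, 0]])
        energy_exact = 0.5 * vol[0] * voigt @ D @ voigt
        assert energy_fem == pytest.approx(energy_exact, rel=1e-12)

    def test_total_mass_is_density_times_volume(self, tiny_system):
        mesh, mats, system = tiny_system
        ones = np.zeros(system.ndof)
        ones[0::3] = 1.0
        total = ones @ (system.M @ ones)
        expect = sum(mats[lab].rho * v for lab, v in
                     system.material_volumes.items())
        assert total == pytest.approx(expect, rel=1e-12)

    def test_sensor_masses_add_to_diagonal(self, tiny_block):
        mesh = sv.voxels_to_tetmesh(tiny_block)
        mats = sv.natural_preset()
        bare = sv.assemble_system(mesh, mats, [])
        sens = [SensorSpec("P/X", [0.0, 0.0, 0.0], [1.0, 0, 0], 0.004)]
        with_s = sv.assemble_system(mesh, mats, sens)
        diff = (with_s.M - bare.M).toarray()
        node = with_s.sensor_nodes["P/X"]
        expect = np.zeros_like(diff)
        for c in range(3):
            expect[3 * node + c, 3 * node + c] = 0.004
        assert np.allclose(diff, expect)

    def test_no_sensors_equals_bare_assembly(self, tiny_block):
        mesh = sv.voxels_to_tetmesh(tiny_block)
        mats = sv.natural_preset()
        a = sv.assemble_system(mesh, mats, [])
        b = sv.assemble_system(mesh, mats, sensors=None)
        assert (a.M - b.M).nnz == 0

    def test_missing_material_label_reported(self, tiny_block):
        mesh = sv.voxels_to_tetmesh(tiny_block)
        with pytest.raises(KeyError, match="label 1"):
            sv.assemble_system(mesh, {2: sv.natural_preset()[2]}, [])

    def test_stiffness_symmetric_positive_semidefinite(self, tiny_system):
        _mesh, _mats, system = tiny_system
        K = system.K_total.toarray()
        assert np.allclose(K, K.T, atol=1e-6 * np.abs(K).max())
        w = np.linalg.eigvalsh(K)
        assert w[0] > -1e-9 * w[-1]
        assert (w < 1e-9 * w[-1]).sum() == 6  # free-free: 6 rigid modes


class TestModalBasis:
    def test_six_rigid_modes_free_free(self, tiny_basis):
        lam = (2 * np.pi * tiny_basis.freqs) ** 2
        assert np.sum(lam < 1e-6 * lam[6]) == 6
        assert tiny_basis.n_rigid == 6

    def test_mass_orthonormal(self, tiny_basis):
        M = tiny_basis.system.M
        gram = tiny_basis.Phi.T @ (M @ tiny_basis.Phi)
        assert np.allclose(gram, np.eye(tiny_basis.n_modes), atol=1e-8)

    def test_cutoff_value(self):
        assert hva.modal_cutoff(1000.0, 1.5) == 1500.0

    def test_quadrupling_stiffness_doubles_frequencies(self, tiny_block):
        mesh = sv.voxels_to_tetmesh(tiny_block)
        mats = sv.natural_preset()
        mats4 = {k: m.replace(E=4 * m.E) for k, m in mats.items()}
        b1 = sv.compute_modal_basis(sv.assemble_system(mesh, mats, []), 1e9)
        b4 = sv.compute_modal_basis(sv.assemble_system(mesh, mats4, []), 1e9)
        el1, el4 = b1.freqs[6:], b4.freqs[6:]
        assert np.allclose(el4, 2 * el1, rtol=1e-6)

    def test_rigid_only_warning_for_low_cutoff(self, tiny_system):
        _m, _mats, system = tiny_system
        with pytest.warns(UserWarning, match="rigid"):
            basis = sv.compute_modal_basis(system, f_max=10.0)
        assert basis.n_modes == 6


class TestPressureLoad:
    def test_uniform_pressure_closed_surface_zero_net_force(self, tiny_system):
        mesh, _mats, system = tiny_system
        nodes = system.surface.node_indices
        spf = press.SurfacePressure(nodes, np.full(len(nodes), 7.0 + 0j), 100.0)
        load = hva.apply_pressure_load(system, spf)
        net = load.reshape(-1, 3).sum(axis=0)
        assert np.abs(net).max() < 1e-12 * np.abs(load).max()

    def test_linear_pressure_buoyancy_identity(self, tiny_system):
        """p = a x gives net force -grad(p) V on a closed body."""
        mesh, _mats, system = tiny_system
        nodes = system.surface.node_indices
        a = 3.0  # Pa per mm
        vals = (a * mesh.nodes[nodes, 0]).astype(complex)
        load = hva.apply_pressure_load(
            system, press.SurfacePressure(nodes, vals, 100.0))
        net = load.reshape(-1, 3).sum(axis=0).real
        V = mesh.volumes().sum() * 1e-9  # m^3
        assert net == pytest.approx([-a * 1e3 * V, 0.0, 0.0], abs=1e-9)

    def test_zero_pressure_zero_load(self, tiny_system):
        _m, _mats, system = tiny_system
        nodes = system.surface.node_indices
        load = hva.apply_pressure_load(
            system, press.SurfacePressure(nodes, np.zeros(len(nodes)), 1.0))
        assert np.all(load == 0)

    def test_mismatched_node_count_reported(self, tiny_system):
        _m, _mats, system = tiny_system
        with pytest.raises(ValueError, match="nodes"):
            hva.apply_pressure_load(
                system, press.SurfacePressure([0, 1], [1.0, 2.0], 1.0))


def sdof_setup(m=0.02, k=5.0e5, eta=0.08, F=0.3):
    """Hand-built single-DOF surrogate bound into the sweep machinery."""
    M = sp.diags([m, m, m]).tocsr()
    K = {1: sp.coo_matrix(([k], ([0], [0])), shape=(3, 3)).tocsr()}
    sensor = SensorSpec("P/X", [0.0, 0.0, 0.0], [1.0, 0.0, 0.0], 0.0)
    system = hva.SystemMatrices(M, K, mesh=None, surface=None,
                                sensor_nodes={"P/X": 0}, sensors=[sensor],
                                material_volumes={})
    Phi = np.array([[1.0 / np.sqrt(m)], [0.0], [0.0]])
    freqs = np.array([np.sqrt(k / m) / (2 * np.pi)])
    basis = hva.ModalBasis(Phi, freqs, {1: Phi.T @ (K[1] @ Phi)},
                           cutoff_hz=1e9, system=system)
    mats = {1: Material(1000.0, 1e9, 0.3, eta)}
    load = np.array([F, 0.0, 0.0], complex)
    return basis, mats, [sensor], load, (m, k, eta, F)


class TestFRFSweep:
    def test_sdof_matches_structural_damping_closed_form(self):
        """|H_accel| = w^2 F / |k(1+i eta) - w^2 m| to 1e-10 relative."""
        basis, mats, sensors, load, (m, k, eta, F) = sdof_setup()
        grid = np.linspace(100.0, 2000.0, 50)
        frf = hva.frf_sweep(basis, lambda f: load, mats, sensors, grid)
        w = 2 * np.pi * grid
        exact = -w**2 * F / (k * (1 + 1j * eta) - w**2 * m)
        assert np.allclose(frf["P/X"], exact, rtol=1e-10)

    def test_sdof_low_frequency_limit_vanishes(self):
        basis, mats, sensors, load, (m, k, eta, F) = sdof_setup()
        frf = hva.frf_sweep(basis, lambda f: load, mats, sensors,
                            np.array([1e-3]))
        assert np.abs(frf["P/X"][0]) < 1e-10

    def test_full_basis_equals_direct_solve(self, tiny_system, tiny_basis):
        mesh, mats, system = tiny_system
        scene = press.scene_from_phantom(
            sv.VoxelPhantom(np.ones((2, 2, 2), np.int8), [5.0] * 3, [0.0] * 3),
            mats)
        fld = press.incident_field(scene, 700.0)
        spf = press.sample_surface_pressure(fld, system.surface, mesh)
        load = hva.apply_pressure_load(system, spf)
        A = hva.reduced_matrix(tiny_basis, mats, 700.0)
        U_modal = tiny_basis.Phi @ np.linalg.solve(A, tiny_basis.Phi.T @ load)
        U_direct = hva.direct_solve(system, mats, load, 700.0)
        rel = np.linalg.norm(U_modal - U_direct) / np.linalg.norm(U_direct)
        assert rel < 1e-8

    def test_truncation_error_monotone_in_mode_count(self, tiny_system,
                                                     tiny_basis):
        mesh, mats, system = tiny_system
        rng = np.random.default_rng(5)
        load = rng.standard_normal(system.ndof) + 0j
        U_direct = hva.direct_solve(system, mats, load, 900.0)
        errs = []
        for n in (10, 30, 60, tiny_basis.n_modes):
            sub = hva.ModalBasis(tiny_basis.Phi[:, :n], tiny_basis.freqs[:n],
                                 {lab: Kt[:n, :n] for lab, Kt in
                                  tiny_basis.Ktil.items()},
                                 tiny_basis.cutoff_hz, system)
            A = hva.reduced_matrix(sub, mats, 900.0)
            U = sub.Phi @ np.linalg.solve(A, sub.Phi.T @ load)
            errs.append(np.linalg.norm(U - U_direct))
        assert all(b <= a * (1 + 1e-9) for a, b in zip(errs, errs[1:]))

    def test_reciprocity(self, tiny_system):
        """Load at DOF a measured at DOF b equals load at b measured
        at a (the damped system matrix is complex symmetric)."""
        _mesh, mats, system = tiny_system
        a, b = 10, 61
        ea = np.zeros(system.ndof, complex)
        eb = np.zeros(system.ndof, complex)
        ea[a] = 1.0
        eb[b] = 1.0
        Ua = hva.direct_solve(system, mats, ea, 800.0)
        Ub = hva.direct_solve(system, mats, eb, 800.0)
        assert Ua[b] == pytest.approx(Ub[a], rel=1e-8)


class TestAmplification:
    def _frfs(self, fac=3.0):
        freq = np.linspace(170, 1000, 20)
        base = np.exp(1j * freq / 100) * (1 + freq / 500)
        return sv.FRFSet(freq, {"S/ML": base, "L/ML": fac * base,
                                "R/ML": fac * base})

    def test_identical_channels_ratio_one(self):
        ratios, avg, flagged = hva.amplification(self._frfs(1.0))
        assert np.allclose(avg, 1.0)
        assert flagged.size == 0

    def test_uniform_scaling_ratio(self):
        ratios, avg, _ = hva.amplification(self._frfs(3.0))
        assert np.allclose(avg, 3.0)
        assert np.allclose(ratios["L/ML"], 3.0)

    def test_zero_denominator_flagged_as_inf(self):
        freq = np.array([170.0, 200.0])
        frfs = sv.FRFSet(freq, {"S/ML": [1.0, 0.0], "L/ML": [2.0, 2.0],
                                "R/ML": [2.0, 2.0]})
        ratios, avg, flagged = hva.amplification(frfs)
        assert flagged.tolist() == [1]
        assert np.isinf(ratios["L/ML"][1])

    def test_missing_channel_reported(self):
        frfs = sv.FRFSet(np.array([170.0]), {"S/ML": [1.0]})
        with pytest.raises(KeyError, match="L/ML"):
            hva.amplification(frfs)
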