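"""Acoustic pressure stage: harmonic extraction, steady-state solve,
frequency interpolation, surface sampling."""

import numpy as np
import pytest

import skullvibe as sv
from skullvibe.press import (AcousticScene, ComplexPressureField,
                             harmonic_projection, incident_field,
                             interpolate_pressure, sample_surface_pressure,
                             scene_from_phantom, simulate_pressure, CFL_MAX)


def water_scene(shape=(20, 20, 24), sponge=6):
    rho = np.full(shape, sv.WATER_DENSITY)
    c = np.full(shape, sv.WATER_SOUND_SPEED)
    return AcousticScene(rho, c, [5.0] * 3, [0.0] * 3, (0, 0, 1), sponge=sponge)


class TestHarmonicProjection:
    @pytest.mark.parametrize("A,phi", [(1.0, 0.0), (2.5, 0.7), (0.3, -2.1)])
    def test_pure_sinusoid_recovered_exactly(self, A, phi):
        """11 equispaced stations over one period recover A e^{i phi}
        from p(t) = A cos(w t + phi) to machine precision."""
        omega = 2 * np.pi * 437.0
        T = 2 * np.pi / omega
        times = 5 * T + np.arange(11) * T / 11
        samples = A * np.cos(omega * times + phi)
        P = harmonic_projection(samples, times, omega)
        assert P == pytest.approx(A * np.exp(1j * phi), abs=1e-12)

    def test_projection_is_linear_over_field_stacks(self):
        omega = 2 * np.pi * 100.0
        T = 2 * np.pi / omega
        times = np.arange(11) * T / 11
        fields = np.cos(omega * times)[:, None, None] * np.ones((11, 2, 3))
        P = harmonic_projection(fields, times, omega)
        assert P.shape == (2, 3)
        assert np.allclose(P, 1.0)


class TestSimulatePressure:
    def test_homogeneous_water_recovers_incident_wave(self):
        """No scatterer: the extracted total field equals the incident
        plane wave within 3% everywhere (scattered field vanishes)."""
        scene = water_scene()
        fld = simulate_pressure(scene, 2000.0, periods=4)
        inc = incident_field(scene, 2000.0)
        err = np.abs(fld.field - inc.field) / np.abs(inc.field)
        assert err.max() < 0.03

    def test_zero_amplitude_gives_zero_field(self):
        scene = water_scene()
        scene.amplitude = 0.0
        fld = simulate_pressure(scene, 2000.0, periods=3)
        assert np.allclose(fld.field, 0.0)

    def test_energy_bounded_in_homogeneous_water(self):
        scene = water_scene()
        fld = simulate_pressure(scene, 3000.0, periods=5)
        assert np.abs(fld.field).max() <= 3.0 * scene.amplitude

    def test_cfl_violation_rejected(self):
        with pytest.raises(ValueError, match="CFL"):
            simulate_pressure(water_scene(), 1000.0, cfl=0.8)
        assert CFL_MAX == pytest.approx(1 / np.sqrt(3))

    def test_too_few_periods_rejected(self):
        with pytest.raises(ValueError, match="periods"):
            simulate_pressure(water_scene(), 1000.0, periods=2)

    def test_steady_state_converged_with_scatterer(self, small_phantom):
        """Doubling the number of periods changes the extracted field
        by < 1% of the incident amplitude (steady state reached)."""
        scene = scene_from_phantom(small_phantom, sv.natural_preset(),
                                   margin=2, sponge=6)
        a = simulate_pressure(scene, 1500.0, periods=4)
        b = simulate_pressure(scene, 1500.0, periods=8)
        assert np.abs(a.field - b.field).max() < 0.01 * scene.amplitude

    def test_deterministic(self):
        scene = water_scene((12, 12, 14), sponge=4)
        a = simulate_pressure(scene, 3000.0, periods=3)
        b = simulate_pressure(scene, 3000.0, periods=3)
        assert np.array_equal(a.field, b.field)


class TestInterpolation:
    def _field(self, values, f):
        return ComplexPressureField(values, f, [5.0] * 3, [0.0] * 3)

    def test_pass_through_at_grid_frequency(self):
        rng = np.random.default_rng(0)
        fields = [self._field(rng.standard_normal((3, 3, 3))
                              + 1j * rng.standard_normal((3, 3, 3)), f)
                  for f in (100.0, 200.0, 300.0)]
        out = interpolate_pressure(fields, 200.0)
        assert out is fields[1]

    def test_exact_on_linear_in_frequency_fields(self):
        base = np.linspace(0, 1, 27).reshape(3, 3, 3)
        fields = [self._field((2.0 + 0.01 * f) * base + 1j * (f * base), f)
                  for f in (100.0, 200.0)]
        out = interpolate_pressure(fields, 150.0)
        expect = (2.0 + 1.5) * base + 1j * 150.0 * base
        assert np.allclose(out.field, expect, rtol=1e-14)

    def test_equal_brackets_returned_unchanged(self):
        v = np.ones((2, 2, 2), complex) * (1 + 2j)
        fields = [self._field(v.copy(), 100.0), self._field(v.copy(), 200.0)]
        out = interpolate_pressure(fields, 137.0)
        assert np.allclose(out.field, v)

    def test_no_extrapolation(self):
        fields = [self._field(np.zeros((2, 2, 2)), f) for f in (100.0, 200.0)]
        with pytest.raises(ValueError, match="outside"):
            interpolate_pressure(fields, 250.0)

    def test_halfway_error_shrinks_with_finer_frequency_grid(self, small_phantom):
        """Interpolating to a mid-grid frequency from a 200 Hz-spaced
        coarse grid is worse than from a 100 Hz-spaced grid (the
        trade-off quantified for the pressure-loading stage)."""
        scene = scene_from_phantom(small_phantom, sv.natural_preset(),
                                   margin=2, sponge=6)
        fs = {f: simulate_pressure(scene, f, periods=4)
              for f in (1000.0, 1500.0, 2000.0)}
        truth = fs[1500.0].field
        coarse = interpolate_pressure([fs[1000.0], fs[2000.0]], 1500.0).field
        # finer bracket: simulate 1250/1750 and interpolate
        f1250 = simulate_pressure(scene, 1250.0, periods=4)
        f1750 = simulate_pressure(scene, 1750.0, periods=4)
        fine = interpolate_pressure([f1250, f1750], 1500.0).field
        assert np.abs(fine - truth).max() <= np.abs(coarse - truth).max()


class TestSurfaceSampling:
    def test_constant_field_sampled_exactly(self, single_voxel):
        mesh = sv.voxels_to_tetmesh(single_voxel)
        surf = sv.extract_wetted_surface(mesh)
        scene = scene_from_phantom(single_voxel, sv.natural_preset(),
                                   margin=2, sponge=2)
        fld = ComplexPressureField(np.full(scene.shape, 3 - 4j), 100.0,
                                   scene.spacing, scene.origin)
        sp = sample_surface_pressure(fld, surf, mesh)
        assert np.allclose(sp.values, 3 - 4j)
        assert len(sp.values) == len(surf.node_indices)

    def test_linear_field_sampled_to_machine_precision(self, single_voxel):
        mesh = sv.voxels_to_tetmesh(single_voxel)
        surf = sv.extract_wetted_surface(mesh)
        scene = scene_from_phantom(single_voxel, sv.natural_preset(),
                                   margin=2, sponge=2)
        xs, ys, zs = scene.cell_centers()
        lin = (2.0 * xs[:, None, None] + 0.5 * ys[None, :, None]
               - zs[None, None, :]).astype(complex)
        fld = ComplexPressureField(lin, 100.0, scene.spacing, scene.origin)
        sp = sample_surface_pressure(fld, surf, mesh)
        pts = mesh.nodes[sp.node_indices]
        expect = 2.0 * pts[:, 0] + 0.5 * pts[:, 1] - pts[:, 2]
        assert np.allclose(sp.values.real, expect, rtol=1e-12)

    def test_plane_wave_phase_gradient_along_incidence(self, small_phantom):
        mesh = sv.voxels_to_tetmesh(small_phantom)
        surf = sv.extract_wetted_surface(mesh)
        scene = scene_from_phantom(small_phantom, sv.natural_preset())
        fld = incident_field(scene, 800.0)
        sp = sample_surface_pressure(fld, surf, mesh)
        z = mesh.nodes[sp.node_indices][:, 2]
        phase = np.angle(sp.values)
        # arg(p) = -k z: fit the slope over unwrapped phase vs z
        order = np.argsort(z)
        slope = np.polyfit(z[order], np.unwrap(phase[order]), 1)[0]
        k = 2 * np.pi * 800.0 / sv.WATER_SOUND_SPEED / 1000.0  # 1/mm
        assert slope == pytest.approx(-k, rel=1e-6)

    def test_point_outside_grid_reported(self, single_voxel):
        mesh = sv.voxels_to_tetmesh(single_voxel)
        surf = sv.extract_wetted_surface(mesh)
        fld = ComplexPressureField(np.zeros((3, 3, 3)), 100.0,
                                   [5.0] * 3, [100.0, 0.0, 0.0])
        with pytest.raises(ValueError, match="outside"):
            sample_surface_pressure(fld, surf, mesh)
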