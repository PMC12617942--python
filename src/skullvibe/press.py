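"""Steady-state acoustic pressure loading around the phantom.

A plane wave of unit amplitude impinges on the skull from the water.
The total pressure field it sets up — incident plus scattered — is the
boundary load for the vibration model.  The field is computed with an
explicit time-domain solve of the heterogeneous scalar wave equation

    (1 / (rho c^2)) d2p/dt2 = div( (1/rho) grad p ),

stepped with the centered-difference scheme until a steady wave train
develops, then sampled at a small number of equispaced time stations
during the final period and projected onto cos/sin at the drive
frequency to extract the complex harmonic amplitude.

Two modeling choices keep the solve small and robust:

* **Scattered-field formulation** — the simulation variable is
  p_scattered = p_total - p_incident, driven by the residual of the
  analytic incident wave under the heterogeneous discrete operator.
  In homogeneous water that residual is only the O(h^2) dispersion
  error, so the total field reduces to the incident wave essentially
  exactly; the absorbing boundary only has to swallow the (small)
  scattered wave.
* **Fluid-equivalent solids** — bone, TPC and connective tissue enter
  acoustically through their density and an equivalent bulk sound
  speed sqrt(E/rho).  This preserves the impedance-contrast structure
  of the scattering problem; the full elastodynamic response lives in
  the vibration model, which consumes this pressure as a one-way load.

The domain is terminated with graded sponge (damping) layers on all
faces, emulating an infinite extent of water.

Phase convention: time-harmonic factor exp(+i w t), so a wave traveling
along unit direction d has complex amplitude A exp(-i k d.x).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .materials import WATER_DENSITY, WATER_SOUND_SPEED, MaterialMap
from .meshing import TetMesh, TriSurface
from .phantom import VoxelPhantom

#: CFL stability ceiling for the 3-D centered-difference scheme.
CFL_MAX = 1.0 / np.sqrt(3.0)


@dataclass
class AcousticScene:
    """Heterogeneous acoustic medium on a padded voxel grid.

    ``rho`` and ``c`` are cell-centered; ``origin`` is the world
    coordinate of the corner of cell (0, 0, 0), mm; ``spacing`` the
    cell edge lengths, mm.  ``sponge`` cells on every face are graded
    absorbers and not part of the physical domain.
    """

    rho: np.ndarray  # kg/m^3
    c: np.ndarray  # m/s
    spacing: np.ndarray  # mm
    origin: np.ndarray  # mm
    direction: np.ndarray  # incident unit direction
    amplitude: float = 1.0  # Pa
    sponge: int = 8
    water_rho: float = WATER_DENSITY
    water_c: float = WATER_SOUND_SPEED

    def __post_init__(self) -> None:
        self.rho = np.asarray(self.rho, float)
        self.c = np.asarray(self.c, float)
        self.spacing = np.asarray(self.spacing, float)
        self.origin = np.asarray(self.origin, float)
        d = np.asarray(self.direction, float)
        self.direction = d / np.linalg.norm(d)
        if np.any(self.rho <= 0) or np.any(self.c <= 0):
            raise ValueError("density and sound speed must be positive everywhere")
        if self.rho.shape != self.c.shape:
            raise ValueError("rho and c grids must have identical shape")

    @property
    def shape(self):
        return self.rho.shape

    def cell_centers(self):
        """World coordinates (mm) of cell centers, as three 1-D axes."""
        return tuple(self.origin[a] + (np.arange(self.shape[a]) + 0.5) * self.spacing[a]
                     for a in range(3))


def scene_from_phantom(phantom: VoxelPhantom, materials: MaterialMap,
                       direction=(0.0, 0.0, 1.0), amplitude: float = 1.0,
                       margin: int = 3, sponge: int = 8) -> AcousticScene:
    """Embed the phantom in water with ``margin`` water cells plus
    ``sponge`` absorber cells padded on every face."""
    pad = margin + sponge
    shape = tuple(n + 2 * pad for n in phantom.shape)
    rho = np.full(shape, WATER_DENSITY)
    c = np.full(shape, WATER_SOUND_SPEED)
    core = tuple(slice(pad, pad + n) for n in phantom.shape)
    rho_map = np.array([WATER_DENSITY] + [materials[m].rho for m in (1, 2, 3)])
    c_map = np.array([WATER_SOUND_SPEED] + [materials[m].bulk_sound_speed
                                            for m in (1, 2, 3)])
    rho[core] = rho_map[phantom.labels]
    c[core] = c_map[phantom.labels]
    origin = phantom.origin - pad * phantom.spacing
    return AcousticScene(rho, c, phantom.spacing, origin, direction,
                         amplitude, sponge)


@dataclass
class ComplexPressureField:
    """Complex harmonic pressure amplitude on a cell-centered grid."""

    field: np.ndarray  # complex, Pa
    frequency: float  # Hz
    spacing: np.ndarray  # mm
    origin: np.ndarray  # mm, corner of cell (0,0,0)

    def __post_init__(self) -> None:
        self.field = np.asarray(self.field, complex)
        self.spacing = np.asarray(self.spacing, float)
        self.origin = np.asarray(self.origin, float)
        if self.frequency <= 0:
            raise ValueError(f"frequency must be positive, got {self.frequency}")
        if not np.all(np.isfinite(self.field.view(float))):
            raise ValueError("pressure field contains non-finite values")

    def sample(self, points: np.ndarray) -> np.ndarray:
        """Trilinear interpolation of the complex field at world points
        (mm).  Points must lie within the hull of cell centers."""
        pts = np.atleast_2d(np.asarray(points, float))
        idx = (pts - self.origin) / self.spacing - 0.5
        hi = np.array(self.field.shape) - 1
        bad = np.any((idx < -1e-9) | (idx > hi + 1e-9), axis=1)
        if bad.any():
            raise ValueError(f"point index {int(np.flatnonzero(bad)[0])} at "
                             f"{pts[bad][0]} mm lies outside the pressure grid")
        idx = np.clip(idx.T, 0, hi[:, None])
        re = ndimage.map_coordinates(self.field.real, idx, order=1, mode="nearest")
        im = ndimage.map_coordinates(self.field.imag, idx, order=1, mode="nearest")
        return re + 1j * im

    def save(self, path) -> None:
        np.savez_compressed(Path(path).with_suffix(".npz"),
                            real=self.field.real, imag=self.field.imag,
                            frequency=self.frequency, spacing=self.spacing,
                            origin=self.origin)

    @classmethod
    def load(cls, path) -> "ComplexPressureField":
        z = np.load(Path(path).with_suffix(".npz"))
        return cls(z["real"] + 1j * z["imag"], float(z["frequency"]),
                   z["spacing"], z["origin"])

    def export_vtk(self, path) -> None:
        """Legacy-ASCII VTK image data with real/imag point fields."""
        n = self.field.shape
        with open(path, "w") as f:
            f.write("# vtk DataFile Version 3.0\nskullvibe pressure field\n"
                    "ASCII\nDATASET STRUCTURED_POINTS\n")
            f.write(f"DIMENSIONS {n[0]} {n[1]} {n[2]}\n")
            o = self.origin + 0.5 * self.spacing
            f.write(f"ORIGIN {o[0]} {o[1]} {o[2]}\n")
            f.write(f"SPACING {self.spacing[0]} {self.spacing[1]} {self.spacing[2]}\n")
            f.write(f"POINT_DATA {self.field.size}\n")
            for name, comp in (("p_real", self.field.real), ("p_imag", self.field.imag)):
                f.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                np.savetxt(f, comp.ravel(order="F"), fmt="%.9g")


def harmonic_projection(samples: np.ndarray, times: np.ndarray,
                        omega: float) -> np.ndarray:
    """Complex amplitude P with p(t) = Re[P exp(i w t)] from equispaced
    samples spanning one period (endpoint excluded).

    For p(t) = A cos(w t + phi) this returns A exp(i phi) exactly.
    ``samples`` may carry extra leading axes (a stack of fields)."""
    phase = np.exp(-1j * omega * np.asarray(times, float))
    return 2.0 * np.tensordot(phase, np.asarray(samples), axes=(0, 0)) / len(times)


def incident_field(scene: AcousticScene, frequency: float) -> ComplexPressureField:
    """The analytic incident plane wave on the scene grid (no
    scattering): P = A exp(-i k d.x)."""
    k = 2 * np.pi * frequency / scene.water_c / 1000.0  # 1/mm
    xs, ys, zs = scene.cell_centers()
    phase = (scene.direction[0] * xs[:, None, None]
             + scene.direction[1] * ys[None, :, None]
             + scene.direction[2] * zs[None, None, :])
    return ComplexPressureField(scene.amplitude * np.exp(-1j * k * phase),
                                frequency, scene.spacing, scene.origin)


def _sponge_mask(scene: AcousticScene, strength: float = 0.10) -> np.ndarray:
    """Per-step multiplicative damping mask, graded quadratically from 1
    at the inner sponge edge to exp(-strength) at the outer face."""
    mask = np.ones(scene.shape)
    n = scene.sponge
    if n <= 0:
        return mask
    for axis, size in enumerate(scene.shape):
        coord = np.arange(size, dtype=float)
        depth = np.maximum(n - coord, coord - (size - 1 - n))
        profile = np.exp(-strength * np.clip(depth / n, 0.0, 1.0) ** 2)
        shape = [1, 1, 1]
        shape[axis] = size
        mask = mask * profile.reshape(shape)
    return mask


def _het_laplacian(p: np.ndarray, kappa_face, out: np.ndarray) -> None:
    """out <- div((1/rho) grad p) using face-averaged 1/rho (already
    scaled by 1/h^2 per axis), with zero-Neumann closure at the outer
    faces (harmless: it sits inside the sponge and the scattered-field
    source vanishes there)."""
    out[:] = 0.0
    for axis in range(3):
        kf = kappa_face[axis]
        d = np.diff(p, axis=axis)  # p_{i+1} - p_i at faces
        flux = kf * d
        sl_lo = [slice(None)] * 3
        sl_hi = [slice(None)] * 3
        sl_lo[axis] = slice(0, -1)
        sl_hi[axis] = slice(1, None)
        out[tuple(sl_lo)] += flux
        out[tuple(sl_hi)] -= flux


def _face_kappa(rho: np.ndarray, h_m: np.ndarray):
    """Face-averaged 1/rho scaled by 1/h^2, one array per axis."""
    kappa = 1.0 / rho
    out = []
    for a in range(3):
        lo = np.take(kappa, range(0, rho.shape[a] - 1), axis=a)
        hi = np.take(kappa, range(1, rho.shape[a]), axis=a)
        out.append(0.5 * (lo + hi) / h_m[a] ** 2)
    return out


def _step_numpy(p, p_old, p_new, kappa_face, A, drive, mask, lap):
    _het_laplacian(p, kappa_face, lap)
    np.multiply(A, lap + drive, out=p_new)
    p_new += 2.0 * p
    p_new -= p_old
    p_new *= mask
    np.multiply(p, mask, out=p_old)


try:  # optional compiled kernel; the numpy path is the reference
    import numba as _nb

    @_nb.njit(cache=True, fastmath=True)
    def _step_fused(p, p_old, p_new, kfx, kfy, kfz, A, Qr, Qi, cwt, swt,
                    g, mask):  # pragma: no cover - exercised via wrapper
        nx, ny, nz = p.shape
        for i in range(nx):
            for j in range(ny):
                for k in range(nz):
                    lap = 0.0
                    if i + 1 < nx:
                        lap += kfx[i, j, k] * (p[i + 1, j, k] - p[i, j, k])
                    if i > 0:
                        lap -= kfx[i - 1, j, k] * (p[i, j, k] - p[i - 1, j, k])
                    if j + 1 < ny:
                        lap += kfy[i, j, k] * (p[i, j + 1, k] - p[i, j, k])
                    if j > 0:
                        lap -= kfy[i, j - 1, k] * (p[i, j, k] - p[i, j - 1, k])
                    if k + 1 < nz:
                        lap += kfz[i, j, k] * (p[i, j, k + 1] - p[i, j, k])
                    if k > 0:
                        lap -= kfz[i, j, k - 1] * (p[i, j, k] - p[i, j, k - 1])
                    drive = g * (Qr[i, j, k] * cwt - Qi[i, j, k] * swt)
                    val = (2.0 * p[i, j, k] - p_old[i, j, k]
                           + A[i, j, k] * (lap + drive))
                    p_new[i, j, k] = val * mask[i, j, k]
                    p_old[i, j, k] = p[i, j, k] * mask[i, j, k]

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False


def simulate_pressure(scene: AcousticScene, frequency: float,
                      periods: int = 4, stations: int = 11,
                      cfl: float = 0.5, ramp_periods: float = 2.0,
                      sponge_strength: float = 0.10) -> ComplexPressureField:
    """Steady-state total pressure for a plane incident wave.

    The scattered field is stepped for ``periods`` periods of the drive,
    the source ramped on over ``ramp_periods``, then sampled at
    ``stations`` equispaced stations in the final period and projected
    onto the drive harmonic.  Returns incident + scattered amplitude.
    """
    if periods < 3:
        raise ValueError(f"periods must be >= 3, got {periods}")
    if stations < 3:
        raise ValueError(f"stations must be >= 3, got {stations}")
    if cfl > CFL_MAX + 1e-12 or cfl <= 0:
        raise ValueError(f"CFL factor {cfl} violates the stability bound "
                         f"0 < cfl <= 1/sqrt(3) = {CFL_MAX:.6f}")
    h_m = scene.spacing * 1e-3
    c_max = float(scene.c.max())
    dt_max = cfl * h_m.min() / c_max
    T = 1.0 / frequency
    spp = int(np.ceil(T / dt_max))
    spp = stations * int(np.ceil(spp / stations))  # stations divide the period
    dt = T / spp
    omega = 2 * np.pi * frequency

    kappa_face = _face_kappa(scene.rho, h_m)
    rc2 = scene.rho * scene.c**2

    # Scattered-field source: the incident wave's residual under the
    # heterogeneous discrete operator MINUS its residual under the
    # uniform-water operator.  The water parts (dispersion error and
    # boundary closure) cancel exactly, so Q is supported only on and
    # around the scatterer and vanishes identically in open water.
    p_inc = incident_field(scene, frequency).field
    lap_het = np.empty(scene.shape, complex)
    _het_laplacian(p_inc, kappa_face, lap_het)
    kappa_water = _face_kappa(np.full(scene.shape, scene.water_rho), h_m)
    lap_wat = np.empty(scene.shape, complex)
    _het_laplacian(p_inc, kappa_water, lap_wat)
    Q = (lap_het - lap_wat) + omega**2 * (1.0 / rc2 - 1.0 / (
        scene.water_rho * scene.water_c**2)) * p_inc
    Qr = np.ascontiguousarray(Q.real)
    Qi = np.ascontiguousarray(Q.imag)

    mask = _sponge_mask(scene, sponge_strength)
    A = (dt * dt) * rc2
    p_old = np.zeros(scene.shape)
    p = np.zeros(scene.shape)
    p_new = np.empty(scene.shape)
    lap = np.empty(scene.shape)

    n_steps = periods * spp
    station_step = spp // stations
    first_station = n_steps - spp  # final period, endpoint excluded
    ramp_steps = ramp_periods * spp
    snaps, times = [], []

    for n in range(n_steps):
        t = n * dt
        g = 0.5 * (1 - np.cos(np.pi * min(n / ramp_steps, 1.0))) if ramp_steps else 1.0
        cwt, swt = np.cos(omega * t), np.sin(omega * t)
        if _HAVE_NUMBA:
            _step_fused(p, p_old, p_new, *kappa_face, A, Qr, Qi,
                        cwt, swt, g, mask)
        else:
            drive = g * (Qr * cwt - Qi * swt)
            _step_numpy(p, p_old, p_new, kappa_face, A, drive, mask, lap)
        p, p_new = p_new, p
        if n + 1 >= first_station and (n + 1 - first_station) % station_step == 0 \
                and len(snaps) < stations:
            snaps.append(p.copy())
            times.append((n + 1) * dt)

    if not np.all(np.isfinite(p)):
        raise RuntimeError("time stepping diverged (non-finite pressure)")
    p_sc = harmonic_projection(np.array(snaps), np.array(times), omega)
    return ComplexPressureField(p_inc + p_sc, frequency, scene.spacing,
                                scene.origin)


def interpolate_pressure(fields: list, f_target: float) -> ComplexPressureField:
    """Linear-in-frequency interpolation of complex pressure fields.

    ``fields`` is a list of ComplexPressureField on a coarse frequency
    grid (e.g. 100, 200, ..., 1000 Hz); the two bracketing fields are
    combined per voxel, real and imaginary parts independently.  Exact
    pass-through at grid frequencies; no extrapolation.
    """
    fields = sorted(fields, key=lambda f: f.frequency)
    freqs = np.array([f.frequency for f in fields])
    if not (freqs[0] - 1e-9 <= f_target <= freqs[-1] + 1e-9):
        raise ValueError(f"target {f_target} Hz outside computed range "
                         f"[{freqs[0]}, {freqs[-1]}] Hz (no extrapolation)")
    exact = np.flatnonzero(np.isclose(freqs, f_target, rtol=0, atol=1e-9))
    if exact.size:
        return fields[int(exact[0])]
    hi = int(np.searchsorted(freqs, f_target))
    lo = hi - 1
    w = (f_target - freqs[lo]) / (freqs[hi] - freqs[lo])
    blend = (1 - w) * fields[lo].field + w * fields[hi].field
    return ComplexPressureField(blend, f_target, fields[lo].spacing,
                                fields[lo].origin)


@dataclass
class SurfacePressure:
    """Complex pressure at the wetted-surface nodes of a mesh."""

    node_indices: np.ndarray  # parent-mesh node ids
    values: np.ndarray  # complex, Pa
    frequency: float

    def __post_init__(self) -> None:
        self.node_indices = np.asarray(self.node_indices, np.int64)
        self.values = np.asarray(self.values, complex)
        if len(self.node_indices) != len(self.values):
            raise ValueError("node index and value counts differ")


def sample_surface_pressure(field: ComplexPressureField, surface: TriSurface,
                            mesh: TetMesh) -> SurfacePressure:
    """Re-interpolate the volumetric pressure onto the wetted-surface
    nodes (trilinear)."""
    nodes = surface.node_indices
    values = field.sample(mesh.nodes[nodes])
    return SurfacePressure(nodes, values, field.frequency)
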