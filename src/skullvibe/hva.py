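"""Damped harmonic forced-vibration FEM with modal reduction.

The skull's steady-state response to harmonic pressure loading solves

    [ -w^2 M + sum_m (1 + i eta_m) K_m ] U = L,

where M is the consistent mass matrix (plus lumped sensor masses), K_m
the stiffness contributed by material m, eta_m its structural loss
factor, and L the nodal load equivalent of the acoustic pressure acting
on the wetted boundary.  Because each material carries its own loss
factor the damped stiffness cannot be diagonalized jointly with M, so
the system is projected onto the undamped free-free modal basis (all
modes up to a safety factor times the top sweep frequency, rigid-body
modes included) and a small dense complex system is solved per
frequency.

Elements are standard 4-node constant-strain tetrahedra.  Coordinates
come in mm and are converted to SI internally; loads are N, outputs
displacement m (acceleration m/s^2 after the -w^2 factor).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg as sla
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .frf import FRFSet
from .materials import MaterialMap
from .meshing import TetMesh, TriSurface, extract_wetted_surface
from .phantom import SensorSpec
from .press import SurfacePressure

#: Eigenvalues below this fraction of the first elastic eigenvalue are
#: treated as rigid-body modes.
RIGID_TOL = 1e-6


def _elasticity_matrix(E: float, nu: float) -> np.ndarray:
    """6x6 isotropic elasticity matrix in Voigt order
    (xx, yy, zz, xy, yz, zx) with engineering shear strains."""
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    D = np.zeros((6, 6))
    D[:3, :3] = lam
    D[np.arange(3), np.arange(3)] += 2 * mu
    D[np.arange(3, 6), np.arange(3, 6)] = mu
    return D


def _shape_gradients(coords: np.ndarray):
    """Per-element shape-function gradients and volumes.

    coords: (n_el, 4, 3) node coordinates in meters.
    Returns grads (n_el, 4, 3) with rows dN_a/dx, and volumes (n_el,).
    """
    J = coords[:, 1:, :] - coords[:, :1, :]  # (n_el, 3, 3), rows = edges
    detJ = np.linalg.det(J)
    vol = detJ / 6.0
    Jinv = np.linalg.inv(J)  # (n_el, 3, 3)
    g123 = np.transpose(Jinv, (0, 2, 1))  # dN_a/dx = rows of J^{-T}
    g0 = -g123.sum(axis=1, keepdims=True)
    return np.concatenate([g0, g123], axis=1), vol


def _element_stiffness(coords: np.ndarray, D: np.ndarray):
    """Constant-strain-tet stiffness matrices, (n_el, 12, 12)."""
    grads, vol = _shape_gradients(coords)
    n_el = len(coords)
    B = np.zeros((n_el, 6, 12))
    for a in range(4):
        gx, gy, gz = grads[:, a, 0], grads[:, a, 1], grads[:, a, 2]
        c = 3 * a
        B[:, 0, c] = gx
        B[:, 1, c + 1] = gy
        B[:, 2, c + 2] = gz
        B[:, 3, c] = gy
        B[:, 3, c + 1] = gx
        B[:, 4, c + 1] = gz
        B[:, 4, c + 2] = gy
        B[:, 5, c] = gz
        B[:, 5, c + 2] = gx
    Ke = np.einsum("eia,ij,ejb,e->eab", B, D, B, vol, optimize=True)
    return Ke, vol


#: Consistent-mass coupling of the 4 tet nodes: (1 + delta_ab) / 20.
_MASS_COUPLING = (np.ones((4, 4)) + np.eye(4)) / 20.0


@dataclass
class SystemMatrices:
    """Assembled FE system for one mesh + material + sensor setup."""

    M: sp.csr_matrix  # kg (sensor point masses included)
    K: dict  # material label -> csr stiffness, N/m
    mesh: TetMesh
    surface: TriSurface
    sensor_nodes: dict  # channel name -> mesh node index
    sensors: list  # SensorSpec in channel order
    material_volumes: dict  # label -> total volume m^3

    @property
    def ndof(self) -> int:
        return 3 * self.mesh.n_nodes

    @property
    def K_total(self) -> sp.csr_matrix:
        return sum(self.K.values())


def assemble_system(mesh: TetMesh, materials: MaterialMap,
                    sensors: list | None = None,
                    surface: TriSurface | None = None) -> SystemMatrices:
    """Assemble mass and per-material stiffness matrices.

    Each sensor's mass is lumped onto the three translational DOFs of
    the mesh node nearest its geometric location.
    """
    sensors = sensors or []
    labels = np.unique(mesh.material)
    for lab in labels:
        if int(lab) not in materials:
            raise KeyError(f"no material properties for label {int(lab)}")
    coords = mesh.nodes * 1e-3  # m
    n_nodes = mesh.n_nodes
    ndof = 3 * n_nodes

    lo, hi = mesh.nodes.min(axis=0), mesh.nodes.max(axis=0)
    tol = 0.02 * np.linalg.norm(hi - lo)  # smoothing may pull the hull in
    for s in sensors:
        if np.any(s.location < lo - tol) or np.any(s.location > hi + tol):
            raise ValueError(f"sensor {s.name} at {s.location} mm lies outside "
                             f"the mesh bounding box")

    # DOF indices per element: (n_el, 12)
    def edofs(tets):
        return (3 * tets[:, :, None] + np.arange(3)[None, None, :]).reshape(len(tets), 12)

    K = {}
    M = sp.coo_matrix((ndof, ndof))
    material_volumes = {}
    for lab in labels:
        mat = materials[int(lab)]
        sel = mesh.material == lab
        tets = mesh.tets[sel]
        ec = coords[tets]
        D = _elasticity_matrix(mat.E, mat.nu)
        Ke, vol = _element_stiffness(ec, D)
        if np.any(vol <= 0):
            bad = int(np.flatnonzero(sel)[np.argmin(vol)])
            raise ValueError(f"degenerate tetrahedron, element {bad} "
                             f"(volume {vol.min():.3g} m^3)")
        material_volumes[int(lab)] = float(vol.sum())
        dof = edofs(tets)
        rows = np.repeat(dof, 12, axis=1).ravel()
        cols = np.tile(dof, (1, 12)).ravel()
        K[int(lab)] = sp.coo_matrix((Ke.ravel(), (rows, cols)),
                                    shape=(ndof, ndof)).tocsr()
        # Consistent mass: block (1+delta)/20 * rho * V per coordinate.
        Me = (mat.rho * vol)[:, None, None] * _MASS_COUPLING[None, :, :]
        nrows = np.repeat(tets, 4, axis=1).ravel()
        ncols = np.tile(tets, (1, 4)).ravel()
        for comp in range(3):
            M += sp.coo_matrix((Me.ravel(), (3 * nrows + comp, 3 * ncols + comp)),
                               shape=(ndof, ndof))

    sensor_nodes = {}
    diag = np.zeros(ndof)
    for s in sensors:
        node = int(np.argmin(np.sum((mesh.nodes - s.location) ** 2, axis=1)))
        sensor_nodes[s.name] = node
        diag[3 * node: 3 * node + 3] += s.mass
    M = (M + sp.diags(diag)).tocsr()

    if surface is None:
        surface = extract_wetted_surface(mesh)
    return SystemMatrices(M, K, mesh, surface, sensor_nodes, list(sensors),
                          material_volumes)


@dataclass
class ModalBasis:
    """Mass-normalized undamped modes below the cutoff frequency."""

    Phi: np.ndarray  # (ndof, n_modes)
    freqs: np.ndarray  # Hz, nondecreasing
    Ktil: dict  # label -> (n_modes, n_modes) projected stiffness
    cutoff_hz: float
    system: SystemMatrices
    n_rigid_count: int | None = None

    @property
    def n_modes(self) -> int:
        return self.Phi.shape[1]

    @property
    def n_rigid(self) -> int:
        if self.n_rigid_count is not None:
            return self.n_rigid_count
        lam = (2 * np.pi * self.freqs) ** 2
        if len(lam) == 0:
            return 0
        return int(np.sum(lam <= RIGID_TOL * lam.max()))


def modal_cutoff(f_max: float, safety: float = 1.5) -> float:
    """Retain-all-modes-below frequency: safety * f_max (default 1.5x,
    ensuring tight approximation power of the reduced model)."""
    if safety < 1:
        raise ValueError(f"safety factor must be >= 1, got {safety}")
    return safety * f_max


def compute_modal_basis(system: SystemMatrices, f_max: float = 1000.0,
                        safety: float = 1.5) -> ModalBasis:
    """Solve the generalized eigenproblem K Phi = M Phi Lambda and keep
    every mode with natural frequency <= safety * f_max.

    Free-free solids retain their 6 rigid-body modes.  Small systems
    are solved densely; larger ones with shift-invert Lanczos at a
    small negative shift (K is singular for free-free structures).
    """
    cutoff = modal_cutoff(f_max, safety)
    lam_cut = (2 * np.pi * cutoff) ** 2
    ndof = system.ndof
    K = system.K_total
    M = system.M

    if ndof <= 600:
        lam, vecs = sla.eigh(K.toarray(), M.toarray())
    else:
        sigma = -1e-4 * lam_cut  # factor K - sigma*M stays SPD
        k = min(max(24, 12), ndof - 2)
        # fixed start vector: keeps repeated runs bit-identical
        v0 = np.random.default_rng(12345).standard_normal(ndof)
        while True:
            lam, vecs = spla.eigsh(K, k=k, M=M, sigma=sigma, which="LM", v0=v0)
            order = np.argsort(lam)
            lam, vecs = lam[order], vecs[:, order]
            if lam[-1] > lam_cut or k >= ndof - 2:
                break
            k = min(2 * k, ndof - 2)
    lam = np.clip(lam, 0.0, None)
    # rigid-body modes judged against the largest computed eigenvalue
    lam_ref = max(float(lam.max()), 1.0)
    keep = lam <= lam_cut
    if not keep.any():
        keep = np.zeros_like(keep)
        keep[: min(6, len(lam))] = True
    n_rigid = int(np.sum(lam[keep] <= RIGID_TOL * lam_ref))
    lam, vecs = lam[keep], vecs[:, keep]

    # Mass-normalize (eigsh already returns M-orthonormal vectors; this
    # guards the dense path and round-off).
    norms = np.sqrt(np.einsum("ij,ij->j", vecs, M @ vecs))
    vecs = vecs / norms
    freqs = np.sqrt(lam) / (2 * np.pi)

    if n_rigid == len(lam):
        warnings.warn(f"modal cutoff {cutoff:g} Hz retains no elastic modes; "
                      "basis contains rigid-body modes only", stacklevel=2)

    Ktil = {lab: vecs.T @ (Km @ vecs) for lab, Km in system.K.items()}
    return ModalBasis(vecs, freqs, Ktil, cutoff, system, n_rigid)


def apply_pressure_load(system: SystemMatrices,
                        sp_field: SurfacePressure) -> np.ndarray:
    """Consistent nodal forces of the surface traction t = -p n.

    Linear pressure interpolation over each boundary triangle gives the
    nodal force  F_a = -(A/12) (p_1 + p_2 + p_3 + p_a) n  with n the
    outward unit normal.  Returns a complex load vector in N.
    """
    surf = system.surface
    if len(sp_field.node_indices) != len(surf.node_indices):
        raise ValueError(
            f"surface pressure has {len(sp_field.node_indices)} nodes, "
            f"wetted surface has {len(surf.node_indices)}")
    lookup = np.full(system.mesh.n_nodes, -1, dtype=np.int64)
    lookup[sp_field.node_indices] = np.arange(len(sp_field.node_indices))
    tri_p = sp_field.values[lookup[surf.triangles]]  # (n_tris, 3)
    areas = surf.areas(system.mesh.nodes) * 1e-6  # m^2
    psum = tri_p.sum(axis=1)
    load = np.zeros(system.ndof, complex)
    for a in range(3):
        coeff = -(areas / 12.0) * (psum + tri_p[:, a])  # Pa * m^2 = N
        fa = coeff[:, None] * surf.normals  # (n_tris, 3)
        dofs = 3 * surf.triangles[:, a]
        for comp in range(3):
            np.add.at(load, dofs + comp, fa[:, comp])
    return load


def reduced_matrix(basis: ModalBasis, materials: MaterialMap,
                   freq_hz: float) -> np.ndarray:
    """Dense reduced system -w^2 I + sum_m (1 + i eta_m) Ktil_m."""
    m = basis.n_modes
    A = np.zeros((m, m), complex)
    for lab, Kt in basis.Ktil.items():
        A += (1.0 + 1j * materials[lab].eta) * Kt
    A -= (2 * np.pi * freq_hz) ** 2 * np.eye(m)
    return A


def frf_sweep(basis: ModalBasis, loads, materials: MaterialMap,
              sensors: list, grid: np.ndarray, p0: float = 1.0) -> FRFSet:
    """Sweep the reduced complex system over the frequency grid.

    ``loads`` is either a sequence of full-DOF complex load vectors
    (one per grid frequency) or a callable ``f -> load``.  Channel
    output is acceleration per unit incident pressure:
    -w^2 (axis . U_sensor) / p0, m/s^2/Pa.
    """
    grid = np.asarray(grid, float)
    system = basis.system
    get_load = loads if callable(loads) else lambda f, _tbl=dict(
        zip(np.round(grid, 9), loads)): _tbl[np.round(f, 9)]

    out = {s.name: np.empty(len(grid), complex) for s in sensors}
    for i, f in enumerate(grid):
        A = reduced_matrix(basis, materials, f)
        try:
            q = np.linalg.solve(A, basis.Phi.T @ get_load(f))
        except np.linalg.LinAlgError as err:
            raise RuntimeError(
                f"reduced system singular at {f} Hz (likely an undamped "
                "resonance; use a nonzero loss factor)") from err
        U = basis.Phi @ q
        w2 = (2 * np.pi * f) ** 2
        for s in sensors:
            node = system.sensor_nodes[s.name]
            out[s.name][i] = -w2 * (s.axis @ U[3 * node: 3 * node + 3]) / p0
    return FRFSet(grid, out)


def direct_solve(system: SystemMatrices, materials: MaterialMap,
                 load: np.ndarray, freq_hz: float) -> np.ndarray:
    """Full-order sparse complex solve of the damped harmonic system
    (reference solution for verifying the modal reduction)."""
    A = sp.csr_matrix((system.ndof, system.ndof), dtype=complex)
    for lab, Km in system.K.items():
        A = A + (1.0 + 1j * materials[lab].eta) * Km
    A = A - (2 * np.pi * freq_hz) ** 2 * system.M
    return spla.spsolve(A.tocsc(), load)


def amplification(frfs: FRFSet, bulla_channels=("L/ML", "R/ML"),
                  skull_channel: str = "S/ML"):
    """Bulla-to-skull magnitude ratio curves and their left/right mean.

    Returns (ratios, average, flagged): ``ratios`` maps each bulla
    channel to |H_bulla| / |H_skull| per frequency, ``average`` is the
    mean of those curves, ``flagged`` the indices where the skull
    response vanished (ratio set to +inf there).
    """
    for name in (*bulla_channels, skull_channel):
        if name not in frfs.channels:
            raise KeyError(f"channel {name!r} not present in FRF set")
    denom = np.abs(frfs[skull_channel])
    flagged = np.flatnonzero(denom == 0.0)
    safe = np.where(denom == 0.0, np.nan, denom)
    ratios = {}
    for name in bulla_channels:
        r = np.abs(frfs[name]) / safe
        r[denom == 0.0] = np.inf
        ratios[name] = r
    average = np.mean(np.vstack(list(ratios.values())), axis=0)
    return ratios, average, flagged
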