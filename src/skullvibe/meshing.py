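"""Voxel-to-tetrahedron meshing and wetted-surface extraction.

Each solid voxel is split into five tetrahedra (one central, four
corner tets).  The decomposition has a handedness: the cube diagonal
pattern must mirror between neighboring voxels or the shared quad faces
would be triangulated with mismatched diagonals, leaving hanging nodes.
Alternating the pattern with voxel parity (i+j+k even/odd) makes every
shared face conform.

The mesh can be smoothed with Taubin's volume-preserving two-step
Laplacian (lambda/mu pair), and the boundary ("wetted") triangle
surface — where acoustic pressure acts — is extracted with outward
normals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .phantom import VoxelPhantom

# Corner offsets of a unit voxel, indexed 0..7 as (dx, dy, dz).
_CORNERS = np.array(
    [(0, 0, 0), (1, 0, 0), (0, 1, 0), (0, 0, 1),
     (1, 1, 0), (1, 0, 1), (0, 1, 1), (1, 1, 1)], dtype=np.int64)

# Five-tet split, even parity: central tet on the even corners
# (000,110,101,011), four corner tets on the odd corners.
_TETS_EVEN = np.array(
    [(0, 4, 5, 6),
     (1, 0, 4, 5),
     (2, 0, 4, 6),
     (3, 0, 5, 6),
     (7, 4, 5, 6)], dtype=np.int64)

# Odd parity: mirrored split on the odd corners (100,010,001,111).
_TETS_ODD = np.array(
    [(1, 2, 3, 7),
     (0, 1, 2, 3),
     (4, 1, 2, 7),
     (5, 1, 3, 7),
     (6, 2, 3, 7)], dtype=np.int64)


@dataclass
class TetMesh:
    """Linear tetrahedral mesh with per-element material labels."""

    nodes: np.ndarray  # (n_nodes, 3) world mm
    tets: np.ndarray  # (n_tets, 4) node indices, positively oriented
    material: np.ndarray  # (n_tets,) labels in {1,2,3}
    region: np.ndarray | None = None  # per-tet region tag

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_tets(self) -> int:
        return len(self.tets)

    def volumes(self) -> np.ndarray:
        """Signed tet volumes, mm^3 (positive for a valid mesh)."""
        p = self.nodes[self.tets]
        a, b, c = (p[:, 1] - p[:, 0], p[:, 2] - p[:, 0], p[:, 3] - p[:, 0])
        return np.einsum("ij,ij->i", a, np.cross(b, c)) / 6.0

    def copy(self) -> "TetMesh":
        return TetMesh(self.nodes.copy(), self.tets.copy(), self.material.copy(),
                       None if self.region is None else self.region.copy())


@dataclass
class TriSurface:
    """Boundary triangles of a tet mesh, outward-oriented.

    ``triangles`` index into the parent mesh's node array; ``tet_index``
    records the unique solid tet owning each face.
    """

    triangles: np.ndarray  # (n_tris, 3) parent-mesh node indices
    normals: np.ndarray  # (n_tris, 3) outward unit normals
    tet_index: np.ndarray  # (n_tris,) owning tet

    @property
    def node_indices(self) -> np.ndarray:
        """Sorted unique parent-mesh node indices on the surface."""
        return np.unique(self.triangles)

    def areas(self, nodes: np.ndarray) -> np.ndarray:
        p = nodes[self.triangles]
        return 0.5 * np.linalg.norm(
            np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]), axis=1)


def voxels_to_tetmesh(phantom: VoxelPhantom) -> TetMesh:
    """Tile every solid voxel with five conforming tetrahedra.

    Tets inherit the voxel's material label (and region tag); node
    coordinates are world mm on the voxel-corner lattice.
    """
    solid = np.argwhere(phantom.labels > 0)
    if len(solid) == 0:
        raise ValueError("phantom has no solid voxels")
    labels = phantom.labels[tuple(solid.T)]
    regions = (phantom.region[tuple(solid.T)]
               if phantom.region is not None else None)

    # Global corner ids on the (nx+1, ny+1, nz+1) lattice.
    nx, ny, nz = phantom.shape
    strides = np.array([(ny + 1) * (nz + 1), nz + 1, 1], dtype=np.int64)
    corner_idx = (solid[:, None, :] + _CORNERS[None, :, :]) @ strides  # (nvox, 8)

    parity = solid.sum(axis=1) % 2
    conn = np.empty((len(solid), 5, 4), dtype=np.int64)
    conn[parity == 0] = corner_idx[parity == 0][:, _TETS_EVEN]
    conn[parity == 1] = corner_idx[parity == 1][:, _TETS_ODD]
    conn = conn.reshape(-1, 4)

    used, conn = np.unique(conn, return_inverse=True)
    conn = conn.reshape(-1, 4)
    ijk = np.stack(np.unravel_index(used, (nx + 1, ny + 1, nz + 1)), axis=1)
    nodes = phantom.origin + ijk * phantom.spacing

    mesh = TetMesh(
        nodes=nodes.astype(float),
        tets=conn,
        material=np.repeat(labels, 5).astype(np.int8),
        region=None if regions is None else np.repeat(regions, 5).astype(np.int8),
    )
    # Fix orientation: make all signed volumes positive.
    neg = mesh.volumes() < 0
    mesh.tets[neg] = mesh.tets[neg][:, [0, 2, 1, 3]]
    if np.any(mesh.volumes() <= 0):
        raise RuntimeError("degenerate tetrahedra after orientation fix")
    return mesh


def _node_adjacency(mesh: TetMesh):
    """Unique undirected edges of the tet mesh as (i, j) arrays."""
    t = mesh.tets
    pairs = np.vstack([t[:, [0, 1]], t[:, [0, 2]], t[:, [0, 3]],
                       t[:, [1, 2]], t[:, [1, 3]], t[:, [2, 3]]])
    pairs = np.sort(pairs, axis=1)
    pairs = np.unique(pairs, axis=0)
    return pairs


def taubin_smooth(mesh: TetMesh, lam: float = 0.5, mu: float = -0.53,
                  iterations: int = 10, preserve_volume: bool = True) -> TetMesh:
    """Taubin's two-step Laplacian smoothing (shrink step lambda,
    inflate step mu) applied to all node positions.

    Connectivity and labels are untouched.  The lambda/mu band-pass
    pair limits shrinkage on smooth meshes, but blocky voxel meshes
    concentrate their geometry at high graph frequencies and still lose
    volume; with ``preserve_volume`` (default) each connected component
    is rescaled about its centroid after smoothing so its volume is
    restored exactly.  Raises if an iteration inverts a tet (reduce
    lambda in that case).
    """
    if not 0 < lam < 1:
        raise ValueError(f"lambda must be in (0, 1), got {lam}")
    if mu >= -lam:
        raise ValueError(f"mu must be < -lambda, got mu={mu}, lambda={lam}")
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    out = mesh.copy()
    if iterations == 0:
        return out
    edges = _node_adjacency(mesh)
    n = mesh.n_nodes
    deg = np.zeros(n)
    np.add.at(deg, edges[:, 0], 1.0)
    np.add.at(deg, edges[:, 1], 1.0)

    def laplacian(p):
        acc = np.zeros_like(p)
        np.add.at(acc, edges[:, 0], p[edges[:, 1]])
        np.add.at(acc, edges[:, 1], p[edges[:, 0]])
        return acc / deg[:, None] - p

    p = out.nodes
    for it in range(iterations):
        p = p + lam * laplacian(p)
        p = p + mu * laplacian(p)
        out.nodes = p
        if np.any(out.volumes() <= 0):
            raise RuntimeError(f"Taubin smoothing inverted a tet at iteration {it}; "
                               f"reduce lambda (got {lam})")
    if preserve_volume:
        _restore_component_volumes(mesh, out)
    return out


def _restore_component_volumes(before: TetMesh, after: TetMesh) -> None:
    """Rescale each connected component of ``after`` about its centroid
    so its total volume matches ``before`` exactly (in place)."""
    import scipy.sparse as sp
    from scipy.sparse.csgraph import connected_components

    edges = _node_adjacency(before)
    n = before.n_nodes
    adj = sp.coo_matrix((np.ones(len(edges)), (edges[:, 0], edges[:, 1])),
                        shape=(n, n))
    _, comp = connected_components(adj, directed=False)
    tet_comp = comp[before.tets[:, 0]]
    vol_before = before.volumes()
    vol_after = after.volumes()
    for c in np.unique(comp):
        sel = tet_comp == c
        scale = (vol_before[sel].sum() / vol_after[sel].sum()) ** (1.0 / 3.0)
        node_sel = comp == c
        # volume-weighted centroid of the component
        tc = after.nodes[after.tets[sel]].mean(axis=1)
        centroid = (tc * vol_after[sel, None]).sum(axis=0) / vol_after[sel].sum()
        after.nodes[node_sel] = centroid + scale * (after.nodes[node_sel] - centroid)


# Local faces of a tet, each ordered so the outward normal (away from
# the opposite node) follows the right-hand rule for a positively
# oriented tet.
_TET_FACES = np.array(
    [(1, 2, 3), (0, 3, 2), (0, 1, 3), (0, 2, 1)], dtype=np.int64)


def extract_wetted_surface(mesh: TetMesh) -> TriSurface:
    """Boundary faces of the solid, outward-oriented.

    A face belonging to exactly one tet is on the boundary; a face
    shared by more than two tets means the mesh is non-manifold and is
    reported as an error.
    """
    faces = mesh.tets[:, _TET_FACES].reshape(-1, 3)  # (4*n_tets, 3), oriented
    owner = np.repeat(np.arange(mesh.n_tets), 4)
    key = np.sort(faces, axis=1)
    _, inv, counts = np.unique(key, axis=0, return_inverse=True,
                               return_counts=True)
    if counts.max() > 2:
        bad = np.flatnonzero(counts[inv] > 2)[0]
        raise ValueError(f"non-manifold face {tuple(key[bad])} shared by "
                         f"{counts[inv[bad]]} tets")
    boundary = counts[inv] == 1
    tris = faces[boundary]
    tet_index = owner[boundary]

    p = mesh.nodes[tris]
    nrm = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
    nrm /= np.linalg.norm(nrm, axis=1, keepdims=True)
    # Sanity: normals must point away from the owning tet's 4th node.
    cent = p.mean(axis=1)
    tet_cent = mesh.nodes[mesh.tets[tet_index]].mean(axis=1)
    flip = np.einsum("ij,ij->i", nrm, cent - tet_cent) < 0
    tris[flip] = tris[flip][:, [0, 2, 1]]
    nrm[flip] *= -1.0
    return TriSurface(tris, nrm, tet_index)


def surface_euler_characteristic(surface: TriSurface) -> int:
    """V - E + F of the boundary surface (2 per sphere-like component,
    reduced by 2 per topological handle)."""
    tris = surface.triangles
    V = len(np.unique(tris))
    edges = np.vstack([tris[:, [0, 1]], tris[:, [1, 2]], tris[:, [2, 0]]])
    E = len(np.unique(np.sort(edges, axis=1), axis=0))
    return V - E + len(tris)


def export_vtk(mesh: TetMesh, path) -> None:
    """Write the mesh as a legacy-ASCII VTK unstructured grid with the
    material label as cell data."""
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\nskullvibe tet mesh\nASCII\n"
                "DATASET UNSTRUCTURED_GRID\n")
        f.write(f"POINTS {mesh.n_nodes} double\n")
        np.savetxt(f, mesh.nodes, fmt="%.9g")
        f.write(f"CELLS {mesh.n_tets} {5 * mesh.n_tets}\n")
        np.savetxt(f, np.column_stack([np.full(mesh.n_tets, 4), mesh.tets]),
                   fmt="%d")
        f.write(f"CELL_TYPES {mesh.n_tets}\n")
        np.savetxt(f, np.full(mesh.n_tets, 10), fmt="%d")
        f.write(f"CELL_DATA {mesh.n_tets}\nSCALARS material int 1\n"
                "LOOKUP_TABLE default\n")
        np.savetxt(f, mesh.material, fmt="%d")


def export_stl(mesh: TetMesh, surface: TriSurface, path) -> None:
    """Export the wetted surface as STL (requires trimesh)."""
    import trimesh

    tm = trimesh.Trimesh(vertices=mesh.nodes, faces=surface.triangles,
                         process=False)
    tm.export(path)
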