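"""Vertex-graph and discrete-geometry primitives.

The segmentation pipeline operates on the "2-D graph representation" of a
cortical surface: vertices are nodes, mesh edges are arcs.  Morphology
(erosion, dilation, opening), connected components and region growing are
all defined in hop-distance layers on that graph.  Geometry (areas,
curvatures, centroids) is computed on the embedded triangle mesh.

Curvature sign convention (FreeSurfer): negative mean curvature = locally
convex = gyral crown; positive = concave = sulcal fundus.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.sparse import csgraph

from .errors import ConsistencyError, ParameterError
from .types import TriangleSurface, VertexScalarField


@dataclass
class VertexGraph:
    """Symmetric vertex adjacency of a triangle mesh, stored as CSR.

    Two vertices are adjacent iff they share a mesh edge.
    """

    n: int
    matrix: sparse.csr_matrix

    def neighbors(self, v: int) -> np.ndarray:
        return self.matrix.indices[self.matrix.indptr[v]:self.matrix.indptr[v + 1]]

    def neighbor_sets(self) -> list[set[int]]:
        """Per-vertex neighbour sets (convenience for inspection/tests)."""
        return [set(self.neighbors(v).tolist()) for v in range(self.n)]

    def degree(self) -> np.ndarray:
        return np.diff(self.matrix.indptr)


def build_adjacency(surface: TriangleSurface) -> VertexGraph:
    """Build the vertex adjacency graph from the mesh faces."""
    surface.validate()
    f = surface.faces
    rows = np.concatenate([f[:, 0], f[:, 1], f[:, 2], f[:, 1], f[:, 2], f[:, 0]])
    cols = np.concatenate([f[:, 1], f[:, 2], f[:, 0], f[:, 0], f[:, 1], f[:, 2]])
    data = np.ones(rows.shape[0], dtype=np.int8)
    m = sparse.coo_matrix((data, (rows, cols)), shape=(surface.n_vertices,) * 2)
    m = m.tocsr()
    m.data[:] = 1  # dedupe multiplicity
    return VertexGraph(n=surface.n_vertices, matrix=m)


def _as_mask(members: np.ndarray, n: int) -> np.ndarray:
    members = np.asarray(members, dtype=np.int64)
    if members.size and (members.min() < 0 or members.max() >= n):
        raise ConsistencyError("vertex set outside graph range")
    mask = np.zeros(n, dtype=bool)
    mask[members] = True
    return mask


def _mask_to_set(mask: np.ndarray) -> np.ndarray:
    return np.flatnonzero(mask)


def hop_distance(graph: VertexGraph, sources: np.ndarray,
                 max_depth: int | None = None) -> np.ndarray:
    """Multi-source BFS hop distance from *sources* to every vertex.

    Unreached vertices (or ones beyond *max_depth*) get ``max_depth + 1`` when
    a depth cap is given, else a large sentinel.
    """
    n = graph.n
    cap = n + 1 if max_depth is None else max_depth + 1
    dist = np.full(n, cap, dtype=np.int64)
    frontier = np.zeros(n, dtype=bool)
    frontier[np.asarray(sources, dtype=np.int64)] = True
    dist[frontier] = 0
    d = 0
    while frontier.any() and d < cap - 1:
        d += 1
        reached = graph.matrix.dot(frontier.astype(np.int8)) > 0
        frontier = reached & (dist >= cap)
        dist[frontier] = d
    return dist


def connected_components(members: np.ndarray, graph: VertexGraph) -> list[np.ndarray]:
    """Partition *members* into maximal subsets connected through edges
    internal to the set, ordered by smallest member index."""
    mask = _as_mask(np.asarray(members, dtype=np.int64), graph.n)
    idx = _mask_to_set(mask)
    if idx.size == 0:
        return []
    sub = graph.matrix[idx][:, idx]
    ncomp, lab = csgraph.connected_components(sub, directed=False)
    comps = [idx[lab == c] for c in range(ncomp)]
    comps.sort(key=lambda c: int(c[0]))
    return comps


def erode(members: np.ndarray, graph: VertexGraph, depth: int) -> np.ndarray:
    """Remove every member within hop distance ≤ *depth* of a non-member."""
    if depth < 1:
        raise ParameterError(f"erosion depth must be ≥ 1, got {depth}")
    mask = _as_mask(members, graph.n)
    complement = _mask_to_set(~mask)
    if complement.size == 0:
        return _mask_to_set(mask)
    dist = hop_distance(graph, complement, max_depth=depth)
    return _mask_to_set(mask & (dist > depth))


def dilate(members: np.ndarray, graph: VertexGraph, depth: int) -> np.ndarray:
    """Add every vertex within hop distance ≤ *depth* of the set."""
    if depth < 1:
        raise ParameterError(f"dilation depth must be ≥ 1, got {depth}")
    mask = _as_mask(members, graph.n)
    if not mask.any():
        return _mask_to_set(mask)
    dist = hop_distance(graph, _mask_to_set(mask), max_depth=depth)
    return _mask_to_set(dist <= depth)


def morphological_open(members: np.ndarray, graph: VertexGraph,
                       depth: int) -> np.ndarray:
    """Opening = erosion then dilation, reconstructed inside the original set.

    Erosion strips *depth* hop-layers off the patch edge, discarding thin
    formations of width up to ``2·depth`` vertices; dilation then restores the
    eroded outer layers of the surviving blobs, intersected with the original
    set so the thin formations stay gone.  Anti-extensive, increasing and
    idempotent.
    """
    if depth < 1:
        raise ParameterError(f"opening depth must be ≥ 1, got {depth}")
    members = np.asarray(members, dtype=np.int64)
    core = erode(members, graph, depth)
    if core.size == 0:
        return core
    grown = dilate(core, graph, depth)
    mask = _as_mask(members, graph.n)
    return grown[mask[grown]]


def region_grow(seeds: np.ndarray, allowed: np.ndarray,
                graph: VertexGraph) -> np.ndarray:
    """Transitive closure of adjacency from *seeds* inside *allowed*.

    Equivalently: the union of connected components of *allowed* that
    intersect *seeds*.
    """
    seeds = np.asarray(seeds, dtype=np.int64)
    allowed_mask = _as_mask(allowed, graph.n)
    seed_mask = _as_mask(seeds, graph.n)
    if np.any(seed_mask & ~allowed_mask):
        raise ParameterError("seeds must be a subset of the allowed set")
    reached = seed_mask.copy()
    frontier = seed_mask
    while frontier.any():
        nxt = (graph.matrix.dot(frontier.astype(np.int8)) > 0) & allowed_mask & ~reached
        reached |= nxt
        frontier = nxt
    return _mask_to_set(reached)


# ---------------------------------------------------------------------------
# discrete geometry
# ---------------------------------------------------------------------------

def _face_geometry(surface: TriangleSurface):
    tri = surface.coords[surface.faces]              # (M, 3, 3)
    e0 = tri[:, 1] - tri[:, 0]
    e1 = tri[:, 2] - tri[:, 0]
    normals = np.cross(e0, e1)                       # 2·area · n̂
    double_area = np.linalg.norm(normals, axis=1)
    return tri, normals, double_area


def vertex_areas(surface: TriangleSurface) -> VertexScalarField:
    """Barycentric vertex areas: one third of each incident triangle's area.

    Their sum equals the total mesh area exactly.  Degenerate (zero-area)
    faces contribute nothing; an all-degenerate mesh raises.
    """
    _, _, double_area = _face_geometry(surface)
    if not np.any(double_area > 0):
        raise ConsistencyError("all faces are degenerate (zero area)")
    face_third = double_area / 6.0
    areas = np.zeros(surface.n_vertices)
    for k in range(3):
        np.add.at(areas, surface.faces[:, k], face_third)
    return VertexScalarField(values=areas, kind="generic")


def _mixed_voronoi_areas(surface: TriangleSurface) -> np.ndarray:
    """Meyer's mixed Voronoi vertex areas (used by the curvature operators).

    Voronoi area inside non-obtuse triangles; T/2 at the obtuse corner and
    T/4 at the other corners of obtuse triangles.  More accurate than the
    barycentric third at irregular-valence vertices.
    """
    coords, faces = surface.coords, surface.faces
    tri = coords[faces]
    areas = np.zeros(surface.n_vertices)
    e = [tri[:, (k + 2) % 3] - tri[:, (k + 1) % 3] for k in range(3)]
    sq = [np.einsum("ij,ij->i", ek, ek) for ek in e]  # |edge opposite k|²
    cots = []
    for k in range(3):
        u = tri[:, (k + 1) % 3] - tri[:, k]
        v = tri[:, (k + 2) % 3] - tri[:, k]
        cross = np.linalg.norm(np.cross(u, v), axis=1)
        dot = np.einsum("ij,ij->i", u, v)
        cots.append(np.where(cross > 1e-30, dot / np.maximum(cross, 1e-30), 0.0))
    cots = np.stack(cots)                       # (3, M), cot of angle at corner k
    face_area = 0.5 * np.linalg.norm(np.cross(tri[:, 1] - tri[:, 0],
                                              tri[:, 2] - tri[:, 0]), axis=1)
    obtuse_at = np.argmin(cots, axis=0)
    any_obtuse = cots.min(axis=0) < 0
    for k in range(3):
        voronoi = (sq[(k + 1) % 3] * cots[(k + 1) % 3]
                   + sq[(k + 2) % 3] * cots[(k + 2) % 3]) / 8.0
        contrib = np.where(
            any_obtuse,
            np.where(obtuse_at == k, face_area / 2.0, face_area / 4.0),
            voronoi,
        )
        np.add.at(areas, faces[:, k], contrib)
    return areas


def boundary_vertices(surface: TriangleSurface) -> np.ndarray:
    """Vertices on edges incident to exactly one face (manifold boundary)."""
    f = surface.faces
    edges = np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
    edges = np.sort(edges, axis=1)
    uniq, counts = np.unique(edges, axis=0, return_counts=True)
    if np.any(counts > 2):
        raise ConsistencyError("non-manifold edge (shared by > 2 faces)")
    return np.unique(uniq[counts == 1])


def vertex_normals(surface: TriangleSurface) -> np.ndarray:
    """Area-weighted vertex normals from consistently oriented faces."""
    _, fnormals, _ = _face_geometry(surface)
    vn = np.zeros_like(surface.coords)
    for k in range(3):
        np.add.at(vn, surface.faces[:, k], fnormals)
    norm = np.linalg.norm(vn, axis=1)
    norm[norm == 0] = 1.0
    return vn / norm[:, None]


def discrete_curvatures(
    surface: TriangleSurface,
) -> tuple[VertexScalarField, VertexScalarField]:
    """Per-vertex mean and Gaussian curvature of a triangle mesh.

    Gaussian curvature is the angle deficit (2π − Σ incident angles; π at
    boundary vertices) divided by the mixed Voronoi vertex area.  Mean
    curvature comes from the cotangent mean-curvature-normal operator over
    the same areas, signed so that convex (outward-bulging) regions are
    NEGATIVE — the FreeSurfer convention.  Units: 1/mm and 1/mm².
    """
    coords, faces = surface.coords, surface.faces
    n = surface.n_vertices
    areas = _mixed_voronoi_areas(surface)
    boundary = np.zeros(n, dtype=bool)
    boundary[boundary_vertices(surface)] = True

    tri = coords[faces]
    angle_sum = np.zeros(n)
    mcv = np.zeros((n, 3))  # Σ (cot α + cot β)(x_i − x_j), accumulated per corner
    for k in range(3):
        i, j, l = faces[:, k], faces[:, (k + 1) % 3], faces[:, (k + 2) % 3]
        u = coords[j] - coords[i]
        v = coords[l] - coords[i]
        cross = np.linalg.norm(np.cross(u, v), axis=1)
        dot = np.einsum("ij,ij->i", u, v)
        ang = np.arctan2(cross, dot)
        np.add.at(angle_sum, i, ang)
        # cotangent at corner i weights the opposite edge (j, l)
        with np.errstate(divide="ignore", invalid="ignore"):
            cot = np.where(cross > 1e-30, dot / np.maximum(cross, 1e-30), 0.0)
        contrib = cot[:, None] * (coords[j] - coords[l])
        np.add.at(mcv, j, contrib)
        np.add.at(mcv, l, -contrib)

    safe_area = np.where(areas > 0, areas, 1.0)
    deficit = np.where(boundary, np.pi, 2 * np.pi) - angle_sum
    gaussian = deficit / safe_area

    mcv /= (2 * safe_area)[:, None]           # mean-curvature vector, |mcv| = 2|H|
    normals = vertex_normals(surface)
    signed = np.einsum("ij,ij->i", mcv, normals) / 2.0
    mean = -signed                            # FreeSurfer sign: convex < 0
    # the cotangent operator is meaningless on the open boundary ring
    mean[boundary] = 0.0
    return (
        VertexScalarField(values=mean, kind="mean_curvature"),
        VertexScalarField(values=gaussian, kind="generic"),
    )


def weighted_centroid(members: np.ndarray, surface: TriangleSurface,
                      areas: VertexScalarField) -> np.ndarray:
    """Area-weighted mean coordinate of a vertex set (mm)."""
    members = np.asarray(members, dtype=np.int64)
    if members.size == 0:
        raise ParameterError("centroid of an empty vertex set")
    w = areas.values[members]
    total = w.sum()
    if total <= 0:
        raise ParameterError("vertex set has zero total area")
    return (surface.coords[members] * w[:, None]).sum(axis=0) / total
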