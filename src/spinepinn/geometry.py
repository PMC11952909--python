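"""Synthetic lumbar-spine phantom geometry.

Builds a stack of alternating vertebra and intervertebral-disc regions along
the cranio-caudal (z) axis, meshed with linear tetrahedra on a structured
grid so that bone-disc interfaces share nodes exactly (tied contact realised
as a conforming mesh). Cross-sections are cylinders (default) or boxes; the
cylinder is obtained by the elliptical square-to-disk map, whose boundary
points lie exactly on the circle, so the generated solid is a polygonal prism
with a closed-form volume.

Coordinates are millimetres. z increases cranially; compression is applied
in -z. All indices are 0-based.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import permutations
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "SurfaceMesh",
    "LabeledTetMesh",
    "PhantomSpec",
    "MeshResolutionError",
    "build_phantom",
    "build_stack",
    "annotate_endplates",
    "default_distance_band",
    "extract_surface",
    "tet_volumes",
    "analytic_volume",
    "cross_section_area",
    "permute_mesh",
]


class MeshResolutionError(ValueError):
    """Mesh resolution too coarse to tile the requested geometry."""


@dataclass
class SurfaceMesh:
    """Triangulated surface with outward unit normals.

    vertices : (n, 3) float array, mm
    triangles : (m, 3) int array of vertex indices
    normals : (m, 3) outward unit normals (recomputed on construction when None)
    watertight : whether every edge is shared by exactly two triangles
    """

    vertices: np.ndarray
    triangles: np.ndarray
    normals: Optional[np.ndarray] = None
    watertight: bool = field(default=False)

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=np.int64)
        if self.triangles.size and self.triangles.max() >= len(self.vertices):
            raise ValueError("triangle references a vertex beyond the vertex array")
        if self.triangles.size and self.triangles.min() < 0:
            raise ValueError("negative vertex index in triangle")
        if self.normals is None:
            self.normals = self._face_normals()
        else:
            self.normals = np.asarray(self.normals, dtype=float)

    def _face_normals(self) -> np.ndarray:
        v = self.vertices
        t = self.triangles
        n = np.cross(v[t[:, 1]] - v[t[:, 0]], v[t[:, 2]] - v[t[:, 0]])
        norms = np.linalg.norm(n, axis=1, keepdims=True)
        norms[norms == 0.0] = 1.0
        return n / norms

    def triangle_centroids(self) -> np.ndarray:
        return self.vertices[self.triangles].mean(axis=1)

    def check_watertight(self) -> bool:
        """True iff every undirected edge belongs to exactly two triangles."""
        t = self.triangles
        edges = np.sort(
            np.concatenate([t[:, [0, 1]], t[:, [1, 2]], t[:, [2, 0]]]), axis=1
        )
        _, counts = np.unique(edges, axis=0, return_counts=True)
        return bool(np.all(counts == 2))


@dataclass
class LabeledTetMesh:
    """Conforming tetrahedral mesh with per-element region labels.

    nodes : (n, 3) float, mm
    tets : (m, 4) int node indices, positively oriented
    region_labels : (m,) int index into ``region_names``
    region_names : e.g. ["vertebra_1", "disc_1", ..., "vertebra_5"]
    boundary_triangles : (b, 3) outward-oriented surface triangles
    boundary_regions : (b,) region index owning each boundary triangle
    endplate_sets : named node sets; always contains "top" (loading surface)
        and "bottom" (constrained surface) plus per-region "<name>_upper"
        and "<name>_lower" sets.
    """

    nodes: np.ndarray
    tets: np.ndarray
    region_labels: np.ndarray
    region_names: List[str]
    boundary_triangles: np.ndarray
    boundary_regions: np.ndarray
    endplate_sets: Dict[str, np.ndarray]

    @property
    def n_regions(self) -> int:
        return len(self.region_names)

    def region_tets(self, name: str) -> np.ndarray:
        idx = self.region_names.index(name)
        return np.nonzero(self.region_labels == idx)[0]

    def volumes(self) -> np.ndarray:
        return tet_volumes(self.nodes, self.tets)

    def total_volume(self) -> float:
        return float(self.volumes().sum())

    def region_volume(self, name: str) -> float:
        return float(self.volumes()[self.region_tets(name)].sum())


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the stacked vertebra/disc phantom.

    Heights and sizes in mm. ``n_vertebrae`` vertebra regions are interleaved
    with ``n_vertebrae - 1`` disc regions. ``mesh_resolution`` is the target
    edge length; the seed is recorded for provenance (generation itself is
    deterministic).
    """

    n_vertebrae: int = 5
    vertebra_height: float = 28.0
    disc_height: float = 10.0
    cross_section: str = "cylinder"
    radius: float = 20.0
    half_widths: Tuple[float, float] = (20.0, 20.0)
    mesh_resolution: float = 5.0
    seed: int = 0

    def __post_init__(self):
        if self.n_vertebrae < 1:
            raise ValueError("n_vertebrae must be >= 1")
        if min(self.vertebra_height, self.disc_height, self.mesh_resolution) <= 0:
            raise ValueError("heights and mesh resolution must be strictly positive")
        if self.cross_section not in ("cylinder", "box"):
            raise ValueError(f"unknown cross_section {self.cross_section!r}")
        if self.cross_section == "cylinder" and self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.cross_section == "box" and min(self.half_widths) <= 0:
            raise ValueError("half_widths must be positive")

    @property
    def n_discs(self) -> int:
        return self.n_vertebrae - 1

    def region_layout(self) -> Tuple[List[float], List[str]]:
        heights, names = [], []
        for i in range(self.n_vertebrae):
            heights.append(self.vertebra_height)
            names.append(f"vertebra_{i + 1}")
            if i < self.n_vertebrae - 1:
                heights.append(self.disc_height)
                names.append(f"disc_{i + 1}")
        return heights, names

    @property
    def total_height(self) -> float:
        return self.n_vertebrae * self.vertebra_height + self.n_discs * self.disc_height


# ---------------------------------------------------------------------------
# Structured stack construction
# ---------------------------------------------------------------------------

def _base_grid(spec: PhantomSpec) -> Tuple[np.ndarray, int]:
    """In-plane node grid (mapped to the cross-section) and division count."""
    if spec.cross_section == "cylinder":
        extent = 2.0 * spec.radius
    else:
        extent = 2.0 * max(spec.half_widths)
    n_div = int(round(extent / spec.mesh_resolution))
    if n_div < 2:
        raise MeshResolutionError(
            f"mesh_resolution={spec.mesh_resolution} mm is too coarse for a "
            f"cross-section of extent {extent} mm (needs >= 2 divisions)"
        )
    u = np.linspace(-1.0, 1.0, n_div + 1)
    U, V = np.meshgrid(u, u, indexing="ij")
    if spec.cross_section == "cylinder":
        # Elliptical square-to-disk map; the square boundary lands exactly on
        # the circle of the given radius.
        X = spec.radius * U * np.sqrt(1.0 - V**2 / 2.0)
        Y = spec.radius * V * np.sqrt(1.0 - U**2 / 2.0)
    else:
        X = spec.half_widths[0] * U
        Y = spec.half_widths[1] * V
    pts = np.column_stack([X.ravel(), Y.ravel()])
    return pts, n_div


# Kuhn subdivision of the unit hexahedron into 6 tetrahedra. Each tet walks
# from corner (0,0,0) to (1,1,1) adding one axis at a time; face diagonals are
# consistent between neighbouring hexes, so the subdivision is conforming on a
# structured grid.
def _kuhn_tets() -> np.ndarray:
    corners = []
    for perm in permutations(range(3)):
        c = np.zeros((4, 3), dtype=np.int64)
        for step, ax in enumerate(perm):
            c[step + 1] = c[step]
            c[step + 1, ax] += 1
        corners.append(c)
    return np.array(corners)  # (6, 4, 3) of (di, dj, dk)


_KUHN = _kuhn_tets()


def build_stack(
    region_heights: Sequence[float],
    region_names: Sequence[str],
    spec: PhantomSpec,
) -> LabeledTetMesh:
    """Mesh a stack of axial regions with a shared in-plane grid.

    The same cross-section grid is extruded through every z-plane, so nodes on
    region interfaces are shared exactly (conforming "tied" interfaces) and the
    meshed solid is a prism over the in-plane polygon.
    """
    if len(region_heights) != len(region_names):
        raise ValueError("region_heights and region_names must have equal length")
    pts2d, n_div = _base_grid(spec)
    npp = (n_div + 1) ** 2  # nodes per plane

    # z-planes: each region r gets ceil(h_r / resolution) layers
    z_planes = [0.0]
    region_of_layer: List[int] = []
    for r, h in enumerate(region_heights):
        n_layers = max(1, int(np.ceil(h / spec.mesh_resolution)))
        z0 = z_planes[-1]
        for k in range(1, n_layers + 1):
            z_planes.append(z0 + h * k / n_layers)
            region_of_layer.append(r)
    z = np.array(z_planes)
    n_planes = len(z)

    nodes = np.empty((n_planes * npp, 3))
    for p in range(n_planes):
        nodes[p * npp : (p + 1) * npp, :2] = pts2d
        nodes[p * npp : (p + 1) * npp, 2] = z[p]

    def nid(i, j, k):
        return k * npp + i * (n_div + 1) + j

    # hex corner index arrays for one layer
    ii, jj = np.meshgrid(np.arange(n_div), np.arange(n_div), indexing="ij")
    ii, jj = ii.ravel(), jj.ravel()

    tets_list, labels_list = [], []
    for layer, region in enumerate(region_of_layer):
        for tet_local in _KUHN:
            tet_nodes = np.stack(
                [nid(ii + d[0], jj + d[1], layer + d[2]) for d in tet_local], axis=1
            )
            tets_list.append(tet_nodes)
            labels_list.append(np.full(len(tet_nodes), region, dtype=np.int64))
    tets = np.concatenate(tets_list)
    labels = np.concatenate(labels_list)

    # enforce positive orientation (the disk map can flip some Kuhn tets)
    vols = _signed_tet_volumes(nodes, tets)
    flip = vols < 0
    tets[flip] = tets[flip][:, [0, 1, 3, 2]]
    if np.any(_signed_tet_volumes(nodes, tets) <= 0):
        raise MeshResolutionError("degenerate (zero-volume) tetrahedron generated")

    boundary_tris, boundary_regions = _boundary_faces(nodes, tets, labels)

    # endplate node sets
    endplates: Dict[str, np.ndarray] = {}
    tol = 1e-9 * max(1.0, float(z[-1]))
    bottom = np.nonzero(np.abs(nodes[:, 2] - z[0]) <= tol)[0]
    top = np.nonzero(np.abs(nodes[:, 2] - z[-1]) <= tol)[0]
    endplates["bottom"] = bottom
    endplates["top"] = top
    z_cum = np.concatenate([[0.0], np.cumsum(region_heights)])
    for r, name in enumerate(region_names):
        lower = np.nonzero(np.abs(nodes[:, 2] - z_cum[r]) <= tol)[0]
        upper = np.nonzero(np.abs(nodes[:, 2] - z_cum[r + 1]) <= tol)[0]
        endplates[f"{name}_lower"] = lower
        endplates[f"{name}_upper"] = upper

    return LabeledTetMesh(
        nodes=nodes,
        tets=tets,
        region_labels=labels,
        region_names=list(region_names),
        boundary_triangles=boundary_tris,
        boundary_regions=boundary_regions,
        endplate_sets=endplates,
    )


def build_phantom(spec: PhantomSpec) -> LabeledTetMesh:
    """Generate the stacked vertebra/disc phantom mesh.

    Alternates vertebra and disc regions along +z starting and ending with a
    vertebra. Deterministic for a fixed spec.
    """
    heights, names = spec.region_layout()
    return build_stack(heights, names, spec)


def _signed_tet_volumes(nodes: np.ndarray, tets: np.ndarray) -> np.ndarray:
    p = nodes[tets]
    return np.linalg.det(p[:, 1:] - p[:, :1]) / 6.0


def tet_volumes(nodes: np.ndarray, tets: np.ndarray) -> np.ndarray:
    """Positive volumes of the given tetrahedra (mm^3 for mm coordinates)."""
    return np.abs(_signed_tet_volumes(nodes, tets))


_TET_FACES = np.array([[1, 2, 3], [0, 3, 2], [0, 1, 3], [0, 2, 1]])


def _boundary_faces(nodes, tets, labels):
    """Outward-oriented boundary triangles and the region owning each."""
    faces = tets[:, _TET_FACES]  # (m, 4, 3)
    flat = faces.reshape(-1, 3)
    key = np.sort(flat, axis=1)
    _, inv, counts = np.unique(key, axis=0, return_inverse=True, return_counts=True)
    boundary = counts[inv] == 1
    tri = flat[boundary]
    owner_tet = np.repeat(np.arange(len(tets)), 4)[boundary]
    # orient outward: normal must point away from the opposite node
    opp_local = np.tile(np.array([0, 1, 2, 3]), len(tets))[boundary]
    opp = tets[owner_tet, opp_local]
    a, b, c = nodes[tri[:, 0]], nodes[tri[:, 1]], nodes[tri[:, 2]]
    n = np.cross(b - a, c - a)
    inward = np.einsum("ij,ij->i", n, nodes[opp] - a) > 0
    tri[inward] = tri[inward][:, [0, 2, 1]]
    return tri, labels[owner_tet]


def extract_surface(mesh: LabeledTetMesh, compact: bool = True) -> SurfaceMesh:
    """Boundary surface of a tet mesh as a SurfaceMesh (watertight by construction)."""
    tris = mesh.boundary_triangles
    if compact:
        used, inv = np.unique(tris, return_inverse=True)
        vertices = mesh.nodes[used]
        triangles = inv.reshape(tris.shape)
    else:
        vertices, triangles = mesh.nodes, tris
    surf = SurfaceMesh(vertices=vertices, triangles=triangles)
    surf.watertight = surf.check_watertight()
    return surf


# ---------------------------------------------------------------------------
# Closed-form volume of the generating solid
# ---------------------------------------------------------------------------

def cross_section_area(spec: PhantomSpec) -> float:
    """Exact area of the meshed cross-section polygon.

    For the box this is the rectangle area. For the cylinder the mesh tiles
    the polygon inscribed in the circle whose vertices are the mapped boundary
    grid points; its area is computed by the shoelace formula.
    """
    if spec.cross_section == "box":
        return 4.0 * spec.half_widths[0] * spec.half_widths[1]
    pts2d, n_div = _base_grid(spec)
    n = n_div + 1
    grid = pts2d.reshape(n, n, 2)
    ring = np.concatenate(
        [grid[0, :-1], grid[:-1, -1], grid[-1, ::-1][:-1], grid[::-1, 0][:-1]]
    )
    x, y = ring[:, 0], ring[:, 1]
    return float(abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))) / 2.0)


def analytic_volume(spec: PhantomSpec) -> float:
    """Closed-form volume (mm^3) of the generated prism: base area x height."""
    return cross_section_area(spec) * spec.total_height


# ---------------------------------------------------------------------------
# Endplate annotation
# ---------------------------------------------------------------------------

def default_distance_band(
    surface: SurfaceMesh, axis=(0.0, 0.0, 1.0), fraction: float = 0.15
) -> Tuple[float, float]:
    """Axial band covering the outer ``fraction`` of the surface's extent.

    Distances are measured along ``axis`` from the surface's axial centroid;
    the returned band selects centroids in the top (equivalently, mirrored
    bottom) ``fraction`` of the z-extent.
    """
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    s = surface.vertices @ axis
    half = (s.max() - s.min()) / 2.0
    return (half * (1.0 - 2.0 * fraction), half)


def annotate_endplates(
    surface: SurfaceMesh,
    max_angle_deg: float = 30.0,
    distance_band: Optional[Tuple[float, float]] = None,
    axis=(0.0, 0.0, 1.0),
) -> Tuple[np.ndarray, np.ndarray]:
    """Identify upper and lower endplate triangles of a vertebral surface.

    A triangle belongs to the *upper* endplate iff its outward normal makes an
    angle <= ``max_angle_deg`` with ``+axis`` and its centroid's signed axial
    distance from the surface's axial centroid lies within ``distance_band``
    (min, max, mm). The *lower* set is defined analogously with ``-axis`` and
    distance measured along ``-axis``. The predicate is purely per-triangle,
    hence idempotent and order-independent; the two sets are disjoint for
    max_angle_deg < 90.

    Returns (upper_idx, lower_idx) triangle-index arrays; empty selections
    produce a warning, not an error.
    """
    if not (0.0 <= max_angle_deg < 90.0):
        raise ValueError("max_angle_deg must lie in [0, 90)")
    axis = np.asarray(axis, dtype=float)
    nrm = np.linalg.norm(axis)
    if nrm == 0:
        raise ValueError("axis must be a nonzero vector")
    axis = axis / nrm
    if distance_band is None:
        distance_band = default_distance_band(surface, axis)
    lo, hi = distance_band

    cos_max = np.cos(np.deg2rad(max_angle_deg))
    normals = surface.normals
    # guard against non-unit normals from external files
    normals = normals / np.maximum(np.linalg.norm(normals, axis=1, keepdims=True), 1e-300)
    c = surface.triangle_centroids()
    s_centroid = float(np.mean(surface.vertices @ axis))
    d = c @ axis - s_centroid

    cosang = normals @ axis
    upper = np.nonzero((cosang >= cos_max) & (d >= lo) & (d <= hi))[0]
    lower = np.nonzero((-cosang >= cos_max) & (-d >= lo) & (-d <= hi))[0]
    if len(upper) == 0 or len(lower) == 0:
        warnings.warn(
            "endplate annotation selected an empty set "
            f"(upper={len(upper)}, lower={len(lower)})",
            stacklevel=2,
        )
    return upper, lower


# ---------------------------------------------------------------------------
# Test / verification helper
# ---------------------------------------------------------------------------

def permute_mesh(mesh: LabeledTetMesh, rng: np.random.Generator) -> LabeledTetMesh:
    """Renumber nodes and reorder elements randomly (same physical mesh)."""
    n = len(mesh.nodes)
    node_perm = rng.permutation(n)
    inv = np.empty(n, dtype=np.int64)
    inv[node_perm] = np.arange(n)
    tet_perm = rng.permutation(len(mesh.tets))
    tets = inv[mesh.tets][tet_perm]
    labels = mesh.region_labels[tet_perm]
    tris = inv[mesh.boundary_triangles]
    endplates = {k: np.sort(inv[v]) for k, v in mesh.endplate_sets.items()}
    return LabeledTetMesh(
        nodes=mesh.nodes[node_perm],
        tets=tets,
        region_labels=labels,
        region_names=list(mesh.region_names),
        boundary_triangles=tris,
        boundary_regions=mesh.boundary_regions.copy(),
        endplate_sets=endplates,
    )
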