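"""Structured background-grid tetrahedral meshing of the dentition solids.

All regions (teeth, PDL shells, splint) are meshed on ONE regular grid:
every grid cube whose centre falls inside a solid is kept, labelled with
that solid's region, and split into the six-tetrahedron Kuhn pattern.
Because the pattern is identical in every cube, meshes of adjacent regions
are node-conforming at shared interfaces by construction — bonded (tied)
contact then reduces to plain node sharing.  All tetrahedra have positive
signed volume under the fixed node-ordering convention.

Region classification priority where solids abut: tooth, then PDL, then
splint (the solids' predicates are mutually exclusive by construction, so
the priority only resolves floating-point boundary ties).

The longest edge of a Kuhn tetrahedron is the cube body diagonal, so a
maximum-edge target `e` per region maps to a cell size `e / sqrt(3)`; one
shared grid uses the smallest cell over all regions.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components

from .geometry import Dentition

__all__ = [
    "DentitionModel",
    "BoundaryFaces",
    "mesh_dentition",
    "box_mesh",
    "cell_size_from_max_edge",
    "tet_volumes",
    "boundary_faces",
    "region_surface",
    "interface_nodes",
]

#: Angular tolerance defining "occlusal" surface: outward normal within 30
#: degrees of vertical (+z).
OCCLUSAL_CONE_DEG = 30.0


def _kuhn_pattern() -> np.ndarray:
    """Six positively oriented tets tiling the unit cube, as corner offsets.

    Each tet follows a monotone lattice path (0,0,0) -> (1,1,1); all six
    share the cube's main diagonal, so translated copies tile space
    conformally.
    """
    tets = []
    for perm in itertools.permutations(range(3)):
        v = [np.zeros(3, dtype=int)]
        for axis in perm:
            nxt = v[-1].copy()
            nxt[axis] = 1
            v.append(nxt)
        tet = np.array(v)
        m = (tet[1:] - tet[0]).astype(float)
        if np.linalg.det(m) < 0:
            tet[[2, 3]] = tet[[3, 2]]
        tets.append(tet)
    return np.array(tets)  # (6, 4, 3)


_KUHN = _kuhn_pattern()

#: Faces of tet (0,1,2,3); face i is opposite vertex i.
_TET_FACES = np.array([[1, 2, 3], [0, 3, 2], [0, 1, 3], [0, 2, 1]])


def tet_volumes(nodes: np.ndarray, elements: np.ndarray) -> np.ndarray:
    """Signed volumes of 4-node tetrahedra (positive for valid ordering)."""
    a, b, c, d = (nodes[elements[:, i]] for i in range(4))
    return np.einsum("ij,ij->i", np.cross(b - a, c - a), d - a) / 6.0


@dataclass
class DentitionModel:
    """Multi-region tetrahedral mesh with named node sets.

    Region labels follow the convention: FDI code string ("36") for a tooth,
    "pdl_<FDI>" for its ligament shell, "splint" for the appliance.  Node
    sets include "occlusal_<FDI>", "occlusal_splint", "pdl_outer",
    "crown_outer_<FDI>" and "splint_inner" where the regions exist.
    """

    nodes: np.ndarray                       # (n, 3) float, mm
    elements: np.ndarray                    # (m, 4) int node indices
    element_region: np.ndarray              # (m,) int index into region_names
    region_names: tuple[str, ...]
    node_sets: dict[str, np.ndarray] = field(default_factory=dict)
    face_sets: dict[str, np.ndarray] = field(default_factory=dict)
    cell_size_mm: float = 0.0
    fdi_codes: tuple[int, ...] = ()

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    def region_id(self, name: str) -> int:
        try:
            return self.region_names.index(name)
        except ValueError:
            raise KeyError(f"unknown region {name!r}") from None

    def elements_of(self, name: str) -> np.ndarray:
        """Indices of elements belonging to a region."""
        return np.flatnonzero(self.element_region == self.region_id(name))

    def region_volume(self, name: str) -> float:
        return float(tet_volumes(self.nodes, self.elements[self.elements_of(name)]).sum())

    def node_set(self, name: str) -> np.ndarray:
        try:
            return self.node_sets[name]
        except KeyError:
            raise KeyError(f"unknown node set {name!r}") from None

    def face_set(self, name: str) -> np.ndarray:
        """Triangles (f, 3 node indices) of a named surface patch."""
        try:
            return self.face_sets[name]
        except KeyError:
            raise KeyError(f"unknown face set {name!r}") from None


@dataclass(frozen=True)
class BoundaryFaces:
    """Exterior triangular faces with outward normals."""

    faces: np.ndarray        # (f, 3) node indices
    element: np.ndarray      # (f,) owning element index
    normals: np.ndarray      # (f, 3) unit outward normals
    centroids: np.ndarray    # (f, 3)


def cell_size_from_max_edge(max_edge: float | Mapping[str, float]) -> float:
    """Grid cell size honouring per-region maximum tetrahedron edge lengths.

    One shared grid serves all regions, so the smallest limit governs; the
    longest Kuhn-tet edge is the cube body diagonal sqrt(3)*h.
    """
    e = min(max_edge.values()) if isinstance(max_edge, Mapping) else float(max_edge)
    if e <= 0:
        raise ValueError("max_edge must be positive")
    return e / np.sqrt(3.0)


def _grid_to_mesh(
    lo: np.ndarray,
    h: float,
    cell_region: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Split every labelled cell (label >= 0) of a cell grid into Kuhn tets.

    Returns compacted (nodes, elements, element_region).
    """
    ncx, ncy, ncz = cell_region.shape
    keep = np.argwhere(cell_region >= 0)
    if len(keep) == 0:
        raise ValueError("no cells inside any region: nothing to mesh")
    nyn, nzn = ncy + 1, ncz + 1

    def node_id(ijk: np.ndarray) -> np.ndarray:
        return (ijk[:, 0] * nyn + ijk[:, 1]) * nzn + ijk[:, 2]

    elem_blocks = []
    for tet in _KUHN:  # (4, 3) corner offsets
        ids = np.stack([node_id(keep + off) for off in tet], axis=1)
        elem_blocks.append(ids)
    # interleave so all 6 tets of a cell are adjacent in element order
    elements = np.stack(elem_blocks, axis=1).reshape(-1, 4)
    element_region = np.repeat(cell_region[keep[:, 0], keep[:, 1], keep[:, 2]], 6)

    used, inverse = np.unique(elements, return_inverse=True)
    elements = inverse.reshape(elements.shape).astype(np.int64)
    i = used // (nyn * nzn)
    j = (used // nzn) % nyn
    k = used % nzn
    nodes = lo[None, :] + h * np.column_stack([i, j, k]).astype(float)
    return nodes, elements, element_region


def boundary_faces(model: DentitionModel, region: str | None = None) -> BoundaryFaces:
    """Exterior faces of the whole mesh, optionally filtered to one region.

    A face is exterior when no second element (of any region) shares it;
    region interfaces are therefore not boundaries.
    """
    elems = model.elements
    faces = elems[:, _TET_FACES]                        # (m, 4, 3)
    flat = faces.reshape(-1, 3)
    owner = np.repeat(np.arange(len(elems)), 4)
    key = np.sort(flat, axis=1)
    _, first, counts = np.unique(key, axis=0, return_index=True, return_counts=True)
    ext = first[counts == 1]
    if region is not None:
        rid = model.region_id(region)
        ext = ext[model.element_region[owner[ext]] == rid]
    tri = flat[ext]
    own = owner[ext]
    a, b, c = model.nodes[tri[:, 0]], model.nodes[tri[:, 1]], model.nodes[tri[:, 2]]
    n = np.cross(b - a, c - a)
    cent = (a + b + c) / 3.0
    opp = elems[own].sum(axis=1) - tri.sum(axis=1)      # the non-face vertex
    flip = np.einsum("ij,ij->i", n, cent - model.nodes[opp]) < 0
    n[flip] *= -1.0
    n /= np.linalg.norm(n, axis=1, keepdims=True)
    return BoundaryFaces(faces=tri, element=own, normals=n, centroids=cent)


def region_surface(model: DentitionModel, region: str) -> BoundaryFaces:
    """Surface of one region: faces not shared by two elements OF THAT region.

    Unlike :func:`boundary_faces`, interfaces with other regions count as
    surface here — so a crown top stays "occlusal" even when a splint covers
    it.  Normals point out of the region.
    """
    rid = model.region_id(region)
    elems_idx = np.flatnonzero(model.element_region == rid)
    elems = model.elements[elems_idx]
    faces = elems[:, _TET_FACES].reshape(-1, 3)
    owner = np.repeat(elems_idx, 4)
    key = np.sort(faces, axis=1)
    _, first, counts = np.unique(key, axis=0, return_index=True, return_counts=True)
    ext = first[counts == 1]
    tri = faces[ext]
    own = owner[ext]
    a, b, c = model.nodes[tri[:, 0]], model.nodes[tri[:, 1]], model.nodes[tri[:, 2]]
    n = np.cross(b - a, c - a)
    cent = (a + b + c) / 3.0
    opp = model.elements[own].sum(axis=1) - tri.sum(axis=1)
    flip = np.einsum("ij,ij->i", n, cent - model.nodes[opp]) < 0
    n[flip] *= -1.0
    n /= np.linalg.norm(n, axis=1, keepdims=True)
    return BoundaryFaces(faces=tri, element=own, normals=n, centroids=cent)


def interface_nodes(model: DentitionModel, region_a: str, region_b: str) -> np.ndarray:
    """Nodes shared by elements of two adjacent regions (bonded interface)."""
    na = np.unique(model.elements[model.elements_of(region_a)])
    nb = np.unique(model.elements[model.elements_of(region_b)])
    return np.intersect1d(na, nb)


def _region_connected(model: DentitionModel, region: str) -> int:
    """Number of node-connected components of a region's element set."""
    idx = model.elements_of(region)
    elems = model.elements[idx]
    used, inv = np.unique(elems, return_inverse=True)
    inv = inv.reshape(elems.shape)
    rows = np.repeat(np.arange(len(elems)), 4)
    inc = sparse.coo_matrix(
        (np.ones(rows.size), (rows, inv.ravel())), shape=(len(elems), len(used))
    ).tocsr()
    adj = inc @ inc.T
    ncomp, _ = connected_components(adj, directed=False)
    return int(ncomp)


def _top_cap(bf: BoundaryFaces, h: float) -> tuple[np.ndarray, np.ndarray]:
    """Upward (occlusal-cone) surface faces on the topmost layer.

    Returns (node indices, face triangles)."""
    cos_lim = np.cos(np.deg2rad(OCCLUSAL_CONE_DEG))
    up = bf.normals[:, 2] > cos_lim
    if not up.any():
        empty = np.array([], dtype=np.int64)
        return empty, empty.reshape(0, 3)
    z_top = bf.centroids[up, 2].max()
    cap = up & (bf.centroids[:, 2] > z_top - 0.6 * h)
    return np.unique(bf.faces[cap]), bf.faces[cap]


def mesh_dentition(
    dentition: Dentition,
    cell_size_mm: float | None = None,
    max_edge_mm: float | Mapping[str, float] | None = None,
) -> DentitionModel:
    """Mesh a dentition (teeth + PDL shells + optional splint) on one grid.

    Exactly one of ``cell_size_mm`` / ``max_edge_mm`` may be given; the
    default cell size equals the PDL thickness, which guarantees the
    one-cell-wide ligament band is captured in every grid column crossing
    the root surface.
    """
    if cell_size_mm is not None and max_edge_mm is not None:
        raise ValueError("give either cell_size_mm or max_edge_mm, not both")
    if max_edge_mm is not None:
        h = cell_size_from_max_edge(max_edge_mm)
    else:
        h = cell_size_mm if cell_size_mm is not None else dentition.spec.pdl_thickness_mm
    if h <= 0:
        raise ValueError("cell size must be positive")

    lo, hi = dentition.bounding_box
    lo = lo - 0.5 * h
    shape = np.maximum(np.ceil((hi + 0.5 * h - lo) / h).astype(int), 1)
    ax = [lo[k] + (np.arange(shape[k]) + 0.5) * h for k in range(3)]
    X, Y, Z = np.meshgrid(*ax, indexing="ij")
    centers = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])

    region_names: list[str] = []
    cell_region = np.full(centers.shape[0], -1, dtype=np.int64)

    def claim(mask: np.ndarray, name: str) -> None:
        mask = mask & (cell_region < 0)
        if not mask.any():
            raise ValueError(f"region {name!r} is empty after meshing at h={h} mm")
        region_names.append(name)
        cell_region[mask] = len(region_names) - 1

    for tooth in dentition.teeth:
        claim(tooth.contains(centers), str(tooth.fdi))
    for shell in dentition.pdl_shells:
        claim(shell.contains(centers), f"pdl_{shell.tooth.fdi}")
    if dentition.splint is not None:
        claim(dentition.splint.contains(centers), "splint")

    nodes, elements, element_region = _grid_to_mesh(
        lo, h, cell_region.reshape(tuple(shape))
    )
    model = DentitionModel(
        nodes=nodes,
        elements=elements,
        element_region=element_region,
        region_names=tuple(region_names),
        cell_size_mm=h,
        fdi_codes=tuple(t.fdi for t in dentition.teeth),
    )

    if (tet_volumes(nodes, elements) <= 0).any():
        raise RuntimeError("background-grid meshing produced a non-positive tet")

    # --- node sets -------------------------------------------------------
    sets: dict[str, np.ndarray] = {}
    fsets: dict[str, np.ndarray] = {}
    pdl_nodes = []
    for tooth in dentition.teeth:
        fdi = tooth.fdi
        sets[f"occlusal_{fdi}"], fsets[f"occlusal_{fdi}"] = _top_cap(
            region_surface(model, str(fdi)), h
        )
        tie = interface_nodes(model, str(fdi), f"pdl_{fdi}")
        if len(tie) == 0:
            raise RuntimeError(
                f"tooth {fdi} is not attached to its PDL shell at h={h} mm; "
                "refine the mesh"
            )
        pdl_nodes.append(np.unique(boundary_faces(model, f"pdl_{fdi}").faces))
    sets["pdl_outer"] = np.unique(np.concatenate(pdl_nodes))

    if dentition.splint is not None:
        if _region_connected(model, "splint") != 1:
            raise RuntimeError("splint region is disconnected; refine the mesh")
        sets["occlusal_splint"], fsets["occlusal_splint"] = _top_cap(
            region_surface(model, "splint"), h
        )
        inner = []
        for tooth in dentition.teeth:
            shared = interface_nodes(model, str(tooth.fdi), "splint")
            if len(shared) == 0:
                raise RuntimeError(f"splint does not contact tooth {tooth.fdi}")
            sets[f"crown_outer_{tooth.fdi}"] = shared
            inner.append(shared)
        sets["splint_inner"] = np.unique(np.concatenate(inner))

    model.node_sets = sets
    model.face_sets = fsets
    return model


def box_mesh(
    lengths: Iterable[float],
    cell_size_mm: float,
    origin: Iterable[float] = (0.0, 0.0, 0.0),
    region: str = "box",
) -> DentitionModel:
    """Mesh an axis-aligned box — the workhorse for solver benchmarks."""
    lengths = np.asarray(tuple(lengths), dtype=float)
    origin = np.asarray(tuple(origin), dtype=float)
    if (lengths <= 0).any() or cell_size_mm <= 0:
        raise ValueError("box lengths and cell size must be positive")
    shape = np.maximum(np.rint(lengths / cell_size_mm).astype(int), 1)
    cell_region = np.zeros(tuple(shape), dtype=np.int64)
    nodes, elements, element_region = _grid_to_mesh(origin, cell_size_mm, cell_region)
    # snap the far faces to the exact requested lengths
    scale = lengths / (shape * cell_size_mm)
    nodes = origin + (nodes - origin) * scale
    return DentitionModel(
        nodes=nodes,
        elements=elements,
        element_region=element_region,
        region_names=(region,),
        cell_size_mm=cell_size_mm,
    )
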