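"""Linear-elastic solver on 4-node (constant-strain) tetrahedra.

Small-strain isotropic elasticity with three translational degrees of
freedom per node — the classical CST tet (ANSYS SOLID285 analogue).  Units
are the consistent mm-N-MPa system: coordinates in mm, forces in N, moduli
and stresses in MPa (1 N/mm^2 = 1 MPa), so handbook material constants are
used verbatim.

Element stiffness is K_e = V * B^T D B with the element-constant
strain-displacement matrix B; stress is element-constant and reported
without nodal averaging.  Dirichlet constraints (zero or prescribed) and
bonded tied-pair constraints are eliminated through a reduction operator
T: the reduced system T^T K T is solved with a sparse LU factorization
(conjugate-gradient fallback), and reactions are recovered as K u - f on
the constrained degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import sparse
from scipy.sparse import linalg as spla

from .meshing import DentitionModel

__all__ = [
    "MaterialModel",
    "TOOTH",
    "PDL",
    "PMMA",
    "LoadCase",
    "SolutionFields",
    "element_stiffness",
    "assemble",
    "apply_occlusal_load",
    "apply_occlusal_pressure",
    "uniform_traction_load",
    "solve_system",
    "recover_von_mises",
    "default_materials",
]

#: Voigt component order used throughout: xx, yy, zz, xy, yz, zx.
VOIGT = ("xx", "yy", "zz", "xy", "yz", "zx")

RESIDUAL_TOL = 1e-10


@dataclass(frozen=True)
class MaterialModel:
    """Isotropic linear-elastic material."""

    young_modulus_MPa: float
    poisson_ratio: float
    name: str = ""

    def __post_init__(self) -> None:
        if self.young_modulus_MPa <= 0.0:
            raise ValueError("Young's modulus must be positive")
        if not 0.0 < self.poisson_ratio < 0.5:
            raise ValueError("Poisson's ratio must lie in (0, 0.5)")

    def stiffness_matrix(self) -> np.ndarray:
        """6x6 isotropic elasticity matrix D in Voigt order (engineering shear)."""
        E, nu = self.young_modulus_MPa, self.poisson_ratio
        lam = E * nu / ((1.0 + nu) * (1.0 - 2.0 * nu))
        mu = E / (2.0 * (1.0 + nu))
        D = np.zeros((6, 6))
        D[:3, :3] = lam
        D[np.arange(3), np.arange(3)] += 2.0 * mu
        D[np.arange(3, 6), np.arange(3, 6)] = mu
        return D


#: Handbook constants for the three model components (MPa, dimensionless).
TOOTH = MaterialModel(20300.00, 0.26, "tooth")
PDL = MaterialModel(68.90, 0.45, "pdl")
PMMA = MaterialModel(2200.00, 0.35, "pmma")


def default_materials(model: DentitionModel) -> dict[str, MaterialModel]:
    """Map every region of a dentition mesh to its component material."""
    mats: dict[str, MaterialModel] = {}
    for name in model.region_names:
        if name == "splint":
            mats[name] = PMMA
        elif name.startswith("pdl_"):
            mats[name] = PDL
        else:
            mats[name] = TOOTH
    return mats


@dataclass
class LoadCase:
    """Nodal forces plus kinematic constraints for one static analysis."""

    nodal_forces: np.ndarray                       # (n, 3) in N
    fixed_nodes: np.ndarray = field(default_factory=lambda: np.array([], dtype=np.int64))
    prescribed: dict[int, np.ndarray] = field(default_factory=dict)  # node -> u (mm)
    tied_pairs: Sequence[tuple[int, int]] = ()

    @property
    def n_nodes(self) -> int:
        return len(self.nodal_forces)

    def constrained_nodes(self) -> np.ndarray:
        return np.unique(
            np.concatenate([self.fixed_nodes, np.array(sorted(self.prescribed), dtype=np.int64)])
        )


@dataclass
class SolutionFields:
    """Static solution: nodal displacements plus element stress state."""

    displacements: np.ndarray        # (n, 3) mm
    element_stress: np.ndarray       # (m, 6) MPa, Voigt order
    von_mises: np.ndarray            # (m,) MPa
    reactions: dict[int, np.ndarray]  # constrained node -> reaction force (N)
    residual: float                  # relative residual of the reduced solve

    @property
    def total_displacement(self) -> np.ndarray:
        """Euclidean norm |u| per node, mm."""
        return np.linalg.norm(self.displacements, axis=1)


# ---------------------------------------------------------------------------
# element and global stiffness


def _shape_gradients(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Constant shape-function gradients and volumes for a batch of tets.

    coords: (m, 4, 3).  Returns (grads (m, 4, 3), volumes (m,)).
    """
    coords = np.asarray(coords, dtype=float)
    single = coords.ndim == 2
    if single:
        coords = coords[None]
    m = coords.shape[0]
    M = np.concatenate([np.ones((m, 4, 1)), coords], axis=2)      # (m, 4, 4)
    vol = np.linalg.det(M) / 6.0
    if (vol <= 0).any():
        bad = int(np.argmax(vol <= 0))
        raise ValueError(f"degenerate tetrahedron (signed volume {vol[bad]:g} mm^3)")
    C = np.linalg.inv(M)
    grads = np.transpose(C[:, 1:4, :], (0, 2, 1))                 # (m, 4, 3)
    return (grads[0], float(vol[0])) if single else (grads, vol)


def _b_matrix(grads: np.ndarray) -> np.ndarray:
    """Strain-displacement matrices B (m, 6, 12) from shape gradients."""
    if grads.ndim == 2:
        grads = grads[None]
    m = grads.shape[0]
    B = np.zeros((m, 6, 12))
    gx, gy, gz = grads[:, :, 0], grads[:, :, 1], grads[:, :, 2]
    cols = 3 * np.arange(4)
    B[:, 0, cols + 0] = gx
    B[:, 1, cols + 1] = gy
    B[:, 2, cols + 2] = gz
    B[:, 3, cols + 0] = gy
    B[:, 3, cols + 1] = gx
    B[:, 4, cols + 1] = gz
    B[:, 4, cols + 2] = gy
    B[:, 5, cols + 0] = gz
    B[:, 5, cols + 2] = gx
    return B


def element_stiffness(coords: np.ndarray, material: MaterialModel) -> np.ndarray:
    """12x12 stiffness of one tet: K_e = V * B^T D B.

    Symmetric with exactly six zero eigenvalues (rigid-body modes).  Raises
    on non-positive volume.
    """
    grads, vol = _shape_gradients(np.asarray(coords, dtype=float))
    B = _b_matrix(grads)[0]
    D = material.stiffness_matrix()
    return vol * B.T @ D @ B


def assemble(
    model: DentitionModel, materials: Mapping[str, MaterialModel]
) -> sparse.csr_matrix:
    """Global sparse stiffness (3n x 3n) from per-region materials.

    Bonded interfaces between conforming regions need no extra treatment:
    the shared nodes already tie the regions together.
    """
    missing = [r for r in model.region_names if r not in materials]
    if missing:
        raise KeyError(f"no material given for regions: {missing}")

    coords = model.nodes[model.elements]                          # (m, 4, 3)
    grads, vols = _shape_gradients(coords)
    B = _b_matrix(grads)                                          # (m, 6, 12)

    D = np.zeros((len(model.elements), 6, 6))
    for name in model.region_names:
        idx = model.elements_of(name)
        D[idx] = materials[name].stiffness_matrix()

    Ke = np.einsum("e,eji,ejk,ekl->eil", vols, B, D, B, optimize=True)  # (m,12,12)

    dof = (3 * model.elements[:, :, None] + np.arange(3)[None, None, :]).reshape(-1, 12)
    rows = np.repeat(dof, 12, axis=1).ravel()
    cols = np.tile(dof, (1, 12)).ravel()
    n = 3 * model.n_nodes
    K = sparse.coo_matrix((Ke.ravel(), (rows, cols)), shape=(n, n)).tocsr()
    K.sum_duplicates()
    return K


# ---------------------------------------------------------------------------
# loads and constraints


def apply_occlusal_load(
    model: DentitionModel,
    node_set: str,
    total_force_N: float,
    direction: Sequence[float] = (0.0, 0.0, -1.0),
    load_case: LoadCase | None = None,
) -> LoadCase:
    """Spread a total force evenly over a named node set.

    Each node receives total/|set| along ``direction`` (unit vector; default
    vertical, downward onto the occlusal surface).  Passing an existing
    ``load_case`` accumulates into a copy of it, so disjoint sets add.
    """
    nodes = model.node_set(node_set)
    if len(nodes) == 0:
        raise ValueError(f"node set {node_set!r} is empty")
    d = np.asarray(direction, dtype=float)
    if not np.isclose(np.linalg.norm(d), 1.0, atol=1e-9):
        raise ValueError("direction must be a unit vector")
    if load_case is None:
        forces = np.zeros((model.n_nodes, 3))
        lc = LoadCase(nodal_forces=forces)
    else:
        lc = LoadCase(
            nodal_forces=load_case.nodal_forces.copy(),
            fixed_nodes=load_case.fixed_nodes,
            prescribed=dict(load_case.prescribed),
            tied_pairs=load_case.tied_pairs,
        )
    lc.nodal_forces[nodes] += (total_force_N / len(nodes)) * d
    return lc


def uniform_traction_load(
    model: DentitionModel,
    faces: np.ndarray,
    traction_MPa: Sequence[float],
    load_case: LoadCase | None = None,
) -> LoadCase:
    """Consistent nodal forces for a uniform traction on boundary triangles.

    Each triangle spreads (area x traction)/3 to its three nodes — the
    consistent load vector of linear elements, which keeps patch-type
    solutions exact (unlike an even per-node split).
    """
    faces = np.asarray(faces, dtype=np.int64)
    t = np.asarray(traction_MPa, dtype=float)
    if load_case is None:
        load_case = LoadCase(nodal_forces=np.zeros((model.n_nodes, 3)))
    else:
        load_case = LoadCase(
            nodal_forces=load_case.nodal_forces.copy(),
            fixed_nodes=load_case.fixed_nodes,
            prescribed=dict(load_case.prescribed),
            tied_pairs=load_case.tied_pairs,
        )
    a, b, c = (model.nodes[faces[:, i]] for i in range(3))
    area = 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)
    contrib = (area[:, None] / 3.0) * t[None, :]
    for i in range(3):
        np.add.at(load_case.nodal_forces, faces[:, i], contrib)
    return load_case


def apply_occlusal_pressure(
    model: DentitionModel,
    face_set: str,
    total_force_N: float,
    direction: Sequence[float] = (0.0, 0.0, -1.0),
    load_case: LoadCase | None = None,
) -> LoadCase:
    """Spread a total force over a surface patch as a uniform pressure.

    The traction magnitude is total/area and nodal forces are the
    consistent (area-weighted) load vector, so the surface stress state is
    uniform — the FE-faithful realization of an evenly distributed occlusal
    load (an exactly-even per-node split over-weights rim nodes and spikes
    the stress under the load points).
    """
    faces = model.face_set(face_set)
    if len(faces) == 0:
        raise ValueError(f"face set {face_set!r} is empty")
    d = np.asarray(direction, dtype=float)
    if not np.isclose(np.linalg.norm(d), 1.0, atol=1e-9):
        raise ValueError("direction must be a unit vector")
    a, b, c = (model.nodes[faces[:, i]] for i in range(3))
    area = float(0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1).sum())
    return uniform_traction_load(model, faces, (total_force_N / area) * d, load_case)


def _reduction_operator(
    n_nodes: int, load_case: LoadCase
) -> tuple[sparse.csr_matrix, np.ndarray, np.ndarray]:
    """Build T and u_p with u = T u_r + u_p.

    Tied pairs (slave, master) force coincident displacement; fixed and
    prescribed nodes pin all three components.  Returns (T, u_p,
    constrained_dofs).
    """
    n = 3 * n_nodes
    rep = np.arange(n)
    for slave, master in load_case.tied_pairs:
        for c in range(3):
            rep[3 * slave + c] = 3 * master + c
    # resolve chains (master itself tied onward)
    for _ in range(64):
        nxt = rep[rep]
        if np.array_equal(nxt, rep):
            break
        rep = nxt

    u_p = np.zeros(n)
    constrained = np.zeros(n, dtype=bool)
    for node in load_case.fixed_nodes:
        constrained[3 * node : 3 * node + 3] = True
    for node, val in load_case.prescribed.items():
        sl = slice(3 * node, 3 * node + 3)
        constrained[sl] = True
        u_p[sl] = np.asarray(val, dtype=float)
    # a constraint on either end of a tie pins the representative
    constrained_rep = np.zeros(n, dtype=bool)
    np.logical_or.at(constrained_rep, rep, constrained)
    u_p_rep = np.zeros(n)
    u_p_rep[rep[constrained]] = u_p[constrained]
    u_p = u_p_rep[rep]

    free_rep = np.unique(rep[~constrained_rep[rep]])
    if len(free_rep) == n:
        raise ValueError(
            "no fixed or prescribed nodes: the stiffness matrix is singular "
            "(rigid-body motion is unconstrained)"
        )
    col_of = -np.ones(n, dtype=np.int64)
    col_of[free_rep] = np.arange(len(free_rep))
    rows = np.flatnonzero(col_of[rep] >= 0)
    T = sparse.coo_matrix(
        (np.ones(len(rows)), (rows, col_of[rep[rows]])), shape=(n, len(free_rep))
    ).tocsr()
    return T, u_p, np.flatnonzero(constrained)


def solve_system(
    model: DentitionModel,
    materials: Mapping[str, MaterialModel],
    load_case: LoadCase,
    stiffness: sparse.csr_matrix | None = None,
) -> SolutionFields:
    """Assemble (unless given), solve, and recover stresses and reactions.

    The reduced system is solved with sparse LU; if factorization fails, a
    Jacobi-preconditioned conjugate gradient takes over.  The relative
    residual of the reduced system must reach 1e-8 or the solve raises.
    """
    K = assemble(model, materials) if stiffness is None else stiffness
    f = load_case.nodal_forces.ravel().astype(float)
    if len(f) != K.shape[0]:
        raise ValueError("load case size does not match the mesh")

    T, u_p, constrained = _reduction_operator(model.n_nodes, load_case)
    Kr = (T.T @ K @ T).tocsc()
    fr = T.T @ (f - K @ u_p)

    try:
        ur = spla.splu(Kr).solve(fr)
    except RuntimeError:
        M = sparse.diags(1.0 / Kr.diagonal())
        ur, info = spla.cg(Kr, fr, M=M, rtol=RESIDUAL_TOL, maxiter=20 * Kr.shape[0])
        if info != 0:
            raise RuntimeError(f"conjugate gradient failed to converge (info={info})")

    denom = np.linalg.norm(fr)
    residual = float(np.linalg.norm(Kr @ ur - fr) / denom) if denom > 0 else 0.0
    if residual > 1e-8:
        raise RuntimeError(f"solver residual {residual:g} exceeds 1e-8")

    u = (T @ ur + u_p).reshape(-1, 3)

    r = (K @ u.ravel() - f).reshape(-1, 3)
    reactions = {
        int(node): r[int(node)].copy()
        for node in np.unique(constrained // 3)
    }

    stress, vm = _recover_stresses(model, materials, u)
    return SolutionFields(
        displacements=u,
        element_stress=stress,
        von_mises=vm,
        reactions=reactions,
        residual=residual,
    )


# ---------------------------------------------------------------------------
# stress recovery


def _recover_stresses(
    model: DentitionModel, materials: Mapping[str, MaterialModel], u: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    coords = model.nodes[model.elements]
    grads, _ = _shape_gradients(coords)
    B = _b_matrix(grads)
    ue = u[model.elements].reshape(-1, 12)
    strain = np.einsum("eij,ej->ei", B, ue)
    stress = np.empty_like(strain)
    for name in model.region_names:
        idx = model.elements_of(name)
        stress[idx] = strain[idx] @ materials[name].stiffness_matrix().T
    return stress, recover_von_mises(stress)


def recover_von_mises(stress: np.ndarray) -> np.ndarray | float:
    """Von Mises equivalent stress from a symmetric stress state.

    Accepts Voigt vectors (..., 6) in (xx, yy, zz, xy, yz, zx) order or full
    tensors (..., 3, 3).
    """
    s = np.asarray(stress, dtype=float)
    if s.shape[-2:] == (3, 3):
        sv = np.stack(
            [s[..., 0, 0], s[..., 1, 1], s[..., 2, 2], s[..., 0, 1], s[..., 1, 2], s[..., 2, 0]],
            axis=-1,
        )
    elif s.shape[-1] == 6:
        sv = s
    else:
        raise ValueError("stress must be (...,6) Voigt or (...,3,3) tensor")
    sx, sy, sz, txy, tyz, tzx = (sv[..., i] for i in range(6))
    vm = np.sqrt(
        0.5 * ((sx - sy) ** 2 + (sy - sz) ** 2 + (sz - sx) ** 2)
        + 3.0 * (txy**2 + tyz**2 + tzx**2)
    )
    return float(vm) if vm.ndim == 0 else vm
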