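"""Independent brute-force references used to cross-check the solver.

Everything here is deliberately written along a different computational
route from the package: shape gradients come from the isoparametric
Jacobian (not the 4x4 coordinate-matrix inverse), assembly is dense, and
the solve is numpy's dense LAPACK path.
"""

from __future__ import annotations

from collections import deque

import numpy as np

#: Reference-element shape-function gradients of the linear tet
#: N = [1-xi-eta-zeta, xi, eta, zeta].
_GRAD_REF = np.array(
    [[-1.0, -1.0, -1.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]]
)


def dense_element_stiffness(coords: np.ndarray, E: float, nu: float) -> np.ndarray:
    """Tet4 stiffness via the isoparametric Jacobian route."""
    coords = np.asarray(coords, dtype=float)
    J = (coords[1:] - coords[0]).T                # J_ij = dx_i/dxi_j
    detJ = np.linalg.det(J)
    vol = detJ / 6.0
    grads = _GRAD_REF @ np.linalg.inv(J)          # (4, 3) physical gradients

    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    D = np.zeros((6, 6))
    D[:3, :3] = lam
    D[np.arange(3), np.arange(3)] += 2 * mu
    D[np.arange(3, 6), np.arange(3, 6)] = mu

    B = np.zeros((6, 12))
    for i in range(4):
        gx, gy, gz = grads[i]
        B[0, 3 * i] = gx
        B[1, 3 * i + 1] = gy
        B[2, 3 * i + 2] = gz
        B[3, 3 * i] = gy
        B[3, 3 * i + 1] = gx
        B[4, 3 * i + 1] = gz
        B[4, 3 * i + 2] = gy
        B[5, 3 * i] = gz
        B[5, 3 * i + 2] = gx
    return vol * B.T @ D @ B


def dense_assemble(
    nodes: np.ndarray, elements: np.ndarray, E_nu: list[tuple[float, float]]
) -> np.ndarray:
    n = 3 * len(nodes)
    K = np.zeros((n, n))
    for e, tet in enumerate(elements):
        Ke = dense_element_stiffness(nodes[tet], *E_nu[e])
        dof = np.repeat(3 * tet, 3) + np.tile(np.arange(3), 4)
        K[np.ix_(dof, dof)] += Ke
    return K


def dense_solve(
    nodes: np.ndarray,
    elements: np.ndarray,
    E_nu: list[tuple[float, float]],
    fixed_nodes: np.ndarray,
    forces: np.ndarray,
) -> np.ndarray:
    """Dense LAPACK solve with zero Dirichlet nodes; returns (n, 3) u."""
    K = dense_assemble(nodes, elements, E_nu)
    n = 3 * len(nodes)
    fixed_dofs = np.repeat(3 * np.asarray(fixed_nodes), 3) + np.tile(
        np.arange(3), len(fixed_nodes)
    )
    free = np.setdiff1d(np.arange(n), fixed_dofs)
    f = np.asarray(forces, dtype=float).ravel()
    u = np.zeros(n)
    u[free] = np.linalg.solve(K[np.ix_(free, free)], f[free])
    return u.reshape(-1, 3)


def flood_fill_components(mask: np.ndarray) -> int:
    """Count 26-connected foreground components by breadth-first search."""
    mask = np.asarray(mask, dtype=bool)
    seen = np.zeros_like(mask)
    offsets = [
        (i, j, k)
        for i in (-1, 0, 1)
        for j in (-1, 0, 1)
        for k in (-1, 0, 1)
        if (i, j, k) != (0, 0, 0)
    ]
    count = 0
    for start in zip(*np.nonzero(mask & ~seen)):
        if seen[start]:
            continue
        count += 1
        q = deque([start])
        seen[start] = True
        while q:
            x, y, z = q.popleft()
            for dx, dy, dz in offsets:
                p = (x + dx, y + dy, z + dz)
                if all(0 <= p[a] < mask.shape[a] for a in range(3)):
                    if mask[p] and not seen[p]:
                        seen[p] = True
                        q.append(p)
    return count
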