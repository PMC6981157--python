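"""Independent brute-force FE oracle for the test suite.

Assembles the global stiffness matrix explicitly (own element-matrix code,
3x3x3 Gauss quadrature, different loop structure from the package) and
solves the constrained system by dense elimination.
"""

import numpy as np

_CORNERS = [
    (0, 0, 0), (1, 0, 0), (0, 1, 0), (1, 1, 0),
    (0, 0, 1), (1, 0, 1), (0, 1, 1), (1, 1, 1),
]


def _dmatrix(e, nu):
    lam = e * nu / ((1 + nu) * (1 - 2 * nu))
    mu = e / (2 * (1 + nu))
    d = np.zeros((6, 6))
    d[:3, :3] = lam
    d[0, 0] = d[1, 1] = d[2, 2] = lam + 2 * mu
    d[3, 3] = d[4, 4] = d[5, 5] = mu
    return d


def _shape_gradients(xi, eta, zeta, h):
    grads = np.zeros((8, 3))
    for a, (cx, cy, cz) in enumerate(_CORNERS):
        sx, sy, sz = 2 * cx - 1, 2 * cy - 1, 2 * cz - 1
        grads[a] = [
            sx * (1 + sy * eta) * (1 + sz * zeta) / 8,
            sy * (1 + sx * xi) * (1 + sz * zeta) / 8,
            sz * (1 + sx * xi) * (1 + sy * eta) / 8,
        ]
    return grads * (2.0 / h)


def element_stiffness(e, nu, h):
    """24x24 element stiffness via 3-point Gauss quadrature per axis."""
    pts = np.array([-np.sqrt(3.0 / 5.0), 0.0, np.sqrt(3.0 / 5.0)])
    wts = np.array([5.0, 8.0, 5.0]) / 9.0
    d = _dmatrix(e, nu)
    ke = np.zeros((24, 24))
    for p, wp in zip(pts, wts):
        for q, wq in zip(pts, wts):
            for r, wr in zip(pts, wts):
                g = _shape_gradients(p, q, r, h)
                b = np.zeros((6, 24))
                for a in range(8):
                    gx, gy, gz = g[a]
                    b[0, 3 * a] = gx
                    b[1, 3 * a + 1] = gy
                    b[2, 3 * a + 2] = gz
                    b[3, 3 * a] = gy
                    b[3, 3 * a + 1] = gx
                    b[4, 3 * a + 1] = gz
                    b[4, 3 * a + 2] = gy
                    b[5, 3 * a] = gz
                    b[5, 3 * a + 2] = gx
                ke += wp * wq * wr * (b.T @ d @ b) * (h / 2.0) ** 3
    return ke


def assemble_dense(youngs, nu, h):
    """Dense global stiffness for an (nx, ny, nz) element grid."""
    nx, ny, nz = youngs.shape
    n_nodes = (nx + 1) * (ny + 1) * (nz + 1)
    k_glob = np.zeros((3 * n_nodes, 3 * n_nodes))
    ke_unit = element_stiffness(1.0, nu, h)
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                nodes = [
                    ((i + c[0]) * (ny + 1) + (j + c[1])) * (nz + 1) + (k + c[2])
                    for c in _CORNERS
                ]
                dofs = np.array([3 * n + ax for n in nodes for ax in range(3)])
                k_glob[np.ix_(dofs, dofs)] += youngs[i, j, k] * ke_unit
    return k_glob


def dense_solve(youngs, nu, h, fixed_dofs, fixed_values, force=None):
    """Displacement solution by dense elimination of the constrained system."""
    k_glob = assemble_dense(youngs, nu, h)
    ndof = k_glob.shape[0]
    u = np.zeros(ndof)
    u[fixed_dofs] = fixed_values
    f = np.zeros(ndof) if force is None else force.copy()
    free = np.ones(ndof, bool)
    free[fixed_dofs] = False
    rhs = f[free] - k_glob[np.ix_(free, ~free)] @ u[~free]
    u[free] = np.linalg.solve(k_glob[np.ix_(free, free)], rhs)
    return u
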