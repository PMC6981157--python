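"""Low-level element loops for the voxel FE solver.

Numba-compiled when available; a vectorised numpy fallback keeps the solver
functional (slower) without it.  All kernels operate on a structured grid of
identical 8-node hexahedra: ``emod`` holds one Young's modulus per element in
C order over the element grid ``(nx, ny, nz)``; displacement vectors are flat
arrays of length ``3 * (nx+1) * (ny+1) * (nz+1)`` with node id
``(i*(ny+1) + j)*(nz+1) + k`` and dof ``3*node + axis``.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a declared dependency
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return wrap

# Corner order shared with the element matrices in microfe.
CORNERS = np.array(
    [
        (0, 0, 0),
        (1, 0, 0),
        (0, 1, 0),
        (1, 1, 0),
        (0, 0, 1),
        (1, 0, 1),
        (0, 1, 1),
        (1, 1, 1),
    ],
    dtype=np.int64,
)


def corner_node_offsets(ny: int, nz: int) -> np.ndarray:
    """Node-id offsets of the 8 element corners relative to the base node."""
    return (CORNERS[:, 0] * (ny + 1) + CORNERS[:, 1]) * (nz + 1) + CORNERS[:, 2]


@njit(cache=True)
def _matvec_numba(emod, x, y, nx, ny, nz, coff, ke):  # pragma: no cover - jitted
    y[:] = 0.0
    ue = np.empty(24)
    ve = np.empty(24)
    e = 0
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                base = (i * (ny + 1) + j) * (nz + 1) + k
                for c in range(8):
                    d = 3 * (base + coff[c])
                    ue[3 * c] = x[d]
                    ue[3 * c + 1] = x[d + 1]
                    ue[3 * c + 2] = x[d + 2]
                E = emod[e]
                for a in range(24):
                    s = 0.0
                    for b in range(24):
                        s += ke[a, b] * ue[b]
                    ve[a] = E * s
                for c in range(8):
                    d = 3 * (base + coff[c])
                    y[d] += ve[3 * c]
                    y[d + 1] += ve[3 * c + 1]
                    y[d + 2] += ve[3 * c + 2]
                e += 1
    return y


@njit(cache=True)
def _diag_numba(emod, diag, nx, ny, nz, coff, kediag):  # pragma: no cover - jitted
    diag[:] = 0.0
    e = 0
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                base = (i * (ny + 1) + j) * (nz + 1) + k
                E = emod[e]
                for c in range(8):
                    d = 3 * (base + coff[c])
                    diag[d] += E * kediag[3 * c]
                    diag[d + 1] += E * kediag[3 * c + 1]
                    diag[d + 2] += E * kediag[3 * c + 2]
                e += 1
    return diag


@njit(cache=True)
def _strain_numba(emod, u, bc, d0, nx, ny, nz, coff, eps_out, sed_out):  # pragma: no cover
    ue = np.empty(24)
    eps = np.empty(6)
    sig = np.empty(6)
    e = 0
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                base = (i * (ny + 1) + j) * (nz + 1) + k
                for c in range(8):
                    d = 3 * (base + coff[c])
                    ue[3 * c] = u[d]
                    ue[3 * c + 1] = u[d + 1]
                    ue[3 * c + 2] = u[d + 2]
                for a in range(6):
                    s = 0.0
                    for b in range(24):
                        s += bc[a, b] * ue[b]
                    eps[a] = s
                    eps_out[e, a] = s
                w = 0.0
                for a in range(6):
                    s = 0.0
                    for b in range(6):
                        s += d0[a, b] * eps[b]
                    sig[a] = s
                    w += s * eps[a]
                sed_out[e] = 0.5 * emod[e] * w
                e += 1


def _element_dof_table(nx: int, ny: int, nz: int) -> np.ndarray:
    """(nelem, 24) dof indices; used by the numpy fallback paths."""
    ii, jj, kk = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    base = ((ii * (ny + 1) + jj) * (nz + 1) + kk).ravel()
    coff = corner_node_offsets(ny, nz)
    nodes = base[:, None] + coff[None, :]
    dofs = (3 * nodes[:, :, None] + np.arange(3)[None, None, :]).reshape(-1, 24)
    return dofs


def _matvec_numpy(emod, x, y, nx, ny, nz, dofs, ke):
    ue = x[dofs]
    ve = (ue @ ke.T) * emod[:, None]
    y[:] = np.bincount(dofs.ravel(), weights=ve.ravel(), minlength=x.size)
    return y


def _diag_numpy(emod, diag, nx, ny, nz, dofs, kediag):
    ve = np.broadcast_to(kediag, (emod.size, 24)) * emod[:, None]
    diag[:] = np.bincount(dofs.ravel(), weights=ve.ravel(), minlength=diag.size)
    return diag


def _strain_numpy(emod, u, bc, d0, nx, ny, nz, dofs, eps_out, sed_out):
    ue = u[dofs]
    eps = ue @ bc.T
    eps_out[:] = eps
    sed_out[:] = 0.5 * emod * np.einsum("ea,ab,eb->e", eps, d0, eps)


class GridKernels:
    """Dispatch wrapper binding a fixed element grid to the fast kernels."""

    def __init__(self, nx: int, ny: int, nz: int):
        self.nx, self.ny, self.nz = nx, ny, nz
        self.ndof = 3 * (nx + 1) * (ny + 1) * (nz + 1)
        self.coff = corner_node_offsets(ny, nz)
        self._dofs = None if HAVE_NUMBA else _element_dof_table(nx, ny, nz)

    def matvec(self, emod: np.ndarray, x: np.ndarray, ke: np.ndarray, out=None) -> np.ndarray:
        y = np.empty(self.ndof) if out is None else out
        if HAVE_NUMBA:
            return _matvec_numba(emod, x, y, self.nx, self.ny, self.nz, self.coff, ke)
        return _matvec_numpy(emod, x, y, self.nx, self.ny, self.nz, self._dofs, ke)

    def diagonal(self, emod: np.ndarray, kediag: np.ndarray) -> np.ndarray:
        diag = np.empty(self.ndof)
        if HAVE_NUMBA:
            return _diag_numba(emod, diag, self.nx, self.ny, self.nz, self.coff, kediag)
        return _diag_numpy(emod, diag, self.nx, self.ny, self.nz, self._dofs, kediag)

    def strains(self, emod: np.ndarray, u: np.ndarray, bc: np.ndarray, d0: np.ndarray):
        nelem = self.nx * self.ny * self.nz
        eps = np.empty((nelem, 6))
        sed = np.empty(nelem)
        if HAVE_NUMBA:
            _strain_numba(emod, u, bc, d0, self.nx, self.ny, self.nz, self.coff, eps, sed)
        else:
            _strain_numpy(emod, u, bc, d0, self.nx, self.ny, self.nz, self._dofs, eps, sed)
        return eps, sed
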