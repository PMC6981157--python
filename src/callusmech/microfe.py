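"""Structured-grid voxel finite-element solver for linear elasticity.

Every image voxel becomes one 8-node trilinear hexahedral element; all
elements are geometrically identical, so a single reference stiffness matrix
(unit Young's modulus) is scaled per element.  The system is solved
matrix-free with Jacobi-preconditioned conjugate gradients.

Outputs per element (at the centroid): strain-energy density U (MPa) and the
scalar effective strain ``eps_eff = sqrt(2 U / E)``, which under
displacement-controlled boundary conditions is independent of a uniform
scaling of all moduli.

Units: lengths mm, moduli/stress MPa, forces N, densities mg HA/cm^3.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._fe_kernels import CORNERS, GridKernels
from .imageproc import DensityImage, ThresholdLadder

__all__ = [
    "MaterialMap",
    "BCSpec",
    "StrainField",
    "VoxelFEModel",
    "FENonConvergence",
    "density_to_modulus",
    "solve",
    "axial_stiffness",
    "coarsen_material",
    "SOFT_TISSUE_MODULUS",
    "E_AT_LOWEST",
    "E_AT_HIGHEST",
]

# Density -> modulus anchor points of the linear law, plus the soft-tissue
# background stiffness (MPa).
SOFT_TISSUE_MODULUS = 3.0
E_AT_LOWEST = 4000.0
E_AT_HIGHEST = 14000.0


class FENonConvergence(RuntimeError):
    """CG failed to reach tolerance; carries the residual history."""

    def __init__(self, message: str, residuals: np.ndarray):
        super().__init__(message)
        self.residuals = residuals


def _elastic_matrix(nu: float) -> np.ndarray:
    """6x6 isotropic stiffness for unit Young's modulus (engineering shear)."""
    c = 1.0 / ((1.0 + nu) * (1.0 - 2.0 * nu))
    d = np.zeros((6, 6))
    d[:3, :3] = nu * c
    np.fill_diagonal(d[:3, :3], (1.0 - nu) * c)
    d[3, 3] = d[4, 4] = d[5, 5] = (1.0 - 2.0 * nu) / 2.0 * c
    return d


def _bmatrix(xi: np.ndarray, h: float) -> np.ndarray:
    """Strain-displacement matrix (6x24) at natural coordinates ``xi``."""
    signs = 2.0 * CORNERS - 1.0
    dn = np.empty((8, 3))
    for a in range(8):
        sx, sy, sz = signs[a]
        dn[a, 0] = sx * (1 + sy * xi[1]) * (1 + sz * xi[2]) / 8.0
        dn[a, 1] = sy * (1 + sx * xi[0]) * (1 + sz * xi[2]) / 8.0
        dn[a, 2] = sz * (1 + sx * xi[0]) * (1 + sy * xi[1]) / 8.0
    dn *= 2.0 / h  # d(xi)/dx for a cube of edge h
    b = np.zeros((6, 24))
    for a in range(8):
        c = 3 * a
        b[0, c] = dn[a, 0]
        b[1, c + 1] = dn[a, 1]
        b[2, c + 2] = dn[a, 2]
        b[3, c] = dn[a, 1]
        b[3, c + 1] = dn[a, 0]
        b[4, c + 1] = dn[a, 2]
        b[4, c + 2] = dn[a, 1]
        b[5, c] = dn[a, 2]
        b[5, c + 2] = dn[a, 0]
    return b


def hex_stiffness(nu: float, h: float) -> np.ndarray:
    """Reference 24x24 element stiffness (unit E), 2x2x2 Gauss quadrature."""
    d = _elastic_matrix(nu)
    g = 1.0 / np.sqrt(3.0)
    ke = np.zeros((24, 24))
    for gx in (-g, g):
        for gy in (-g, g):
            for gz in (-g, g):
                b = _bmatrix(np.array([gx, gy, gz]), h)
                ke += b.T @ d @ b * (h / 2.0) ** 3
    return ke


def density_to_modulus(
    density: np.ndarray | float,
    ladder: ThresholdLadder | None = None,
    mode: str = "banded",
    soft_modulus: float = SOFT_TISSUE_MODULUS,
) -> np.ndarray:
    """Map mineral density (mg HA/cm^3) to Young's modulus (MPa).

    Densities below the lowest ladder threshold are soft tissue
    (``soft_modulus``).  In ``banded`` mode the element takes the modulus of
    the highest ladder threshold it reaches; the band value is mapped
    linearly between 4000 MPa at the lowest rung and 14000 MPa at the
    highest.  ``continuous`` mode applies the linear law to the raw density
    (clamped to the ladder range).
    """
    ladder = ladder or ThresholdLadder()
    rho = np.asarray(density, dtype=float)
    lo, hi = ladder.lowest, ladder.highest
    if mode == "banded":
        taus = np.asarray(ladder.thresholds)
        band_idx = np.searchsorted(taus, rho, side="right") - 1
        band = taus[np.clip(band_idx, 0, len(taus) - 1)]
        level = band
    elif mode == "continuous":
        level = np.clip(rho, lo, hi)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    e = E_AT_LOWEST + (E_AT_HIGHEST - E_AT_LOWEST) * (level - lo) / (hi - lo)
    e = np.where(rho < lo, soft_modulus, e)
    return e if e.ndim else float(e)


@dataclass
class MaterialMap:
    """Per-element Young's modulus field on the voxel grid."""

    youngs: np.ndarray  # MPa, shape (nx, ny, nz)
    nu: float = 0.3
    voxel_size: float = 10.5  # micrometres

    def __post_init__(self) -> None:
        self.youngs = np.asarray(self.youngs, dtype=np.float64)
        if self.youngs.ndim != 3:
            raise ValueError(f"expected 3D modulus field, got shape {self.youngs.shape}")
        if not (0.0 < self.nu < 0.5):
            raise ValueError(f"Poisson ratio must lie in (0, 0.5), got {self.nu}")
        if np.any(self.youngs < SOFT_TISSUE_MODULUS):
            raise ValueError(f"moduli below the soft-tissue floor ({SOFT_TISSUE_MODULUS} MPa)")

    @classmethod
    def from_image(
        cls,
        image: DensityImage,
        ladder: ThresholdLadder | None = None,
        nu: float = 0.3,
        mode: str = "banded",
        soft_modulus: float = SOFT_TISSUE_MODULUS,
    ) -> "MaterialMap":
        e = density_to_modulus(image.values, ladder, mode=mode, soft_modulus=soft_modulus)
        return cls(e, nu=nu, voxel_size=image.voxel_size)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.youngs.shape  # type: ignore[return-value]

    @property
    def h_mm(self) -> float:
        return self.voxel_size / 1000.0


def coarsen_material(material: MaterialMap, factor: int) -> MaterialMap:
    """Block-average the modulus field over ``factor``-cubed blocks.

    Used to keep large simulation grids solvable at desk scale; every grid
    dimension must be divisible by ``factor``.
    """
    if factor == 1:
        return material
    nx, ny, nz = material.shape
    if any(n % factor for n in (nx, ny, nz)):
        raise ValueError(f"grid {material.shape} not divisible by coarsening factor {factor}")
    e = material.youngs.reshape(nx // factor, factor, ny // factor, factor, nz // factor, factor)
    e = e.mean(axis=(1, 3, 5))
    return MaterialMap(e, nu=material.nu, voxel_size=material.voxel_size * factor)


@dataclass
class BCSpec:
    """Boundary conditions: prescribed dof values and optional nodal forces.

    ``fixed_dofs``/``fixed_values`` list constrained global dof indices;
    ``force`` is a dense load vector over all dofs (or None).  Use the
    classmethod builders for the standard cases.
    """

    grid_shape: tuple[int, int, int]  # element grid
    fixed_dofs: np.ndarray
    fixed_values: np.ndarray
    force: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.fixed_dofs = np.asarray(self.fixed_dofs, dtype=np.int64)
        self.fixed_values = np.asarray(self.fixed_values, dtype=np.float64)
        if self.fixed_dofs.shape != self.fixed_values.shape:
            raise ValueError("fixed_dofs and fixed_values must have the same length")
        if not np.all(np.isfinite(self.fixed_values)):
            raise ValueError("prescribed displacements must be finite")
        if self.fixed_dofs.size == 0:
            raise ValueError("at least some dofs must be constrained (rigid-body motion)")

    @staticmethod
    def _node_grid(shape):
        nx, ny, nz = shape
        return nx + 1, ny + 1, nz + 1

    @staticmethod
    def _node_id(shape, i, j, k):
        nx, ny, nz = shape
        return (i * (ny + 1) + j) * (nz + 1) + k

    @classmethod
    def affine(cls, shape: tuple[int, int, int], h_mm: float, strain: np.ndarray) -> "BCSpec":
        """Prescribe ``u = strain @ x`` on all boundary nodes (patch-test BC)."""
        strain = np.asarray(strain, dtype=float)
        mx, my, mz = cls._node_grid(shape)
        ii, jj, kk = np.meshgrid(np.arange(mx), np.arange(my), np.arange(mz), indexing="ij")
        boundary = (
            (ii == 0) | (ii == mx - 1) | (jj == 0) | (jj == my - 1) | (kk == 0) | (kk == mz - 1)
        )
        coords = np.stack([ii[boundary], jj[boundary], kk[boundary]], axis=1) * h_mm
        nodes = ((ii[boundary] * my) + jj[boundary]) * mz + kk[boundary]
        disp = coords @ strain.T
        dofs = (3 * nodes[:, None] + np.arange(3)[None, :]).ravel()
        vals = disp.ravel()
        return cls(tuple(shape), dofs, vals, meta={"kind": "affine"})

    @classmethod
    def axial_compression(
        cls,
        shape: tuple[int, int, int],
        h_mm: float,
        total_displacement: float,
        region: np.ndarray | None = None,
    ) -> "BCSpec":
        """Equal-and-opposite axial (z) face displacements closing by ``total_displacement``.

        Only the z-component is prescribed on face nodes adjacent to
        ``region`` elements (default: all); transverse image faces are
        traction-free.  Lateral rigid-body modes are suppressed by point
        pins on the bottom face (zero-force in symmetric problems).
        """
        nx, ny, nz = shape
        if region is None:
            region = np.ones(shape, dtype=bool)
        dofs: list[int] = []
        vals: list[float] = []
        pins_meta = []
        for face_k, uz in ((0, +total_displacement / 2.0), (nz, -total_displacement / 2.0)):
            ksl = 0 if face_k == 0 else nz - 1
            elem_face = region[:, :, ksl]
            node_mask = np.zeros((nx + 1, ny + 1), dtype=bool)
            node_mask[:-1, :-1] |= elem_face
            node_mask[1:, :-1] |= elem_face
            node_mask[:-1, 1:] |= elem_face
            node_mask[1:, 1:] |= elem_face
            iis, jjs = np.nonzero(node_mask)
            nodes = cls._node_id(shape, iis, jjs, face_k)
            dofs.extend((3 * nodes + 2).tolist())
            vals.extend([uz] * nodes.size)
            if face_k == 0 and nodes.size:
                # pin lateral translations at the first node and the in-plane
                # rotation at the farthest node sharing its j index
                a = 0
                dofs.extend([int(3 * nodes[a]), int(3 * nodes[a] + 1)])
                vals.extend([0.0, 0.0])
                same_j = np.nonzero(jjs == jjs[a])[0]
                b = same_j[np.argmax(np.abs(iis[same_j] - iis[a]))]
                if b != a:
                    dofs.append(int(3 * nodes[b] + 1))
                    vals.append(0.0)
                pins_meta = [int(nodes[a]), int(nodes[b])]
        return cls(
            tuple(shape),
            np.array(dofs),
            np.array(vals),
            meta={"kind": "axial_compression", "total_displacement": total_displacement,
                  "pins": pins_meta},
        )

    @classmethod
    def face_load(
        cls,
        shape: tuple[int, int, int],
        h_mm: float,
        axial_force: float = 0.0,
        bending_moment: float = 0.0,
        bending_axis: int = 0,
        region: np.ndarray | None = None,
    ) -> "BCSpec":
        """Force-controlled case: bottom face held (uz=0), loads on the top face.

        ``axial_force`` (N, negative = compression) is distributed over the
        top-face nodes of ``region`` elements with tributary-area weights.
        ``bending_moment`` (N mm) about the in-plane axis ``bending_axis``
        (0 = x, 1 = y) through the section centroid is applied as a linear
        axial-force distribution.
        """
        nx, ny, nz = shape
        mx, my, mz = cls._node_grid(shape)
        if region is None:
            region = np.ones(shape, dtype=bool)

        def face_nodes_weights(ksl):
            elem_face = region[:, :, ksl]
            w = np.zeros((mx, my))
            w[:-1, :-1] += elem_face
            w[1:, :-1] += elem_face
            w[:-1, 1:] += elem_face
            w[1:, 1:] += elem_face
            iis, jjs = np.nonzero(w)
            return iis, jjs, w[iis, jjs] / 4.0

        # bottom: hold uz, pin lateral rigid modes
        iis, jjs, _ = face_nodes_weights(0)
        nodes0 = cls._node_id(shape, iis, jjs, 0)
        dofs = (3 * nodes0 + 2).tolist()
        vals = [0.0] * nodes0.size
        dofs.extend([int(3 * nodes0[0]), int(3 * nodes0[0] + 1)])
        vals.extend([0.0, 0.0])
        same_j = np.nonzero(jjs == jjs[0])[0]
        b = same_j[np.argmax(np.abs(iis[same_j] - iis[0]))]
        if b != 0:
            dofs.append(int(3 * nodes0[b] + 1))
            vals.append(0.0)

        # top: nodal forces
        iis, jjs, w = face_nodes_weights(nz - 1)
        nodes1 = cls._node_id(shape, iis, jjs, nz)
        force = np.zeros(3 * mx * my * mz)
        if axial_force != 0.0:
            force[3 * nodes1 + 2] += axial_force * w / w.sum()
        if bending_moment != 0.0:
            coord = (iis if bending_axis == 1 else jjs) * h_mm
            cbar = np.sum(w * coord) / w.sum()
            lever = coord - cbar
            denom = np.sum(w * lever**2)
            if denom == 0:
                raise ValueError("degenerate section: cannot apply a bending moment")
            sign = 1.0 if bending_axis == 0 else -1.0
            force[3 * nodes1 + 2] += sign * bending_moment * w * lever / denom
        return cls(
            tuple(shape),
            np.array(dofs),
            np.array(vals),
            force=force,
            meta={
                "kind": "face_load",
                "axial_force": axial_force,
                "bending_moment": bending_moment,
                "bending_axis": bending_axis,
            },
        )


@dataclass
class StrainField:
    """Per-element strain measures from one FE solve."""

    eff_strain: np.ndarray  # (nx, ny, nz), dimensionless
    sed: np.ndarray  # (nx, ny, nz), MPa
    displacement: np.ndarray  # (n_nodes, 3), mm
    residual: float
    n_iter: int
    strain_voigt: np.ndarray | None = None  # (nx, ny, nz, 6), engineering shear
    reaction_dofs: np.ndarray | None = None
    reaction_values: np.ndarray | None = None

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.eff_strain.shape  # type: ignore[return-value]

    def face_reaction_z(self, face: str) -> float:
        """Total z-reaction on an axial face ('bottom' = k=0, 'top' = k=nz)."""
        if self.reaction_dofs is None:
            raise ValueError("solve did not record reactions")
        nx, ny, nz = self.shape
        mz = nz + 1
        node = self.reaction_dofs // 3
        axis = self.reaction_dofs % 3
        kk = node % mz
        sel = (axis == 2) & (kk == (0 if face == "bottom" else nz))
        return float(self.reaction_values[sel].sum())


class VoxelFEModel:
    """Matrix-free voxel FE model bound to one material map."""

    def __init__(self, material: MaterialMap):
        self.material = material
        nx, ny, nz = material.shape
        self.kernels = GridKernels(nx, ny, nz)
        self.h = material.h_mm
        self.ke = hex_stiffness(material.nu, self.h)
        self.d0 = _elastic_matrix(material.nu)
        self.bc_centroid = _bmatrix(np.zeros(3), self.h)
        self._emod = np.ascontiguousarray(material.youngs.ravel())
        self.ndof = self.kernels.ndof

    def matvec(self, x: np.ndarray) -> np.ndarray:
        return self.kernels.matvec(self._emod, x, self.ke)

    def diagonal(self) -> np.ndarray:
        return self.kernels.diagonal(self._emod, np.ascontiguousarray(np.diag(self.ke)))

    def solve(
        self,
        bc: BCSpec,
        tol: float = 1e-8,
        maxiter: int | None = None,
        x0: np.ndarray | None = None,
        store_tensors: bool = False,
    ) -> StrainField:
        """Jacobi-preconditioned CG to relative residual ``tol``."""
        if tuple(bc.grid_shape) != tuple(self.material.shape):
            raise ValueError(f"BC grid {bc.grid_shape} does not match material {self.material.shape}")
        ndof = self.ndof
        free = np.ones(ndof, dtype=bool)
        free[bc.fixed_dofs] = False

        u0 = np.zeros(ndof)
        u0[bc.fixed_dofs] = bc.fixed_values
        b = -self.matvec(u0)
        if bc.force is not None:
            b = b + bc.force
        b[~free] = 0.0

        diag = self.diagonal()
        minv = np.where(free, 1.0 / diag, 0.0)

        x = np.zeros(ndof)
        if x0 is not None:
            x[free] = x0[free]
        r = b - self._apply_free(x, free)
        r[~free] = 0.0
        bnorm = np.linalg.norm(b)
        residuals = []
        if bnorm == 0.0:
            w = x * 0.0
            n_iter = 0
            rel = 0.0
        else:
            z = minv * r
            p = z.copy()
            rz = float(r @ z)
            if maxiter is None:
                maxiter = max(2000, 30 * int(round(ndof ** (1 / 3))) * 10)
            n_iter = 0
            rel = np.linalg.norm(r) / bnorm
            residuals.append(rel)
            while rel > tol and n_iter < maxiter:
                q = self._apply_free(p, free)
                alpha = rz / float(p @ q)
                x += alpha * p
                r -= alpha * q
                rel = np.linalg.norm(r) / bnorm
                residuals.append(rel)
                z = minv * r
                rz_new = float(r @ z)
                p = z + (rz_new / rz) * p
                rz = rz_new
                n_iter += 1
            if rel > tol:
                raise FENonConvergence(
                    f"CG did not reach tol={tol:g} in {maxiter} iterations (residual {rel:.3e})",
                    np.array(residuals),
                )
            w = x
        u = u0 + w

        eps, sed = self.kernels.strains(self._emod, u, self.bc_centroid, self.d0)
        nx, ny, nz = self.material.shape
        sed3 = sed.reshape(nx, ny, nz)
        eff = np.sqrt(np.maximum(2.0 * sed3 / self.material.youngs, 0.0))

        ku = self.matvec(u)
        f = bc.force if bc.force is not None else 0.0
        reaction = ku - f

        return StrainField(
            eff_strain=eff,
            sed=sed3,
            displacement=u.reshape(-1, 3),
            residual=float(rel),
            n_iter=n_iter,
            strain_voigt=eps.reshape(nx, ny, nz, 6) if store_tensors else None,
            reaction_dofs=bc.fixed_dofs.copy(),
            reaction_values=np.asarray(reaction)[bc.fixed_dofs],
        )

    def _apply_free(self, x: np.ndarray, free: np.ndarray) -> np.ndarray:
        xm = np.where(free, x, 0.0)
        y = self.kernels.matvec(self._emod, xm, self.ke)
        y[~free] = 0.0
        return y


def solve(
    material: MaterialMap,
    bc: BCSpec,
    tol: float = 1e-8,
    maxiter: int | None = None,
    x0: np.ndarray | None = None,
    store_tensors: bool = False,
) -> StrainField:
    """One-shot convenience wrapper around :class:`VoxelFEModel`."""
    return VoxelFEModel(material).solve(
        bc, tol=tol, maxiter=maxiter, x0=x0, store_tensors=store_tensors
    )


def axial_stiffness(
    material: MaterialMap,
    region: np.ndarray | None = None,
    strain: float = 0.01,
    tol: float = 1e-8,
) -> float:
    """Axial stiffness k (N/mm) from a prescribed-compression probe.

    A compressive displacement of ``strain`` times the axial length is
    applied across the region (default 1%, split equally between the two
    axial faces, transverse faces free); k is the reaction force on the
    displaced face divided by the applied displacement.
    """
    nx, ny, nz = material.shape
    if region is not None and not (region[:, :, 0].any() and region[:, :, -1].any()):
        raise ValueError("region must span the axial extent of the grid")
    length = nz * material.h_mm
    delta = strain * length
    bc = BCSpec.axial_compression(material.shape, material.h_mm, delta, region=region)
    field = VoxelFEModel(material).solve(bc, tol=tol)
    # reaction on the bottom face opposes its +delta/2 motion
    f = field.face_reaction_z("bottom")
    return float(abs(f) / delta)
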