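"""Voxel finite-element solver for the quasi-static current-flow problem.

The conduction domain is the set of non-air voxels; each voxel is a
trilinear hexahedral element with its own conductivity. The assembled
stiffness matrix is the pure-Neumann Laplace operator (symmetric positive
semi-definite, nullspace = constants). Balanced nodal current loads are
solved with preconditioned conjugate gradients on the complement of the
nullspace and the potential is reported in a zero-mean gauge.

Unit chain (locked by tests): conductivity [S/cm], grid spacing [mm],
currents [mA] -> potentials [mV] -> current density reported in uA/cm^2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.sparse import coo_matrix, csr_matrix
from scipy.sparse.linalg import LinearOperator, cg

from .montage import Montage
from .resistivity import ConductivityVolume

S_PER_CM_TO_S_PER_MM = 0.1
MA_PER_MM2_TO_UA_PER_CM2 = 1.0e5

# corner offsets of a hexahedral element, x fastest
CORNER_OFFSETS = np.array([(0, 0, 0), (1, 0, 0), (0, 1, 0), (1, 1, 0),
                           (0, 0, 1), (1, 0, 1), (0, 1, 1), (1, 1, 1)])


def _reference_stiffness() -> np.ndarray:
    """8x8 stiffness of the unit trilinear hexahedron with unit conductivity.

    K[a, b] = int_{[0,1]^3} grad(N_a) . grad(N_b) dV via 2x2x2 Gauss
    quadrature (exact for this quadratic-per-axis integrand).
    """
    gp = np.array([0.5 - 0.5 / np.sqrt(3.0), 0.5 + 0.5 / np.sqrt(3.0)])
    K = np.zeros((8, 8))
    for gx in gp:
        for gy in gp:
            for gz in gp:
                grads = np.empty((8, 3))
                for a, (dx, dy, dz) in enumerate(CORNER_OFFSETS):
                    fx = gx if dx else 1.0 - gx
                    fy = gy if dy else 1.0 - gy
                    fz = gz if dz else 1.0 - gz
                    sx = 1.0 if dx else -1.0
                    sy = 1.0 if dy else -1.0
                    sz = 1.0 if dz else -1.0
                    grads[a] = (sx * fy * fz, fx * sy * fz, fx * fy * sz)
                K += 0.125 * grads @ grads.T
    return K


REFERENCE_STIFFNESS = _reference_stiffness()


class SolverError(RuntimeError):
    pass


@dataclass(frozen=True)
class FEMSystem:
    """Assembled pure-Neumann system on the conduction domain."""

    stiffness: csr_matrix          # [S], symmetric PSD
    node_id: np.ndarray            # (nx+1, ny+1, nz+1) int32, -1 = unused
    element_nodes: np.ndarray      # (n_elements, 8) global node ids
    conduction_mask: np.ndarray    # (nx, ny, nz) bool
    sigma: ConductivityVolume

    @property
    def n_nodes(self) -> int:
        return self.stiffness.shape[0]

    @property
    def voxel_size_mm(self) -> float:
        return self.sigma.voxel_size_mm


@dataclass(frozen=True)
class PotentialField:
    """Per-node electric potential in mV, zero-mean gauge."""

    phi: np.ndarray
    system: FEMSystem
    iterations: int
    relative_residual: float

    def node_grid(self) -> np.ndarray:
        """Potential scattered onto the (nx+1, ny+1, nz+1) node lattice."""
        grid = np.zeros(self.system.node_id.shape)
        used = self.system.node_id >= 0
        grid[used] = self.phi[self.system.node_id[used]]
        return grid


@dataclass(frozen=True)
class CurrentDensityField:
    """Per-voxel current density; vector and magnitude in uA/cm^2."""

    J_vector: np.ndarray     # (nx, ny, nz, 3)
    J_magnitude: np.ndarray  # (nx, ny, nz)
    voxel_size_mm: float


def assemble(sigma: ConductivityVolume) -> FEMSystem:
    """Assemble the global stiffness matrix from per-voxel conductivities."""
    conduction = ~sigma.air_mask
    if np.any(sigma.sigma[conduction] <= 0):
        raise ValueError("conductivity must be positive on the domain")

    n_comp, comp = _connected_components(conduction)
    if n_comp != 1:
        sizes = np.bincount(comp[conduction])
        raise SolverError(
            f"conduction domain has {n_comp} disconnected components "
            f"(voxel counts {sorted(sizes[1:], reverse=True)})")

    nx, ny, nz = conduction.shape
    h = sigma.voxel_size_mm
    vox = np.argwhere(conduction)

    node_shape = (nx + 1, ny + 1, nz + 1)
    corner = vox[:, None, :] + CORNER_OFFSETS[None, :, :]  # (ne, 8, 3)
    corner_flat = np.ravel_multi_index(
        (corner[..., 0], corner[..., 1], corner[..., 2]), node_shape)

    node_id = -np.ones(node_shape, dtype=np.int32).ravel()
    used = np.unique(corner_flat)
    node_id[used] = np.arange(len(used), dtype=np.int32)
    elem_nodes = node_id[corner_flat]
    node_id = node_id.reshape(node_shape)

    sigma_scaled = (sigma.sigma[conduction] * S_PER_CM_TO_S_PER_MM * h)
    rows = np.repeat(elem_nodes, 8, axis=1).ravel()
    cols = np.tile(elem_nodes, (1, 8)).ravel()
    data = (sigma_scaled[:, None] * REFERENCE_STIFFNESS.ravel()[None, :]) \
        .ravel()
    K = coo_matrix((data, (rows, cols)),
                   shape=(len(used), len(used))).tocsr()

    return FEMSystem(stiffness=K, node_id=node_id, element_nodes=elem_nodes,
                     conduction_mask=conduction, sigma=sigma)


def _connected_components(mask: np.ndarray):
    structure = ndimage.generate_binary_structure(3, 1)  # 6-connectivity
    comp, n = ndimage.label(mask, structure=structure)
    return n, comp


def montage_load(system: FEMSystem, montage: Montage) -> np.ndarray:
    """Nodal current vector (mA): each electrode's current split uniformly
    over the distinct corner nodes of its footprint voxels."""
    f = np.zeros(system.n_nodes)
    node_shape = system.node_id.shape
    for e in montage.electrodes:
        vox = np.asarray(e.footprint)
        corner = vox[:, None, :] + CORNER_OFFSETS[None, :, :]
        flat = np.ravel_multi_index(
            (corner[..., 0], corner[..., 1], corner[..., 2]), node_shape)
        ids = np.unique(system.node_id.ravel()[flat])
        if np.any(ids < 0):
            raise SolverError(
                f"electrode {e.site.label} footprint touches non-domain nodes")
        f[ids] += e.current_mA / len(ids)
    return f


def solve_potential(system: FEMSystem, load: np.ndarray,
                    tol: float = 1e-8, max_iter: int = 20000,
                    preconditioner: str = "jacobi") -> PotentialField:
    """CG solve of the balanced pure-Neumann system; zero-mean potential."""
    f = np.asarray(load, dtype=np.float64)
    imbalance = abs(f.sum())
    if imbalance > 1e-9 * max(1.0, np.abs(f).max() * len(f)):
        raise SolverError(f"load vector not balanced: net {imbalance} mA")
    f = f - f.mean()  # project exactly onto the range of the operator

    K = system.stiffness
    if preconditioner == "jacobi":
        inv_diag = 1.0 / K.diagonal()
        M = LinearOperator(K.shape, matvec=lambda r: inv_diag * r)
    elif preconditioner in (None, "none"):
        M = None
    else:
        raise ValueError(f"unknown preconditioner {preconditioner!r}")

    count = {"n": 0}

    def callback(_xk):
        count["n"] += 1

    phi, info = cg(K, f, rtol=tol, atol=0.0, maxiter=max_iter, M=M,
                   callback=callback)
    residual = float(np.linalg.norm(K @ phi - f) / np.linalg.norm(f))
    if info != 0 or residual > 10 * tol:
        raise SolverError(
            f"CG failed to converge: info={info}, iterations={count['n']}, "
            f"relative residual={residual:.3e} (tol {tol:.1e})")
    phi = phi - phi.mean()
    return PotentialField(phi=phi, system=system, iterations=count["n"],
                          relative_residual=residual)


def compute_current_density(potential: PotentialField,
                            sigma: ConductivityVolume | None = None,
                            ) -> CurrentDensityField:
    """J = -sigma * grad(phi) at voxel centers from trilinear gradients."""
    system = potential.system
    if sigma is None:
        sigma = system.sigma
    h = sigma.voxel_size_mm
    P = potential.node_grid()

    c000 = P[:-1, :-1, :-1]
    c100 = P[1:, :-1, :-1]
    c010 = P[:-1, 1:, :-1]
    c110 = P[1:, 1:, :-1]
    c001 = P[:-1, :-1, 1:]
    c101 = P[1:, :-1, 1:]
    c011 = P[:-1, 1:, 1:]
    c111 = P[1:, 1:, 1:]

    gx = ((c100 + c110 + c101 + c111) - (c000 + c010 + c001 + c011)) / (4 * h)
    gy = ((c010 + c110 + c011 + c111) - (c000 + c100 + c001 + c101)) / (4 * h)
    gz = ((c001 + c101 + c011 + c111) - (c000 + c100 + c010 + c110)) / (4 * h)

    sig_mm = sigma.sigma * S_PER_CM_TO_S_PER_MM
    mask = ~sigma.air_mask
    J = np.zeros(sigma.sigma.shape + (3,))
    J[..., 0] = np.where(mask, -sig_mm * gx, 0.0)
    J[..., 1] = np.where(mask, -sig_mm * gy, 0.0)
    J[..., 2] = np.where(mask, -sig_mm * gz, 0.0)
    J *= MA_PER_MM2_TO_UA_PER_CM2
    return CurrentDensityField(J_vector=J,
                               J_magnitude=np.linalg.norm(J, axis=-1),
                               voxel_size_mm=h)


def plane_flux_mA(field: CurrentDensityField, axis: int, index: int) -> float:
    """Total current (mA) through one full transverse voxel plane."""
    sl = [slice(None)] * 3
    sl[axis] = index
    j_axis = field.J_vector[tuple(sl) + (axis,)]
    area_mm2 = field.voxel_size_mm ** 2
    return float(j_axis.sum() * area_mm2 / MA_PER_MM2_TO_UA_PER_CM2)
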