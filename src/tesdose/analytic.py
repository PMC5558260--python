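"""Closed-form reference solutions used to validate the FEM solver.

Two oracles: a uniform conducting slab driven face-to-face (linear
potential, uniform current density I/A), and a homogeneous sphere with two
point current injections on its surface (Legendre-series solution).
"""

from __future__ import annotations

import numpy as np
from scipy.sparse import coo_matrix
from scipy.special import eval_legendre

from .fem import (CORNER_OFFSETS, MA_PER_MM2_TO_UA_PER_CM2,
                  S_PER_CM_TO_S_PER_MM, FEMSystem)
from .resistivity import ConductivityVolume


def uniform_slab_conductivity(shape=(25, 25, 25), sigma_s_cm: float = 0.01,
                              voxel_size_mm: float = 2.0,
                              ) -> ConductivityVolume:
    """A fully conducting uniform box (no air)."""
    return ConductivityVolume(sigma=np.full(shape, sigma_s_cm),
                              air_mask=np.zeros(shape, dtype=bool),
                              voxel_size_mm=voxel_size_mm)


def slab_face_load(system: FEMSystem, current_mA: float = 1.0) -> np.ndarray:
    """Consistent nodal loads for uniform flux through the z faces.

    Each top-face element face contributes current/(n_faces*4) to its four
    corner nodes (and the negated amount on the bottom face), which is the
    Galerkin-consistent load for a spatially uniform current density and
    makes the discrete solution exactly linear in depth.
    """
    nx, ny, nz = system.conduction_mask.shape
    if not system.conduction_mask.all():
        raise ValueError("slab load requires a fully conducting box")
    f = np.zeros(system.n_nodes)
    n_faces = nx * ny
    per_node = current_mA / (n_faces * 4.0)
    for k_node, sign in ((nz, +1.0), (0, -1.0)):
        for i in range(nx):
            for j in range(ny):
                for di, dj in ((0, 0), (1, 0), (0, 1), (1, 1)):
                    f[system.node_id[i + di, j + dj, k_node]] += \
                        sign * per_node
    return f


def slab_expected_potential(system: FEMSystem, current_mA: float = 1.0,
                            ) -> np.ndarray:
    """Exact zero-mean nodal potential for the slab problem, in mV.

    phi(z) = (I / (sigma * A)) * z with the gradient J/sigma; current flows
    from the top (+ injection) to the bottom, so potential increases with z.
    """
    nx, ny, nz = system.conduction_mask.shape
    h = system.voxel_size_mm
    sigma_mm = float(system.sigma.sigma.flat[0]) * S_PER_CM_TO_S_PER_MM
    area_mm2 = nx * ny * h * h
    grad = current_mA / (sigma_mm * area_mm2)  # mV/mm
    z = np.arange(nz + 1) * h
    phi_line = grad * z
    phi_line -= phi_line.mean()
    return _scatter_line(system, phi_line)


def _scatter_line(system: FEMSystem, phi_line: np.ndarray) -> np.ndarray:
    out = np.empty(system.n_nodes)
    node_id = system.node_id
    for k in range(node_id.shape[2]):
        ids = node_id[:, :, k]
        out[ids[ids >= 0]] = phi_line[k]
    return out


def slab_expected_J_magnitude(shape, voxel_size_mm: float,
                              current_mA: float = 1.0) -> float:
    """Uniform |J| = I/A in uA/cm^2."""
    nx, ny, _ = shape
    area_mm2 = nx * ny * voxel_size_mm ** 2
    return current_mA / area_mm2 * MA_PER_MM2_TO_UA_PER_CM2


# ---------------------------------------------------------------------------
# homogeneous sphere with two surface point electrodes

def sphere_conductivity(radius_mm: float, grid_n: int,
                        sigma_s_cm: float = 0.01,
                        voxel_size_mm: float = 1.0) -> ConductivityVolume:
    """Voxelized homogeneous sphere centered in a cubic grid."""
    h = voxel_size_mm
    c = grid_n * h / 2.0
    idx = np.arange(grid_n) * h + h / 2
    x, y, z = np.meshgrid(idx, idx, idx, indexing="ij")
    inside = (x - c) ** 2 + (y - c) ** 2 + (z - c) ** 2 <= radius_mm ** 2
    return ConductivityVolume(sigma=np.where(inside, sigma_s_cm, 0.0),
                              air_mask=~inside, voxel_size_mm=h)


def sphere_point_potential(points_mm: np.ndarray, radius_mm: float,
                           sigma_s_cm: float, electrode_mm: np.ndarray,
                           current_mA: float, n_terms: int = 200,
                           ) -> np.ndarray:
    """Series potential (mV) inside an insulated homogeneous sphere with a
    point current injection on its surface.

    phi(r, theta) = I / (4 pi sigma a) * sum_{n>=1} (2n+1)/n (r/a)^n
                    P_n(cos theta),
    with theta measured from the electrode direction and the monopole term
    absent because the net injected current is balanced by the companion
    electrode (superpose one series per electrode).
    """
    a = radius_mm
    sigma_mm = sigma_s_cm * S_PER_CM_TO_S_PER_MM
    p = np.asarray(points_mm, dtype=np.float64)
    r = np.linalg.norm(p, axis=-1)
    e = np.asarray(electrode_mm, dtype=np.float64)
    e_hat = e / np.linalg.norm(e)
    with np.errstate(invalid="ignore", divide="ignore"):
        cos_t = np.where(r > 0, (p @ e_hat) / np.where(r > 0, r, 1.0), 1.0)
    cos_t = np.clip(cos_t, -1.0, 1.0)
    rho = r / a
    phi = np.zeros_like(r)
    rho_n = np.ones_like(r)
    for n in range(1, n_terms + 1):
        rho_n = rho_n * rho
        phi += (2 * n + 1) / n * rho_n * eval_legendre(n, cos_t)
    return current_mA / (4.0 * np.pi * sigma_mm * a) * phi


def sphere_two_electrode_potential(points_mm, radius_mm, sigma_s_cm,
                                   anode_mm, cathode_mm, current_mA,
                                   n_terms: int = 200) -> np.ndarray:
    """Superposed series solution for a +I/-I surface electrode pair."""
    return (sphere_point_potential(points_mm, radius_mm, sigma_s_cm,
                                   anode_mm, current_mA, n_terms)
            - sphere_point_potential(points_mm, radius_mm, sigma_s_cm,
                                     cathode_mm, current_mA, n_terms))
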