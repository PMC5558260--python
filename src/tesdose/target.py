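"""Spherical brain target under the stimulating electrode and dose summary.

The target is a 10 mm diameter sphere of brain voxels tangent to the brain
surface directly beneath the electrode (center one radius deep along the
electrode normal); the dose statistic is the mean per-voxel current-density
magnitude over the member voxels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fem import CurrentDensityField
from .montage import ElectrodeSite
from .phantom import BRAIN, HeadPhantom


class TargetError(ValueError):
    pass


@dataclass(frozen=True)
class TargetSphere:
    center_mm: tuple[float, float, float]
    diameter_mm: float
    member_voxels: np.ndarray  # (n, 3) int voxel indices, all brain

    @property
    def n_voxels(self) -> int:
        return len(self.member_voxels)


@dataclass(frozen=True)
class DoseSummary:
    mean_J: float   # uA/cm^2
    sd_J: float
    min_J: float
    max_J: float
    n_voxels: int
    tags: dict = field(default_factory=dict)


def sphere_members(center_mm, radius_mm, voxel_size_mm, grid_shape):
    """Voxels whose centers lie within radius of the center point."""
    h = voxel_size_mm
    c = np.asarray(center_mm)
    lo = np.maximum(((c - radius_mm) / h).astype(int) - 1, 0)
    hi = np.minimum(((c + radius_mm) / h).astype(int) + 2, grid_shape)
    ranges = [np.arange(a, b) for a, b in zip(lo, hi)]
    ii, jj, kk = np.meshgrid(*ranges, indexing="ij")
    centers = np.stack([ii, jj, kk], axis=-1) * h + h / 2
    d2 = np.sum((centers - c) ** 2, axis=-1)
    inside = d2 <= radius_mm ** 2
    return np.stack([ii[inside], jj[inside], kk[inside]], axis=-1)


def locate_target(site: ElectrodeSite, phantom: HeadPhantom,
                  diameter_mm: float = 10.0,
                  max_extra_depth_mm: float = 6.0) -> TargetSphere:
    """March inward along the electrode normal to the brain surface, then one
    radius deeper; deepen further (bounded) if the sphere pokes out of brain."""
    h = phantom.voxel_size_mm
    labels = phantom.label_volume
    radius = diameter_mm / 2.0
    start = (np.asarray(site.surface_voxel) + 0.5) * h
    u = -np.asarray(site.normal)
    u = u / np.linalg.norm(u)

    # find the brain surface along the ray
    t, t_max = 0.0, 1.5 * max(phantom.grid_shape) * h
    entry = None
    while t < t_max:
        p = start + t * u
        ijk = tuple((p // h).astype(int))
        if any(i < 0 or i >= n for i, n in zip(ijk, phantom.grid_shape)):
            break
        if labels[ijk] == BRAIN:
            entry = t
            break
        t += h / 4.0
    if entry is None:
        raise TargetError(f"no brain tissue beneath electrode {site.label}")

    depth = entry + radius
    while depth <= entry + radius + max_extra_depth_mm:
        center = start + depth * u
        members = sphere_members(center, radius, h, phantom.grid_shape)
        if len(members) and np.all(labels[tuple(members.T)] == BRAIN):
            return TargetSphere(center_mm=tuple(center),
                                diameter_mm=diameter_mm,
                                member_voxels=members)
        depth += h / 2.0
    raise TargetError(
        f"a {diameter_mm} mm sphere does not fit in brain beneath "
        f"electrode {site.label}")


def dose_summary(J: CurrentDensityField, sphere: TargetSphere,
                 tags: dict | None = None) -> DoseSummary:
    """Mean/SD/min/max of per-voxel |J| over the target sphere, uA/cm^2."""
    if sphere.n_voxels == 0:
        raise TargetError("target sphere has no member voxels")
    vals = J.J_magnitude[tuple(sphere.member_voxels.T)]
    return DoseSummary(mean_J=float(vals.mean()), sd_J=float(vals.std(ddof=1))
                       if len(vals) > 1 else 0.0,
                       min_J=float(vals.min()), max_J=float(vals.max()),
                       n_voxels=int(len(vals)), tags=dict(tags or {}))
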