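"""10-20 electrode placement and stimulation montage construction.

Sites are placed by angular parametrization of the phantom scalp: C3/C4 sit
at +/-40% of the vertex-to-ear arc on the central coronal plane, F3/F4 on
the arc tilted 20% anterior. Three configurations are supported:

* non_cephalic - anode at the target site, equal cathode on the neck base;
* bi_cranial   - anode at the target site, equal cathode at the
  contralateral homologue (C4 for C3, F4 for F3);
* ring         - anode at the target site plus four cathodes at one quarter
  of the anode current each, 30 mm away along the scalp at 90 deg spacing.

Every montage carries zero net current exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra

from .phantom import AIR, NECK, SCALP, HeadPhantom

CONFIGURATIONS = ("non_cephalic", "bi_cranial", "ring")
SITES = ("C3", "F3")
INTENSITIES_MA = (0.5, 1.0, 2.0)

# angular convention: polar angle of the central sites from vertex, and the
# anterior tilt of the frontal arc (40% resp. 20% of a quarter arc)
_CENTRAL_POLAR_DEG = 36.0
_FRONTAL_TILT_DEG = 18.0
DEFAULT_ELECTRODE_RADIUS_MM = 5.0   # 1 cm diameter disc
DEFAULT_RING_DISTANCE_MM = 30.0


class MontageError(ValueError):
    pass


@dataclass(frozen=True)
class ElectrodeSite:
    label: str
    surface_voxel: tuple[int, int, int]
    normal: tuple[float, float, float]


@dataclass(frozen=True)
class StimulationSpec:
    configuration: str
    site: str
    intensity_mA: float

    def __post_init__(self):
        if self.configuration not in CONFIGURATIONS:
            raise ValueError(f"unknown configuration {self.configuration!r}")
        if self.site not in SITES:
            raise ValueError(f"unknown site {self.site!r}")
        if self.intensity_mA <= 0:
            raise ValueError("intensity_mA must be > 0")


@dataclass(frozen=True)
class Electrode:
    site: ElectrodeSite
    current_mA: float
    footprint: tuple[tuple[int, int, int], ...]
    radius_mm: float

    def __post_init__(self):
        if len(self.footprint) == 0:
            raise MontageError(f"electrode {self.site.label}: empty footprint")


@dataclass(frozen=True)
class Montage:
    electrodes: tuple[Electrode, ...]
    spec: StimulationSpec

    def __post_init__(self):
        total = math.fsum(e.current_mA for e in self.electrodes)
        if total != 0.0:
            raise MontageError(f"net montage current {total} mA != 0")
        anodes = [e for e in self.electrodes if e.current_mA > 0]
        if len(anodes) != 1 or anodes[0].site.label != self.spec.site:
            raise MontageError("montage must have exactly one anode at the "
                               "target site")


# ---------------------------------------------------------------------------
# surface geometry

def surface_mask(phantom: HeadPhantom) -> np.ndarray:
    """Head voxels with a 6-neighbor that is air or outside the grid."""
    head = phantom.head_mask()
    exposed = np.zeros_like(head)
    for axis in range(3):
        for shift in (1, -1):
            nb = np.roll(~head, shift, axis=axis)
            # rolled-in edge counts as exterior
            sl = [slice(None)] * 3
            sl[axis] = 0 if shift == 1 else -1
            nb[tuple(sl)] = True
            exposed |= nb
    return head & exposed


def _site_directions() -> dict[str, np.ndarray]:
    a = math.radians(_CENTRAL_POLAR_DEG)
    b = math.radians(_FRONTAL_TILT_DEG)
    c3 = np.array([-math.sin(a), 0.0, math.cos(a)])
    c4 = np.array([+math.sin(a), 0.0, math.cos(a)])
    # tilt the central directions about the x axis toward anterior (-y)
    f3 = np.array([-math.sin(a), -math.cos(a) * math.sin(b),
                   math.cos(a) * math.cos(b)])
    f4 = f3 * np.array([-1.0, 1.0, 1.0])
    return {"C3": c3, "C4": c4, "F3": f3, "F4": f4}


def _march_to_surface(phantom: HeadPhantom, direction: np.ndarray,
                      surface: np.ndarray) -> tuple[int, int, int]:
    """Outermost surface voxel along a ray from the head center."""
    h = phantom.voxel_size_mm
    center = np.asarray(phantom.center)
    u = direction / np.linalg.norm(direction)
    shape = phantom.grid_shape
    best = None
    t = 0.0
    t_max = 1.5 * max(shape) * h
    head = phantom.head_mask()
    while t < t_max:
        p = center + t * u
        ijk = tuple(int(c // h) for c in p)
        if any(i < 0 or i >= n for i, n in zip(ijk, shape)):
            break
        if surface[ijk]:
            return ijk
        if head[ijk]:
            best = ijk
        t += h / 4.0
    if best is None:
        raise MontageError("ray from head center found no surface voxel "
                           "(degenerate phantom)")
    # the ray exited between voxels only diagonally adjacent to air: snap to
    # the nearest surface voxel around the last head voxel on the ray
    for pad in (2, 4):
        lo = [max(0, b - pad) for b in best]
        hi = [min(n, b + pad + 1) for b, n in zip(best, shape)]
        box = surface[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        cand = np.argwhere(box)
        if len(cand):
            cand = cand + lo
            d2 = np.sum((cand - np.asarray(best)) ** 2, axis=1)
            return tuple(int(c) for c in cand[int(np.argmin(d2))])
    raise MontageError("ray from head center found no surface voxel "
                       "(degenerate phantom)")


def place_1020_sites(phantom: HeadPhantom) -> dict[str, ElectrodeSite]:
    """Locate C3/C4/F3/F4 and the neck return on the phantom surface."""
    surface = surface_mask(phantom)
    sites: dict[str, ElectrodeSite] = {}
    for label, u in _site_directions().items():
        ijk = _march_to_surface(phantom, u, surface)
        sites[label] = ElectrodeSite(label=label, surface_voxel=ijk,
                                     normal=tuple(u))
    # neck return: center of the neck-stub base at the domain floor
    labels = phantom.label_volume
    neck_floor = np.argwhere(labels[:, :, 0] == NECK)
    if len(neck_floor) == 0:
        raise MontageError("phantom has no neck stub at the domain floor")
    cx = phantom.center[0] / phantom.voxel_size_mm
    cy = phantom.center[1] / phantom.voxel_size_mm
    d2 = (neck_floor[:, 0] - cx) ** 2 + (neck_floor[:, 1] - cy) ** 2
    i, j = neck_floor[int(np.argmin(d2))]
    sites["neck"] = ElectrodeSite(label="neck", surface_voxel=(int(i), int(j), 0),
                                  normal=(0.0, 0.0, -1.0))
    return sites


_NEIGHBOR_OFFSETS = np.array(
    [(dx, dy, dz) for dx in (-1, 0, 1) for dy in (-1, 0, 1)
     for dz in (-1, 0, 1) if (dx, dy, dz) != (0, 0, 0)])
_NEIGHBOR_DISTS = np.linalg.norm(_NEIGHBOR_OFFSETS, axis=1)


def geodesic_distances(phantom: HeadPhantom, source: tuple[int, int, int],
                       max_distance_mm: float):
    """Surface geodesic distances (mm) from a source surface voxel.

    Runs Dijkstra on the 26-connected graph of surface voxels restricted to a
    bounding box of ``max_distance_mm`` around the source. Returns
    (voxel_index_array, distance_array).
    """
    h = phantom.voxel_size_mm
    surface = surface_mask(phantom)
    if not surface[source]:
        raise MontageError(f"source voxel {source} is not on the surface")
    pad = int(max_distance_mm / h) + 2
    lo = [max(0, s - pad) for s in source]
    hi = [min(n, s + pad + 1) for s, n in zip(source, phantom.grid_shape)]
    box = surface[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    coords = np.argwhere(box)  # (n, 3) box-local
    n = len(coords)
    index_of = -np.ones(box.shape, dtype=np.int64)
    index_of[tuple(coords.T)] = np.arange(n)

    rows, cols, vals = [], [], []
    for off, dist in zip(_NEIGHBOR_OFFSETS, _NEIGHBOR_DISTS):
        nb = coords + off
        ok = np.all((nb >= 0) & (nb < box.shape), axis=1)
        tgt = -np.ones(n, dtype=np.int64)
        tgt[ok] = index_of[tuple(nb[ok].T)]
        valid = tgt >= 0
        rows.append(np.arange(n)[valid])
        cols.append(tgt[valid])
        vals.append(np.full(valid.sum(), dist * h))
    graph = coo_matrix((np.concatenate(vals),
                        (np.concatenate(rows), np.concatenate(cols))),
                       shape=(n, n)).tocsr()
    src_id = index_of[tuple(np.asarray(source) - lo)]
    dist = dijkstra(graph, indices=src_id, limit=max_distance_mm * 1.2)
    reach = np.isfinite(dist)
    return coords[reach] + lo, dist[reach]


def electrode_footprint(site: ElectrodeSite, radius_mm: float,
                        phantom: HeadPhantom) -> tuple[tuple[int, int, int], ...]:
    """Surface voxels within geodesic ``radius_mm`` of the site center."""
    if radius_mm < phantom.voxel_size_mm:
        raise MontageError("electrode radius must be >= voxel size")
    coords, dist = geodesic_distances(phantom, site.surface_voxel,
                                      max_distance_mm=radius_mm + 3.0)
    members = coords[dist <= radius_mm]
    if len(members) == 0:
        raise MontageError(f"empty footprint at {site.label}")
    return tuple(map(tuple, members.tolist()))


def _ring_cathode_sites(anode: ElectrodeSite, phantom: HeadPhantom,
                        ring_distance_mm: float) -> list[ElectrodeSite]:
    """Four sites ~ring_distance_mm geodesic from the anode at 90 deg spacing."""
    h = phantom.voxel_size_mm
    coords, dist = geodesic_distances(
        phantom, anode.surface_voxel,
        max_distance_mm=ring_distance_mm + 10.0)
    pool = np.abs(dist - ring_distance_mm) <= 2.0
    if pool.sum() < 4:
        raise MontageError(
            f"cannot place ring cathodes {ring_distance_mm} mm from "
            f"{anode.label}: phantom surface too small")
    coords, dist = coords[pool], dist[pool]

    n = np.asarray(anode.normal)
    ref = np.array([0.0, 1.0, 0.0])
    if abs(np.dot(ref, n)) > 0.9:
        ref = np.array([1.0, 0.0, 0.0])
    t1 = np.cross(n, ref)
    t1 /= np.linalg.norm(t1)
    t2 = np.cross(n, t1)
    rel = (coords + 0.5) * h - (np.asarray(anode.surface_voxel) + 0.5) * h
    azimuth = np.arctan2(rel @ t2, rel @ t1)

    surface = surface_mask(phantom)
    center = np.asarray(phantom.center)
    chosen = []
    for target in (0.0, math.pi / 2, math.pi, -math.pi / 2):
        ang = np.angle(np.exp(1j * (azimuth - target)))
        score = (ang * ring_distance_mm) ** 2 + (dist - ring_distance_mm) ** 2
        k = int(np.argmin(score))
        ijk = tuple(int(c) for c in coords[k])
        out = (np.asarray(ijk) + 0.5) * h - center
        chosen.append(ElectrodeSite(
            label=f"{anode.label}_ring{len(chosen) + 1}",
            surface_voxel=ijk,
            normal=tuple(out / np.linalg.norm(out))))
        if not surface[ijk]:  # defensive; pool is drawn from the surface
            raise MontageError("ring cathode not on surface")
    if len({s.surface_voxel for s in chosen}) != 4:
        raise MontageError("ring cathodes collapsed onto each other")
    return chosen


def build_montage(spec: StimulationSpec, sites: dict[str, ElectrodeSite],
                  phantom: HeadPhantom,
                  radius_mm: float = DEFAULT_ELECTRODE_RADIUS_MM,
                  ring_distance_mm: float = DEFAULT_RING_DISTANCE_MM,
                  ) -> Montage:
    """Realize one configuration at one site and intensity."""
    anode_site = sites[spec.site]
    I = float(spec.intensity_mA)

    def electrode(site, current):
        return Electrode(site=site, current_mA=current,
                         footprint=electrode_footprint(site, radius_mm,
                                                       phantom),
                         radius_mm=radius_mm)

    electrodes = [electrode(anode_site, +I)]
    if spec.configuration == "non_cephalic":
        electrodes.append(electrode(sites["neck"], -I))
    elif spec.configuration == "bi_cranial":
        homologue = {"C3": "C4", "F3": "F4"}[spec.site]
        electrodes.append(electrode(sites[homologue], -I))
    else:  # ring
        for cathode in _ring_cathode_sites(anode_site, phantom,
                                           ring_distance_mm):
            electrodes.append(electrode(cathode, -I / 4.0))
    return Montage(electrodes=tuple(electrodes), spec=spec)


def enumerate_stimulation_specs(intensities=INTENSITIES_MA):
    """All configuration x site x intensity combinations (18 by default)."""
    return [StimulationSpec(c, s, i)
            for c in CONFIGURATIONS for s in SITES for i in intensities]


def montage_rows(montage: Montage) -> list[dict]:
    """Serializable per-electrode rows (label, voxel, current, radius)."""
    rows = []
    for e in montage.electrodes:
        i, j, k = e.site.surface_voxel
        rows.append({"label": e.site.label, "x": i, "y": j, "z": k,
                     "current_mA": e.current_mA, "radius_mm": e.radius_mm,
                     "configuration": montage.spec.configuration,
                     "site": montage.spec.site,
                     "intensity_mA": montage.spec.intensity_mA})
    return rows
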