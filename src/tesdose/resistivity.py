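"""MRI-channel combination and intensity-to-resistivity conversion.

The three intensity channels are combined into a normalized water-content
index v in [0, 1], which is mapped to resistivity by

    R(v) = K * (1 - v)**E + D      [ohm*cm]

with defaults K=16000, E=4, D=65. Conductivity is the reciprocal (S/cm) on
head voxels; air is excluded from the conduction domain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phantom import AIR, MRITriplet


@dataclass(frozen=True)
class ResistivityParams:
    K: float = 16000.0
    E: float = 4.0
    D: float = 65.0

    def __post_init__(self):
        if self.K <= 0 or self.E <= 0 or self.D <= 0:
            raise ValueError("K, E and D must all be > 0")


@dataclass(frozen=True)
class NormalizedIntensityVolume:
    v: np.ndarray  # in [0, 1]

    def __post_init__(self):
        if np.any(self.v < 0) or np.any(self.v > 1):
            raise ValueError("normalized intensity outside [0, 1]")


@dataclass(frozen=True)
class ResistivityVolume:
    R: np.ndarray  # ohm*cm
    params: ResistivityParams

    def __post_init__(self):
        tol = 1e-9
        if np.any(self.R < self.params.D - tol) or \
                np.any(self.R > self.params.K + self.params.D + tol):
            raise ValueError("resistivity outside [D, K + D]")


@dataclass(frozen=True)
class ConductivityVolume:
    """Per-voxel conductivity sigma = 1/R in S/cm with an air exclusion mask."""

    sigma: np.ndarray      # S/cm; 0 on air
    air_mask: np.ndarray   # True where excluded from conduction
    voxel_size_mm: float = 1.0

    def __post_init__(self):
        head = ~self.air_mask
        if np.any(self.sigma[head] <= 0):
            raise ValueError("non-positive conductivity on head voxels")


DEFAULT_WEIGHTS = (0.5, 0.25, 0.25)  # (PD, T2, inverted T1)


def combine_mri(triplet: MRITriplet,
                weights: tuple[float, float, float] = DEFAULT_WEIGHTS,
                mode: str = "calibrated",
                percentiles: tuple[float, float] = (2.0, 98.0),
                ) -> NormalizedIntensityVolume:
    """Combine PD/T2/T1 channels into a single water index v in [0, 1].

    ``calibrated`` mode assumes channels on the phantom forward-map scale
    (PD=w, T2=sqrt(w), T1=1-w on head, all 0 on air) and inverts each channel
    to a water estimate before weighted averaging; with noiseless input this
    recovers the ground-truth water fraction exactly. ``robust`` mode instead
    applies per-channel percentile min-max normalization (for channels on an
    arbitrary scanner scale) before the same weighted combination.

    weights are (PD, T2, inverted-T1) and are renormalized to sum to 1.
    """
    pd, t2, t1 = triplet.pd_volume, triplet.t2_volume, triplet.t1_volume
    wsum = float(sum(weights))
    if wsum <= 0:
        raise ValueError("weights must have positive sum")
    w_pd, w_t2, w_t1 = (w / wsum for w in weights)

    if mode == "calibrated":
        est_pd = np.clip(pd, 0.0, 1.0)
        est_t2 = np.clip(t2, 0.0, 1.0) ** 2
        support = (pd > 0) | (t2 > 0)  # air is dark in PD and T2
        est_t1 = np.where(support, 1.0 - np.clip(t1, 0.0, 1.0), 0.0)
    elif mode == "robust":
        est_pd = _percentile_minmax(pd, percentiles)
        est_t2 = _percentile_minmax(t2, percentiles)
        est_t1 = 1.0 - _percentile_minmax(t1, percentiles)
    else:
        raise ValueError(f"unknown combination mode {mode!r}")

    v = w_pd * est_pd + w_t2 * est_t2 + w_t1 * est_t1
    return NormalizedIntensityVolume(np.clip(v, 0.0, 1.0))


def _percentile_minmax(channel: np.ndarray, percentiles) -> np.ndarray:
    lo, hi = np.percentile(channel, percentiles)
    if hi <= lo:
        return np.zeros_like(channel, dtype=np.float64)
    return np.clip((channel - lo) / (hi - lo), 0.0, 1.0)


def resistivity_from_intensity(v: NormalizedIntensityVolume | np.ndarray,
                               params: ResistivityParams = ResistivityParams(),
                               ) -> ResistivityVolume:
    """Apply R(v) = K*(1-v)^E + D elementwise."""
    arr = v.v if isinstance(v, NormalizedIntensityVolume) else np.asarray(v)
    if np.any(arr < 0) or np.any(arr > 1):
        raise ValueError("normalized intensity outside [0, 1]")
    R = params.K * (1.0 - arr) ** params.E + params.D
    return ResistivityVolume(R=R, params=params)


def conductivity_from_resistivity(R: ResistivityVolume,
                                  labels: np.ndarray,
                                  voxel_size_mm: float = 1.0,
                                  ) -> ConductivityVolume:
    """Reciprocal map to S/cm, with air voxels masked out of the domain."""
    air = labels == AIR
    sigma = np.where(air, 0.0, 1.0 / R.R)
    return ConductivityVolume(sigma=sigma, air_mask=air,
                              voxel_size_mm=voxel_size_mm)
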