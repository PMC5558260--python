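"""Synthetic head phantom cohorts.

Generates voxelized multi-shell heads (nested ellipsoids plus a cylindrical
neck stub reaching the domain floor) with known per-voxel tissue water
fractions, and simulates T1/T2/PD-like intensity volumes from them.

Sex enters only through the skull water-fraction distribution (female skulls
are denser, i.e. lower water fraction); the frontal skull sector is denser
than the rest for both sexes.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

# tissue label codes
AIR = 0
SCALP = 1
SKULL = 2
CSF = 3
BRAIN = 4
NECK = 5

LABEL_NAMES = {AIR: "air", SCALP: "scalp", SKULL: "skull", CSF: "csf",
               BRAIN: "brain", NECK: "neck"}

FEMALE = "female"
MALE = "male"


class PhantomSizingError(ValueError):
    """Grid cannot contain the requested head geometry."""


@dataclass(frozen=True)
class VariabilitySpec:
    """Dispersion of per-subject morphology draws.

    radius_cv: coefficient of variation of the global head-size factor.
    skull_wf_sd: SD of the Beta-distributed skull water-fraction base.
    tissue_wf_sd: SD of additive jitter on scalp/CSF/brain water fractions.
    """

    radius_cv: float = 0.04
    skull_wf_sd: float = 0.025
    tissue_wf_sd: float = 0.02

    @classmethod
    def zero(cls) -> "VariabilitySpec":
        return cls(radius_cv=0.0, skull_wf_sd=0.0, tissue_wf_sd=0.0)

    def scaled(self, factor: float) -> "VariabilitySpec":
        return VariabilitySpec(self.radius_cv * factor,
                               self.skull_wf_sd * factor,
                               self.tissue_wf_sd * factor)


def default_sex_assignment(n_subjects: int) -> tuple[str, ...]:
    """Alternate sexes, starting female; 23 subjects -> 12 female... adjusted below."""
    # default cohort mirrors an 11 female / 12 male split for n=23 and stays
    # near-balanced otherwise (males get the extra slot on odd n)
    sexes = [MALE if i % 2 == 0 else FEMALE for i in range(n_subjects)]
    return tuple(sexes)


@dataclass(frozen=True)
class CohortSpec:
    """Configuration of a synthetic cohort."""

    n_subjects: int = 23
    sex_assignment: tuple[str, ...] | None = None
    grid_shape: tuple[int, int, int] = (96, 96, 96)
    voxel_size_mm: float = 1.0
    variability: VariabilitySpec = field(default_factory=VariabilitySpec)
    seed: int = 0
    female_skull_wf_mean: float = 0.08
    male_skull_wf_mean: float = 0.15
    frontal_density_modifier: float = 0.7
    mri_noise_sd: float = 0.0

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel_size_mm must be > 0")
        if self.sex_assignment is None:
            object.__setattr__(self, "sex_assignment",
                               default_sex_assignment(self.n_subjects))
        if len(self.sex_assignment) != self.n_subjects:
            raise ValueError("sex_assignment length must equal n_subjects")
        for s in self.sex_assignment:
            if s not in (FEMALE, MALE):
                raise ValueError(f"unknown sex label {s!r}")


@dataclass(frozen=True)
class MorphologyParams:
    """Per-subject geometric and tissue parameters.

    Radii are ellipsoid semi-axes (x, y, z) in mm, strictly nested
    scalp > skull > csf > brain. Water fractions are in [0, 1].
    """

    scalp_radii: tuple[float, float, float]
    skull_radii: tuple[float, float, float]
    csf_radii: tuple[float, float, float]
    brain_radii: tuple[float, float, float]
    skull_water_fraction_base: float
    frontal_density_modifier: float = 0.7
    scalp_water_fraction: float = 0.70
    csf_water_fraction: float = 0.98
    brain_water_fraction: float = 0.75
    neck_water_fraction: float = 0.70
    neck_radius_mm: float = 12.0
    frontal_sector_fraction: float = 0.15

    def __post_init__(self):
        shells = [self.scalp_radii, self.skull_radii, self.csf_radii,
                  self.brain_radii]
        for outer, inner in zip(shells[:-1], shells[1:]):
            if not all(o > i for o, i in zip(outer, inner)):
                raise ValueError(
                    f"shell radii not strictly nested: {outer} !> {inner}")
        for name in ("skull_water_fraction_base", "scalp_water_fraction",
                     "csf_water_fraction", "brain_water_fraction",
                     "neck_water_fraction"):
            w = getattr(self, name)
            if not 0.0 <= w <= 1.0:
                raise ValueError(f"{name}={w} outside [0, 1]")
        if not 0.0 < self.frontal_density_modifier <= 1.0:
            raise ValueError("frontal_density_modifier must be in (0, 1]")


@dataclass(frozen=True)
class HeadPhantom:
    """A voxelized head with ground-truth water fractions."""

    label_volume: np.ndarray          # uint8, tissue codes above
    water_fraction_volume: np.ndarray  # float64 in [0, 1], 0 on air
    morphology: MorphologyParams
    sex: str
    subject_id: str
    voxel_size_mm: float = 1.0
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.label_volume.shape

    def head_mask(self) -> np.ndarray:
        return self.label_volume != AIR


@dataclass(frozen=True)
class MRITriplet:
    """Simulated T1-, T2- and PD-weighted intensity volumes (arbitrary units)."""

    t1_volume: np.ndarray
    t2_volume: np.ndarray
    pd_volume: np.ndarray

    def __post_init__(self):
        if not (self.t1_volume.shape == self.t2_volume.shape
                == self.pd_volume.shape):
            raise ValueError("triplet volumes must share a grid shape")
        for name in ("t1_volume", "t2_volume", "pd_volume"):
            if np.any(getattr(self, name) < 0):
                raise ValueError(f"{name} has negative intensities")


def base_radii_for_grid(grid_shape, voxel_size_mm: float = 1.0):
    """Nominal shell semi-axes (mm) scaled to the smallest grid dimension.

    At the default 96-voxel/1 mm grid this gives a ~37x41x38 mm scalp with a
    6 mm scalp, 5 mm skull and 2 mm CSF shell.
    """
    g = min(grid_shape) * voxel_size_mm
    scalp = (0.39 * g, 0.43 * g, 0.40 * g)
    t_scalp, t_skull, t_csf = 0.0625 * g, 0.052 * g, 0.021 * g
    skull = tuple(r - t_scalp for r in scalp)
    csf = tuple(r - t_scalp - t_skull for r in scalp)
    brain = tuple(r - t_scalp - t_skull - t_csf for r in scalp)
    return scalp, skull, csf, brain


def _beta_draw(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Beta draw with given mean/SD; degenerate at sd=0."""
    if sd <= 0:
        return mean
    conc = mean * (1 - mean) / sd**2 - 1
    if conc <= 0:
        raise ValueError(f"skull_wf_sd={sd} too large for mean {mean}")
    a, b = mean * conc, (1 - mean) * conc
    return float(rng.beta(a, b))


def sample_morphology(spec: CohortSpec, subject_index: int,
                      max_retries: int = 20) -> MorphologyParams:
    """Draw subject morphology; deterministic given (spec.seed, subject_index)."""
    if not 0 <= subject_index < spec.n_subjects:
        raise IndexError(f"subject_index {subject_index} out of range")
    sex = spec.sex_assignment[subject_index]
    rng = np.random.default_rng(
        np.random.SeedSequence([spec.seed, 7001, subject_index]))
    var = spec.variability
    scalp0, skull0, csf0, brain0 = base_radii_for_grid(
        spec.grid_shape, spec.voxel_size_mm)
    wf_mean = (spec.female_skull_wf_mean if sex == FEMALE
               else spec.male_skull_wf_mean)

    last_err: Exception | None = None
    for _ in range(max_retries):
        # truncate the size draw at 2.5 sigma so jittered heads keep fitting
        # grids sized for the nominal radii
        size = float(np.exp(np.clip(rng.normal(0.0, var.radius_cv),
                                    -2.5 * var.radius_cv,
                                    2.5 * var.radius_cv))) \
            if var.radius_cv > 0 else 1.0
        skull_wf = _beta_draw(rng, wf_mean, var.skull_wf_sd)
        jit = (rng.normal(0.0, var.tissue_wf_sd, size=3)
               if var.tissue_wf_sd > 0 else np.zeros(3))
        try:
            return MorphologyParams(
                scalp_radii=tuple(size * r for r in scalp0),
                skull_radii=tuple(size * r for r in skull0),
                csf_radii=tuple(size * r for r in csf0),
                brain_radii=tuple(size * r for r in brain0),
                skull_water_fraction_base=skull_wf,
                frontal_density_modifier=spec.frontal_density_modifier,
                scalp_water_fraction=float(np.clip(0.70 + jit[0], 0.0, 1.0)),
                csf_water_fraction=float(np.clip(0.98 + jit[1], 0.0, 1.0)),
                brain_water_fraction=float(np.clip(0.75 + jit[2], 0.0, 1.0)),
            )
        except ValueError as err:  # non-nested draw; resample
            last_err = err
    raise ValueError(
        f"could not sample valid morphology for subject {subject_index}: "
        f"{last_err}")


def _ellipsoid_mask(coords, center, radii):
    x, y, z = coords
    cx, cy, cz = center
    rx, ry, rz = radii
    return (((x - cx) / rx) ** 2 + ((y - cy) / ry) ** 2
            + ((z - cz) / rz) ** 2) <= 1.0


def build_phantom(morphology: MorphologyParams, spec: CohortSpec,
                  sex: str = FEMALE, subject_id: str = "S0") -> HeadPhantom:
    """Voxelize the nested-ellipsoid head plus neck stub onto the grid."""
    nx, ny, nz = spec.grid_shape
    h = spec.voxel_size_mm
    m = morphology

    top_margin = 2.0 * h
    cz = nz * h - m.scalp_radii[2] - top_margin
    cx, cy = nx * h / 2.0, ny * h / 2.0
    if cz - 1.0 * h < 0:
        raise PhantomSizingError(
            f"grid z extent {nz * h} mm too small for scalp semi-axis "
            f"{m.scalp_radii[2]} mm plus neck stub")
    if (cx - m.scalp_radii[0] < h or cx + m.scalp_radii[0] > (nx - 1) * h
            or cy - m.scalp_radii[1] < h or cy + m.scalp_radii[1] > (ny - 1) * h):
        raise PhantomSizingError(
            f"grid {spec.grid_shape} too small for scalp radii {m.scalp_radii}")

    # voxel-center coordinates in mm
    idx = [np.arange(n, dtype=np.float64) * h + h / 2 for n in (nx, ny, nz)]
    x, y, z = np.meshgrid(*idx, indexing="ij")
    center = (cx, cy, cz)

    labels = np.zeros(spec.grid_shape, dtype=np.uint8)
    labels[_ellipsoid_mask((x, y, z), center, m.scalp_radii)] = SCALP
    labels[_ellipsoid_mask((x, y, z), center, m.skull_radii)] = SKULL
    labels[_ellipsoid_mask((x, y, z), center, m.csf_radii)] = CSF
    labels[_ellipsoid_mask((x, y, z), center, m.brain_radii)] = BRAIN

    # neck stub: cylinder from the domain floor up to head-center height,
    # filling only voxels not already inside the head
    neck = (((x - cx) ** 2 + (y - cy) ** 2 <= m.neck_radius_mm ** 2)
            & (z < cz) & (labels == AIR))
    labels[neck] = NECK

    wf = np.zeros(spec.grid_shape, dtype=np.float64)
    wf[labels == SCALP] = m.scalp_water_fraction
    wf[labels == CSF] = m.csf_water_fraction
    wf[labels == BRAIN] = m.brain_water_fraction
    wf[labels == NECK] = m.neck_water_fraction
    skull_mask = labels == SKULL
    wf[skull_mask] = m.skull_water_fraction_base
    # denser (drier) frontal sector; anterior is -y
    frontal = skull_mask & (y - cy <= -m.frontal_sector_fraction
                            * m.skull_radii[1])
    wf[frontal] *= m.frontal_density_modifier

    return HeadPhantom(label_volume=labels, water_fraction_volume=wf,
                       morphology=m, sex=sex, subject_id=subject_id,
                       voxel_size_mm=h, center=center)


def simulate_mri_triplet(phantom: HeadPhantom, noise_sd: float = 0.0,
                         seed: int = 0) -> MRITriplet:
    """Forward-map water fraction to T1/T2/PD-like intensities.

    Noiseless maps (on head voxels; air is 0 in all channels):
    PD = w, T2 = sqrt(w), T1 = 1 - w. Additive Gaussian noise truncated at 0.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    w = phantom.water_fraction_volume
    head = phantom.head_mask()
    pd = w.copy()
    t2 = np.sqrt(w)
    t1 = np.where(head, 1.0 - w, 0.0)
    if noise_sd > 0:
        rng = np.random.default_rng(np.random.SeedSequence([seed, 7002]))
        pd = np.maximum(pd + rng.normal(0, noise_sd, w.shape), 0.0)
        t2 = np.maximum(t2 + rng.normal(0, noise_sd, w.shape), 0.0)
        t1 = np.maximum(t1 + rng.normal(0, noise_sd, w.shape), 0.0)
    return MRITriplet(t1_volume=t1, t2_volume=t2, pd_volume=pd)


def generate_cohort(spec: CohortSpec) -> list[tuple[HeadPhantom, MRITriplet]]:
    """Generate the full cohort; reproducible from spec.seed."""
    out = []
    for i in range(spec.n_subjects):
        try:
            morph = sample_morphology(spec, i)
            phantom = build_phantom(morph, spec, sex=spec.sex_assignment[i],
                                    subject_id=f"S{i:03d}")
            triplet = simulate_mri_triplet(
                phantom, noise_sd=spec.mri_noise_sd,
                seed=int(np.random.SeedSequence([spec.seed, 7003, i])
                         .generate_state(1)[0]))
        except Exception as err:
            raise RuntimeError(f"cohort generation failed at subject {i}") \
                from err
        out.append((phantom, triplet))
    return out


# ---------------------------------------------------------------------------
# I/O

def save_phantom_nifti(phantom: HeadPhantom, out_dir: str | Path,
                       triplet: MRITriplet | None = None) -> list[Path]:
    """Write label/water-fraction (and optionally MRI) volumes as NIfTI."""
    import nibabel as nib

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    affine = np.diag([phantom.voxel_size_mm] * 3 + [1.0])
    written = []
    volumes = {"labels": phantom.label_volume.astype(np.uint8),
               "water_fraction": phantom.water_fraction_volume}
    if triplet is not None:
        volumes.update(t1=triplet.t1_volume, t2=triplet.t2_volume,
                       pd=triplet.pd_volume)
    for name, vol in volumes.items():
        path = out_dir / f"{phantom.subject_id}_{name}.nii.gz"
        nib.save(nib.Nifti1Image(np.asarray(vol), affine), path)
        written.append(path)
    return written


def cohort_manifest_rows(spec: CohortSpec,
                         cohort: list[tuple[HeadPhantom, MRITriplet]]):
    """Manifest rows (one per subject) for the cohort CSV."""
    rows = []
    for phantom, _ in cohort:
        m = dataclasses.asdict(phantom.morphology)
        row = {"subject_id": phantom.subject_id, "sex": phantom.sex,
               "seed": spec.seed}
        for k, v in m.items():
            if isinstance(v, tuple):
                for axis, val in zip("xyz", v):
                    row[f"{k}_{axis}"] = val
            else:
                row[k] = v
        rows.append(row)
    return rows
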