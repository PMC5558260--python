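# tesdose

Voxel finite-element dosimetry for transcranial electrical stimulation
(tES/tDCS) on synthetic head phantom cohorts.

The package generates seeded cohorts of multi-shell voxel head phantoms
(nested ellipsoids plus a neck stub, with sex- and region-dependent skull
water fraction), simulates T1/T2/PD-like intensity volumes, converts the
combined intensity to resistivity via `R(v) = K(1-v)^E + D` (K=16000, E=4,
D=65, ohm·cm), solves the quasi-static current-flow problem with a trilinear
hexahedral finite-element method (conjugate gradients, Jacobi
preconditioning), and evaluates the mean current-density magnitude (µA/cm²)
in a 10 mm sphere of brain directly under the C3 or F3 electrode for three
montages — non-cephalic, bi-cranial, and 4×1 ring — at 0.5/1.0/2.0 mA.
The resulting 18-condition-per-subject dose table is analysed with a
REML linear mixed model of natural-log dose (random subject intercept;
reference levels ring / female / C3 / 0.5 mA), with interaction fits,
cell summaries, cross-site correlations, and QQ diagnostics.

## Layout

| module | purpose |
|---|---|
| `tesdose.phantom` | cohort specs, morphology sampling, phantom voxelization, MRI simulation |
| `tesdose.resistivity` | MRI-channel combination, intensity→resistivity→conductivity |
| `tesdose.montage` | 10–20 site placement, electrode footprints, montage construction |
| `tesdose.fem` | stiffness assembly, CG solve, current-density evaluation |
| `tesdose.analytic` | closed-form slab and Legendre-series sphere oracles |
| `tesdose.target` | 10 mm target sphere location and dose summary |
| `tesdose.stats` | measurement table, mixed-effects ANOVA, correlations, QQ |
| `tesdose.pipeline` | end-to-end orchestration, manifests, solver validation |
| `tesdose.cli` | `tesdose` command-line interface |

## CLI

```bash
tesdose validate                          # solver oracles; exit 1 on failure
tesdose cohort --n-subjects 5 --seed 1 --out-dir out [--nifti]
tesdose run-all --n-subjects 10 --seed 1 --out-dir out
tesdose anova out/doses.csv [--interactions]
```

`run-all` writes `cohort.csv`, `doses.csv`, the three results tables
(`table1_cells.csv`, `table2_main_effects.csv`, `table3_interactions.csv`),
`cross_site_correlations.csv`, and a `manifest.json` with seeds, hashes and
timings. A YAML config file (see `RunConfig.from_yaml`) can override every
default, including grid size, variability, solver tolerances and electrode
geometry. One linear solve is performed per (subject, configuration, site);
other intensities follow exactly by linearity (set
`independent_solves: true` to force separate solves).

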