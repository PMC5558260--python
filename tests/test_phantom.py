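import numpy as np
import pytest

from tesdose import phantom as ph
from tesdose.phantom import (AIR, BRAIN, CSF, NECK, SCALP, SKULL, CohortSpec,
                             PhantomSizingError, VariabilitySpec,
                             build_phantom, generate_cohort, sample_morphology,
                             simulate_mri_triplet)
from tesdose.resistivity import combine_mri


class TestSampleMorphology:
    def test_deterministic_given_seed_and_index(self, small_spec):
        a = sample_morphology(small_spec, 0)
        b = sample_morphology(small_spec, 0)
        assert a == b

    def test_female_skull_water_below_male_monte_carlo(self):
        # Monte-Carlo over the configured Beta distributions
        spec = CohortSpec(n_subjects=200,
                          sex_assignment=tuple(["female"] * 100 + ["male"] * 100),
                          grid_shape=(48, 48, 48), seed=5)
        wf = np.array([sample_morphology(spec, i).skull_water_fraction_base
                       for i in range(200)])
        f, m = wf[:100], wf[100:]
        assert f.mean() < m.mean()
        gap = m.mean() - f.mean()
        assert abs(gap - (spec.male_skull_wf_mean
                          - spec.female_skull_wf_mean)) < 0.02

    def test_zero_dispersion_gives_identical_same_sex_subjects(self):
        spec = CohortSpec(n_subjects=4,
                          sex_assignment=("female", "female", "male", "male"),
                          grid_shape=(48, 48, 48), seed=7,
                          variability=VariabilitySpec.zero())
        f0, f1 = sample_morphology(spec, 0), sample_morphology(spec, 1)
        m0, m1 = sample_morphology(spec, 2), sample_morphology(spec, 3)
        assert f0 == f1
        assert m0 == m1
        assert f0 != m0  # sexes differ through the skull water fraction

    def test_subject_index_out_of_range(self, small_spec):
        with pytest.raises(IndexError):
            sample_morphology(small_spec, small_spec.n_subjects)


class TestBuildPhantom:
    def test_labels_partition_grid(self, phantom48):
        labels = phantom48.label_volume
        counts = np.bincount(labels.ravel(), minlength=6)
        assert counts.sum() == labels.size
        assert all(counts[t] > 0 for t in (SCALP, SKULL, CSF, BRAIN, NECK))

    def test_ray_crosses_shells_in_order(self, phantom48):
        # from head center straight up: brain -> CSF -> skull -> scalp -> air
        h = phantom48.voxel_size_mm
        i, j = (int(phantom48.center[0] // h), int(phantom48.center[1] // h))
        k0 = int(phantom48.center[2] // h)
        column = phantom48.label_volume[i, j, k0:]
        seen = [column[0]]
        for lab in column[1:]:
            if lab != seen[-1]:
                seen.append(lab)
        assert seen == [BRAIN, CSF, SKULL, SCALP, AIR]

    def test_frontal_sector_ratio_equals_modifier(self, phantom48):
        # direct aggregation over labeled voxels
        m = phantom48.morphology
        labels = phantom48.label_volume
        wf = phantom48.water_fraction_volume
        h = phantom48.voxel_size_mm
        y = (np.arange(labels.shape[1]) + 0.5) * h
        yy = np.broadcast_to(y[None, :, None], labels.shape)
        frontal = (labels == SKULL) & \
            (yy - phantom48.center[1] <= -m.frontal_sector_fraction
             * m.skull_radii[1])
        posterior = (labels == SKULL) & ~frontal
        ratio = wf[frontal].mean() / wf[posterior].mean()
        assert ratio == pytest.approx(m.frontal_density_modifier, abs=1e-12)

    def test_water_fraction_zero_exactly_on_air(self, phantom48):
        assert np.all(phantom48.water_fraction_volume[
            phantom48.label_volume == AIR] == 0.0)

    def test_brain_single_connected_component(self, phantom48):
        from scipy import ndimage

        _, n = ndimage.label(phantom48.label_volume == BRAIN)
        assert n == 1

    def test_grid_too_small_raises(self, small_spec):
        morph = sample_morphology(small_spec, 0)
        tiny = CohortSpec(n_subjects=1, sex_assignment=("male",),
                          grid_shape=(20, 20, 20), seed=1)
        with pytest.raises(PhantomSizingError):
            build_phantom(morph, tiny)


class TestMRITriplet:
    def test_noiseless_round_trip(self, phantom48, triplet48):
        v = combine_mri(triplet48)
        err = np.abs(v.v - phantom48.water_fraction_volume).max()
        assert err < 1e-10

    def test_air_voxels_dark_in_all_channels(self, phantom48, triplet48):
        air = phantom48.label_volume == AIR
        for vol in (triplet48.t1_volume, triplet48.t2_volume,
                    triplet48.pd_volume):
            assert np.all(vol[air] == 0.0)

    def test_noise_seeds(self, phantom48):
        clean = simulate_mri_triplet(phantom48, noise_sd=0.0)
        n1 = simulate_mri_triplet(phantom48, noise_sd=0.05, seed=1)
        n2 = simulate_mri_triplet(phantom48, noise_sd=0.05, seed=2)
        # different noise realizations around the same noiseless component
        assert not np.array_equal(n1.pd_volume, n2.pd_volume)
        for noisy in (n1, n2):
            diff = noisy.pd_volume - clean.pd_volume
            assert np.abs(diff).max() < 0.05 * 6  # bounded noise excursion
        r1 = simulate_mri_triplet(phantom48, noise_sd=0.05, seed=1)
        assert np.array_equal(n1.pd_volume, r1.pd_volume)

    def test_negative_noise_sd_rejected(self, phantom48):
        with pytest.raises(ValueError):
            simulate_mri_triplet(phantom48, noise_sd=-1.0)


class TestGenerateCohort:
    def test_default_cohort_is_twelve_male_eleven_female(self):
        spec = CohortSpec(n_subjects=23, grid_shape=(48, 48, 48), seed=2)
        assert spec.sex_assignment.count("male") == 12
        assert spec.sex_assignment.count("female") == 11

    def test_requested_sex_mix_recorded(self):
        sexes = tuple(["female"] * 2 + ["male"] * 1)
        spec = CohortSpec(n_subjects=3, sex_assignment=sexes,
                          grid_shape=(48, 48, 48), seed=2)
        cohort = generate_cohort(spec)
        assert [p.sex for p, _ in cohort] == list(sexes)

    def test_single_subject(self):
        spec = CohortSpec(n_subjects=1, sex_assignment=("female",),
                          grid_shape=(48, 48, 48), seed=3)
        assert len(generate_cohort(spec)) == 1

    def test_same_seed_bitwise_identical(self, small_spec):
        a = generate_cohort(small_spec)
        b = generate_cohort(small_spec)
        for (pa, _), (pb, _) in zip(a, b):
            assert np.array_equal(pa.water_fraction_volume,
                                  pb.water_fraction_volume)

    def test_member_failure_reports_subject_index(self):
        spec = CohortSpec(n_subjects=1, sex_assignment=("male",),
                          grid_shape=(16, 16, 16), seed=1)
        with pytest.raises(RuntimeError, match="subject 0"):
            generate_cohort(spec)

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            CohortSpec(n_subjects=0)
        with pytest.raises(ValueError):
            CohortSpec(n_subjects=2, sex_assignment=("male",))
        with pytest.raises(ValueError):
            CohortSpec(voxel_size_mm=0.0)


def test_nifti_round_trip(tmp_path, phantom48, triplet48):
    import nibabel as nib

    from tesdose.phantom import save_phantom_nifti

    paths = save_phantom_nifti(phantom48, tmp_path, triplet48)
    assert len(paths) == 5
    wf = nib.load(tmp_path / "S000_water_fraction.nii.gz").get_fdata()
    assert np.allclose(wf, phantom48.water_fraction_volume)
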