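import numpy as np
import pytest

from bbhmap import (
    ATLAS_LABELS,
    CohortSpec,
    PatientRecord,
    classify_target,
    generate_cohort,
    generate_hemorrhage_mask,
    generate_template,
    read_cohort_csv,
    write_cohort_csv,
)
from bbhmap.axisprofile import axial_profile
from bbhmap.stats import logistic_fit
from bbhmap.synthetic import (
    REGION_LABELS,
    records_to_frame,
    spec_from_yaml,
    spec_to_yaml,
)


class TestTemplate:
    def test_atlas_has_all_region_labels(self, template_atlas):
        _, atlas = template_atlas
        labels = set(np.unique(atlas.data)) - {0}
        assert labels >= set(ATLAS_LABELS.values())
        assert len(labels) >= 8

    def test_atlas_mirror_symmetric(self, template_atlas):
        template, atlas = template_atlas
        np.testing.assert_array_equal(atlas.data, atlas.data[::-1])
        np.testing.assert_array_equal(template.data, template.data[::-1])

    def test_affine_roundtrip(self, template_atlas, rng):
        template, _ = template_atlas
        v = rng.integers(0, 64, size=(100, 3)).astype(float)
        np.testing.assert_allclose(
            template.world_to_voxel(template.voxel_to_world(v)), v, atol=1e-9
        )

    def test_odd_x_extent_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            generate_template((63, 64, 64), 2.0)


class TestCohort:
    def test_same_seed_is_bit_identical(self, small_template_atlas):
        _, atlas = small_template_atlas
        a = generate_cohort(CohortSpec(n_patients=60, seed=3), atlas)
        b = generate_cohort(CohortSpec(n_patients=60, seed=3), atlas)
        assert a == b

    def test_record_invariants_enforced_by_generation(self, cohort):
        for r in cohort:
            assert r.age > 0
            if not r.bbh:
                assert r.bbh_volume_ml == 0 and not r.symptomatic
                assert r.bbh_location == "none"
            if r.symptomatic:
                assert r.bbh
            if r.bbh:
                assert r.bbh_volume_ml >= 0.5

    def test_marginal_rates_near_study_values(self, template_atlas):
        _, atlas = template_atlas
        df = records_to_frame(generate_cohort(CohortSpec(n_patients=2000, seed=11), atlas))
        assert df["bbh"].mean() == pytest.approx(0.18, abs=0.03)
        assert df["symptomatic"].mean() == pytest.approx(0.04, abs=0.03)

    def test_mean_trajectory_length_in_study_range(self, cohort):
        df = records_to_frame(cohort)
        assert 40 <= df["trajectory_length_mm"].mean() <= 60

    def test_target_classification_agrees_with_generator(self, template_atlas, cohort):
        _, atlas = template_atlas
        agree = 0
        for r in cohort:
            label = classify_target(r.target_mm, atlas)
            name = {v: k for k, v in ATLAS_LABELS.items()}.get(label, "unclassified")
            region = "basal_ganglia" if name.startswith("basal_ganglia") else name
            agree += region == r.target_label
        assert agree / len(cohort) >= 0.95

    def test_null_effects_leave_bbh_independent_of_age(self, template_atlas):
        _, atlas = template_atlas
        spec = CohortSpec(n_patients=4000, seed=5, beta_age=0, beta_bg=0, beta_hgg=0)
        df = records_to_frame(generate_cohort(spec, atlas))
        fit = logistic_fit(
            df["bbh"].astype(int), {"age": df["age"].to_numpy()}
        )
        assert abs(fit.coefficients["age"]) < 0.01

    def test_unreachable_region_named_in_error(self, small_template_atlas):
        _, atlas = small_template_atlas
        probs = dict(CohortSpec().region_probs)
        probs["frontal"] -= 0.05
        probs["occipital"] += 0.05
        spec = CohortSpec(n_patients=5, region_probs=probs)
        empty_atlas = atlas.with_data(np.where(atlas.data == 4, 0, atlas.data))
        with pytest.raises(ValueError, match="occipital"):
            generate_cohort(spec, empty_atlas)

    def test_probabilities_must_sum_to_one(self):
        probs = dict(CohortSpec().region_probs)
        probs["frontal"] += 0.1
        with pytest.raises(ValueError, match="sum to 1"):
            CohortSpec(region_probs=probs)


class TestHemorrhageMask:
    def _record(self, location="intralesional", volume=0.5):
        return PatientRecord(
            patient_id="P0001", age=60, sex="f", system="frame", histology="HGG",
            entry_mm=(10.0, 40.0, 40.0), target_mm=(15.0, 0.0, 2.0),
            target_label="basal_ganglia", bbh=True, bbh_volume_ml=volume,
            bbh_location=location, symptomatic=False, sensorimotor_deficit=False,
            reduced_vigilance=False, aphasia=False, revision=False,
            persistent_deficit=False,
        )

    def test_half_ml_at_1mm_voxels_is_500_voxels(self):
        template, _ = generate_template((64, 64, 64), 1.0)
        mask = generate_hemorrhage_mask(self._record(), template, seed=0)
        assert abs(int(mask.data.sum()) - 500) <= 1

    def test_intralesional_mask_stays_near_target(self):
        template, _ = generate_template((64, 64, 64), 1.0)
        rec = self._record(volume=2.0)
        mask = generate_hemorrhage_mask(rec, template, seed=1)
        pts = mask.voxel_to_world(np.argwhere(mask.data))
        nominal_r = (3 * 2000 / (4 * np.pi)) ** (1 / 3)
        assert np.linalg.norm(pts - np.array(rec.target_mm), axis=1).max() <= 2.5 * nominal_r

    def test_no_bbh_rejected(self):
        template, _ = generate_template((32, 32, 32), 4.0)
        rec = self._record()
        rec.bbh = False
        rec.bbh_volume_ml = 0.0
        rec.bbh_location = "none"
        with pytest.raises(ValueError, match="bbh"):
            generate_hemorrhage_mask(rec, template, seed=0)

    def test_cohort_centroid_in_distal_third(self, template_atlas):
        template, atlas = template_atlas
        masks, specs = [], []
        seed = 0
        for s in range(5):
            for r in generate_cohort(CohortSpec(seed=s), atlas):
                if r.bbh and len(masks) < 200:
                    masks.append(generate_hemorrhage_mask(r, template, seed=seed))
                    specs.append(r.trajectory)
                    seed += 1
        prof = axial_profile(masks, specs)
        mean_frac = float(
            (prof.centers * prof.counts_per_bin).sum() / prof.counts_per_bin.sum()
        )
        assert mean_frac > 2 / 3


class TestIO:
    def test_cohort_csv_roundtrip(self, small_template_atlas, tmp_path):
        _, atlas = small_template_atlas
        records = generate_cohort(CohortSpec(n_patients=30, seed=2), atlas)
        write_cohort_csv(records, tmp_path / "c.csv")
        back = read_cohort_csv(tmp_path / "c.csv")
        assert back == records

    def test_spec_yaml_roundtrip(self, tmp_path):
        spec = CohortSpec(n_patients=99, seed=4, beta_bg=0.5)
        spec_to_yaml(spec, tmp_path / "s.yaml")
        assert spec_from_yaml(tmp_path / "s.yaml") == spec
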