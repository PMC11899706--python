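import numpy as np
import pandas as pd
import pytest

from conftest import SMALL_CLASS_PARAMS, small_config
from octradiomics.stability import ccc
from octradiomics.synthetic import (
    LesionClassParams,
    RetestPerturbation,
    generate_lesion_volume,
    generate_retest_pair,
    generate_study_cohorts,
    write_cohort,
)

SMALL_SHAPE = (64, 64, 32)
SPACING = (0.05, 0.05, 0.05)
NEVUS = SMALL_CLASS_PARAMS["nevus"]


def test_same_seed_is_bit_identical():
    a = generate_lesion_volume(NEVUS, SMALL_SHAPE, SPACING, seed=7)
    b = generate_lesion_volume(NEVUS, SMALL_SHAPE, SPACING, seed=7)
    np.testing.assert_array_equal(a[0].values, b[0].values)
    np.testing.assert_array_equal(a[1].values, b[1].values)
    c = generate_lesion_volume(NEVUS, SMALL_SHAPE, SPACING, seed=8)
    assert not np.array_equal(a[0].values, c[0].values)


def test_degenerate_field_gives_flat_lesion():
    # no texture, no speckle, no depth attenuation -> constant interior
    params = LesionClassParams(
        "nevus", 0.12, 0.0, 120.0, 10.0, (0.7, 0.5, 0.3), depth_attenuation=0.0
    )
    vol, mask = generate_lesion_volume(params, SMALL_SHAPE, SPACING, seed=1)
    assert (vol.values[mask.values] == 120).all()


def test_depth_attenuation_darkens_the_lesion_bottom():
    params = LesionClassParams("nevus", 0.12, 0.0, 160.0, 10.0, (0.7, 0.5, 0.3))
    vol, mask = generate_lesion_volume(params, SMALL_SHAPE, SPACING, seed=1)
    zs = np.argwhere(mask.values)[:, 2]
    top = vol.values[mask.values][zs == zs.min()].mean()
    bottom = vol.values[mask.values][zs == zs.max()].mean()
    # 0.6 mm of depth at 100 gray/mm
    assert top - bottom == pytest.approx(60, abs=5)


def test_mask_voxel_count_matches_analytic_ellipsoid_volume():
    params = LesionClassParams("nevus", 0.15, 12.0, 120.0, 10.0, (1.5, 1.0, 0.5))
    _, mask = generate_lesion_volume(params, (128, 128, 64), SPACING, seed=2)
    analytic = 4.0 / 3.0 * np.pi * 1.5 * 1.0 * 0.5 / 0.05**3
    assert mask.voxel_count == pytest.approx(analytic, rel=0.05)


def test_lesion_exceeding_bounds_is_rejected():
    params = LesionClassParams("nevus", 0.15, 12.0, 120.0, 10.0, (4.0, 3.0, 2.0))
    with pytest.raises(ValueError, match="bounds"):
        generate_lesion_volume(params, SMALL_SHAPE, SPACING, seed=0)


def test_semi_axis_ordering_is_validated():
    with pytest.raises(ValueError):
        LesionClassParams("nevus", 0.1, 1.0, 100.0, 5.0, (0.5, 1.0, 0.3))


class TestRetestPair:
    def test_zero_perturbation_is_voxel_identical(self):
        pair = generate_retest_pair(
            NEVUS, RetestPerturbation(0, 0, 0), SMALL_SHAPE, SPACING, seed=5
        )
        np.testing.assert_array_equal(
            pair.test.volume.values, pair.retest.volume.values
        )
        np.testing.assert_array_equal(pair.test.mask.values, pair.retest.mask.values)

    def test_large_translation_moves_the_mask_centroid(self):
        pert = RetestPerturbation(translation_sd=0.5, axial_scale_sd=0, speckle_sd=0)
        pair = generate_retest_pair(NEVUS, pert, SMALL_SHAPE, SPACING, seed=3)
        c1 = np.argwhere(pair.test.mask.values).mean(axis=0)
        c2 = np.argwhere(pair.retest.mask.values).mean(axis=0)
        assert np.linalg.norm(c1 - c2) > 1.0  # voxels

    def test_retest_mask_is_rederived_not_copied(self):
        pert = RetestPerturbation(translation_sd=0.2, axial_scale_sd=0.05, speckle_sd=0)
        pair = generate_retest_pair(NEVUS, pert, SMALL_SHAPE, SPACING, seed=4)
        assert pair.test.mask.voxel_count != pair.retest.mask.voxel_count

    def test_default_perturbation_minimum_beats_pure_noise(self):
        """First-Order Minimum over lesion pairs agrees far better between
        test and retest than an independent pure-noise pseudo-feature."""
        rng = np.random.default_rng(0)
        mins_t, mins_r = [], []
        for i in range(12):
            pair = generate_retest_pair(
                NEVUS, RetestPerturbation(), SMALL_SHAPE, SPACING, seed=100 + i
            )
            mins_t.append(pair.test.volume.values[pair.test.mask.values].min())
            mins_r.append(pair.retest.volume.values[pair.retest.mask.values].min())
        ccc_min = ccc(mins_t, mins_r)
        ccc_noise = ccc(rng.normal(size=12), rng.normal(size=12))
        assert ccc_min >= ccc_noise


class TestCohorts:
    def test_counts_and_manifest_of_small_cohort(self, small_cohort):
        pairs, cls_scans, retest_manifest, cls_manifest = small_cohort
        cfg = small_config()
        assert len(pairs) == cfg.n_nevus
        assert len(retest_manifest) == cfg.n_retest_scans
        assert len(cls_scans) == len(cls_manifest) == cfg.n_classification_scans
        assert cls_manifest["class_label"].value_counts().to_dict() == {
            "bcc": cfg.n_bcc,
            "nevus": cfg.n_nevus,
            "bowen": cfg.n_bowen,
        }
        assert retest_manifest["scan_id"].is_unique

    def test_single_subject_single_lesion_yields_two_retest_scans(self):
        cfg = small_config(n_subjects=1, lesions_per_subject=1, n_bcc=1, n_bowen=1)
        pairs, _, manifest, _ = generate_study_cohorts(cfg)
        assert len(pairs) == 1
        assert len(manifest) == 2
        assert sorted(manifest["timepoint"]) == [1, 2]

    def test_inconsistent_counts_error(self):
        with pytest.raises(ValueError):
            generate_study_cohorts(small_config(n_bcc=0))

    def test_determinism_of_cohort_generation(self):
        cfg = small_config(n_subjects=1, lesions_per_subject=1, n_bcc=1, n_bowen=1)
        a = generate_study_cohorts(cfg)
        b = generate_study_cohorts(cfg)
        np.testing.assert_array_equal(
            a[0][0].test.volume.values, b[0][0].test.volume.values
        )
        pd.testing.assert_frame_equal(a[3], b[3])

    def test_class_separability_in_mean_roi_intensity(self, small_cohort):
        _, cls_scans, _, _ = small_cohort
        means = pd.DataFrame(
            {
                "label": [s.class_label for s in cls_scans],
                "mean": [
                    float(s.volume.values[s.mask.values].mean()) for s in cls_scans
                ],
            }
        )
        by = means.groupby("label")["mean"]
        centers = by.mean()
        within_sd = by.std().max()
        gaps = [
            abs(centers[a] - centers[b])
            for a, b in (("nevus", "bcc"), ("nevus", "bowen"), ("bcc", "bowen"))
        ]
        assert min(gaps) > within_sd

    def test_write_cohort_roundtrip(self, tmp_path):
        cfg = small_config(n_subjects=1, lesions_per_subject=1, n_bcc=1, n_bowen=1)
        pairs, cls_scans, manifest, _ = generate_study_cohorts(cfg)
        scans = [pairs[0].test, pairs[0].retest]
        write_cohort(scans, manifest, tmp_path)
        from octradiomics.io_formats import read_mask, read_volume

        for scan in scans:
            vol = read_volume(tmp_path / f"{scan.scan_id}.nrrd")
            msk = read_mask(tmp_path / f"{scan.scan_id}_mask.nrrd")
            np.testing.assert_array_equal(vol.values, scan.volume.values)
            np.testing.assert_array_equal(msk.values, scan.mask.values)
        assert (tmp_path / "manifest.csv").exists()
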