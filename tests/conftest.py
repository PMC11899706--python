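"""Shared fixtures.

Two scales are used throughout: a *small* scale (64 x 64 x 32 voxel volumes,
sub-millimetre lesions) for fast unit-level checks, and the *default* scale
(the study-mirroring cohort: 20 subjects x 2 nevi x 2 timepoints, 134-scan
classification cohort, 128 x 128 x 64 volumes) for the end-to-end
acceptance checks.  Expensive cohort-level artefacts are session-scoped.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from octradiomics.features import extract_feature_table, wide_table
from octradiomics.quantize import DEFAULT_BIN_WIDTHS, QuantizedRoi
from octradiomics.stability import run_stability
from octradiomics.synthetic import (
    CohortConfig,
    LesionClassParams,
    RetestPerturbation,
    generate_study_cohorts,
)
from octradiomics.types import RoiMask, VoxelVolume


def qroi_from_levels(levels: np.ndarray, spacing=(1.0, 1.0, 1.0)) -> QuantizedRoi:
    """Wrap a hand-written integer level array as a QuantizedRoi."""
    levels = np.asarray(levels, dtype=np.int32)
    return QuantizedRoi(
        levels=levels,
        mask=levels > 0,
        n_levels=int(levels.max()),
        bin_width=1.0,
        anchor=0.0,
        spacing=tuple(spacing),
    )


def volume_from_array(arr, spacing=(1.0, 1.0, 1.0)) -> VoxelVolume:
    return VoxelVolume(np.asarray(arr, dtype=np.uint8), spacing)


def mask_like(arr, spacing=(1.0, 1.0, 1.0)) -> RoiMask:
    return RoiMask(np.asarray(arr), spacing)


SMALL_CLASS_PARAMS = {
    "nevus": LesionClassParams(
        "nevus", 0.12, 12.0, 120.0, 10.0, (0.7, 0.5, 0.3)
    ),
    "bcc": LesionClassParams(
        "bcc", 0.25, 25.0, 155.0, 10.0, (0.8, 0.55, 0.32)
    ),
    "bowen": LesionClassParams(
        "bowen", 0.07, 18.0, 90.0, 10.0, (0.65, 0.45, 0.28)
    ),
}


def small_config(**overrides) -> CohortConfig:
    kw = dict(
        n_subjects=5,
        lesions_per_subject=2,
        n_bcc=12,
        n_bowen=8,
        volume_shape=(64, 64, 32),
        voxel_spacing=(0.05, 0.05, 0.05),
        class_params=dict(SMALL_CLASS_PARAMS),
        master_seed=424242,
    )
    kw.update(overrides)
    return CohortConfig(**kw)


@pytest.fixture(scope="session")
def small_cohort():
    return generate_study_cohorts(small_config())


@pytest.fixture(scope="session")
def small_tables(small_cohort):
    """Lesion-indexed test/retest wide tables of the small cohort at BW 25."""
    pairs, _, manifest, _ = small_cohort
    lesion_of = dict(zip(manifest["scan_id"], manifest["lesion_id"]))
    long_t = extract_feature_table([p.test for p in pairs], [25])
    long_r = extract_feature_table([p.retest for p in pairs], [25])
    return (
        wide_table(long_t, 25).rename(index=lesion_of),
        wide_table(long_r, 25).rename(index=lesion_of),
    )


# ---------------------------------------------------------- default scale ----


@pytest.fixture(scope="session")
def default_config() -> CohortConfig:
    return CohortConfig()


@pytest.fixture(scope="session")
def default_cohort(default_config):
    """The full study-mirroring cohort: 40 test-retest pairs + 134-scan
    classification cohort."""
    return generate_study_cohorts(default_config)


@pytest.fixture(scope="session")
def default_tables(default_cohort):
    """Scan-indexed wide feature tables of the retest cohort at every bin
    width in the grid: ({bw: test}, {bw: retest})."""
    pairs, _, _, _ = default_cohort
    long_t = extract_feature_table([p.test for p in pairs], DEFAULT_BIN_WIDTHS)
    long_r = extract_feature_table([p.retest for p in pairs], DEFAULT_BIN_WIDTHS)
    test_tables = {bw: wide_table(long_t, bw) for bw in DEFAULT_BIN_WIDTHS}
    retest_tables = {bw: wide_table(long_r, bw) for bw in DEFAULT_BIN_WIDTHS}
    return test_tables, retest_tables


@pytest.fixture(scope="session")
def default_stability(default_cohort, default_tables):
    pairs, _, manifest, _ = default_cohort
    lesion_of = dict(zip(manifest["scan_id"], manifest["lesion_id"]))
    test_tables = {bw: t.rename(index=lesion_of) for bw, t in default_tables[0].items()}
    retest_tables = {bw: t.rename(index=lesion_of) for bw, t in default_tables[1].items()}
    return run_stability(test_tables, retest_tables)


@pytest.fixture(scope="session")
def default_classification(default_cohort, default_tables):
    """(features at BW 25, labels) for the 134-scan classification cohort."""
    pairs, cls_scans, _, cls_manifest = default_cohort
    extra = [s for s in cls_scans if s.class_label != "nevus"]
    long_extra = extract_feature_table(extra, [25])
    features = pd.concat([default_tables[0][25], wide_table(long_extra, 25)])
    labels = pd.Series(
        cls_manifest["class_label"].to_numpy(), index=cls_manifest["scan_id"]
    )
    return features.loc[labels.index], labels, cls_manifest
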