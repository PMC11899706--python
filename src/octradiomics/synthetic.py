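"""Synthetic OCT cohort generator with known ground truth.

Emulates the structure of a dermatological OCT test-retest study: a
depth-attenuated layered skin background, an ellipsoidal lesion whose
interior combines a correlated Gaussian random field with linear depth
attenuation of the OCT signal (the dominant intensity gradient inside real
lesions), multiplicative log-normal speckle, paired test-retest scans
differing by small rigid translation plus axial (probe-pressure)
compression and freshly drawn speckle, and a three-class cohort
(nevus-like, BCC-like, Bowen-like) whose classes differ in texture-field
parameters and intensity distribution.  Individual lesions of one class
vary substantially (log-normal spread of size and texture parameters),
reflecting the wide morphological diversity of real lesions; this
between-lesion variance is what makes agreement coefficients computed
across the cohort meaningful.

Defaults mirror the study conditions the pipeline is designed around:
20 subjects x 2 nevi x 2 timepoints = 80 test-retest scans, and a
classification cohort of 63 BCC-like + 31 Bowen-like + 40 nevus scans = 134
(the nevus scans being the test-timepoint scans of the retest cohort).
Volumes default to 128 x 128 x 64 voxels at 0.05 mm isotropic spacing — a
desk-scale stand-in for 6 x 6 x 1.5 mm clinical scans.

Everything is a pure function of (config, master_seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter, map_coordinates

from .io_formats import write_mask, write_volume
from .types import RoiMask, VoxelVolume

__all__ = [
    "LesionClassParams",
    "RetestPerturbation",
    "CohortConfig",
    "Scan",
    "ScanPair",
    "DEFAULT_CLASS_PARAMS",
    "generate_lesion_volume",
    "generate_retest_pair",
    "generate_study_cohorts",
    "write_cohort",
]


@dataclass(frozen=True)
class LesionClassParams:
    """Generative parameters of one lesion class.

    ``texture_correlation_length`` (mm) sets the spatial scale of the
    correlated random field inside the lesion; ``texture_contrast`` its
    amplitude in gray values.  ``mean_intensity`` is the class-mean lesion
    intensity at the lesion top and ``intensity_sd`` the between-lesion SD
    of that mean (individual lesions of a class differ in brightness).
    ``ellipsoid_semi_axes`` are (a, b, c) in mm with a >= b >= c > 0.
    ``depth_attenuation`` (gray value / mm) is the linear decay of the OCT
    signal with depth below the lesion top, a tissue property shared by all
    classes by default.
    """

    class_label: str
    texture_correlation_length: float
    texture_contrast: float
    mean_intensity: float
    intensity_sd: float
    ellipsoid_semi_axes: tuple[float, float, float]
    depth_attenuation: float = 100.0

    def __post_init__(self) -> None:
        a, b, c = self.ellipsoid_semi_axes
        if not (a >= b >= c > 0):
            raise ValueError(
                f"semi-axes must satisfy a >= b >= c > 0, got {self.ellipsoid_semi_axes}"
            )


@dataclass(frozen=True)
class RetestPerturbation:
    """Magnitude of the test-to-retest acquisition differences.

    ``translation_sd`` (mm per axis) emulates probe repositioning,
    ``axial_scale_sd`` (dimensionless) probe-pressure compression of the
    depth axis, ``speckle_sd`` (gray value at mid-scale intensity) the
    independent multiplicative speckle of each scan.  All zero means the
    retest is voxel-identical to the test.
    """

    translation_sd: float = 0.05
    axial_scale_sd: float = 0.02
    speckle_sd: float = 2.0

    def __post_init__(self) -> None:
        if min(self.translation_sd, self.axial_scale_sd, self.speckle_sd) < 0:
            raise ValueError("perturbation SDs must be >= 0")


DEFAULT_CLASS_PARAMS: dict[str, LesionClassParams] = {
    "nevus": LesionClassParams(
        "nevus",
        texture_correlation_length=0.15,
        texture_contrast=12.0,
        mean_intensity=120.0,
        intensity_sd=10.0,
        ellipsoid_semi_axes=(1.5, 1.0, 0.5),
    ),
    "bcc": LesionClassParams(
        "bcc",
        texture_correlation_length=0.30,
        texture_contrast=25.0,
        mean_intensity=155.0,
        intensity_sd=10.0,
        ellipsoid_semi_axes=(1.8, 1.2, 0.6),
    ),
    "bowen": LesionClassParams(
        "bowen",
        texture_correlation_length=0.08,
        texture_contrast=18.0,
        mean_intensity=90.0,
        intensity_sd=10.0,
        ellipsoid_semi_axes=(1.3, 0.9, 0.45),
    ),
}


@dataclass(frozen=True)
class CohortConfig:
    """Full study configuration; defaults mirror the study composition."""

    n_subjects: int = 20
    lesions_per_subject: int = 2
    n_bcc: int = 63
    n_bowen: int = 31
    volume_shape: tuple[int, int, int] = (128, 128, 64)
    voxel_spacing: tuple[float, float, float] = (0.05, 0.05, 0.05)
    class_params: dict[str, LesionClassParams] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_PARAMS)
    )
    perturbation: RetestPerturbation = field(default_factory=RetestPerturbation)
    master_seed: int = 20250768

    @property
    def n_retest_scans(self) -> int:
        return self.n_subjects * self.lesions_per_subject * 2

    @property
    def n_nevus(self) -> int:
        return self.n_subjects * self.lesions_per_subject

    @property
    def n_classification_scans(self) -> int:
        return self.n_bcc + self.n_bowen + self.n_nevus


@dataclass
class Scan:
    scan_id: str
    subject_id: str
    lesion_id: str
    timepoint: int
    class_label: str
    seed: int
    volume: VoxelVolume
    mask: RoiMask


@dataclass
class ScanPair:
    test: Scan
    retest: Scan


# ------------------------------------------------------------ rendering ----


def _check_bounds(center, semi, extent, margin=0.0):
    c = np.asarray(center)
    s = np.asarray(semi) + margin
    if ((c - s) < 0).any() or ((c + s) > np.asarray(extent)).any():
        raise ValueError(
            f"lesion (center {tuple(c)}, semi-axes {tuple(s)} mm) exceeds "
            f"volume bounds {tuple(extent)} mm"
        )


def _background(shape, spacing, rng) -> np.ndarray:
    """Layered, depth-attenuated skin background with mild banding."""
    z_mm = np.arange(shape[2]) * spacing[2]
    profile = 40.0 + 140.0 * np.exp(-z_mm / 0.8) + 15.0 * np.sin(
        2.0 * np.pi * z_mm / 0.6
    )
    bg = np.broadcast_to(profile, shape).astype(np.float64).copy()
    bg += rng.normal(0.0, 3.0, size=shape)
    return bg


def _texture_field(shape, spacing, corr_len, rng) -> np.ndarray:
    """Unit-variance correlated Gaussian field (smoothed white noise)."""
    white = rng.standard_normal(shape)
    sigma_vox = [max(corr_len / s, 1e-6) for s in spacing]
    f = gaussian_filter(white, sigma=sigma_vox, mode="nearest")
    sd = f.std()
    return f / sd if sd > 0 else f


_SPECKLE_AMPLITUDE_CV = 0.3


def _speckle_factor(shape, speckle_sd, rng) -> np.ndarray:
    """Multiplicative log-normal speckle with unit mean.

    ``speckle_sd`` is calibrated as the nominal gray-value SD induced at the
    mid-scale intensity 128.  The realised amplitude of each acquisition
    jitters log-normally around the nominal level (CV 0.3): the noise level
    of an OCT scan depends on probe contact and signal attenuation and is
    not perfectly reproducible between consecutive acquisitions, which is
    precisely what makes strong speckle degrade test-retest agreement.
    """
    if speckle_sd == 0:
        rng.standard_normal()  # keep the draw count independent of sd
        return np.ones(shape)
    realised = speckle_sd * np.exp(_SPECKLE_AMPLITUDE_CV * rng.standard_normal())
    z = rng.standard_normal(shape)
    s = realised / 128.0
    return np.exp(s * z - 0.5 * s * s)


def _render(
    params: LesionClassParams,
    shape,
    spacing,
    field: np.ndarray,
    center_mm: np.ndarray,
    translation_mm: np.ndarray,
    axial_scale: float,
    speckle_sd: float,
    rng_bg: np.random.Generator,
    rng_speckle: np.random.Generator,
) -> tuple[VoxelVolume, RoiMask]:
    """Render one scan of the continuous lesion model.

    The retest is the test model evaluated at p' = c + diag(1,1,1/s)(p-c-t):
    the lesion appears shifted by t and axially compressed by s.  An exactly
    zero perturbation reduces to the identity map, making the retest
    voxel-identical (the speckle generator is the caller's to share or not).
    """
    shape = tuple(shape)
    spacing = np.asarray(spacing, dtype=float)
    extent = np.asarray(shape) * spacing
    a, b, c = params.ellipsoid_semi_axes
    identity = float(axial_scale) == 1.0 and not translation_mm.any()
    eff_center = center_mm + translation_mm
    eff_semi = np.array([a, b, c * axial_scale])
    _check_bounds(eff_center, eff_semi, extent)

    grids = np.meshgrid(
        *(np.arange(n) * s for n, s in zip(shape, spacing)), indexing="ij", sparse=True
    )
    if identity:
        back = grids
    else:
        # back-transform into the test model's coordinates
        back = [
            grids[0] - translation_mm[0],
            grids[1] - translation_mm[1],
            center_mm[2] + (grids[2] - center_mm[2] - translation_mm[2]) / axial_scale,
        ]
    ell = (
        ((back[0] - center_mm[0]) / a) ** 2
        + ((back[1] - center_mm[1]) / b) ** 2
        + ((back[2] - center_mm[2]) / c) ** 2
    )
    inside = ell <= 1.0

    img = _background(shape, spacing, rng_bg)
    idx = np.argwhere(inside)
    if identity:
        vals = field[inside]
        z_model = idx[:, 2] * spacing[2]
    else:
        pts = (idx * spacing).T.astype(float)
        pts[0] -= translation_mm[0]
        pts[1] -= translation_mm[1]
        pts[2] = center_mm[2] + (pts[2] - center_mm[2] - translation_mm[2]) / axial_scale
        vals = map_coordinates(
            field, pts / spacing[:, None], order=1, mode="nearest"
        )
        z_model = pts[2]
    depth = z_model - (center_mm[2] - c)  # depth below the lesion top, model coords
    img[inside] = (
        params.mean_intensity
        + params.texture_contrast * vals
        - params.depth_attenuation * depth
    )
    img *= _speckle_factor(shape, speckle_sd, rng_speckle)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    sp = tuple(spacing)
    return VoxelVolume(img, sp), RoiMask(inside, sp)


def _default_center(shape, spacing, params) -> np.ndarray:
    extent = np.asarray(shape) * np.asarray(spacing)
    c = params.ellipsoid_semi_axes[2]
    return np.array([extent[0] / 2.0, extent[1] / 2.0, c + 0.25 * extent[2]])


def generate_lesion_volume(
    params: LesionClassParams,
    shape=(128, 128, 64),
    spacing=(0.05, 0.05, 0.05),
    seed: int = 0,
    center_mm=None,
    speckle_sd: float = 0.0,
) -> tuple[VoxelVolume, RoiMask]:
    """Generate a single OCT-like scan and its lesion mask.

    Deterministic in (params, shape, spacing, seed).  Raises ``ValueError``
    if the ellipsoid does not fit inside the volume.
    """
    ss = np.random.SeedSequence(seed)
    rng_field, rng_bg, rng_speckle = (np.random.default_rng(s) for s in ss.spawn(3))
    center = (
        np.asarray(center_mm, dtype=float)
        if center_mm is not None
        else _default_center(shape, spacing, params)
    )
    field = _texture_field(
        tuple(shape), spacing, params.texture_correlation_length, rng_field
    )
    return _render(
        params,
        shape,
        spacing,
        field,
        center,
        translation_mm=np.zeros(3),
        axial_scale=1.0,
        speckle_sd=speckle_sd,
        rng_bg=rng_bg,
        rng_speckle=rng_speckle,
    )


def generate_retest_pair(
    params: LesionClassParams,
    perturbation: RetestPerturbation,
    shape=(128, 128, 64),
    spacing=(0.05, 0.05, 0.05),
    seed: int = 0,
    center_mm=None,
    ids: tuple[str, str, str] | None = None,
) -> ScanPair:
    """Generate matched test and retest scans of one lesion.

    Both scans share the lesion's underlying texture field and background;
    the retest applies a rigid translation, axial compression, and freshly
    drawn speckle.  With all perturbation SDs zero the two scans are
    voxel-identical.
    """
    ss = np.random.SeedSequence(seed)
    (
        s_field,
        s_bg,
        s_speckle_t,
        s_speckle_r,
        s_perturb,
    ) = ss.spawn(5)
    center = (
        np.asarray(center_mm, dtype=float)
        if center_mm is not None
        else _default_center(shape, spacing, params)
    )
    field = _texture_field(
        tuple(shape), spacing, params.texture_correlation_length, np.random.default_rng(s_field)
    )
    rng_p = np.random.default_rng(s_perturb)
    translation = perturbation.translation_sd * rng_p.standard_normal(3)
    axial_scale = float(np.exp(perturbation.axial_scale_sd * rng_p.standard_normal()))

    test_vol, test_mask = _render(
        params, shape, spacing, field, center,
        translation_mm=np.zeros(3), axial_scale=1.0,
        speckle_sd=perturbation.speckle_sd,
        rng_bg=np.random.default_rng(s_bg),
        rng_speckle=np.random.default_rng(s_speckle_t),
    )
    zero = (
        perturbation.translation_sd == 0
        and perturbation.axial_scale_sd == 0
        and perturbation.speckle_sd == 0
    )
    retest_vol, retest_mask = _render(
        params, shape, spacing, field, center,
        translation_mm=translation, axial_scale=axial_scale,
        speckle_sd=perturbation.speckle_sd,
        rng_bg=np.random.default_rng(s_bg),  # static tissue: same background
        rng_speckle=np.random.default_rng(s_speckle_t if zero else s_speckle_r),
    )
    subj, lesion, label = ids if ids is not None else ("S00", "L00", params.class_label)
    test = Scan(f"{lesion}_T1", subj, lesion, 1, label, seed, test_vol, test_mask)
    retest = Scan(f"{lesion}_T2", subj, lesion, 2, label, seed, retest_vol, retest_mask)
    return ScanPair(test, retest)


# --------------------------------------------------------------- cohorts ----


def _sample_params(
    template: LesionClassParams, rng: np.random.Generator
) -> LesionClassParams:
    """Per-lesion biological variability around the class template.

    Semi-axes jitter log-normally at 15% CV; texture contrast and
    correlation length spread log-normally at CVs of 0.8 and 0.6 — real
    lesions of one diagnosis span a wide textural range, and this
    between-lesion variance is what the cohort-level concordance analysis
    measures feature stability against.  The lesion mean intensity jitters
    normally with the class ``intensity_sd``.
    """
    axes = np.asarray(template.ellipsoid_semi_axes) * np.exp(
        rng.normal(0.0, 0.15, size=3)
    )
    axes = tuple(np.sort(axes)[::-1])
    return replace(
        template,
        ellipsoid_semi_axes=axes,
        mean_intensity=float(
            template.mean_intensity + rng.normal(0.0, template.intensity_sd)
        ),
        texture_contrast=float(
            template.texture_contrast * np.exp(rng.normal(0.0, 0.8))
        ),
        texture_correlation_length=float(
            template.texture_correlation_length * np.exp(rng.normal(0.0, 0.6))
        ),
    )


def _jitter_center(base, rng) -> np.ndarray:
    return base + rng.normal(0.0, 0.15, size=3) * np.array([1.0, 1.0, 0.3])


def generate_study_cohorts(
    config: CohortConfig | None = None,
) -> tuple[list[ScanPair], list[Scan], pd.DataFrame, pd.DataFrame]:
    """Generate the test-retest cohort and the classification cohort.

    Returns ``(pairs, classification_scans, retest_manifest,
    classification_manifest)``.  The nevus arm of the classification cohort
    reuses the test-timepoint scans of the retest cohort, as a repeatability
    study feeding its benign lesions into a classifier would.
    """
    config = config or CohortConfig()
    for key in ("nevus", "bcc", "bowen"):
        if key not in config.class_params:
            raise ValueError(f"class_params missing entry for {key!r}")
    if min(config.n_subjects, config.lesions_per_subject, config.n_bcc, config.n_bowen) <= 0:
        raise ValueError("cohort counts must be positive")

    ss = np.random.SeedSequence(config.master_seed)
    seed_rng = np.random.default_rng(ss)

    pairs: list[ScanPair] = []
    retest_rows = []
    nevus_template = config.class_params["nevus"]
    for si in range(config.n_subjects):
        subj = f"S{si + 1:02d}"
        for li in range(config.lesions_per_subject):
            lesion = f"{subj}_N{li + 1}"
            lesion_seed = int(seed_rng.integers(2**31))
            prng = np.random.default_rng(lesion_seed)
            params = _sample_params(nevus_template, prng)
            center = _jitter_center(
                _default_center(config.volume_shape, config.voxel_spacing, params), prng
            )
            pair = generate_retest_pair(
                params,
                config.perturbation,
                config.volume_shape,
                config.voxel_spacing,
                seed=lesion_seed,
                center_mm=center,
                ids=(subj, lesion, "nevus"),
            )
            pairs.append(pair)
            for scan in (pair.test, pair.retest):
                retest_rows.append(
                    (scan.scan_id, subj, lesion, scan.timepoint, "nevus", scan.seed)
                )

    cls_scans: list[Scan] = [p.test for p in pairs]
    for label, count in (("bcc", config.n_bcc), ("bowen", config.n_bowen)):
        template = config.class_params[label]
        for k in range(count):
            subj = f"P_{label}{k + 1:02d}"
            lesion = f"{subj}_L1"
            lesion_seed = int(seed_rng.integers(2**31))
            prng = np.random.default_rng(lesion_seed)
            params = _sample_params(template, prng)
            center = _jitter_center(
                _default_center(config.volume_shape, config.voxel_spacing, params), prng
            )
            vol, mask = generate_lesion_volume(
                params,
                config.volume_shape,
                config.voxel_spacing,
                seed=lesion_seed,
                center_mm=center,
                speckle_sd=config.perturbation.speckle_sd,
            )
            cls_scans.append(
                Scan(f"{lesion}_T1", subj, lesion, 1, label, lesion_seed, vol, mask)
            )

    columns = ["scan_id", "subject_id", "lesion_id", "timepoint", "class_label", "seed"]
    retest_manifest = pd.DataFrame(retest_rows, columns=columns)
    cls_manifest = pd.DataFrame(
        [
            (s.scan_id, s.subject_id, s.lesion_id, s.timepoint, s.class_label, s.seed)
            for s in cls_scans
        ],
        columns=columns,
    )
    assert len(retest_manifest) == config.n_retest_scans
    assert len(cls_manifest) == config.n_classification_scans
    return pairs, cls_scans, retest_manifest, cls_manifest


def write_cohort(scans: list[Scan], manifest: pd.DataFrame, out_dir: str | Path) -> None:
    """Persist scans as NRRD volume/mask pairs plus a CSV manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for scan in scans:
        write_volume(scan.volume, out / f"{scan.scan_id}.nrrd")
        write_mask(scan.mask, out / f"{scan.scan_id}_mask.nrrd")
    manifest.to_csv(out / "manifest.csv", index=False)
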