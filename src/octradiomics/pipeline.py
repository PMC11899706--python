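"""End-to-end orchestration: synth -> extract -> stability -> classify.

A run directory is self-describing: the serialized configuration and seed
written into it suffice to regenerate every artifact byte-for-byte.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .classify import make_split, negative_control, train_rfe, train_robust
from .features import extract_feature_table, wide_table
from .quantize import DEFAULT_BIN_WIDTHS
from .stability import (
    DEFAULT_CCC_THRESHOLD,
    DEFAULT_SPEARMAN_THRESHOLD,
    StabilityReport,
    run_stability,
)
from .synthetic import (
    CohortConfig,
    DEFAULT_CLASS_PARAMS,
    LesionClassParams,
    RetestPerturbation,
    generate_study_cohorts,
    write_cohort,
)

log = logging.getLogger("octradiomics")

__all__ = ["RunConfig", "run_pipeline", "load_config"]


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one reproducible study run.

    Every source of randomness in a run — cohort synthesis, the 70/30
    split, the learner, the negative-control label permutation — derives
    from the cohort ``master_seed``, so a run is a pure function of its
    configuration.  ``classifier_seed`` can override the derived split /
    learner seed for sensitivity checks.
    """

    cohort: CohortConfig = field(default_factory=CohortConfig)
    bin_widths: tuple[float, ...] = DEFAULT_BIN_WIDTHS
    ccc_threshold: float = DEFAULT_CCC_THRESHOLD
    spearman_threshold: float = DEFAULT_SPEARMAN_THRESHOLD
    classifier_bin_width: float = 25.0
    classifier_seed: int | None = None
    write_scans: bool = False

    def to_dict(self) -> dict:
        # json round-trip turns nested tuples into YAML-safe lists
        return json.loads(json.dumps(asdict(self)))


def derive_seed(master_seed: int, stream: str) -> int:
    """A deterministic sub-seed (< 2**31) for a named randomness stream."""
    tag = int.from_bytes(stream.encode(), "little") % 2**32
    return int(np.random.SeedSequence([master_seed, tag]).generate_state(1)[0] % 2**31)


def load_config(path: str | Path) -> RunConfig:
    """Build a RunConfig from a YAML file (missing keys take defaults)."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    cohort_raw = raw.pop("cohort", {})
    class_params = {
        k: LesionClassParams(class_label=k, **v)
        for k, v in cohort_raw.pop("class_params", {}).items()
    } or dict(DEFAULT_CLASS_PARAMS)
    perturbation = RetestPerturbation(**cohort_raw.pop("perturbation", {}))
    for key in ("volume_shape", "voxel_spacing"):
        if key in cohort_raw:
            cohort_raw[key] = tuple(cohort_raw[key])
    cohort = CohortConfig(
        class_params=class_params, perturbation=perturbation, **cohort_raw
    )
    if "bin_widths" in raw:
        raw["bin_widths"] = tuple(raw["bin_widths"])
    return RunConfig(cohort=cohort, **raw)


def _stage(name: str):
    log.info("stage %s", name)
    return time.perf_counter()


def _write_stability(report: StabilityReport, out: Path) -> None:
    for bw, cccs in report.ccc_per_bw.items():
        df = pd.DataFrame(
            {
                "feature": cccs.index,
                "ccc": cccs.to_numpy(),
                "repeatable": [f in report.repeatable_per_bw[bw] for f in cccs.index],
                "kept_after_dedup": [f in report.dedup_per_bw[bw] for f in cccs.index],
            }
        )
        df.to_csv(out / f"stability_bw{bw:g}.csv", index=False)
    (out / "core_features.txt").write_text(
        "\n".join(sorted(report.core)) + "\n"
    )
    if report.reproducibility_counts is not None:
        report.reproducibility_counts.to_csv(out / "reproducibility_counts.csv")


def _summary_markdown(report: StabilityReport, class_reports: dict) -> str:
    lines = ["# Study summary", "", "## Repeatable features per family per bin width", ""]
    families = sorted({f.split("_", 1)[0] for s in report.repeatable_per_bw.values() for f in s} | {"shape"})
    header = "| BW | " + " | ".join(families) + " | total |"
    lines += [header, "|" + "---|" * (len(families) + 2)]
    for bw in sorted(report.repeatable_per_bw):
        s = report.repeatable_per_bw[bw]
        per = [sum(f.startswith(fam + "_") for f in s) for fam in families]
        lines.append(
            f"| {bw:g} | " + " | ".join(str(c) for c in per) + f" | {len(s)} |"
        )
    lines += ["", f"Consistent core across all bin widths ({len(report.core)}): "
              + ", ".join(sorted(report.core)), ""]
    if report.reproducibility_counts is not None:
        lines += ["## Bin-width-pair reproducibility counts", "",
                  report.reproducibility_counts.to_markdown(), ""]
    lines += ["## Classifier one-vs-rest test metrics", ""]
    for tag, rep in class_reports.items():
        lines += [
            f"### {tag}",
            "",
            f"accuracy {rep.accuracy:.3f}, macro AUC {rep.macro_auc:.3f}, "
            f"CV macro AUC {rep.cv_macro_auc_mean:.3f} "
            f"(95% CI {rep.cv_macro_auc_ci[0]:.3f}-{rep.cv_macro_auc_ci[1]:.3f})",
            "",
            rep.per_class.round(3).to_markdown(),
            "",
        ]
    return "\n".join(lines)


def run_pipeline(config: RunConfig, out_dir: str | Path) -> Path:
    """Execute the full study and write all artifacts into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.yaml").write_text(yaml.safe_dump(config.to_dict()))

    t = _stage("synth")
    pairs, cls_scans, retest_manifest, cls_manifest = generate_study_cohorts(config.cohort)
    retest_manifest.to_csv(out / "retest_manifest.csv", index=False)
    cls_manifest.to_csv(out / "classification_manifest.csv", index=False)
    if config.write_scans:
        all_scans = [s for p in pairs for s in (p.test, p.retest)]
        extra = [s for s in cls_scans if s.timepoint != 1 or s.class_label != "nevus"]
        write_cohort(all_scans + extra, pd.concat([retest_manifest, cls_manifest]).drop_duplicates("scan_id"), out / "scans")
    log.info("synth done in %.1fs", time.perf_counter() - t)

    t = _stage("extract")
    test_scans = [p.test for p in pairs]
    retest_scans = [p.retest for p in pairs]
    long_test = extract_feature_table(test_scans, config.bin_widths)
    long_retest = extract_feature_table(retest_scans, config.bin_widths)
    cls_long = extract_feature_table(
        [s for s in cls_scans if s.class_label != "nevus"], [config.classifier_bin_width]
    )
    features_long = pd.concat([long_test, long_retest, cls_long], ignore_index=True)
    features_long.to_csv(out / "features.csv", index=False)
    log.info("extract done in %.1fs", time.perf_counter() - t)

    t = _stage("stability")
    lesion_of = dict(zip(retest_manifest["scan_id"], retest_manifest["lesion_id"]))
    test_tables, retest_tables = {}, {}
    for bw in config.bin_widths:
        tt = wide_table(long_test, bw)
        rt = wide_table(long_retest, bw)
        test_tables[bw] = tt.rename(index=lesion_of)
        retest_tables[bw] = rt.rename(index=lesion_of)
    report = run_stability(
        test_tables, retest_tables, config.ccc_threshold, config.spearman_threshold
    )
    _write_stability(report, out)
    log.info("stability done in %.1fs", time.perf_counter() - t)

    t = _stage("classify")
    bw = config.classifier_bin_width
    cls_features = pd.concat([wide_table(long_test, bw), wide_table(cls_long, bw)])
    labels = pd.Series(
        cls_manifest["class_label"].to_numpy(), index=cls_manifest["scan_id"]
    )
    cls_features = cls_features.loc[labels.index]
    split_seed = (
        config.classifier_seed
        if config.classifier_seed is not None
        else derive_seed(config.cohort.master_seed, "split")
    )
    perm_seed = derive_seed(config.cohort.master_seed, "negative-control")
    plan = make_split(cls_manifest, split_seed)
    class_reports = {}
    _, class_reports["robust"] = train_robust(cls_features, labels, plan, report.core)
    _, class_reports["rfe"] = train_rfe(cls_features, labels, plan)
    _, class_reports["negative_control"], _ = negative_control(
        cls_features, labels, plan, report.core, seed=perm_seed
    )
    for tag, rep in class_reports.items():
        payload = {
            "model": tag,
            "accuracy": rep.accuracy,
            "macro_auc": rep.macro_auc,
            "cv_macro_auc_mean": rep.cv_macro_auc_mean,
            "cv_macro_auc_ci": list(rep.cv_macro_auc_ci),
            "selected_features": list(rep.selected_features),
            "per_class": json.loads(rep.per_class.to_json(orient="index")),
        }
        (out / f"classifier_{tag}.json").write_text(json.dumps(payload, indent=2))
    log.info("classify done in %.1fs", time.perf_counter() - t)

    (out / "summary.md").write_text(_summary_markdown(report, class_reports))
    return out
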