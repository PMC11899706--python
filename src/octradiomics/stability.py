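"""Repeatability, redundancy removal and cross-bin-width reproducibility.

The agreement measure throughout is Lin's concordance correlation
coefficient

    CCC = 2 * rho * s1 * s2 / (s1**2 + s2**2 + (m1 - m2)**2)

with population means m, standard deviations s and Pearson correlation rho
of the two paired samples.  CCC combines correlation with equality of the
first two moments: it reaches 1 only for exact agreement, 0 for no
concordance and -1 for perfect inverse concordance, and it never exceeds
|rho| in magnitude.  A feature is called repeatable (test vs. retest at one
bin width) or reproducible (same scans at two bin widths) when CCC >= 0.9.

When both samples are constant the coefficient is undefined (0/0); such
features are marked non-evaluable (NaN) and excluded from repeatable sets,
since agreement of constants is unmeasurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

__all__ = [
    "ccc",
    "ccc_per_feature",
    "repeatability_screen",
    "spearman_dedup",
    "consistent_core",
    "cross_bw_reproducibility",
    "StabilityReport",
    "run_stability",
]

DEFAULT_CCC_THRESHOLD = 0.9
DEFAULT_SPEARMAN_THRESHOLD = 0.9


def ccc(x, y) -> float:
    """Lin's concordance correlation coefficient of two paired samples.

    Uses population (biased) moments.  Returns NaN when both samples are
    constant; is symmetric in its arguments.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    m1, m2 = x.mean(), y.mean()
    v1 = ((x - m1) ** 2).mean()
    v2 = ((y - m2) ** 2).mean()
    if v1 == 0.0 and v2 == 0.0:
        return float("nan")
    cov = ((x - m1) * (y - m2)).mean()
    return float(2.0 * cov / (v1 + v2 + (m1 - m2) ** 2))


def _paired_frames(a: pd.DataFrame, b: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    common_rows = a.index.intersection(b.index)
    common_cols = a.columns.intersection(b.columns)
    if len(common_rows) < 3:
        raise ValueError(f"need >= 3 paired rows, have {len(common_rows)}")
    return a.loc[common_rows, common_cols], b.loc[common_rows, common_cols]


def ccc_per_feature(a: pd.DataFrame, b: pd.DataFrame) -> pd.Series:
    """Column-wise CCC between two aligned (items x features) tables.

    Rows are matched on the index (lesion id for repeatability, scan id for
    reproducibility).
    """
    a, b = _paired_frames(a, b)
    return pd.Series(
        {col: ccc(a[col].to_numpy(), b[col].to_numpy()) for col in a.columns},
        name="ccc",
    )


def repeatability_screen(
    test: pd.DataFrame,
    retest: pd.DataFrame,
    threshold: float = DEFAULT_CCC_THRESHOLD,
) -> tuple[set[str], pd.Series]:
    """Per-feature test-retest CCC and the repeatable set {CCC >= threshold}.

    ``test``/``retest`` are (lesion x feature) tables indexed by lesion id.
    Non-evaluable features (NaN CCC) are excluded from the set.
    """
    cccs = ccc_per_feature(test, retest)
    repeatable = {f for f, v in cccs.items() if np.isfinite(v) and v >= threshold}
    return repeatable, cccs


def spearman_dedup(
    repeatable: set[str],
    values: pd.DataFrame,
    ccc_values: pd.Series,
    threshold: float = DEFAULT_SPEARMAN_THRESHOLD,
) -> set[str]:
    """Greedy redundancy removal among repeatable features.

    Features are visited in decreasing repeatability CCC (ties broken by
    name); a feature is kept only if its |Spearman rho| with every
    already-kept feature is below ``threshold``.  Equivalently: of any
    highly-correlated pair, the member with the lower CCC is dropped.
    """
    if not repeatable:
        return set()
    order = sorted(repeatable, key=lambda f: (-ccc_values[f], f))
    sub = values[order].to_numpy(dtype=np.float64)
    if len(order) == 1:
        rho = np.ones((1, 1))
    elif len(order) == 2:  # scipy returns a scalar for exactly two columns
        r = float(spearmanr(sub[:, 0], sub[:, 1]).statistic)
        rho = np.array([[1.0, r], [r, 1.0]])
    else:
        rho = np.asarray(spearmanr(sub).statistic)
    kept: list[int] = []
    for i in range(len(order)):
        if all(abs(rho[i, j]) < threshold for j in kept):
            kept.append(i)
    return {order[i] for i in kept}


def consistent_core(dedup_sets: dict[float, set[str]]) -> tuple[set[str], dict[float, set[str]]]:
    """Intersection of the per-bin-width deduplicated sets, plus the
    features unique to a single bin width."""
    sets = list(dedup_sets.values())
    core = set.intersection(*sets) if sets else set()
    only: dict[float, set[str]] = {}
    for bw, s in dedup_sets.items():
        others = set().union(*(o for b, o in dedup_sets.items() if b != bw)) if len(dedup_sets) > 1 else set()
        only[bw] = s - others
    return core, only


def cross_bw_reproducibility(
    tables: dict[float, pd.DataFrame],
    threshold: float = DEFAULT_CCC_THRESHOLD,
) -> pd.DataFrame:
    """Symmetric matrix of reproducible-feature counts per bin-width pair.

    Entry (b1, b2) counts features whose CCC between the two bin-width value
    vectors (same scans) is >= threshold.  Bin-width-invariant features
    (e.g. shape) give CCC = 1 and always count; features constant across
    scans at both bin widths are non-evaluable and never count.
    """
    bws = sorted(tables)
    counts = pd.DataFrame(0, index=bws, columns=bws, dtype=int)
    for i, b1 in enumerate(bws):
        for b2 in bws[i:]:
            cccs = ccc_per_feature(tables[b1], tables[b2])
            n = int(((cccs >= threshold) & np.isfinite(cccs)).sum())
            counts.loc[b1, b2] = n
            counts.loc[b2, b1] = n
    return counts


@dataclass
class StabilityReport:
    """Complete stability screen over a bin-width grid."""

    ccc_per_bw: dict[float, pd.Series]
    repeatable_per_bw: dict[float, set[str]]
    dedup_per_bw: dict[float, set[str]]
    core: set[str]
    bw_only: dict[float, set[str]]
    reproducibility_counts: pd.DataFrame | None = None
    ccc_threshold: float = DEFAULT_CCC_THRESHOLD
    spearman_threshold: float = DEFAULT_SPEARMAN_THRESHOLD

    def repeatable_counts(self) -> pd.Series:
        return pd.Series({bw: len(s) for bw, s in self.repeatable_per_bw.items()})


def run_stability(
    test_tables: dict[float, pd.DataFrame],
    retest_tables: dict[float, pd.DataFrame],
    ccc_threshold: float = DEFAULT_CCC_THRESHOLD,
    spearman_threshold: float = DEFAULT_SPEARMAN_THRESHOLD,
    with_reproducibility: bool = True,
) -> StabilityReport:
    """Full screen: repeatability per bin width, Spearman redundancy removal
    (on test-scan values), the cross-bin-width consistent core, and the
    bin-width-pair reproducibility matrix (on test-scan values)."""
    ccc_per_bw: dict[float, pd.Series] = {}
    repeatable: dict[float, set[str]] = {}
    dedup: dict[float, set[str]] = {}
    for bw in sorted(test_tables):
        rep, cccs = repeatability_screen(test_tables[bw], retest_tables[bw], ccc_threshold)
        ccc_per_bw[bw] = cccs
        repeatable[bw] = rep
        dedup[bw] = spearman_dedup(rep, test_tables[bw], cccs, spearman_threshold)
    core, bw_only = consistent_core(dedup)
    repro = (
        cross_bw_reproducibility(test_tables, ccc_threshold)
        if with_reproducibility
        else None
    )
    return StabilityReport(
        ccc_per_bw=ccc_per_bw,
        repeatable_per_bw=repeatable,
        dedup_per_bw=dedup,
        core=core,
        bw_only=bw_only,
        reproducibility_counts=repro,
        ccc_threshold=ccc_threshold,
        spearman_threshold=spearman_threshold,
    )
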