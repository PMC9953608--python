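"""Per-sample and per-gene sequencing-coverage quality control.

Differential exome capture between cases and controls creates differential
callability, which a carrier-frequency comparison mistakes for association.
Coverage harmonization removes that confounder: samples failing cohort-wide
depth bounds are dropped, and a gene enters the analyzable set only when its
depth profile is adequate and even between the two groups.

Coverage summaries arrive as a long-format table with one row per
(gene, sample): ``gene, sample_id, mean_depth, frac_lt20x, frac_ge10x``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from rarecollapse.cohort import CASE, SampleRecord, update_qc

COVERAGE_COLUMNS = ["gene", "sample_id", "mean_depth", "frac_lt20x", "frac_ge10x"]

# Exclusion reasons, in the order the rules are checked.
REASON_ONE_SIDED = "one-sided coverage"
REASON_MEAN_DEPTH = "gene mean depth <= minimum"
REASON_FRAC_GE10X = "fraction of bases >=10x below minimum"
REASON_SAMPLE_LT20X = "a sample exceeds the <20x fraction bound"
REASON_GROUP_DIFF = "case/control mean depth differ beyond bound"


@dataclass(frozen=True)
class CoverageThresholds:
    """Gene-inclusion and per-sample coverage bounds.

    Gene rules (a gene is analyzable only if all hold over QC-passing samples):

    * cohort mean of per-sample mean depth strictly above ``min_gene_mean_depth``;
    * cohort mean fraction of bases covered >=10x at least ``min_frac_ge10x``;
    * fraction of bases covered <20x strictly below ``max_frac_lt20x_per_sample``
      in every sample;
    * case and control mean depths within ``max_rel_mean_diff`` of each other
      (relative to the larger group mean by default; absolute difference in
      depth units when ``relative_mean_diff`` is False).

    Sample rules: cohort-wide (across genes) mean depth at least
    ``min_sample_mean_depth`` and cohort-wide mean <20x fraction at most
    ``max_sample_frac_lt20x``.
    """

    min_gene_mean_depth: float = 50.0
    min_frac_ge10x: float = 0.95
    max_frac_lt20x_per_sample: float = 0.20
    max_rel_mean_diff: float = 0.10
    relative_mean_diff: bool = True
    min_sample_mean_depth: float = 50.0
    max_sample_frac_lt20x: float = 0.20

    def __post_init__(self) -> None:
        for name in ("min_frac_ge10x", "max_frac_lt20x_per_sample", "max_sample_frac_lt20x"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.min_gene_mean_depth < 0 or self.min_sample_mean_depth < 0:
            raise ValueError("depth bounds must be non-negative")
        if self.max_rel_mean_diff < 0:
            raise ValueError("max_rel_mean_diff must be non-negative")


def read_coverage_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(COVERAGE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"coverage TSV missing columns: {sorted(missing)}")
    return df


def _validate_coverage(coverage: pd.DataFrame) -> None:
    for col in ("frac_lt20x", "frac_ge10x"):
        bad = coverage[(coverage[col] < 0) | (coverage[col] > 1)]
        if len(bad):
            raise ValueError(f"{col} outside [0, 1] for {len(bad)} records")
    if (coverage["mean_depth"] < 0).any():
        raise ValueError("negative mean_depth in coverage records")
    if coverage.duplicated(["gene", "sample_id"]).any():
        raise ValueError("duplicate (gene, sample) coverage records")


def sample_qc(
    coverage: pd.DataFrame,
    samples: Sequence[SampleRecord],
    thresholds: CoverageThresholds = CoverageThresholds(),
) -> list[SampleRecord]:
    """Flag samples failing cohort-wide coverage bounds (``qc_pass=False``).

    Every sample must have at least one coverage record; a sample with none is
    a hard error (its coverage was never measured, so no QC verdict exists).
    """
    _validate_coverage(coverage)
    by_sample = coverage.groupby("sample_id")[["mean_depth", "frac_lt20x"]].mean()
    missing = [s.sample_id for s in samples if s.sample_id not in by_sample.index]
    if missing:
        raise ValueError(f"samples with zero coverage records: {missing}")

    failing: set[str] = set()
    for s in samples:
        row = by_sample.loc[s.sample_id]
        if (
            row["mean_depth"] < thresholds.min_sample_mean_depth
            or row["frac_lt20x"] > thresholds.max_sample_frac_lt20x
        ):
            failing.add(s.sample_id)
    return update_qc(samples, failing)


def harmonize_genes(
    coverage: pd.DataFrame,
    samples: Sequence[SampleRecord],
    thresholds: CoverageThresholds = CoverageThresholds(),
) -> tuple[set[str], pd.DataFrame]:
    """Decide per-gene analyzability over the QC-passing samples.

    Returns the analyzable gene set and a report frame with one row per gene:
    ``gene, excluded, reason`` (the first failing rule; empty when included).
    The verdict is independent of the order of input records.
    """
    _validate_coverage(coverage)
    passing = [s for s in samples if s.qc_pass]
    if not passing:
        raise ValueError("no QC-passing samples")
    pass_ids = {s.sample_id for s in passing}
    case_ids = {s.sample_id for s in passing if s.group == CASE}
    ctrl_ids = pass_ids - case_ids

    cov = coverage[coverage["sample_id"].isin(pass_ids)].copy()
    cov["is_case"] = cov["sample_id"].isin(case_ids)

    grp = cov.groupby("gene")
    stats = grp.agg(
        mean_depth=("mean_depth", "mean"),
        mean_ge10x=("frac_ge10x", "mean"),
        max_lt20x=("frac_lt20x", "max"),
    )
    group_means = cov.pivot_table(
        index="gene", columns="is_case", values="mean_depth", aggfunc="mean"
    ).reindex(columns=[False, True])
    mean_case = group_means[True]
    mean_ctrl = group_means[False]
    has_case = mean_case.notna()
    has_ctrl = mean_ctrl.notna()
    if thresholds.relative_mean_diff:
        larger = np.maximum(mean_case, mean_ctrl)
        diff = (mean_case - mean_ctrl).abs() / larger
    else:
        diff = (mean_case - mean_ctrl).abs()

    reason = pd.Series("", index=stats.index, dtype=object)
    # Rules applied in fixed order; the first failing rule is recorded.
    rule_masks = [
        (~(has_case & has_ctrl), REASON_ONE_SIDED),
        (~(stats["mean_depth"] > thresholds.min_gene_mean_depth), REASON_MEAN_DEPTH),
        (~(stats["mean_ge10x"] >= thresholds.min_frac_ge10x), REASON_FRAC_GE10X),
        (~(stats["max_lt20x"] < thresholds.max_frac_lt20x_per_sample), REASON_SAMPLE_LT20X),
        (~(diff <= thresholds.max_rel_mean_diff), REASON_GROUP_DIFF),
    ]
    for mask, label in rule_masks:
        mask = mask.reindex(stats.index, fill_value=True)
        reason[(reason == "") & mask] = label

    report = pd.DataFrame(
        {"gene": stats.index, "excluded": (reason != "").to_numpy(), "reason": reason.to_numpy()}
    ).sort_values("gene", kind="stable").reset_index(drop=True)
    analyzable = set(report.loc[~report["excluded"], "gene"])
    return analyzable, report
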