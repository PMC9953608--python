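"""Gene-based collapsing analysis (GCA).

Each subject is recoded per gene as carrier / non-carrier of at least one
qualifying variant; carrier frequency is then compared between cases and
controls with a two-sided Fisher exact test.  With a = cases carrying,
b = cases not carrying, c / d likewise for controls, the test conditions on
both margins, so a ~ Hypergeometric(N, a+c, a+b) under the null, and the
two-sided p-value follows the minimum-likelihood rule

    p = sum over k of  P(X = k)  for all k with  P(X = k) <= P(X = a),

which is the convention of ``fisher.test`` in R (probabilities compared with
a 1 + 1e-7 relative tolerance to absorb floating-point noise).

The module also provides the subcohort comparison of per-sample homozygous
qualifying-variant counts via the unpaired Wilcoxon rank-sum test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from rarecollapse.cohort import CASE, CONTROL, SampleRecord, VariantRecord

logger = logging.getLogger(__name__)

#: Relative tolerance for the minimum-likelihood comparison (R convention).
_REL_ERR = 1.0 + 1e-7


@lru_cache(maxsize=65536)
def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p-value for the 2x2 table [[a, b], [c, d]].

    Exact minimum-likelihood rule: enumerate the hypergeometric support at the
    observed margins and sum the probabilities of all tables no more likely
    than the observed one.  Symmetric under swapping the two rows.
    """
    for x in (a, b, c, d):
        if x < 0:
            raise ValueError("table entries must be non-negative")
    n_top = a + b
    n_bot = c + d
    if n_top == 0 or n_bot == 0:
        raise ValueError("both row margins must be positive")
    total = n_top + n_bot
    k_carriers = a + c
    support = np.arange(
        max(0, n_top - (total - k_carriers)), min(k_carriers, n_top) + 1
    )
    pmf = stats.hypergeom.pmf(support, total, k_carriers, n_top)
    p_obs = pmf[support == a][0]
    p = float(pmf[pmf <= p_obs * _REL_ERR].sum())
    return min(p, 1.0)


@dataclass(frozen=True)
class CarrierMatrix:
    """Gene x sample binary carrier matrix over QC-passing samples.

    ``matrix`` rows are genes with at least one qualifying variant, columns
    the QC-passing sample ids; a cell is 1 when the sample carries >= 1
    qualifying variant allele in the gene.  ``groups`` maps sample id to
    ``case`` / ``control``.
    """

    matrix: pd.DataFrame
    groups: Mapping[str, str]

    def __post_init__(self) -> None:
        values = self.matrix.to_numpy()
        if values.size and not np.isin(values, (0, 1)).all():
            raise ValueError("carrier matrix cells must be 0/1")
        missing = set(self.matrix.columns) - set(self.groups)
        if missing:
            raise ValueError(f"samples without group labels: {sorted(missing)}")

    @property
    def n_cases(self) -> int:
        return sum(1 for s in self.matrix.columns if self.groups[s] == CASE)

    @property
    def n_controls(self) -> int:
        return sum(1 for s in self.matrix.columns if self.groups[s] == CONTROL)

    @property
    def universe(self) -> frozenset[str]:
        """Genes with >= 1 qualifying variant (the burden-test universe)."""
        return frozenset(self.matrix.index)


def build_carrier_matrix(
    variants: Iterable[VariantRecord], samples: Sequence[SampleRecord]
) -> CarrierMatrix:
    """Collapse tier-filtered variants to the binary carrier matrix.

    Any positive dosage marks a carrier regardless of how many qualifying
    variants the sample holds in the gene; missing genotypes count as
    non-carrier (logged).
    """
    passing = [s for s in samples if s.qc_pass]
    sample_ids = [s.sample_id for s in passing]
    groups = {s.sample_id: s.group for s in passing}
    id_index = {sid: j for j, sid in enumerate(sample_ids)}

    gene_rows: dict[str, np.ndarray] = {}
    n_missing = 0
    for v in variants:
        if not v.gene_symbol:
            continue
        row = gene_rows.get(v.gene_symbol)
        if row is None:
            row = gene_rows[v.gene_symbol] = np.zeros(len(sample_ids), dtype=np.int8)
        for sid, dosage in v.genotypes.items():
            j = id_index.get(sid)
            if j is None:
                continue
            if dosage is None:
                n_missing += 1
            elif dosage > 0:
                row[j] = 1
    if n_missing:
        logger.info("%d missing genotypes counted as non-carrier", n_missing)

    genes = sorted(gene_rows)
    matrix = pd.DataFrame(
        np.vstack([gene_rows[g] for g in genes]) if genes else np.empty((0, len(sample_ids)), dtype=np.int8),
        index=pd.Index(genes, name="gene"),
        columns=sample_ids,
    )
    return CarrierMatrix(matrix=matrix, groups=groups)


CASE_ENRICHED = "case_enriched"
CONTROL_ENRICHED = "control_enriched"
NO_DIRECTION = "none"

GCA_COLUMNS = [
    "gene",
    "cases_with",
    "cases_without",
    "controls_with",
    "controls_without",
    "p_value",
    "p_bonferroni",
    "direction",
    "rank",
]


@dataclass(frozen=True)
class GcaResult:
    """Ranked per-gene collapsing results plus the nominal hit set."""

    table: pd.DataFrame
    hits: frozenset[str]
    universe: frozenset[str]
    alpha: float


def run_gca(matrix: CarrierMatrix, alpha: float = 0.05) -> GcaResult:
    """Per-gene Fisher tests over the carrier matrix.

    Genes with zero carriers in both groups are uninformative and are dropped
    from the result table, but the reported universe still counts every gene
    with >= 1 qualifying variant.  Results are ranked by ascending p-value,
    ties broken by descending case-carrier count then gene symbol.  The
    nominal hit set contains case-enriched genes with p < ``alpha``; a
    Bonferroni-adjusted column (over the tested genes) is included for
    reference only.
    """
    if matrix.matrix.empty:
        return GcaResult(
            table=pd.DataFrame(columns=GCA_COLUMNS),
            hits=frozenset(),
            universe=matrix.universe,
            alpha=alpha,
        )
    case_cols = [s for s in matrix.matrix.columns if matrix.groups[s] == CASE]
    ctrl_cols = [s for s in matrix.matrix.columns if matrix.groups[s] == CONTROL]
    n_cases, n_controls = len(case_cols), len(ctrl_cols)

    a = matrix.matrix[case_cols].sum(axis=1).astype(int)
    c = matrix.matrix[ctrl_cols].sum(axis=1).astype(int)
    informative = (a + c) > 0

    rows = []
    for gene, ai, ci in zip(a.index[informative], a[informative], c[informative]):
        bi, di = n_cases - ai, n_controls - ci
        p = fisher_two_sided(ai, bi, ci, di)
        if ai * n_controls > ci * n_cases:
            direction = CASE_ENRICHED
        elif ai * n_controls < ci * n_cases:
            direction = CONTROL_ENRICHED
        else:
            direction = NO_DIRECTION
        rows.append((gene, ai, bi, ci, di, p, direction))

    table = pd.DataFrame(
        rows,
        columns=["gene", "cases_with", "cases_without", "controls_with", "controls_without", "p_value", "direction"],
    )
    m = len(table)
    table["p_bonferroni"] = np.minimum(table["p_value"] * m, 1.0)
    table = table.sort_values(
        by=["p_value", "cases_with", "gene"],
        ascending=[True, False, True],
        kind="stable",
    ).reset_index(drop=True)
    table["rank"] = np.arange(1, m + 1)
    table = table[GCA_COLUMNS]

    hits = frozenset(
        table.loc[(table["p_value"] < alpha) & (table["direction"] == CASE_ENRICHED), "gene"]
    )
    logger.info(
        "GCA: %d genes tested (universe %d), %d nominal case-enriched hits at alpha=%g",
        m,
        len(matrix.universe),
        len(hits),
        alpha,
    )
    return GcaResult(table=table, hits=hits, universe=matrix.universe, alpha=alpha)


@dataclass(frozen=True)
class HomozygousBurdenResult:
    """Rank-sum comparison of per-sample homozygous qualifying-variant counts."""

    strata: tuple[str, str]
    counts: dict[str, list[int]]
    totals: dict[str, int]
    statistic: float
    p_value: float


def homozygous_counts(
    variants: Iterable[VariantRecord], sample_ids: Sequence[str]
) -> dict[str, int]:
    """Per-sample number of genes carrying >= 1 homozygous qualifying variant."""
    genes_by_sample: dict[str, set[str]] = {sid: set() for sid in sample_ids}
    for v in variants:
        if not v.gene_symbol:
            continue
        for sid, dosage in v.genotypes.items():
            if sid in genes_by_sample and dosage == 2:
                genes_by_sample[sid].add(v.gene_symbol)
    return {sid: len(genes) for sid, genes in genes_by_sample.items()}


def compare_homozygous_burden(
    variants: Sequence[VariantRecord],
    samples: Sequence[SampleRecord],
    stratify_by: str = "subpopulation",
    strata: tuple[str, str] | None = None,
    group: str | None = CASE,
) -> HomozygousBurdenResult:
    """Compare homozygous ultra-rare burden between two sample strata.

    Counts, per sample, the genes with a homozygous (dosage 2) qualifying
    variant, then compares the two strata with the two-sided unpaired Wilcoxon
    rank-sum (Mann-Whitney) test — the appropriate rank test for independent
    strata of unequal size.  By default samples are stratified by
    subpopulation within cases; pass ``group=None`` to use the whole cohort.
    """
    pool = [s for s in samples if s.qc_pass and (group is None or s.group == group)]
    labels = sorted({getattr(s, stratify_by) for s in pool}) if strata is None else list(strata)
    if len(labels) != 2:
        raise ValueError(f"need exactly two strata, got {labels}")
    members = {lab: [s.sample_id for s in pool if getattr(s, stratify_by) == lab] for lab in labels}
    for lab, ids in members.items():
        if not ids:
            raise ValueError(f"stratum {lab!r} has no samples")

    all_ids = members[labels[0]] + members[labels[1]]
    per_sample = homozygous_counts(variants, all_ids)
    x = [per_sample[sid] for sid in members[labels[0]]]
    y = [per_sample[sid] for sid in members[labels[1]]]
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="auto")
    return HomozygousBurdenResult(
        strata=(labels[0], labels[1]),
        counts={labels[0]: x, labels[1]: y},
        totals={labels[0]: int(sum(x)), labels[1]: int(sum(y))},
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
    )
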