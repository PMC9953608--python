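"""Tiered ultra-rare variant selection.

Two tiers qualify variants for the downstream statistics:

* the **strict tier** (feeds over-representation analysis): PASS variants,
  protein-altering, absent from the population frequency resource, and
  CADD PHRED >= 20;
* the **permissive tier** (feeds the gene-based collapsing analysis): PASS
  variants, protein-altering, population AF <= 0.01 (absent counts as rare),
  no deleteriousness restriction.

A synonymous comparator stream applies the strict tier's AF/CADD rules to
synonymous variants only; genes it selects in cases act as a negative control
for the enrichment comparison.

Every strict-tier variant also satisfies the permissive tier (absent implies
AF <= 0.01 and dropping the CADD bound only loosens), so the strict variant
set nests inside the permissive one whenever both use the same gene
restriction and consequence classes.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from rarecollapse.cohort import (
    CASE,
    CONTROL,
    PROTEIN_ALTERING,
    SYNONYMOUS,
    SampleRecord,
    VariantRecord,
)

logger = logging.getLogger(__name__)

#: Default rarity bound for the permissive tier.  The qualifying condition is
#: AF <= 0.01 (inclusive), configurable per profile.
DEFAULT_MAX_AF = 0.01
#: Default deleteriousness bound for the strict tier (top 1% of CADD PHRED).
DEFAULT_MIN_CADD = 20.0


@dataclass(frozen=True)
class FilterProfile:
    """A named tier of variant-inclusion rules.

    ``absent_required`` demands the variant have no population frequency
    record; otherwise ``max_af`` bounds the recorded AF (an absent AF always
    qualifies as rare).  ``min_cadd`` of ``None`` disables the deleteriousness
    rule; under an active bound an unscored variant fails (conservative).
    ``restrict_to_genes`` of ``None`` disables the gene restriction.
    """

    name: str
    require_pass: bool = True
    absent_required: bool = False
    max_af: float | None = DEFAULT_MAX_AF
    min_cadd: float | None = None
    consequence_classes: frozenset[str] = field(default_factory=lambda: PROTEIN_ALTERING)
    restrict_to_genes: frozenset[str] | None = None

    def __post_init__(self) -> None:
        if not self.consequence_classes:
            raise ValueError("consequence_classes must be non-empty")
        if not self.absent_required:
            if self.max_af is None or not 0.0 < self.max_af <= 1.0:
                raise ValueError("max_af must lie in (0, 1] when absence is not required")

    def admits(self, v: VariantRecord) -> tuple[bool, str]:
        """Whether the variant qualifies; on rejection, the first failing rule."""
        if self.require_pass and v.filter_status != "PASS":
            return False, "non_pass_filter"
        if self.restrict_to_genes is not None and v.gene_symbol not in self.restrict_to_genes:
            return False, "gene_not_analyzable"
        if v.consequence not in self.consequence_classes:
            return False, "consequence_class"
        if self.absent_required:
            if v.population_af is not None:
                return False, "present_in_population"
        elif v.population_af is not None and v.population_af > self.max_af:
            return False, "af_above_bound"
        if self.min_cadd is not None:
            if v.cadd_phred is None or v.cadd_phred < self.min_cadd:
                return False, "cadd_below_bound"
        return True, ""


def strict_profile(analyzable: Iterable[str] | None = None) -> FilterProfile:
    """Strict tier: protein-altering, absent from the population, CADD >= 20."""
    genes = frozenset(analyzable) if analyzable is not None else None
    return FilterProfile(
        name="strict",
        absent_required=True,
        max_af=None,
        min_cadd=DEFAULT_MIN_CADD,
        restrict_to_genes=genes,
    )


def permissive_profile(analyzable: Iterable[str] | None = None) -> FilterProfile:
    """Permissive tier: protein-altering, AF <= 0.01, no CADD restriction."""
    genes = frozenset(analyzable) if analyzable is not None else None
    return FilterProfile(name="permissive", max_af=DEFAULT_MAX_AF, restrict_to_genes=genes)


def synonymous_profile(analyzable: Iterable[str] | None = None) -> FilterProfile:
    """Synonymous comparator: strict-tier AF/CADD rules, synonymous class only."""
    return replace(
        strict_profile(analyzable),
        name="synonymous",
        consequence_classes=frozenset({SYNONYMOUS}),
    )


def apply_filter(
    variants: Iterable[VariantRecord], profile: FilterProfile
) -> tuple[list[VariantRecord], Counter[str]]:
    """Pure selection: retained records plus counts of each rejection reason.

    Idempotent and order-independent: re-filtering the output changes nothing,
    and the retained set does not depend on input order.
    """
    kept: list[VariantRecord] = []
    rejections: Counter[str] = Counter()
    for v in variants:
        ok, reason = profile.admits(v)
        if ok:
            kept.append(v)
        else:
            rejections[reason] += 1
    logger.info(
        "profile %s: kept %d, rejected %s", profile.name, len(kept), dict(rejections)
    )
    return kept, rejections


@dataclass(frozen=True)
class EnrichmentGeneLists:
    """The three query lists for over-representation analysis."""

    case_genes: frozenset[str]
    control_genes: frozenset[str]
    case_synonymous_genes: frozenset[str]


def _carried_genes(variants: Iterable[VariantRecord], sample_ids: set[str]) -> frozenset[str]:
    genes = set()
    for v in variants:
        if not v.gene_symbol:
            continue
        if any(v.genotypes.get(sid) or 0 for sid in sample_ids):
            genes.add(v.gene_symbol)
    return frozenset(genes)


def gene_lists_for_enrichment(
    protein_altering: Sequence[VariantRecord],
    synonymous: Sequence[VariantRecord],
    samples: Sequence[SampleRecord],
    subpopulation: str | None = None,
) -> EnrichmentGeneLists:
    """Distinct gene symbols carried by each group, for the three query streams.

    ``protein_altering`` and ``synonymous`` must already be tier-filtered.
    When ``subpopulation`` is given, case lists are restricted to cases from
    that subpopulation (controls are never restricted); this mirrors limiting
    the enrichment queries to the ancestry-homogeneous part of the cohort.
    A gene may legitimately appear in several lists.
    """
    passing = [s for s in samples if s.qc_pass]
    case_ids = {
        s.sample_id
        for s in passing
        if s.group == CASE and (subpopulation is None or s.subpopulation == subpopulation)
    }
    ctrl_ids = {s.sample_id for s in passing if s.group == CONTROL}

    lists = EnrichmentGeneLists(
        case_genes=_carried_genes(protein_altering, case_ids),
        control_genes=_carried_genes(protein_altering, ctrl_ids),
        case_synonymous_genes=_carried_genes(synonymous, case_ids),
    )
    for label, genes in (
        ("case", lists.case_genes),
        ("control", lists.control_genes),
        ("case-synonymous", lists.case_synonymous_genes),
    ):
        if not genes:
            logger.warning("empty %s gene list for enrichment", label)
    return lists
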