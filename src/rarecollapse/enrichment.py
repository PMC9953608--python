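"""Local gene-set over-representation analysis.

For each gene set, the overlap between a query gene list and the set (both
intersected with an explicit universe) is scored with the inclusive
upper-tail hypergeometric test; Benjamini-Hochberg step-up adjustment is then
applied independently within each gene-set category (e.g. GO:MF terms are
corrected against other GO:MF terms only).

A three-way exclusivity comparison flags terms enriched in the case query but
in neither the control query nor the case-synonymous comparator — the pattern
expected of a genuine protein-altering signal rather than a cohort artifact.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from rarecollapse.burden import hypergeom_upper_tail
from rarecollapse.cohort import GeneSet

logger = logging.getLogger(__name__)

ENRICHMENT_COLUMNS = [
    "term_id",
    "term_name",
    "category",
    "set_size_in_universe",
    "query_size_in_universe",
    "universe_size",
    "overlap_size",
    "overlap_genes",
    "nominal_p",
    "adjusted_p",
    "significant",
]


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in the input order.

    adjusted_(i) = min_{j >= rank(i)} ( p_(j) * m / j ), capped at 1.
    Monotone along the sorted ordering and pointwise >= the input.  Note the
    step-up procedure is not idempotent: re-adjusting already-adjusted values
    inflates them further (e.g. [0.25, 1.0] -> [0.5, 1.0] -> [1.0, 1.0]).
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    adjusted_sorted = np.minimum(1.0, np.minimum.accumulate(scaled[::-1])[::-1])
    adjusted = np.empty(m, dtype=float)
    adjusted[order] = adjusted_sorted
    return adjusted


def enrich(
    query: Iterable[str],
    collection: Sequence[GeneSet],
    universe: Iterable[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Over-representation of the query list in each gene set of the collection.

    Query symbols outside the universe are dropped (logged); sets with an
    empty universe intersection are skipped (logged).  Returns one row per
    scored term, sorted by adjusted then nominal p-value, with BH adjustment
    applied within each category.
    """
    universe = frozenset(universe)
    if not universe:
        raise ValueError("empty gene universe")
    query = frozenset(query)
    query_in = query & universe
    if len(query_in) < len(query):
        logger.info("%d query genes outside the universe dropped", len(query) - len(query_in))

    rows = []
    for gs in collection:
        set_in = gs.members & universe
        if not set_in:
            logger.info("term %s has no members in the universe; skipped", gs.term_id)
            continue
        overlap = set_in & query_in
        p = hypergeom_upper_tail(len(universe), len(set_in), len(query_in), len(overlap))
        rows.append(
            {
                "term_id": gs.term_id,
                "term_name": gs.term_name,
                "category": gs.category,
                "set_size_in_universe": len(set_in),
                "query_size_in_universe": len(query_in),
                "universe_size": len(universe),
                "overlap_size": len(overlap),
                "overlap_genes": ";".join(sorted(overlap)),
                "nominal_p": p,
            }
        )
    if not rows:
        return pd.DataFrame(columns=ENRICHMENT_COLUMNS)

    table = pd.DataFrame(rows)
    table["adjusted_p"] = np.nan
    for _, idx in table.groupby("category").groups.items():
        table.loc[idx, "adjusted_p"] = bh_adjust(table.loc[idx, "nominal_p"].to_numpy())
    table["significant"] = table["adjusted_p"] < alpha
    table = table.sort_values(
        by=["adjusted_p", "nominal_p", "term_id"], kind="stable"
    ).reset_index(drop=True)
    return table[ENRICHMENT_COLUMNS]


@dataclass(frozen=True)
class ExclusivityVerdict:
    """Whether a term's enrichment is exclusive to the case query."""

    term_id: str
    enriched_in_cases: bool
    enriched_in_controls: bool
    enriched_in_synonymous: bool

    @property
    def exclusive(self) -> bool:
        return (
            self.enriched_in_cases
            and not self.enriched_in_controls
            and not self.enriched_in_synonymous
        )


def exclusivity(
    case_results: pd.DataFrame,
    control_results: pd.DataFrame,
    synonymous_results: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Three-way comparison of enrichment verdicts over the same collection.

    One row per term appearing in the case results; a term absent from a
    comparison collection counts as not enriched there.
    """

    def significant_terms(df: pd.DataFrame) -> set[str]:
        if df.empty:
            return set()
        return set(df.loc[df["adjusted_p"] < alpha, "term_id"])

    in_cases = significant_terms(case_results)
    in_controls = significant_terms(control_results)
    in_synonymous = significant_terms(synonymous_results)

    rows = []
    for term in case_results["term_id"] if not case_results.empty else []:
        v = ExclusivityVerdict(
            term_id=term,
            enriched_in_cases=term in in_cases,
            enriched_in_controls=term in in_controls,
            enriched_in_synonymous=term in in_synonymous,
        )
        rows.append(
            {
                "term_id": v.term_id,
                "enriched_in_cases": v.enriched_in_cases,
                "enriched_in_controls": v.enriched_in_controls,
                "enriched_in_synonymous": v.enriched_in_synonymous,
                "exclusive": v.exclusive,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "term_id",
            "enriched_in_cases",
            "enriched_in_controls",
            "enriched_in_synonymous",
            "exclusive",
        ],
    )
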