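"""Hypergeometric gene-set burden test.

Tests whether a curated disease-gene list is over-represented among the
nominally significant genes of the collapsing analysis.  With a universe of N
testable genes of which K belong to the curated list, and n nominal hits of
which k are curated, the overlap under the null of no preferential ranking is
X ~ Hypergeometric(N, K, n) and the reported p-value is the inclusive upper
tail P(X >= k), assembled in log space for numerical safety.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from scipy import stats
from scipy.special import logsumexp
import numpy as np

from rarecollapse.cohort import CuratedGeneList

logger = logging.getLogger(__name__)


def hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), inclusive of k.

    Parameters follow the draw convention: population N, K marked, n drawn,
    k marked among the drawn.  Computed by log-sum-exp over the upper support.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"infeasible parameters N={N}, K={K}, n={n}")
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"k={k} outside [0, min(K, n)={min(K, n)}]")
    if k == 0:
        return 1.0
    support = np.arange(k, min(K, n) + 1)
    log_terms = stats.hypergeom.logpmf(support, N, K, n)
    return float(min(1.0, np.exp(logsumexp(log_terms))))


@dataclass(frozen=True)
class OverlapTestResult:
    """Outcome of the curated-list burden test.

    ``universe_N``: testable genes (>= 1 qualifying variant); ``list_K``:
    curated genes present in the universe; ``hits_n``: nominal hit genes;
    ``overlap_k``: curated genes among the hits; ``p_value``: P(X >= k).
    """

    universe_N: int
    list_K: int
    hits_n: int
    overlap_k: int
    overlap_genes: frozenset[str]
    p_value: float

    def as_dict(self) -> dict:
        return {
            "N": self.universe_N,
            "K": self.list_K,
            "n": self.hits_n,
            "k": self.overlap_k,
            "overlap_genes": sorted(self.overlap_genes),
            "p_value": self.p_value,
        }


def run_burden_test(
    hits: frozenset[str] | set[str],
    universe: frozenset[str] | set[str],
    curated: CuratedGeneList,
    n_hits_override: int | None = None,
) -> OverlapTestResult:
    """Burden test of a curated list against the collapsing-analysis hits.

    Curated genes absent from the universe were never testable and are dropped
    from K (logged).  ``n_hits_override`` substitutes an externally fixed hit
    count for |hits| in the draw size — used to replicate a published
    configuration whose exact hit list is not recoverable — while the overlap
    k is still counted from the supplied ``hits``.
    """
    universe = frozenset(universe)
    if not universe:
        raise ValueError("empty gene universe")
    hits = frozenset(hits)
    if not hits <= universe:
        raise ValueError("hit genes must lie within the universe")

    curated_in = frozenset(curated.members) & universe
    dropped = len(curated.members) - len(curated_in)
    if dropped:
        logger.info("%d curated genes outside the universe dropped from K", dropped)
    if not curated_in:
        raise ValueError("curated list is disjoint from the gene universe")

    overlap = curated_in & hits
    n = len(hits) if n_hits_override is None else int(n_hits_override)
    result = OverlapTestResult(
        universe_N=len(universe),
        list_K=len(curated_in),
        hits_n=n,
        overlap_k=len(overlap),
        overlap_genes=overlap,
        p_value=hypergeom_upper_tail(len(universe), len(curated_in), n, len(overlap)),
    )
    logger.info(
        "burden test: N=%d K=%d n=%d k=%d p=%.3g",
        result.universe_N,
        result.list_K,
        result.hits_n,
        result.overlap_k,
        result.p_value,
    )
    return result
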