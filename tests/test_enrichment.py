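"""Over-representation analysis, BH adjustment and the exclusivity comparison."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

from rarecollapse.burden import hypergeom_upper_tail
from rarecollapse.cohort import GeneSet
from rarecollapse.enrichment import bh_adjust, enrich, exclusivity
from tests.test_burden import upper_tail_oracle


def test_bh_hand_computed_cases():
    assert bh_adjust([0.5]) == pytest.approx([0.5])
    assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)
    assert bh_adjust([0.2, 0.2, 0.2]) == pytest.approx([0.2] * 3)
    # order must not matter beyond the pairing of inputs to outputs
    assert bh_adjust([0.04, 0.01, 0.03, 0.02]) == pytest.approx([0.04] * 4)


def test_bh_rejects_invalid_pvalues():
    with pytest.raises(ValueError):
        bh_adjust([0.5, 1.5])
    with pytest.raises(ValueError):
        bh_adjust([-0.1])


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=30))
def test_bh_properties_and_statsmodels_agreement(pvals):
    adjusted = bh_adjust(pvals)
    assert np.all(adjusted >= np.asarray(pvals) - 1e-15)  # pointwise >= nominal
    assert np.all(adjusted <= 1.0)
    order = np.argsort(pvals, kind="stable")
    assert np.all(np.diff(adjusted[order]) >= -1e-12)  # step-up monotone
    # re-application never lowers a value (the procedure is not idempotent)
    assert np.all(bh_adjust(adjusted) >= adjusted - 1e-15)
    reference = multipletests(pvals, method="fdr_bh")[1]
    assert adjusted == pytest.approx(reference, abs=1e-12)


def test_bh_is_not_idempotent():
    """Re-adjusting adjusted values inflates them: a documented property."""
    adjusted = bh_adjust([0.25, 1.0])
    assert adjusted == pytest.approx([0.5, 1.0])
    assert bh_adjust(adjusted) == pytest.approx([1.0, 1.0])
    assert multipletests([0.5, 1.0], method="fdr_bh")[1] == pytest.approx([1.0, 1.0])


def _set(term, members, category="Pathway"):
    return GeneSet(term, term, category, frozenset(members))


def test_enrich_degenerate_query_equals_universe():
    universe = {"A", "B", "C"}
    res = enrich(universe, [_set("S", universe)], universe)
    assert res.loc[0, "nominal_p"] == 1.0  # overlap forced, no surprise


def test_enrich_matches_enumeration_oracle_on_small_universes():
    rng = np.random.default_rng(3)
    universe = [f"G{i}" for i in range(20)]
    for _ in range(20):
        set_members = rng.choice(universe, size=rng.integers(1, 10), replace=False)
        query = rng.choice(universe, size=rng.integers(1, 10), replace=False)
        res = enrich(query, [_set("S", set_members)], universe)
        overlap = len(set(set_members) & set(query))
        expected = upper_tail_oracle(20, len(set(set_members)), len(set(query)), overlap)
        assert res.loc[0, "nominal_p"] == pytest.approx(expected, abs=1e-12)


def test_enrich_adjusts_within_category_and_sorts():
    universe = [f"G{i}" for i in range(50)]
    query = universe[:10]
    sets = [
        _set("HIT", universe[:10], "Pathway"),  # perfect overlap
        _set("P2", universe[30:40], "Pathway"),
        _set("MF1", universe[20:30], "GO:MF"),
    ]
    res = enrich(query, sets, universe)
    assert list(res["term_id"])[0] == "HIT"
    by_term = res.set_index("term_id")
    # BH within category: the lone GO:MF term keeps its nominal p
    assert by_term.loc["MF1", "adjusted_p"] == pytest.approx(by_term.loc["MF1", "nominal_p"])
    # two Pathway terms: the worse one is adjusted against m=2
    assert by_term.loc["P2", "adjusted_p"] == pytest.approx(
        min(1.0, by_term.loc["P2", "nominal_p"]), abs=1e-12
    )
    assert (res["adjusted_p"] >= res["nominal_p"] - 1e-15).all()


def test_enrich_drops_out_of_universe_terms_and_query_genes():
    universe = {"A", "B"}
    res = enrich({"A", "ZZ"}, [_set("IN", {"A"}), _set("OUT", {"QQ"})], universe)
    assert list(res["term_id"]) == ["IN"]
    assert res.loc[0, "query_size_in_universe"] == 1


def test_enrich_requires_universe():
    with pytest.raises(ValueError, match="empty"):
        enrich({"A"}, [_set("S", {"A"})], set())


def test_enrich_null_queries_are_calibrated():
    """Random queries yield a roughly uniform nominal-p distribution."""
    rng = np.random.default_rng(5)
    universe = [f"G{i}" for i in range(200)]
    sets = [
        _set(f"S{j}", rng.choice(universe, size=30, replace=False)) for j in range(10)
    ]
    pvals = []
    for _ in range(50):
        query = rng.choice(universe, size=40, replace=False)
        res = enrich(query, sets, universe)
        pvals.extend(res["nominal_p"])
    frac = np.mean(np.asarray(pvals) < 0.05)
    # the discrete upper-tail test is conservative; allow Monte-Carlo slack
    assert frac <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / len(pvals))


def _results(rows):
    return pd.DataFrame(rows, columns=["term_id", "adjusted_p"])


def test_exclusivity_verdicts():
    case = _results([("ONLYCASE", 0.01), ("SHARED", 0.01), ("SYNTOO", 0.01), ("WEAK", 0.5)])
    control = _results([("SHARED", 0.02), ("ONLYCASE", 0.7)])
    synonymous = _results([("SYNTOO", 0.03)])
    verdicts = exclusivity(case, control, synonymous).set_index("term_id")
    assert verdicts.loc["ONLYCASE", "exclusive"]
    assert not verdicts.loc["SHARED", "exclusive"]  # enriched in controls too
    assert not verdicts.loc["SYNTOO", "exclusive"]  # synonymous comparator fires
    assert not verdicts.loc["WEAK", "exclusive"]  # not enriched in cases at all
    # a term absent from a comparison collection counts as not enriched there
    assert not verdicts.loc["ONLYCASE", "enriched_in_synonymous"]
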