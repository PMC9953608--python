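"""Carrier collapsing, the exact Fisher test and the homozygous-burden comparison."""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import fisher_exact

from rarecollapse.cohort import SampleRecord, VariantRecord
from rarecollapse.collapsing import (
    CASE_ENRICHED,
    CONTROL_ENRICHED,
    CarrierMatrix,
    build_carrier_matrix,
    compare_homozygous_burden,
    fisher_two_sided,
    homozygous_counts,
    run_gca,
)
from rarecollapse.pipeline import PUBLISHED_COUNTS


def fisher_oracle(a: int, b: int, c: int, d: int) -> float:
    """Exhaustive minimum-likelihood enumeration in exact rational arithmetic."""
    n_top, k_carriers, total = a + b, a + c, a + b + c + d
    p_obs = Fraction(comb(k_carriers, a) * comb(total - k_carriers, n_top - a))
    p_sum = Fraction(0)
    for k in range(max(0, n_top - (total - k_carriers)), min(k_carriers, n_top) + 1):
        p_k = Fraction(comb(k_carriers, k) * comb(total - k_carriers, n_top - k))
        if p_k <= p_obs:
            p_sum += p_k
    return float(p_sum / comb(total, n_top))


@st.composite
def small_tables(draw):
    total = draw(st.integers(min_value=2, max_value=60))
    n_top = draw(st.integers(min_value=1, max_value=total - 1))
    k = draw(st.integers(min_value=0, max_value=total))
    a = draw(st.integers(min_value=max(0, n_top - (total - k)), max_value=min(k, n_top)))
    return a, n_top - a, k - a, (total - n_top) - (k - a)


@settings(max_examples=300, deadline=None, derandomize=True)
@given(small_tables())
def test_fisher_matches_enumeration_oracle(table):
    a, b, c, d = table
    assert fisher_two_sided(a, b, c, d) == pytest.approx(fisher_oracle(a, b, c, d), abs=1e-12)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(small_tables())
def test_fisher_group_swap_symmetry_and_scipy_agreement(table):
    a, b, c, d = table
    p = fisher_two_sided(a, b, c, d)
    assert p == pytest.approx(fisher_two_sided(c, d, a, b), abs=1e-12)
    assert p == pytest.approx(fisher_exact([[a, b], [c, d]])[1], rel=1e-9)


def test_fisher_degenerate_and_invalid_tables():
    assert fisher_two_sided(0, 35, 0, 38) == 1.0
    assert fisher_two_sided(2, 33, 1, 37) == pytest.approx(fisher_oracle(2, 33, 1, 37), abs=1e-12)
    with pytest.raises(ValueError):
        fisher_two_sided(-1, 2, 3, 4)
    with pytest.raises(ValueError):
        fisher_two_sided(0, 0, 3, 4)


def test_published_carrier_tables_reproduce_printed_pvalues():
    """Every printed per-gene 2x2 table reproduces its p-value at 4 decimals."""
    table = pd.read_csv(PUBLISHED_COUNTS, sep="\t")
    assert len(table) == 39
    for _, r in table.iterrows():
        p = fisher_two_sided(
            r["cases_with"], r["cases_without"], r["controls_with"], r["controls_without"]
        )
        assert round(p, 4) == pytest.approx(r["published_p"], abs=1e-12), r["gene"]


SAMPLES = [
    SampleRecord("CA1", "case"),
    SampleRecord("CA2", "case"),
    SampleRecord("CA3", "case"),
    SampleRecord("CA4", "case"),
    SampleRecord("CO1", "control"),
    SampleRecord("CO2", "control"),
    SampleRecord("FAIL", "control", qc_pass=False),
]


def _v(pos, gene, gts):
    return VariantRecord("1", pos, "A", "G", gene_symbol=gene, consequence="missense", genotypes=gts)


def test_carrier_matrix_binary_coding_and_qc_restriction():
    variants = [
        _v(1, "G1", {"CA1": 1, "CA2": 0, "FAIL": 2}),
        _v(2, "G1", {"CA1": 2, "CO1": 1}),  # second variant in the same carrier
        _v(3, "G1", {"CA1": 1}),
        _v(4, "G2", {"CA3": None, "CO2": 1}),  # missing genotype is non-carrier
    ]
    m = build_carrier_matrix(variants, SAMPLES)
    assert list(m.matrix.columns) == ["CA1", "CA2", "CA3", "CA4", "CO1", "CO2"]
    assert m.matrix.loc["G1", "CA1"] == 1  # three variants still one carrier flag
    assert m.matrix.loc["G1", "CO1"] == 1
    assert m.matrix.loc["G2", "CA3"] == 0
    assert "FAIL" not in m.matrix.columns
    assert m.n_cases == 4 and m.n_controls == 2


def test_carrier_matrix_empty_variants():
    m = build_carrier_matrix([], SAMPLES)
    assert m.matrix.empty
    assert run_gca(m).table.empty


def test_carrier_matrix_rejects_non_binary():
    bad = pd.DataFrame([[2]], index=["G1"], columns=["CA1"])
    with pytest.raises(ValueError, match="0/1"):
        CarrierMatrix(matrix=bad, groups={"CA1": "case"})


def test_run_gca_ranking_directions_and_universe():
    variants = [
        _v(1, "STRONG", {"CA1": 1, "CA2": 1, "CA3": 1, "CA4": 1}),
        _v(2, "WEAK", {"CA1": 1, "CO1": 1}),
        _v(3, "CTRLSIDE", {"CO1": 1, "CO2": 1}),
        _v(4, "SILENT", {"FAIL": 1}),  # carriers only in a QC-failed sample
    ]
    res = run_gca(build_carrier_matrix(variants, SAMPLES), alpha=0.2)
    assert res.universe == {"STRONG", "WEAK", "CTRLSIDE", "SILENT"}
    assert list(res.table["gene"])[0] == "STRONG"  # lowest p first
    assert set(res.table["gene"]) == {"STRONG", "WEAK", "CTRLSIDE"}  # SILENT untestable
    directions = dict(zip(res.table["gene"], res.table["direction"]))
    assert directions["STRONG"] == CASE_ENRICHED
    assert directions["CTRLSIDE"] == CONTROL_ENRICHED
    assert res.hits <= {"STRONG", "WEAK"}  # control-enriched genes never hit
    a_row = res.table.set_index("gene").loc["STRONG"]
    assert a_row["cases_with"] + a_row["cases_without"] == 4


def test_gca_type_i_error_under_global_null():
    """With no planted effect, the nominal hit fraction stays near or below alpha."""
    rng = np.random.default_rng(11)
    n_genes, n_cases, n_controls = 400, 35, 38
    samples = [SampleRecord(f"CA{i}", "case") for i in range(n_cases)] + [
        SampleRecord(f"CO{i}", "control") for i in range(n_controls)
    ]
    carrier = rng.random((n_genes, len(samples))) < 0.05
    matrix = pd.DataFrame(
        carrier.astype(np.int8),
        index=[f"G{i}" for i in range(n_genes)],
        columns=[s.sample_id for s in samples],
    )
    m = CarrierMatrix(matrix=matrix, groups={s.sample_id: s.group for s in samples})
    res = run_gca(m)
    frac = (res.table["p_value"] < 0.05).mean()
    # Fisher is conservative at this n; allow Monte-Carlo slack above alpha
    assert frac <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / len(res.table))


def rank_sum_permutation_oracle(x, y, n_perm=10000, seed=0):
    """Two-sided permutation p-value of the rank-sum statistic."""
    rng = np.random.default_rng(seed)
    pooled = np.concatenate([x, y])
    ranks = pd.Series(pooled).rank().to_numpy()
    observed = ranks[: len(x)].sum()
    mu = ranks.mean() * len(x)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(ranks)
        if abs(perm[: len(x)].sum() - mu) >= abs(observed - mu) - 1e-9:
            count += 1
    return count / n_perm


def _stratified_variants(counts_by_sample):
    variants = []
    pos = 1
    for sid, k in counts_by_sample.items():
        for j in range(k):
            variants.append(
                VariantRecord(
                    "1", pos, "A", "G", gene_symbol=f"HG{pos}",
                    consequence="missense", genotypes={sid: 2},
                )
            )
            pos += 1
    return variants


def test_homozygous_counts_and_rank_test_against_permutation_oracle():
    # minority stratum: counts {1,1,1,1,1,1,2}; majority: 27 samples with 19 total
    minority = {f"M{i}": 1 for i in range(6)} | {"M6": 2}
    majority_counts = [1] * 11 + [2] * 4 + [0] * 12  # sums to 19 over 27 samples
    majority = {f"J{i}": c for i, c in enumerate(majority_counts)}
    samples = [SampleRecord(sid, "case", "IRN") for sid in minority] + [
        SampleRecord(sid, "case", "ITA") for sid in majority
    ]
    variants = _stratified_variants(minority | majority)

    per_sample = homozygous_counts(variants, list(minority) + list(majority))
    assert sum(per_sample[s] for s in minority) == 8
    assert sum(per_sample[s] for s in majority) == 19

    res = compare_homozygous_burden(variants, samples)
    assert res.strata == ("IRN", "ITA")
    assert res.totals == {"IRN": 8, "ITA": 19}
    oracle_p = rank_sum_permutation_oracle(
        np.array(res.counts["IRN"]), np.array(res.counts["ITA"])
    )
    assert res.p_value == pytest.approx(oracle_p, abs=0.05)


def test_homozygous_burden_identical_strata_not_significant():
    minority = {f"M{i}": 1 for i in range(5)}
    majority = {f"J{i}": 1 for i in range(5)}
    samples = [SampleRecord(sid, "case", "IRN") for sid in minority] + [
        SampleRecord(sid, "case", "ITA") for sid in majority
    ]
    res = compare_homozygous_burden(_stratified_variants(minority | majority), samples)
    assert res.p_value > 0.9  # identical count vectors: no detectable difference


def test_homozygous_burden_requires_two_nonempty_strata():
    samples = [SampleRecord("M0", "case", "IRN")]
    with pytest.raises(ValueError, match="two strata"):
        compare_homozygous_burden([], samples)
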