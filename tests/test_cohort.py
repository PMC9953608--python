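"""Readers, variant normalization and round-trips."""

from __future__ import annotations

import pytest

from rarecollapse.cohort import (
    CohortMismatchError,
    GmtFormatError,
    SampleRecord,
    VariantRecord,
    VcfParseError,
    normalize_consequence,
    read_annotation_tsv,
    read_gene_list,
    read_gmt,
    read_sample_sheet,
    read_vcf,
    write_annotation_tsv,
    write_sample_sheet,
)
from tests.conftest import write_vcf

SHEET = [SampleRecord(f"S{i}", "case" if i < 2 else "control", "ITA") for i in range(4)]
IDS = [s.sample_id for s in SHEET]


def test_sample_sheet_roundtrip(tmp_path):
    path = tmp_path / "samples.tsv"
    write_sample_sheet(SHEET, path)
    back = read_sample_sheet(path)
    assert [(s.sample_id, s.group, s.subpopulation) for s in back] == [
        (s.sample_id, s.group, s.subpopulation) for s in SHEET
    ]


def test_sample_sheet_rejects_duplicates(tmp_path):
    path = tmp_path / "samples.tsv"
    path.write_text("sample_id\tgroup\tsubpopulation\nS1\tcase\tITA\nS1\tcase\tITA\n")
    with pytest.raises(ValueError, match="duplicate"):
        read_sample_sheet(path)


def test_sample_group_validated():
    with pytest.raises(ValueError, match="group"):
        SampleRecord("S1", "patient")


def test_variant_normalization_rules():
    v = VariantRecord("1", 100, "A", "G", population_af=0.0)
    assert v.population_af is None  # recorded AF of 0 means absent
    with pytest.raises(ValueError):
        VariantRecord("1", 0, "A", "G")
    with pytest.raises(ValueError):
        VariantRecord("1", 100, "A", "A")


@pytest.mark.parametrize(
    "term, expected",
    [
        ("missense_variant", "missense"),
        ("stop_gain", "stop_gained"),
        ("stop_loss", "stop_lost"),
        ("splice_donor_variant&intron_variant", "splice_donor"),
        ("intergenic_variant", "other"),
    ],
)
def test_consequence_normalization(term, expected):
    assert normalize_consequence(term) == expected


def _annotation(tmp_path, rows):
    path = tmp_path / "ann.tsv"
    header = "chrom\tpos\tref\talt\tgene\tconsequence\tgnomad_af\tcadd_phred\n"
    path.write_text(header + "".join("\t".join(map(str, r)) + "\n" for r in rows))
    return path


def test_read_vcf_biallelic_site(tmp_path):
    vcf = write_vcf(
        tmp_path / "a.vcf",
        ["12\t48377883\t.\tG\tT\t100\tPASS\t.\tGT\t0/1\t0/0\t0/0\t0/0"],
        IDS,
    )
    ann = _annotation(tmp_path, [("12", 48377883, "G", "T", "COL2A1", "missense", "7.16e-6", 28)])
    records = read_vcf(vcf, SHEET, ann)
    assert len(records) == 1
    v = records[0]
    assert len(v.genotypes) == 4
    assert v.genotypes["S0"] == 1 and v.genotypes["S1"] == 0
    assert v.gene_symbol == "COL2A1"
    assert v.population_af == pytest.approx(7.16e-6)


def test_read_vcf_splits_multiallelic_and_conserves_alt_count(tmp_path):
    vcf = write_vcf(
        tmp_path / "a.vcf",
        [
            "12\t100\t.\tG\tA,T\t100\tPASS\t.\tGT\t0/1\t0/2\t1/2\t./.",
            "12\t200\t.\tC\tT\t100\tLowQual\t.\tGT\t0/0\t0/0\t0/0\t0/1",
        ],
        IDS,
    )
    records = read_vcf(vcf, SHEET, annotations={})
    assert len(records) == 3  # 2 alts + 1 biallelic
    first, second = records[0], records[1]
    assert (first.chrom, first.pos, first.ref) == (second.chrom, second.pos, second.ref)
    assert {first.alt, second.alt} == {"A", "T"}
    # per-alt dosages: S0 carries A only, S1 carries T only, S2 both, S3 missing
    by_alt = {r.alt: r for r in records[:2]}
    assert by_alt["A"].genotypes == {"S0": 1, "S1": 0, "S2": 1, "S3": None}
    assert by_alt["T"].genotypes == {"S0": 0, "S1": 1, "S2": 1, "S3": None}
    assert records[2].filter_status == "LowQual"  # FILTER preserved verbatim


def test_read_vcf_stop_gain_with_zero_population_frequency(tmp_path):
    # a stop-gain scored CADD 46 with printed population frequency 0 is an
    # absent-from-population variant, not a common one
    vcf = write_vcf(
        tmp_path / "a.vcf",
        ["12\t48373812\t.\tG\tA\t100\tPASS\t.\tGT\t0/1\t0/0\t0/0\t0/0"],
        IDS,
    )
    ann = _annotation(tmp_path, [("12", 48373812, "G", "A", "COL2A1", "stop_gain", 0, 46)])
    v = read_vcf(vcf, SHEET, ann)[0]
    assert v.consequence == "stop_gained"
    assert v.population_af is None
    assert v.cadd_phred == 46


def test_read_vcf_record_without_gene_is_kept_as_other(tmp_path):
    vcf = write_vcf(
        tmp_path / "a.vcf",
        ["12\t300\t.\tA\tC\t100\tPASS\t.\tGT\t0/0\t0/0\t0/0\t0/1"],
        IDS,
    )
    records = read_vcf(vcf, SHEET, annotations={})
    assert len(records) == 1
    assert records[0].gene_symbol == "" and records[0].consequence == "other"


def test_read_vcf_unknown_sample_is_cohort_mismatch(tmp_path):
    vcf = write_vcf(
        tmp_path / "a.vcf",
        ["12\t300\t.\tA\tC\t100\tPASS\t.\tGT\t0/0\t0/0\t0/0\t0/0\t0/0"],
        IDS + ["INTRUDER"],
    )
    with pytest.raises(CohortMismatchError, match="INTRUDER"):
        read_vcf(vcf, SHEET, annotations={})


def test_read_vcf_malformed_line_names_line_number(tmp_path):
    vcf = write_vcf(
        tmp_path / "a.vcf",
        [
            "12\t300\t.\tA\tC\t100\tPASS\t.\tGT\t0/0\t0/0\t0/0\t0/0",
            "12\tnot_a_position\t.\tA\tC\t100\tPASS\t.\tGT\t0/0\t0/0\t0/0\t0/0",
        ],
        IDS,
    )
    with pytest.raises(VcfParseError, match="line 8"):
        read_vcf(vcf, SHEET, annotations={})


def test_read_vcf_csq_annotations(tmp_path):
    samples = IDS
    header = [
        "##fileformat=VCFv4.2",
        "##contig=<ID=7,length=160000000>",
        '##INFO=<ID=CSQ,Number=.,Type=String,Description="Consequence annotations. '
        'Format: Allele|SYMBOL|Consequence|gnomAD_AF|CADD_PHRED">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples),
        "7\t42007446\t.\tC\tT\t100\tPASS\tCSQ=T|GLI3|missense_variant|0.007131|27.5\tGT\t0/1\t0/0\t0/0\t0/0",
    ]
    path = tmp_path / "csq.vcf"
    path.write_text("\n".join(header) + "\n")
    v = read_vcf(path, SHEET, annotations=None)[0]
    assert v.gene_symbol == "GLI3"
    assert v.consequence == "missense"
    assert v.population_af == pytest.approx(0.007131)
    assert v.cadd_phred == pytest.approx(27.5)


def test_annotation_sidecar_roundtrip(tmp_path):
    variants = [
        VariantRecord("1", 10, "A", "G", "GENEA", "missense", 1e-4, 23.5),
        VariantRecord("1", 20, "C", "T", "GENEB", "stop_gained", None, 46.0),
        VariantRecord("2", 30, "G", "A", "GENEC", "synonymous", 0.5, None),
    ]
    path = tmp_path / "ann.tsv"
    write_annotation_tsv(variants, path)
    table = read_annotation_tsv(path)
    for v in variants:
        gene, cons, af, cadd = table[v.key]
        assert (gene, cons) == (v.gene_symbol, v.consequence)
        assert af == v.population_af and cadd == v.cadd_phred


def test_read_gmt(tmp_path):
    path = tmp_path / "sets.gmt"
    path.write_text("ECM\tPathway\tCOL2A1\tLAMA3\nMF_SET\tGO:MF: binding\tA\tB\tA\n")
    sets = read_gmt(path)
    assert sets[0].members == frozenset({"COL2A1", "LAMA3"})
    assert sets[0].category == "Pathway"
    assert sets[1].members == frozenset({"A", "B"})  # duplicates collapsed
    assert sets[1].category == "GO:MF"


def test_read_gmt_empty_and_malformed(tmp_path):
    empty = tmp_path / "empty.gmt"
    empty.write_text("")
    assert read_gmt(empty) == []
    bad = tmp_path / "bad.gmt"
    bad.write_text("TERM\tdesc-only\n")
    with pytest.raises(GmtFormatError, match="2 fields"):
        read_gmt(bad)


def test_read_gmt_ecm_receptor_fixture(tmp_path):
    # the ECM-receptor interaction pathway set used downstream has 12 members
    members = "COL2A1 COL4A2 COL5A2 ITGA10 TNN LAMA1 ITGA2B ITGB7 LAMA3 LAMA4 LAMB2 LAMB3".split()
    path = tmp_path / "ecm.gmt"
    path.write_text("M7098\tPathway\t" + "\t".join(members) + "\n")
    (gs,) = read_gmt(path)
    assert len(gs.members) == 12


def test_read_gene_list_normalizes_case(tmp_path):
    path = tmp_path / "genes.txt"
    path.write_text("col2a1\nGLI3\n# comment\n\ngli3\n")
    gl = read_gene_list(path)
    assert gl.members == frozenset({"COL2A1", "GLI3"})
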