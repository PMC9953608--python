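"""Domain types and readers for samples, annotated variants and gene sets.

The atom of the pipeline is :class:`VariantRecord`: one normalized,
single-alt variant site with a gene assignment, a consequence class, a
population allele frequency (``None`` when the variant is absent from the
frequency resource), a CADD PHRED score (``None`` when unscored) and
per-sample alt-allele dosages.

Annotations travel either in a VEP-style ``CSQ`` INFO field or in a sidecar
TSV keyed on ``(chrom, pos, ref, alt)``; the sidecar is the canonical internal
representation and round-trips losslessly.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from cyvcf2 import VCF

logger = logging.getLogger(__name__)

CASE = "case"
CONTROL = "control"

# Normalized consequence classes.
MISSENSE = "missense"
SPLICE_ACCEPTOR = "splice_acceptor"
SPLICE_DONOR = "splice_donor"
STOP_GAINED = "stop_gained"
STOP_LOST = "stop_lost"
SYNONYMOUS = "synonymous"
OTHER = "other"

CONSEQUENCES = frozenset(
    {MISSENSE, SPLICE_ACCEPTOR, SPLICE_DONOR, STOP_GAINED, STOP_LOST, SYNONYMOUS, OTHER}
)

#: Consequence classes counted as protein-altering in the collapsing analysis.
PROTEIN_ALTERING = frozenset(
    {MISSENSE, SPLICE_ACCEPTOR, SPLICE_DONOR, STOP_GAINED, STOP_LOST}
)

# Synonyms seen in VEP/SnpEff-style annotations, mapped onto the normalized classes.
_CONSEQUENCE_ALIASES = {
    "missense": MISSENSE,
    "missense_variant": MISSENSE,
    "splice_acceptor": SPLICE_ACCEPTOR,
    "splice_acceptor_variant": SPLICE_ACCEPTOR,
    "splice_donor": SPLICE_DONOR,
    "splice_donor_variant": SPLICE_DONOR,
    "stop_gained": STOP_GAINED,
    "stop_gain": STOP_GAINED,
    "stop_lost": STOP_LOST,
    "stop_loss": STOP_LOST,
    "synonymous": SYNONYMOUS,
    "synonymous_variant": SYNONYMOUS,
}


class VcfParseError(ValueError):
    """Raised when a VCF body line cannot be parsed; carries the line number."""


class CohortMismatchError(ValueError):
    """Raised when VCF sample columns are not covered by the sample sheet."""


class GmtFormatError(ValueError):
    """Raised for GMT lines with fewer than three fields."""


def normalize_consequence(term: str) -> str:
    """Map an annotation consequence term onto one of the normalized classes.

    Unknown terms map to ``other``.  For comma/ampersand-joined multi-term
    annotations, the first recognized term wins.
    """
    for part in term.replace("&", ",").split(","):
        mapped = _CONSEQUENCE_ALIASES.get(part.strip().lower())
        if mapped is not None:
            return mapped
    return OTHER


@dataclass(frozen=True)
class SampleRecord:
    """One cohort member: id, case/control group, subpopulation, QC flag."""

    sample_id: str
    group: str
    subpopulation: str = ""
    qc_pass: bool = True

    def __post_init__(self) -> None:
        if self.group not in (CASE, CONTROL):
            raise ValueError(f"group must be {CASE!r} or {CONTROL!r}, got {self.group!r}")


@dataclass
class VariantRecord:
    """One normalized single-alt variant site with per-sample dosages.

    ``population_af`` is ``None`` when the variant has no record in the
    population frequency resource; a recorded frequency of exactly 0 is also
    normalized to ``None`` (an AF of 0 means the resource has never observed
    the allele, which is what "absent" means for rarity filtering).
    ``cadd_phred`` is ``None`` when no score is available.  Genotypes map
    sample id -> alt-allele dosage in {0, 1, 2}, or ``None`` for missing calls.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    gene_symbol: str = ""
    consequence: str = OTHER
    population_af: float | None = None
    cadd_phred: float | None = None
    filter_status: str = "PASS"
    genotypes: dict[str, int | None] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref!r}) at {self.chrom}:{self.pos}")
        if self.consequence not in CONSEQUENCES:
            raise ValueError(f"unknown consequence {self.consequence!r}")
        if self.population_af is not None and self.population_af == 0.0:
            self.population_af = None

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    def dosage(self, sample_id: str) -> int | None:
        return self.genotypes.get(sample_id)


@dataclass(frozen=True)
class GeneSet:
    """A named gene set (GMT line): term id, display name, category, members."""

    term_id: str
    term_name: str
    category: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.term_id!r} has no members")


@dataclass(frozen=True)
class CuratedGeneList:
    """A curated disease-relevant gene list, symbols uppercase-normalized."""

    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("curated gene list is empty")


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

SAMPLE_SHEET_COLUMNS = ["sample_id", "group", "subpopulation"]
ANNOTATION_COLUMNS = ["chrom", "pos", "ref", "alt", "gene", "consequence", "gnomad_af", "cadd_phred"]


def read_sample_sheet(path: str | Path) -> list[SampleRecord]:
    """Read a TSV with header ``sample_id, group, subpopulation``."""
    records: list[SampleRecord] = []
    seen: set[str] = set()
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            sid = row["sample_id"].strip()
            if sid in seen:
                raise ValueError(f"duplicate sample_id {sid!r} in sample sheet")
            seen.add(sid)
            records.append(
                SampleRecord(sid, row["group"].strip(), row.get("subpopulation", "").strip())
            )
    return records


def write_sample_sheet(samples: Iterable[SampleRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(SAMPLE_SHEET_COLUMNS)
        for s in samples:
            writer.writerow([s.sample_id, s.group, s.subpopulation])


AnnotationKey = tuple[str, int, str, str]
AnnotationValue = tuple[str, str, float | None, float | None]  # gene, consequence, af, cadd


def _parse_optional_float(text: str) -> float | None:
    text = text.strip()
    if text in ("", ".", "NA", "nan", "ABSENT", "MISSING"):
        return None
    return float(text)


def read_annotation_tsv(path: str | Path) -> dict[AnnotationKey, AnnotationValue]:
    """Read the sidecar annotation TSV keyed on (chrom, pos, ref, alt)."""
    table: dict[AnnotationKey, AnnotationValue] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = set(ANNOTATION_COLUMNS) - set(reader.fieldnames or [])
        if missing:
            raise ValueError(f"annotation TSV missing columns: {sorted(missing)}")
        for row in reader:
            key = (row["chrom"], int(row["pos"]), row["ref"], row["alt"])
            table[key] = (
                row["gene"].strip(),
                normalize_consequence(row["consequence"]),
                _parse_optional_float(row["gnomad_af"]),
                _parse_optional_float(row["cadd_phred"]),
            )
    return table


def write_annotation_tsv(variants: Iterable[VariantRecord], path: str | Path) -> None:
    """Write the sidecar annotation TSV; round-trips with ``read_annotation_tsv``."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(ANNOTATION_COLUMNS)
        for v in variants:
            writer.writerow(
                [
                    v.chrom,
                    v.pos,
                    v.ref,
                    v.alt,
                    v.gene_symbol,
                    v.consequence,
                    "" if v.population_af is None else repr(v.population_af),
                    "" if v.cadd_phred is None else repr(v.cadd_phred),
                ]
            )


def _first_symbol(symbols: str) -> str:
    """Keep the first of several gene symbols (overlapping-gene annotations)."""
    parts = [p for p in symbols.replace(";", ",").split(",") if p.strip()]
    if len(parts) > 1:
        logger.info("multiple gene symbols %r; keeping %r", symbols, parts[0].strip())
    return parts[0].strip() if parts else ""


def _csq_spec(vcf: VCF) -> list[str] | None:
    """Field layout of the CSQ INFO tag, parsed from its header description."""
    try:
        desc = vcf.get_header_type("CSQ").get("Description", "")
    except KeyError:
        return None
    if "Format:" not in desc:
        return None
    return desc.split("Format:", 1)[1].strip().strip('"').split("|")


def _alt_dosages(genotype_rows: Sequence[Sequence[int]], alt_index: int) -> list[int | None]:
    """Per-sample dosage of a given alt allele (1-based index into ALT list).

    A call with all alleles unknown (``./.``) is missing; partially known
    calls count the known alleles only.
    """
    out: list[int | None] = []
    for row in genotype_rows:
        alleles = row[:-1]  # last element is the phasing flag
        known = [a for a in alleles if a >= 0]
        if not known:
            out.append(None)
        else:
            out.append(sum(1 for a in known if a == alt_index))
    return out


def _locate_bad_line(path: str | Path) -> int | None:
    """Best-effort scan for the first malformed body line of a VCF."""
    n_fields = None
    try:
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                if line.startswith("##"):
                    continue
                if line.startswith("#CHROM"):
                    n_fields = len(line.rstrip("\n").split("\t"))
                    continue
                fields = line.rstrip("\n").split("\t")
                if n_fields is not None and len(fields) != n_fields:
                    return lineno
                if len(fields) < 8:
                    return lineno
                try:
                    int(fields[1])
                except ValueError:
                    return lineno
    except OSError:
        return None
    return None


def read_vcf(
    path: str | Path,
    sample_sheet: Sequence[SampleRecord],
    annotations: str | Path | Mapping[AnnotationKey, AnnotationValue] | None = None,
) -> list[VariantRecord]:
    """Read a VCF into normalized :class:`VariantRecord` objects.

    Multi-allelic sites are split into one record per alt allele.  Annotations
    come from a sidecar TSV (path or pre-read mapping) or, when ``annotations``
    is ``None``, from a VEP-style ``CSQ`` INFO field with fields ``SYMBOL``,
    ``Consequence``, ``gnomAD_AF`` and ``CADD_PHRED``.  Records without a gene
    annotation are retained with ``consequence=other``.  FILTER is preserved
    verbatim (cyvcf2 reports a passing FILTER as ``None``; normalized to
    ``"PASS"``).
    """
    sheet_ids = {s.sample_id for s in sample_sheet}
    annot_table: Mapping[AnnotationKey, AnnotationValue] | None
    if annotations is None:
        annot_table = None
    elif isinstance(annotations, (str, Path)):
        annot_table = read_annotation_tsv(annotations)
    else:
        annot_table = annotations

    try:
        vcf = VCF(str(path), gts012=False)
    except Exception as exc:  # htslib parse failure
        lineno = _locate_bad_line(path)
        raise VcfParseError(f"cannot parse VCF {path}" + (f" (line {lineno})" if lineno else "")) from exc

    vcf_samples = list(vcf.samples)
    unknown = set(vcf_samples) - sheet_ids
    if unknown:
        raise CohortMismatchError(
            f"VCF samples absent from the sample sheet: {sorted(unknown)}"
        )

    csq_fields = None if annot_table is not None else _csq_spec(vcf)
    records: list[VariantRecord] = []
    seen_keys: set[AnnotationKey] = set()
    n_missing_gt = 0

    try:
        variant_iter = list(vcf)
    except Exception as exc:
        lineno = _locate_bad_line(path)
        raise VcfParseError(
            f"malformed VCF record in {path}" + (f" (line {lineno})" if lineno else "")
        ) from exc

    for variant in variant_iter:
        genotype_rows = variant.genotypes if vcf_samples else []
        filter_status = variant.FILTER or "PASS"
        for alt_index, alt in enumerate(variant.ALT, start=1):
            key = (variant.CHROM, variant.POS, variant.REF, alt)
            if key in seen_keys:
                raise VcfParseError(f"duplicate normalized variant {key}")
            seen_keys.add(key)

            gene, consequence, af, cadd = "", OTHER, None, None
            if annot_table is not None:
                ann = annot_table.get(key)
                if ann is not None:
                    gene, consequence, af, cadd = ann
            elif csq_fields is not None:
                csq = variant.INFO.get("CSQ")
                if csq:
                    # first CSQ entry for this alt allele
                    for entry in str(csq).split(","):
                        values = dict(zip(csq_fields, entry.split("|")))
                        if "Allele" in values and values["Allele"] != alt:
                            continue
                        gene = _first_symbol(values.get("SYMBOL", ""))
                        consequence = normalize_consequence(values.get("Consequence", ""))
                        af = _parse_optional_float(values.get("gnomAD_AF", ""))
                        cadd = _parse_optional_float(values.get("CADD_PHRED", ""))
                        break
            if gene:
                gene = _first_symbol(gene)
            else:
                consequence = OTHER

            dosages = _alt_dosages(genotype_rows, alt_index)
            n_missing_gt += sum(1 for d in dosages if d is None)
            records.append(
                VariantRecord(
                    chrom=variant.CHROM,
                    pos=variant.POS,
                    ref=variant.REF,
                    alt=alt,
                    gene_symbol=gene,
                    consequence=consequence,
                    population_af=af,
                    cadd_phred=cadd,
                    filter_status=filter_status,
                    genotypes=dict(zip(vcf_samples, dosages)),
                )
            )
    if n_missing_gt:
        logger.info("%d missing genotype calls treated as non-carrier downstream", n_missing_gt)
    return records


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Read a GMT file: term, description, then member symbols, tab-separated.

    The description field doubles as the category when present (the ``Category``
    convention ``"<category>"`` or ``"<category>: <free text>"``); otherwise the
    set is ``uncategorized``.
    """
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GmtFormatError(f"{path}:{lineno}: GMT line has {len(fields)} fields (< 3)")
            term, description = fields[0], fields[1]
            members = []
            seen = set()
            for sym in fields[2:]:
                sym = sym.strip().upper()
                if sym and sym not in seen:
                    seen.add(sym)
                    members.append(sym)
            category = description.split(": ")[0].strip() if description.strip() else "uncategorized"
            sets.append(GeneSet(term, term, category or "uncategorized", frozenset(members)))
    return sets


def write_gmt(sets: Iterable[GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.term_id, s.category, *sorted(s.members)]) + "\n")


def read_gene_list(path: str | Path, name: str | None = None) -> CuratedGeneList:
    """Read a plain-text gene list, one symbol per line, uppercase-normalized."""
    members = set()
    with open(path) as fh:
        for line in fh:
            sym = line.strip().upper()
            if sym and not sym.startswith("#"):
                members.add(sym)
    return CuratedGeneList(name or Path(path).stem, frozenset(members))


def write_gene_list(gene_list: CuratedGeneList, path: str | Path) -> None:
    with open(path, "w") as fh:
        for sym in sorted(gene_list.members):
            fh.write(sym + "\n")


def update_qc(samples: Sequence[SampleRecord], failing: set[str]) -> list[SampleRecord]:
    """Return a copy of the sample list with ``qc_pass`` cleared for ``failing``."""
    return [replace(s, qc_pass=s.sample_id not in failing) for s in samples]
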