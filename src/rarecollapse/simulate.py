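"""Synthetic cohort generator with a ground-truth manifest.

Generates a fully self-contained analysis bundle — VCF with per-sample
genotypes, sidecar annotation TSV, sample sheet, per-gene coverage table, GMT
gene-set collection, curated gene list and a JSON manifest naming every
planted truth — with the statistical structure the pipeline assumes:

* a small two-group exome cohort (default 37 pre-QC cases of which 2 are
  planted to fail sample-level coverage QC, and 38 controls; cases split
  across two subpopulations, the minority one treated as consanguineous);
* ~7,500 genes with a background per-gene carrier probability, a handful of
  planted risk genes with an elevated carrier probability in cases, and
  planted genes violating exactly one coverage-harmonization rule each;
* variant-level dressing (consequence class, population AF, CADD score) drawn
  from mixtures that exercise both filter tiers, plus a synonymous comparator
  stream and deliberate decoy variants that each fail exactly one filter rule;
* a gene-set collection with one planted set built around the risk genes, and
  a curated list mixing the risk genes with decoy genes.

Carrier events are generated at the gene x sample level and then dressed with
variant-level annotations: that is exactly the structure the collapsing
statistic consumes, so the generator is honest about what the analysis
assumes (no linkage, no relatedness, no shared haplotypes).

Everything is a deterministic function of the seed; the same config yields a
byte-identical bundle.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from rarecollapse.cohort import (
    CuratedGeneList,
    GeneSet,
    MISSENSE,
    SPLICE_ACCEPTOR,
    SPLICE_DONOR,
    STOP_GAINED,
    STOP_LOST,
    SYNONYMOUS,
    SampleRecord,
    write_gene_list,
    write_gmt,
)
from rarecollapse.collapsing import fisher_two_sided

_GENE_SPAN = 2000  # bp reserved per gene on the synthetic contig
_BASES = np.array(["A", "C", "G", "T"])

# Coverage harmonization rules a planted uneven gene can violate.
UNEVEN_RULES = ("mean_depth", "frac_ge10x", "sample_lt20x", "group_diff")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Defaults emulate the target cohort: 37 enrolled cases (30 + 7 across two
    subpopulations, 2 planted to fail sample QC leaving 35), 38 controls,
    7,500 analyzable-scale genes, protein-altering consequence mix of 96.9%
    missense / 2.1% stop / 1.0% splice, and ultra-rare frequencies (absent
    from the population resource with probability 0.6, otherwise log-uniform
    on [1e-6, 1e-2]).
    """

    seed: int = 1
    n_cases_prefilter: int = 37
    n_qc_fail_cases: int = 2
    n_controls: int = 38
    n_minority_cases: int = 7  # consanguineous subpopulation size
    majority_label: str = "ITA"
    minority_label: str = "IRN"
    n_genes: int = 7500
    background_carrier_prob: float = 0.01
    n_risk_genes: int = 10
    risk_carrier_prob: float = 0.25
    # protein-altering consequence mix: missense / stop / splice
    missense_frac: float = 0.969
    stop_frac: float = 0.021
    splice_frac: float = 0.010
    synonymous_rate: float = 0.01
    af_absent_prob: float = 0.6
    af_log10_min: float = -6.0
    af_log10_max: float = -2.0
    cadd_ge20_prob: float = 0.6
    extra_variant_rate: float = 0.05  # Poisson rate of additional variants per carrier event
    hom_fraction: float = 0.02  # probability a carrier event is homozygous
    consanguineous_hom_multiplier: float = 2.0
    n_uneven_genes: int = 20
    n_gene_sets: int = 50
    planted_set_extra_genes: int = 10
    curated_list_size: int = 25
    decoy_rate: float = 0.002  # per gene-sample rate of filter-failing decoy variants

    @property
    def n_cases(self) -> int:
        return self.n_cases_prefilter - self.n_qc_fail_cases

    def validate(self) -> None:
        if self.n_risk_genes + self.n_uneven_genes > self.n_genes:
            raise ValueError("more planted genes than genes")
        if self.curated_list_size < self.n_risk_genes:
            raise ValueError("curated list smaller than the planted risk-gene set")
        if self.n_qc_fail_cases >= self.n_cases_prefilter:
            raise ValueError("all cases planted to fail QC")
        if self.n_minority_cases > self.n_cases_prefilter:
            raise ValueError("minority stratum larger than the case cohort")
        for name in (
            "background_carrier_prob",
            "risk_carrier_prob",
            "af_absent_prob",
            "cadd_ge20_prob",
            "hom_fraction",
            "synonymous_rate",
            "decoy_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        mix = self.missense_frac + self.stop_frac + self.splice_frac
        if abs(mix - 1.0) > 1e-9:
            raise ValueError(f"consequence mix sums to {mix}, expected 1")


@dataclass
class Manifest:
    """Ground truth of a generated bundle."""

    config: dict
    samples: dict[str, dict]
    risk_genes: list[str]
    uneven_genes: dict[str, str]  # gene -> violated rule
    qc_fail_samples: list[str]
    curated_decoys: list[str]
    planted_set_id: str
    counts: dict[str, int] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    # per-stream sub-seeds so each file section can be regenerated independently
    return np.random.default_rng([config.seed, stream])


def _gene_names(n: int) -> list[str]:
    return [f"SIMG{i + 1:05d}" for i in range(n)]


def _sample_records(config: SimulationConfig) -> list[SampleRecord]:
    records = []
    n_majority = config.n_cases_prefilter - config.n_minority_cases
    for i in range(config.n_cases_prefilter):
        pop = config.majority_label if i < n_majority else config.minority_label
        records.append(SampleRecord(f"CASE{i + 1:03d}", "case", pop))
    for i in range(config.n_controls):
        records.append(SampleRecord(f"CTRL{i + 1:03d}", "control", config.majority_label))
    return records


def _consequence_probs(config: SimulationConfig) -> tuple[list[str], list[float]]:
    classes = [MISSENSE, STOP_GAINED, STOP_LOST, SPLICE_ACCEPTOR, SPLICE_DONOR]
    probs = [
        config.missense_frac,
        config.stop_frac * 0.9,
        config.stop_frac * 0.1,
        config.splice_frac * 0.5,
        config.splice_frac * 0.5,
    ]
    return classes, probs


def generate(config: SimulationConfig, out_dir: str | Path) -> Manifest:
    """Write the full synthetic bundle to ``out_dir`` and return its manifest.

    Files: ``samples.tsv``, ``cohort.vcf``, ``annotations.tsv``,
    ``coverage.tsv``, ``genesets.gmt``, ``curated_genes.txt``,
    ``manifest.json``.
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    genes = _gene_names(config.n_genes)
    samples = _sample_records(config)
    sample_ids = [s.sample_id for s in samples]
    case_mask = np.array([s.group == "case" for s in samples])
    majority_case_ids = [
        s.sample_id for s in samples if s.group == "case" and s.subpopulation == config.majority_label
    ]
    consang_mask = np.array(
        [s.group == "case" and s.subpopulation == config.minority_label for s in samples]
    )

    # --- planted structure -------------------------------------------------
    layout = _rng(config, 0)
    planted = layout.choice(
        config.n_genes, size=config.n_risk_genes + config.n_uneven_genes, replace=False
    )
    risk_idx = np.sort(planted[: config.n_risk_genes])
    uneven_idx = np.sort(planted[config.n_risk_genes :])
    risk_genes = [genes[i] for i in risk_idx]
    uneven_rules = {
        genes[g]: UNEVEN_RULES[j % len(UNEVEN_RULES)] for j, g in enumerate(uneven_idx)
    }
    qc_fail = sorted(
        layout.choice(majority_case_ids, size=config.n_qc_fail_cases, replace=False).tolist()
    )

    unplanted = sorted(set(range(config.n_genes)) - set(planted.tolist()))
    n_decoy_curated = config.curated_list_size - config.n_risk_genes
    curated_decoys = [
        genes[i] for i in layout.choice(unplanted, size=n_decoy_curated, replace=False)
    ]
    planted_set_extra = [
        genes[i]
        for i in layout.choice(unplanted, size=config.planted_set_extra_genes, replace=False)
    ]

    gene_sets: list[GeneSet] = [
        GeneSet(
            "PLANTED_SET",
            "PLANTED_SET",
            "Pathway",
            frozenset(risk_genes) | frozenset(planted_set_extra),
        )
    ]
    for j in range(config.n_gene_sets):
        size = int(layout.integers(10, 61))
        members = frozenset(genes[i] for i in layout.choice(config.n_genes, size=size, replace=False))
        category = "GO:MF" if j % 2 == 0 else "Pathway"
        gene_sets.append(GeneSet(f"NULLSET{j + 1:03d}", f"NULLSET{j + 1:03d}", category, members))

    # --- carrier events -----------------------------------------------------
    events_rng = _rng(config, 1)
    p = np.full((config.n_genes, len(samples)), config.background_carrier_prob)
    p[np.ix_(risk_idx, np.flatnonzero(case_mask))] = config.risk_carrier_prob
    carrier = events_rng.random(p.shape) < p
    ev_gene, ev_sample = np.nonzero(carrier)

    hom_p = np.where(
        consang_mask[ev_sample],
        min(1.0, config.hom_fraction * config.consanguineous_hom_multiplier),
        config.hom_fraction,
    )
    ev_dosage = np.where(events_rng.random(ev_gene.shape) < hom_p, 2, 1)

    # extra qualifying variants on top of each carrier event
    n_extra = events_rng.poisson(config.extra_variant_rate, size=ev_gene.shape)
    ev_gene = np.concatenate([ev_gene, np.repeat(ev_gene, n_extra)])
    ev_sample = np.concatenate([ev_sample, np.repeat(ev_sample, n_extra)])
    ev_dosage = np.concatenate([ev_dosage, np.ones(int(n_extra.sum()), dtype=int)])
    ev_kind = np.zeros(ev_gene.shape, dtype=int)  # 0 = protein-altering

    # synonymous comparator stream
    syn_rng = _rng(config, 2)
    syn_carrier = syn_rng.random((config.n_genes, len(samples))) < config.synonymous_rate
    sg, ss = np.nonzero(syn_carrier)
    ev_gene = np.concatenate([ev_gene, sg])
    ev_sample = np.concatenate([ev_sample, ss])
    ev_dosage = np.concatenate([ev_dosage, np.ones(sg.shape, dtype=int)])
    ev_kind = np.concatenate([ev_kind, np.full(sg.shape, 1)])  # 1 = synonymous

    # decoys, each failing exactly one filter rule
    decoy_rng = _rng(config, 3)
    decoy = decoy_rng.random((config.n_genes, len(samples))) < config.decoy_rate
    dg, ds = np.nonzero(decoy)
    ev_gene = np.concatenate([ev_gene, dg])
    ev_sample = np.concatenate([ev_sample, ds])
    ev_dosage = np.concatenate([ev_dosage, np.ones(dg.shape, dtype=int)])
    ev_kind = np.concatenate([ev_kind, np.full(dg.shape, 2)])  # 2 = decoy

    # --- variant-level dressing --------------------------------------------
    ann_rng = _rng(config, 4)
    n_var = ev_gene.size
    classes, probs = _consequence_probs(config)
    consequence = np.array(classes)[ann_rng.choice(len(classes), size=n_var, p=probs)]
    consequence[ev_kind == 1] = SYNONYMOUS

    af_absent = ann_rng.random(n_var) < config.af_absent_prob
    af = 10 ** ann_rng.uniform(config.af_log10_min, config.af_log10_max, size=n_var)
    cadd_high = ann_rng.random(n_var) < config.cadd_ge20_prob
    cadd = np.where(
        cadd_high,
        ann_rng.uniform(20.0, 45.0, size=n_var),
        ann_rng.uniform(0.0, 20.0, size=n_var),
    ).round(1)

    filter_status = np.full(n_var, "PASS", dtype=object)
    decoy_pos = np.flatnonzero(ev_kind == 2)
    for j, idx in enumerate(decoy_pos):
        mode = j % 3
        if mode == 0:
            filter_status[idx] = "VQSRTrancheSNP99.90to100.00"
        elif mode == 1:
            af_absent[idx] = False
            af[idx] = 0.05  # too common for either tier
        else:
            consequence[idx] = "other"

    # positions: stable order by (gene, then event order), sequential within gene
    order = np.argsort(ev_gene, kind="stable")
    ev_gene, ev_sample, ev_dosage, ev_kind = (
        ev_gene[order],
        ev_sample[order],
        ev_dosage[order],
        ev_kind[order],
    )
    consequence, af, af_absent, cadd, filter_status = (
        consequence[order],
        af[order],
        af_absent[order],
        cadd[order],
        filter_status[order],
    )
    within = np.zeros(n_var, dtype=int)
    if n_var:
        starts = np.flatnonzero(np.diff(ev_gene, prepend=-1))
        within = np.arange(n_var) - np.repeat(np.arange(n_var)[starts], np.diff(np.append(starts, n_var)))
    pos = ev_gene * _GENE_SPAN + 1 + within

    ref_idx = ann_rng.integers(0, 4, size=n_var)
    alt_idx = (ref_idx + ann_rng.integers(1, 4, size=n_var)) % 4
    ref = _BASES[ref_idx]
    alt = _BASES[alt_idx]

    # --- write the bundle ---------------------------------------------------
    _write_sample_sheet(samples, out / "samples.tsv")
    _write_vcf(
        out / "cohort.vcf",
        sample_ids,
        pos,
        ref,
        alt,
        filter_status,
        ev_sample,
        ev_dosage,
        contig_length=config.n_genes * _GENE_SPAN + _GENE_SPAN,
    )
    _write_annotations(
        out / "annotations.tsv", genes, ev_gene, pos, ref, alt, consequence, af, af_absent, cadd
    )
    _write_coverage(config, out / "coverage.tsv", genes, samples, uneven_rules, qc_fail)
    write_gmt(gene_sets, out / "genesets.gmt")
    write_gene_list(
        CuratedGeneList("curated", frozenset(risk_genes) | frozenset(curated_decoys)),
        out / "curated_genes.txt",
    )

    manifest = Manifest(
        config=dataclasses.asdict(config),
        samples={s.sample_id: {"group": s.group, "subpopulation": s.subpopulation} for s in samples},
        risk_genes=sorted(risk_genes),
        uneven_genes=uneven_rules,
        qc_fail_samples=qc_fail,
        curated_decoys=sorted(curated_decoys),
        planted_set_id="PLANTED_SET",
        counts={
            "n_variants": int(n_var),
            "n_protein_altering": int((ev_kind == 0).sum()),
            "n_synonymous": int((ev_kind == 1).sum()),
            "n_decoys": int((ev_kind == 2).sum()),
        },
    )
    (out / "manifest.json").write_text(manifest.to_json() + "\n")
    return manifest


def _write_sample_sheet(samples, path: Path) -> None:
    from rarecollapse.cohort import write_sample_sheet

    write_sample_sheet(samples, path)


def _write_vcf(
    path: Path,
    sample_ids: list[str],
    pos: np.ndarray,
    ref: np.ndarray,
    alt: np.ndarray,
    filter_status: np.ndarray,
    ev_sample: np.ndarray,
    ev_dosage: np.ndarray,
    contig_length: int,
) -> None:
    header = [
        "##fileformat=VCFv4.2",
        "##source=rarecollapse-simulator",
        f"##contig=<ID=1,length={contig_length}>",
        '##FILTER=<ID=VQSRTrancheSNP99.90to100.00,Description="Low VQSR tranche">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(sample_ids),
    ]
    order = np.argsort(pos, kind="stable")
    gts = {1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("\n".join(header) + "\n")
        for i in order:
            row = ["0/0"] * len(sample_ids)
            row[int(ev_sample[i])] = gts[int(ev_dosage[i])]
            fh.write(
                f"1\t{int(pos[i])}\t.\t{ref[i]}\t{alt[i]}\t100\t{filter_status[i]}\t.\tGT\t"
                + "\t".join(row)
                + "\n"
            )


def _write_annotations(
    path: Path,
    genes: list[str],
    ev_gene: np.ndarray,
    pos: np.ndarray,
    ref: np.ndarray,
    alt: np.ndarray,
    consequence: np.ndarray,
    af: np.ndarray,
    af_absent: np.ndarray,
    cadd: np.ndarray,
) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tref\talt\tgene\tconsequence\tgnomad_af\tcadd_phred\n")
        for i in range(pos.size):
            af_text = "" if af_absent[i] else format(af[i], ".6g")
            fh.write(
                f"1\t{int(pos[i])}\t{ref[i]}\t{alt[i]}\t{genes[int(ev_gene[i])]}\t"
                f"{consequence[i]}\t{af_text}\t{cadd[i]}\n"
            )


def _write_coverage(
    config: SimulationConfig,
    path: Path,
    genes: list[str],
    samples: list[SampleRecord],
    uneven_rules: dict[str, str],
    qc_fail: list[str],
) -> None:
    cov_rng = _rng(config, 5)
    n_genes, n_samples = len(genes), len(samples)
    sample_ids = [s.sample_id for s in samples]
    is_control = np.array([s.group == "control" for s in samples])
    qc_fail_mask = np.array([sid in qc_fail for sid in sample_ids])

    baseline = cov_rng.normal(100.0, 8.0, size=n_genes).clip(min=60.0)
    depth = baseline[:, None] + cov_rng.normal(0.0, 5.0, size=(n_genes, n_samples))
    lt20 = cov_rng.uniform(0.0, 0.08, size=(n_genes, n_samples))
    ge10 = cov_rng.uniform(0.96, 1.0, size=(n_genes, n_samples))

    gene_index = {g: i for i, g in enumerate(genes)}
    controls = np.flatnonzero(is_control)
    for gene, rule in sorted(uneven_rules.items()):
        gi = gene_index[gene]
        if rule == "mean_depth":
            depth[gi, :] = cov_rng.normal(40.0, 3.0, size=n_samples).clip(min=5.0)
        elif rule == "frac_ge10x":
            ge10[gi, :] = cov_rng.uniform(0.80, 0.90, size=n_samples)
        elif rule == "sample_lt20x":
            victim = int(cov_rng.choice(controls))
            lt20[gi, victim] = 0.30
        elif rule == "group_diff":
            depth[gi, is_control] *= 1.3

    # planted sample-QC failures: uniformly poor coverage across all genes
    fail_cols = np.flatnonzero(qc_fail_mask)
    if fail_cols.size:
        depth[:, fail_cols] = cov_rng.normal(30.0, 3.0, size=(n_genes, fail_cols.size)).clip(min=1.0)
        lt20[:, fail_cols] = cov_rng.uniform(0.30, 0.50, size=(n_genes, fail_cols.size))
        ge10[:, fail_cols] = cov_rng.uniform(0.70, 0.90, size=(n_genes, fail_cols.size))

    depth = depth.clip(min=1.0)
    with open(path, "w") as fh:
        fh.write("gene\tsample_id\tmean_depth\tfrac_lt20x\tfrac_ge10x\n")
        for gi, gene in enumerate(genes):
            for sj, sid in enumerate(sample_ids):
                fh.write(
                    f"{gene}\t{sid}\t{depth[gi, sj]:.2f}\t{lt20[gi, sj]:.4f}\t{ge10[gi, sj]:.4f}\n"
                )


def expected_power(
    config: SimulationConfig, alpha: float = 0.05
) -> float:
    """Probability a planted risk gene attains Fisher p < ``alpha``.

    Exact enumeration over the case-carrier count a ~ Binomial(n_cases,
    risk_carrier_prob) and control-carrier count c ~ Binomial(n_controls,
    background_carrier_prob), over the post-QC cohort sizes.  The a = c = 0
    cell is counted as a non-discovery (the gene never enters the matrix).
    """
    config.validate()
    n1, n2 = config.n_cases, config.n_controls
    pa = stats.binom.pmf(np.arange(n1 + 1), n1, config.risk_carrier_prob)
    pc = stats.binom.pmf(np.arange(n2 + 1), n2, config.background_carrier_prob)
    power = 0.0
    for a, wa in enumerate(pa):
        for c, wc in enumerate(pc):
            if a == 0 and c == 0:
                continue
            if fisher_two_sided(a, n1 - a, c, n2 - c) < alpha:
                power += wa * wc
    return float(power)
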