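"""Config-driven end-to-end orchestration.

``run_all`` drives the full analysis over a file bundle — sample QC, coverage
harmonization, tier filtering, collapsing analysis, curated-list burden test,
three-way over-representation analysis — writing every stage artifact plus a
machine-readable report of all exclusion and retention counts.

``counts_mode`` exercises the statistical layer alone from a pre-built
carrier-count table (gene, cases with/without, controls with/without): it
re-tests every row with the exact Fisher test and runs the curated-list
burden test against a stated universe size.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from rarecollapse import burden as burden_mod
from rarecollapse import collapsing, coverage, enrichment, filters
from rarecollapse.cohort import (
    CuratedGeneList,
    read_gene_list,
    read_gmt,
    read_sample_sheet,
    read_vcf,
)

logger = logging.getLogger(__name__)

_FLOAT_FORMAT = "%.6e"  # fixed scientific notation => byte-identical reruns

#: Carrier-count table bundled from the original cleft-palate exome cohort
#: (the printed per-gene 2x2 counts of the nominally significant genes).
PUBLISHED_COUNTS = Path(__file__).parent / "data" / "nscpo_gca_counts.tsv"
#: Published configuration of that cohort's burden test.
PUBLISHED_UNIVERSE_N = 7496
PUBLISHED_CURATED_K = 25
PUBLISHED_HITS_N = 34


@dataclass
class RunConfig:
    """Paths, thresholds and options for an end-to-end run."""

    vcf: Path
    sample_sheet: Path
    annotations: Path
    coverage: Path
    gene_sets: Path
    curated_list: Path
    out_dir: Path
    thresholds: coverage.CoverageThresholds = field(default_factory=coverage.CoverageThresholds)
    max_af: float = filters.DEFAULT_MAX_AF
    min_cadd: float = filters.DEFAULT_MIN_CADD
    alpha_gca: float = 0.05
    alpha_enrichment: float = 0.05
    universe_mode: str = "analyzable"  # or "annotation"
    enrichment_subpopulation: str | None = None
    hits_file: Path | None = None
    n_hits_override: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("vcf", "sample_sheet", "annotations", "coverage", "gene_sets", "curated_list"):
            setattr(self, name, Path(getattr(self, name)))
        self.out_dir = Path(self.out_dir)
        if self.hits_file is not None:
            self.hits_file = Path(self.hits_file)
        if not 0 < self.alpha_gca < 1 or not 0 < self.alpha_enrichment < 1:
            raise ValueError("alpha levels must lie in (0, 1)")
        if self.universe_mode not in ("analyzable", "annotation"):
            raise ValueError(f"unknown universe_mode {self.universe_mode!r}")

    def validate_paths(self) -> None:
        missing = [
            str(p)
            for p in (
                self.vcf,
                self.sample_sheet,
                self.annotations,
                self.coverage,
                self.gene_sets,
                self.curated_list,
            )
            if not Path(p).exists()
        ]
        if self.hits_file is not None and not self.hits_file.exists():
            missing.append(str(self.hits_file))
        if missing:
            raise FileNotFoundError(f"missing input files: {missing}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        thresholds = coverage.CoverageThresholds(**raw.pop("thresholds", {}))
        return cls(thresholds=thresholds, **raw)


def _bundle_config(bundle_dir: str | Path, out_dir: str | Path, **kwargs) -> RunConfig:
    """RunConfig over a simulator bundle directory."""
    b = Path(bundle_dir)
    return RunConfig(
        vcf=b / "cohort.vcf",
        sample_sheet=b / "samples.tsv",
        annotations=b / "annotations.tsv",
        coverage=b / "coverage.tsv",
        gene_sets=b / "genesets.gmt",
        curated_list=b / "curated_genes.txt",
        out_dir=Path(out_dir),
        **kwargs,
    )


def run_all(config: RunConfig) -> dict:
    """Run every stage; write artifacts under ``config.out_dir``; return the report."""
    config.validate_paths()
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"stages": {}}

    # --- sample QC -----------------------------------------------------------
    samples = read_sample_sheet(config.sample_sheet)
    cov = coverage.read_coverage_tsv(config.coverage)
    samples = coverage.sample_qc(cov, samples, config.thresholds)
    failed_samples = sorted(s.sample_id for s in samples if not s.qc_pass)
    passing = [s for s in samples if s.qc_pass]
    report["stages"]["sample_qc"] = {
        "n_samples": len(samples),
        "n_failed": len(failed_samples),
        "failed_samples": failed_samples,
        "n_cases_passing": sum(1 for s in passing if s.group == "case"),
        "n_controls_passing": sum(1 for s in passing if s.group == "control"),
    }

    # --- coverage harmonization ---------------------------------------------
    analyzable, exclusions = coverage.harmonize_genes(cov, samples, config.thresholds)
    exclusions.to_csv(out / "gene_exclusions.tsv", sep="\t", index=False)
    reason_counts = (
        exclusions.loc[exclusions["excluded"], "reason"].value_counts().to_dict()
    )
    report["stages"]["coverage_harmonization"] = {
        "n_genes": int(len(exclusions)),
        "n_analyzable": len(analyzable),
        "n_excluded": int(exclusions["excluded"].sum()),
        "excluded_by_reason": reason_counts,
    }

    # --- variant filtering ---------------------------------------------------
    variants = read_vcf(config.vcf, samples, config.annotations)
    profiles = {
        "permissive": filters.FilterProfile(
            name="permissive", max_af=config.max_af, restrict_to_genes=frozenset(analyzable)
        ),
        "strict": filters.FilterProfile(
            name="strict",
            absent_required=True,
            max_af=None,
            min_cadd=config.min_cadd,
            restrict_to_genes=frozenset(analyzable),
        ),
        "synonymous": filters.synonymous_profile(analyzable),
    }
    filtered: dict[str, list] = {}
    stage = {"n_input_variants": len(variants)}
    for name, profile in profiles.items():
        kept, rejections = filters.apply_filter(variants, profile)
        filtered[name] = kept
        stage[name] = {"n_retained": len(kept), "rejections": dict(rejections)}
    report["stages"]["variant_filtering"] = stage

    # --- collapsing analysis -------------------------------------------------
    matrix = collapsing.build_carrier_matrix(filtered["permissive"], samples)
    gca = collapsing.run_gca(matrix, alpha=config.alpha_gca)
    gca.table.to_csv(out / "gca_results.tsv", sep="\t", index=False, float_format=_FLOAT_FORMAT)
    report["stages"]["gca"] = {
        "universe_size": len(gca.universe),
        "n_tested": int(len(gca.table)),
        "n_nominal_hits": len(gca.hits),
    }

    # --- curated-list burden test --------------------------------------------
    curated = read_gene_list(config.curated_list)
    hits = gca.hits
    if config.hits_file is not None:
        hits = frozenset(read_gene_list(config.hits_file).members) & gca.universe
    burden = burden_mod.run_burden_test(
        hits, gca.universe, curated, n_hits_override=config.n_hits_override
    )
    (out / "burden_test.json").write_text(json.dumps(burden.as_dict(), indent=1) + "\n")
    report["stages"]["burden_test"] = burden.as_dict()

    # --- over-representation analysis ----------------------------------------
    gene_sets = read_gmt(config.gene_sets)
    if config.universe_mode == "annotation":
        universe: frozenset[str] = frozenset().union(*(gs.members for gs in gene_sets))
    else:
        universe = frozenset(analyzable)
    lists = filters.gene_lists_for_enrichment(
        filtered["strict"], filtered["synonymous"], samples, config.enrichment_subpopulation
    )
    results = {}
    for label, query in (
        ("cases", lists.case_genes),
        ("controls", lists.control_genes),
        ("case_synonymous", lists.case_synonymous_genes),
    ):
        res = enrichment.enrich(query, gene_sets, universe, alpha=config.alpha_enrichment)
        res.to_csv(
            out / f"enrichment_{label}.tsv", sep="\t", index=False, float_format=_FLOAT_FORMAT
        )
        results[label] = res
    verdicts = enrichment.exclusivity(
        results["cases"], results["controls"], results["case_synonymous"],
        alpha=config.alpha_enrichment,
    )
    verdicts.to_csv(out / "exclusivity.tsv", sep="\t", index=False)
    report["stages"]["enrichment"] = {
        "query_sizes": {
            "cases": len(lists.case_genes),
            "controls": len(lists.control_genes),
            "case_synonymous": len(lists.case_synonymous_genes),
        },
        "n_terms_scored": int(len(results["cases"])),
        "n_significant_cases": int(results["cases"]["significant"].sum()) if not results["cases"].empty else 0,
        "n_exclusive": int(verdicts["exclusive"].sum()) if not verdicts.empty else 0,
        "exclusive_terms": sorted(verdicts.loc[verdicts["exclusive"], "term_id"]) if not verdicts.empty else [],
    }

    # --- homozygous burden between case subpopulations ------------------------
    case_pops = sorted({s.subpopulation for s in passing if s.group == "case"})
    if len(case_pops) == 2:
        hom = collapsing.compare_homozygous_burden(filtered["permissive"], samples)
        report["stages"]["homozygous_burden"] = {
            "strata": list(hom.strata),
            "totals": hom.totals,
            "n_samples": {k: len(v) for k, v in hom.counts.items()},
            "statistic": hom.statistic,
            "p_value": hom.p_value,
        }

    (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True) + "\n")
    return report


def counts_mode(
    counts_tsv: str | Path = PUBLISHED_COUNTS,
    curated: CuratedGeneList | None = None,
    universe_n: int = PUBLISHED_UNIVERSE_N,
    curated_in_universe_k: int | None = None,
    n_hits_override: int | None = None,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, burden_mod.OverlapTestResult | None]:
    """Exact Fisher re-tests of a carrier-count table, plus the burden test.

    The table needs columns ``gene, cases_with, cases_without, controls_with,
    controls_without``.  Because only counts are available, the universe enters
    as its size ``universe_n`` and the curated-in-universe count defaults to
    the full curated list size; the overlap k is counted between the curated
    list and the case-enriched rows with p < ``alpha``.
    """
    table = pd.read_csv(counts_tsv, sep="\t")
    rows = []
    for _, r in table.iterrows():
        a, b, c, d = (
            int(r["cases_with"]),
            int(r["cases_without"]),
            int(r["controls_with"]),
            int(r["controls_without"]),
        )
        p = collapsing.fisher_two_sided(a, b, c, d)
        if a * (c + d) > c * (a + b):
            direction = collapsing.CASE_ENRICHED
        elif a * (c + d) < c * (a + b):
            direction = collapsing.CONTROL_ENRICHED
        else:
            direction = collapsing.NO_DIRECTION
        rows.append({**r.to_dict(), "p_value": p, "direction": direction})
    result = pd.DataFrame(rows)

    overlap_test = None
    if curated is not None:
        hit_genes = set(
            result.loc[
                (result["p_value"] < alpha) & (result["direction"] == collapsing.CASE_ENRICHED),
                "gene",
            ].str.upper()
        )
        overlap = frozenset(curated.members) & hit_genes
        K = len(curated.members) if curated_in_universe_k is None else curated_in_universe_k
        n = len(hit_genes) if n_hits_override is None else n_hits_override
        overlap_test = burden_mod.OverlapTestResult(
            universe_N=universe_n,
            list_K=K,
            hits_n=n,
            overlap_k=len(overlap),
            overlap_genes=overlap,
            p_value=burden_mod.hypergeom_upper_tail(universe_n, K, n, len(overlap)),
        )
    return result, overlap_test
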