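#!/usr/bin/env python
"""Re-test the published carrier-count table with the exact statistics.

The original cohort's per-gene 2x2 carrier counts (the 39 genes reported at
nominal p < 0.05) are bundled with the package.  This driver recomputes every
Fisher p-value from the counts, compares against the printed values, and runs
the curated-list burden test in the published configuration (universe 7,496
genes, 25 curated genes, 34 nominal hits, overlap {COL2A1, GLI3}).

Writes results/published_counts_retested.tsv and results/published_burden.json.
"""

import json
from pathlib import Path

from rarecollapse.cohort import CuratedGeneList
from rarecollapse.pipeline import PUBLISHED_COUNTS, counts_mode

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    curated = CuratedGeneList("nscpo_relevant", frozenset({"COL2A1", "GLI3"}))
    table, overlap = counts_mode(
        PUBLISHED_COUNTS,
        curated=curated,
        universe_n=7496,
        curated_in_universe_k=25,
        n_hits_override=34,
    )

    out = ROOT / "results"
    out.mkdir(exist_ok=True)
    table.to_csv(out / "published_counts_retested.tsv", sep="\t", index=False,
                 float_format="%.6e")
    (out / "published_burden.json").write_text(json.dumps(overlap.as_dict(), indent=1) + "\n")

    agree = (table["p_value"].round(4) == table["published_p"]).all()
    n_case = (table["direction"] == "case_enriched").sum()
    print(f"{len(table)} published tables re-tested; "
          f"all printed p-values reproduced at 4 decimals: {agree}")
    print(f"direction: {n_case} case-enriched, "
          f"{(table['direction'] == 'control_enriched').sum()} control-enriched (EXO1)")
    print(f"burden test (N={overlap.universe_N}, K={overlap.list_K}, n={overlap.hits_n}, "
          f"k={overlap.overlap_k}, overlap={sorted(overlap.overlap_genes)}): "
          f"p = {overlap.p_value:.4g}")
    print("note: the originally reported value for this configuration is 5.86e-3; "
          "exact enumeration, this implementation and R's phyper all give 5.61e-3")


if __name__ == "__main__":
    main()
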