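#!/usr/bin/env python
"""Generate the default synthetic cohort bundle.

Emulates the study conditions: 37 enrolled cases (2 planted to fail sample
coverage QC, leaving 35) and 38 controls across 7,500 genes, with 10 planted
risk genes (case carrier probability 0.25 vs background 0.01), 20 genes
planted to violate one coverage-harmonization rule each, a planted enriched
gene set and a 25-gene curated list containing the risk genes.

Writes the bundle to scratch/cohort/ (large, regenerable) and a copy of the
ground-truth manifest to results/.
"""

import json
import shutil
import sys
from pathlib import Path

from rarecollapse.simulate import SimulationConfig, expected_power, generate

ROOT = Path(__file__).resolve().parents[1]


def main(seed: int = 1) -> None:
    bundle_dir = ROOT / "scratch" / "cohort"
    config = SimulationConfig(seed=seed)
    manifest = generate(config, bundle_dir)

    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    shutil.copy(bundle_dir / "manifest.json", results / "cohort_manifest.json")

    power = expected_power(config)
    print(f"bundle written to {bundle_dir}")
    print(f"variants: {manifest.counts['n_variants']} "
          f"({manifest.counts['n_protein_altering']} protein-altering, "
          f"{manifest.counts['n_synonymous']} synonymous, "
          f"{manifest.counts['n_decoys']} filter-failing decoys)")
    print(f"planted risk genes: {len(manifest.risk_genes)}; "
          f"expected per-gene detection power at alpha=0.05: {power:.3f}")
    print(f"planted QC failures: {manifest.qc_fail_samples}")
    print(json.dumps({"expected_power": power}, indent=1))


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
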