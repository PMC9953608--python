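"""Shared fixtures: synthetic bundles and small handwritten inputs."""

from __future__ import annotations

import json
from pathlib import Path

import pytest

from rarecollapse import pipeline
from rarecollapse.simulate import SimulationConfig, generate

DEFAULT_SEED = 1


@pytest.fixture(scope="session")
def default_bundle(tmp_path_factory) -> tuple[Path, dict]:
    """Full-size default synthetic bundle (seed 1): the study conditions."""
    out = tmp_path_factory.mktemp("bundle_default")
    generate(SimulationConfig(seed=DEFAULT_SEED), out)
    manifest = json.loads((out / "manifest.json").read_text())
    return out, manifest


@pytest.fixture(scope="session")
def default_run(default_bundle, tmp_path_factory) -> tuple[dict, Path, dict]:
    """End-to-end pipeline report over the default bundle."""
    bundle_dir, manifest = default_bundle
    out = tmp_path_factory.mktemp("run_default")
    report = pipeline.run_all(pipeline._bundle_config(bundle_dir, out))
    return report, out, manifest


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory) -> tuple[Path, dict]:
    """Reduced bundle (300 genes) for fast structural tests."""
    out = tmp_path_factory.mktemp("bundle_small")
    config = SimulationConfig(seed=7, n_genes=300, n_gene_sets=10, n_uneven_genes=8)
    generate(config, out)
    manifest = json.loads((out / "manifest.json").read_text())
    return out, manifest


def write_vcf(path: Path, body_lines: list[str], samples: list[str]) -> Path:
    """Minimal VCF writer for handwritten fixtures."""
    header = [
        "##fileformat=VCFv4.2",
        "##contig=<ID=12,length=60000000>",
        "##contig=<ID=7,length=160000000>",
        '##FILTER=<ID=LowQual,Description="Low quality">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples),
    ]
    path.write_text("\n".join(header + body_lines) + "\n")
    return path
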