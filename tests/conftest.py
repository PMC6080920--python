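"""Shared fixtures: one small synthetic study bundle per test session."""

from __future__ import annotations

from pathlib import Path

import pytest

from mammomics import genome_io
from mammomics.synthetic import SimulationConfig, simulate_study

BUNDLE_SEED = 11


def small_config(seed: int = BUNDLE_SEED, **overrides) -> SimulationConfig:
    """Down-scaled study conditions used throughout the suite."""
    defaults = dict(
        seed=seed,
        n_genes=120,
        n_cpg_background=4000,
        n_peaks=400,
        chrom_length=1_500_000,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def bundle(tmp_path_factory) -> tuple[Path, dict, SimulationConfig]:
    outdir = tmp_path_factory.mktemp("bundle")
    cfg = small_config()
    truth = simulate_study(cfg, outdir)
    return outdir, truth, cfg


@pytest.fixture(scope="session")
def annotation(bundle) -> genome_io.AnnotationSet:
    outdir, _, _ = bundle
    return genome_io.load_annotation(outdir / "genes.tsv", outdir / "cgi.bed")


@pytest.fixture(scope="session")
def methylation(bundle):
    outdir, _, _ = bundle
    return genome_io.read_beta_table(outdir / "methylation.tsv")
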