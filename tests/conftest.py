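"""Shared fixtures: small synthetic studies and toy tracks."""

from __future__ import annotations

import numpy as np
import pytest

from pausekit import (
    CoverageTrack,
    GeneratorConfig,
    GenomicInterval,
    Peak,
    generate_genome,
    simulate_coverage,
)


@pytest.fixture(scope="session")
def small_config() -> GeneratorConfig:
    return GeneratorConfig(
        n_genes=300, chrom_length=4_000_000, seed=11, n_decoys=50
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    """(genes, truth, ctrl tracks, treat tracks) for a 300-gene study."""
    genes, truth = generate_genome(small_config)
    ctrl = simulate_coverage(genes, truth, small_config, "ctrl")
    treat = simulate_coverage(genes, truth, small_config, "treat")
    return genes, truth, ctrl, treat


@pytest.fixture(scope="session")
def small_bundle_dir(tmp_path_factory, small_config):
    from pausekit import generate_bundle

    out = tmp_path_factory.mktemp("bundle")
    paths = generate_bundle(small_config, str(out))
    return paths


def make_track(records, strand="."):
    """Convenience: CoverageTrack from (chrom, start, end, value) tuples."""
    return CoverageTrack.from_records(records, strand=strand)


def make_peak(chrom, start, end, fdr=0.01, score=0.0):
    return Peak(GenomicInterval(chrom, start, end), score, fdr)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
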