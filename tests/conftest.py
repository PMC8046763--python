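"""Shared fixtures: a small synthetic cohort and one full pipeline run."""
from __future__ import annotations

import numpy as np
import pytest

from sescape.synth import simulate_chip_cohort, simulate_expression, simulate_genome
from sescape.types import EnhancerRegion, GenomicInterval


@pytest.fixture(scope="session")
def small_genome():
    """One 5-Mb chromosome with 300 genes (10% TFs)."""
    annotation, chrom_lengths = simulate_genome(
        n_chrom=1, chrom_length_bp=5_000_000, n_genes=300, tf_fraction=0.1, seed=11
    )
    return annotation, chrom_lengths


@pytest.fixture(scope="session")
def small_cohort(small_genome):
    """6+6 ChIP cohort with planted typical enhancers and SEs."""
    annotation, chrom_lengths = small_genome
    tracks, truth = simulate_chip_cohort(annotation, chrom_lengths, seed=11)
    return annotation, tracks, truth


@pytest.fixture(scope="session")
def small_expression(small_cohort):
    """Expression matrix for the small cohort (20+20 samples)."""
    annotation, _, truth = small_cohort
    matrix = simulate_expression(annotation, truth, seed=11)
    return matrix, truth


@pytest.fixture(scope="session")
def cohort_se_calls(small_cohort):
    """Per-sample SE calls on the small cohort."""
    from sescape.enhancers import call_enhancers
    from sescape.secall import call_superenhancers

    annotation, tracks, _ = small_cohort
    calls = {}
    for sid in sorted(tracks):
        regions, _ = call_enhancers(tracks[sid], annotation, seed=0)
        calls[sid] = call_superenhancers(regions, metric="length", sample_id=sid)
    return calls


@pytest.fixture(scope="session")
def cohort_graph(cohort_se_calls):
    from sescape.network import build_similarity_network

    se_sets = {
        sid: [e.interval for e in res.superenhancers]
        for sid, res in cohort_se_calls.items()
    }
    return build_similarity_network(se_sets)


@pytest.fixture(scope="session")
def demo_run(tmp_path_factory):
    """One complete pipeline run on the bundled demo conditions."""
    from sescape.config import PipelineConfig
    from sescape.pipeline import run_all

    out = tmp_path_factory.mktemp("demo") / "run"
    manifest = run_all(PipelineConfig(seed=7), out)
    return out, manifest


def make_enhancers(lengths, gap: int = 1000, chrom: str = "chr1", density: float = 1.0):
    """Non-overlapping EnhancerRegions with the given lengths (test helper)."""
    regions = []
    pos = 0
    for L in lengths:
        L = max(1, int(L))
        iv = GenomicInterval(chrom, pos, pos + L)
        regions.append(EnhancerRegion(iv, density * L, density, max(1, L // 200)))
        pos += L + gap
    return regions


@pytest.fixture
def enhancer_factory():
    return make_enhancers


def balanced_accuracy(truth: np.ndarray, called: np.ndarray) -> float:
    truth = truth.astype(bool)
    called = called.astype(bool)
    sens = called[truth].mean() if truth.any() else 1.0
    spec = (~called[~truth]).mean() if (~truth).any() else 1.0
    return (sens + spec) / 2
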