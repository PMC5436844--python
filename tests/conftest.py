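"""Shared fixtures: the default synthetic locus and full pipeline runs.

Expensive closed-loop runs are session-scoped so the acceptance tests and the
module tests share them.
"""

from __future__ import annotations

import pytest

from microexon.genome_model import extract_mature_cds
from microexon.pipeline import run_all
from microexon.synthetic import (
    LocusConfig,
    build_transcript_set,
    generate_locus,
    naive_model,
)

DEFAULT_SEED = 42


@pytest.fixture(scope="session")
def default_locus():
    """(genome, true 9-exon model, truth) for the default configuration."""
    return generate_locus(LocusConfig(seed=DEFAULT_SEED))


@pytest.fixture(scope="session")
def default_naive(default_locus):
    genome, model, truth = default_locus
    return naive_model(model, truth)


@pytest.fixture(scope="session")
def default_cds(default_locus):
    genome, model, _ = default_locus
    return extract_mature_cds(genome, model)


@pytest.fixture(scope="session")
def default_transcripts(default_locus):
    genome, model, truth = default_locus
    return build_transcript_set(genome, model, truth, world="micro_exon")


@pytest.fixture(scope="session")
def run_micro_exon_world(tmp_path_factory):
    """Full default closed-loop run, micro-exon world (seed 42, 40x, 0.5% error)."""
    outdir = tmp_path_factory.mktemp("run_micro")
    return run_all(
        {"simulate": {"world": "micro_exon"}, "seed": DEFAULT_SEED, "outdir": str(outdir)}
    )


@pytest.fixture(scope="session")
def run_editing_world(tmp_path_factory):
    """Full default closed-loop run, editing world."""
    outdir = tmp_path_factory.mktemp("run_editing")
    return run_all(
        {"simulate": {"world": "editing"}, "seed": DEFAULT_SEED, "outdir": str(outdir)}
    )
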