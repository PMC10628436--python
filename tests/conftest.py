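"""Shared fixtures: small seeded corpora and SAM/FASTA files on disk."""

from __future__ import annotations

import pytest

from dsrnascan.synthetic_data import Corpus, SimulationConfig, simulate_corpus, write_corpus


@pytest.fixture(scope="session")
def small_corpus() -> Corpus:
    """~16 loci, enough reads for parser and feature oracles."""
    return simulate_corpus(SimulationConfig(n_dsrna_loci=8, n_splice_loci=8, seed=7))


@pytest.fixture(scope="session")
def small_corpus_dir(small_corpus, tmp_path_factory):
    out = tmp_path_factory.mktemp("corpus")
    paths = write_corpus(small_corpus, str(out))
    return paths


@pytest.fixture(scope="session")
def training_corpus() -> Corpus:
    """Classifier-scale corpus (~60+60 loci)."""
    return simulate_corpus(SimulationConfig(n_dsrna_loci=60, n_splice_loci=60, seed=21))
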