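"""Shared fixtures: tiny hand-built transcripts and mid-sized simulations."""

from __future__ import annotations

import numpy as np
import pytest

from ribostate import (
    SimulationParams,
    TranscriptModel,
    simulate,
    uniform_weights,
)
from ribostate.codons import SENSE_CODONS, START_CODON


def make_transcript(
    tid: str = "t1",
    n_codons: int = 100,
    utr5: int = 50,
    utr3: int = 50,
    seed: int = 0,
) -> TranscriptModel:
    """Random transcript with ATG + sense codons + TAA, reproducible."""
    rng = np.random.default_rng(seed)
    internal = rng.choice(np.array(SENSE_CODONS), size=n_codons - 2)
    cds = START_CODON + "".join(internal) + "TAA"
    bases = np.array(list("ACGT"))
    seq = (
        "".join(rng.choice(bases, size=utr5))
        + cds
        + "".join(rng.choice(bases, size=utr3))
    )
    return TranscriptModel(tid, seq, utr5, utr5 + len(cds))


def varied_weights(seed: int, sigma: float = 0.5) -> dict[str, float]:
    """Codon-specific lognormal dwell weights, reproducible."""
    rng = np.random.default_rng(seed)
    return {c: float(w) for c, w in zip(SENSE_CODONS, rng.lognormal(0.0, sigma, len(SENSE_CODONS)))}


@pytest.fixture(scope="session")
def small_sim():
    """20 genes, ~500 reads/gene, uniform dwell: quick end-to-end dataset."""
    params = SimulationParams(
        n_genes=20,
        cds_codon_range=(120, 200),
        reads_per_gene_mean=500.0,
        seed=7,
    )
    transcripts, reads, truth = simulate(params)
    return params, transcripts, reads, truth


@pytest.fixture(scope="session")
def noiseless_sim():
    """No UTR background: every tabled-length read should assign cleanly."""
    params = SimulationParams(
        n_genes=10,
        cds_codon_range=(120, 160),
        reads_per_gene_mean=400.0,
        utr_noise_frac=0.0,
        seed=11,
    )
    transcripts, reads, truth = simulate(params)
    return params, transcripts, reads, truth
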