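"""Synthetic transcriptomes and two-state ribosome footprints.

The generator emulates the statistical structure of a two-footprint-size
ribosome-profiling experiment: each elongating ribosome is observed either in
the decoding (non-rotated) state, protecting a large 28–29 nt fragment, or in
the post-peptide-bond (rotated) state, protecting a small 20–22 nt fragment.
Per codon, the expected number of observed footprints in each state is
proportional to a codon-specific dwell weight for that state, so the marginal
(codon, state) counts follow a per-gene multinomial. Reads carry the canonical
5' geometry — ``five_prime = a_site_codon_start − offset`` with the
(length, offset) pairing of the size-class table — plus 3-nt periodicity by
construction, a small uniform UTR background, and optional inhibitor modes:

* ``cycloheximide``: the post state is suppressed (no small footprints) except
  a phenomenological spike of small reads at the start codon;
* ``anisomycin``: the decoding state is suppressed (no large footprints);
* ``three_at``: histidine-codon (CAT/CAC) decoding dwell is multiplied by
  ``three_at_factor``, mimicking His-tRNA depletion;
* ``runoff``: ribosomes are depleted from the first ``runoff_codons`` codons
  with probability proportional to the distance from that boundary.

States are sampled independently per read (no correlated trajectories): the
downstream analysis only consumes marginal per-(codon, state) counts, so
marginal fidelity suffices.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .codons import SENSE_CODONS, START_CODON, STOP_CODONS
from .io import FootprintRead, TranscriptModel

MODES = ("none", "cycloheximide", "anisomycin", "three_at", "runoff")


def uniform_weights(value: float = 1.0) -> dict[str, float]:
    """A dwell-weight map giving every sense codon the same weight."""
    return {c: value for c in SENSE_CODONS}


@dataclass(frozen=True)
class SimulationParams:
    """Parameters of the two-state footprint generator.

    Dwell weights are relative (only ratios matter within a gene);
    ``decode_weight`` governs large-footprint emission, ``post_weight`` small.
    The global small:large balance — left open by the data, since it varied
    between replicates — is set by the overall scale of ``post_weight``
    relative to ``decode_weight`` (defaults are balanced).
    """

    n_genes: int = 100
    cds_codon_range: tuple[int, int] = (120, 400)
    utr5_len: int = 50
    utr3_len: int = 50
    decode_weight: Mapping[str, float] = field(default_factory=uniform_weights)
    post_weight: Mapping[str, float] = field(default_factory=uniform_weights)
    large_length_probs: Mapping[int, float] = field(
        default_factory=lambda: {28: 0.7, 29: 0.3}
    )
    small_length_probs: Mapping[int, float] = field(
        default_factory=lambda: {20: 0.3, 21: 0.4, 22: 0.3}
    )
    offset_probs: Mapping[int, float] = field(
        default_factory=lambda: {15: 0.5, 16: 0.5}
    )
    reads_per_gene_mean: float = 2000.0
    utr_noise_frac: float = 0.01
    mode: str = "none"
    three_at_factor: float = 10.0
    runoff_codons: int = 50
    start_peak_frac: float = 0.05  # cycloheximide-mode small-read mass at codon 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}; expected one of {MODES}")
        if not 0 <= self.utr_noise_frac < 0.05:
            raise ValueError("utr_noise_frac must be in [0, 0.05)")
        for name, probs in (
            ("large_length_probs", self.large_length_probs),
            ("small_length_probs", self.small_length_probs),
            ("offset_probs", self.offset_probs),
        ):
            if abs(sum(probs.values()) - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1")
            if any(p < 0 for p in probs.values()):
                raise ValueError(f"{name} has negative probabilities")
        for name, w in (("decode_weight", self.decode_weight), ("post_weight", self.post_weight)):
            if any(v <= 0 for v in w.values()):
                raise ValueError(f"{name} must be strictly positive")
        lo, hi = self.cds_codon_range
        if not 3 <= lo <= hi:
            raise ValueError("cds_codon_range must satisfy 3 <= min <= max")
        if self.reads_per_gene_mean <= 0:
            raise ValueError("reads_per_gene_mean must be positive")
        if set(self.offset_probs) - {15, 16}:
            raise ValueError("offsets must be 15 or 16")


def simulate_transcriptome(params: SimulationParams) -> dict[str, TranscriptModel]:
    """Generate random transcripts: ATG + sense codons + stop, flanked by UTRs.

    Internal codons are drawn uniformly from the 61 sense codons, which
    guarantees no premature in-frame stop. Reproducible from ``params.seed``.
    """
    rng = np.random.default_rng([params.seed, 0])
    lo, hi = params.cds_codon_range
    sense = np.array(SENSE_CODONS)
    stops = np.array(STOP_CODONS)
    bases = np.array(list("ACGT"))
    models: dict[str, TranscriptModel] = {}
    width = max(4, len(str(params.n_genes)))
    for g in range(params.n_genes):
        n_cod = int(rng.integers(lo, hi + 1))
        internal = rng.choice(sense, size=n_cod - 2)
        cds = START_CODON + "".join(internal) + str(rng.choice(stops))
        utr5 = "".join(rng.choice(bases, size=params.utr5_len))
        utr3 = "".join(rng.choice(bases, size=params.utr3_len))
        tid = f"synth{g:0{width}d}"
        models[tid] = TranscriptModel(
            tid, utr5 + cds + utr3, params.utr5_len, params.utr5_len + len(cds)
        )
    return models


def _mode_weights(
    codons: list[str], params: SimulationParams
) -> tuple[np.ndarray, np.ndarray]:
    """Per-codon decode/post weights for the emitting codons, mode-adjusted."""
    w_dec = np.array([params.decode_weight[c] for c in codons], dtype=float)
    w_post = np.array([params.post_weight[c] for c in codons], dtype=float)
    if params.mode == "cycloheximide":
        w_post = np.zeros_like(w_post)
    elif params.mode == "anisomycin":
        w_dec = np.zeros_like(w_dec)
    elif params.mode == "three_at":
        his = np.isin(np.array(codons), ["CAT", "CAC"])
        w_dec = np.where(his, w_dec * params.three_at_factor, w_dec)
    return w_dec, w_post


def simulate_footprints(
    transcripts: dict[str, TranscriptModel],
    params: SimulationParams,
) -> tuple[list[FootprintRead], pd.DataFrame]:
    """Emit footprint reads from the two-state model, plus a truth table.

    Returns ``(reads, truth)`` where ``truth`` has one row per emitting
    (gene, codon index, state) cell with the expected read share (normalized
    per gene, before UTR noise and runoff thinning). ``truth.attrs`` carries
    ``n_reads_per_gene`` (drawn totals) and ``n_emitted`` for conservation
    checks. Emission support is codon indices 1..n−2: the start codon
    initializes in the P site and stop codons are not decoded by elongating
    ribosomes. Genes too short to place any footprint are skipped with a
    warning row in the log.
    """
    rng = np.random.default_rng([params.seed, 1])
    large_lens = sorted(params.large_length_probs)
    large_p = np.array([params.large_length_probs[l] for l in large_lens])
    small_lens = sorted(params.small_length_probs)
    small_p = np.array([params.small_length_probs[l] for l in small_lens])
    offset21 = sorted(params.offset_probs)
    offset21_p = np.array([params.offset_probs[o] for o in offset21])
    # forced (length -> offset) pairs; 21-mers draw from offset_probs
    forced_offset = {28: 15, 29: 16, 20: 15, 22: 16}

    counts: dict[tuple[str, int, int], int] = {}
    truth_rows: list[tuple[str, int, str, float]] = []
    n_reads_per_gene: dict[str, int] = {}
    n_emitted = 0

    def emit(tid: str, five_prime: int, length: int, n: int) -> int:
        if five_prime < 0:
            return 0
        key = (tid, five_prime, length)
        counts[key] = counts.get(key, 0) + n
        return n

    def draw_length_offset(state: str, n: int) -> list[tuple[int, int, int]]:
        """Split n reads of one state into (length, offset, count) triples."""
        out: list[tuple[int, int, int]] = []
        lens, p = (large_lens, large_p) if state == "decode" else (small_lens, small_p)
        for length, ln in zip(lens, rng.multinomial(n, p)):
            if ln == 0:
                continue
            if length in forced_offset:
                out.append((length, forced_offset[length], int(ln)))
            else:  # 21-mers: either offset keeps the A site in frame
                for off, on in zip(offset21, rng.multinomial(int(ln), offset21_p)):
                    if on:
                        out.append((length, int(off), int(on)))
        return out

    for tid, model in transcripts.items():
        n_cod = model.n_codons
        emit_idx = list(range(1, n_cod - 1))
        # a footprint needs five_prime >= 0: codon 1 start is cds_start + 3
        if not emit_idx or model.codon_start(emit_idx[0]) - 16 < 0:
            import warnings

            warnings.warn(f"{tid}: too short for any valid footprint placement; skipped")
            continue
        codons = [model.codon(i) for i in emit_idx]
        w_dec, w_post = _mode_weights(codons, params)
        w = np.concatenate([w_dec, w_post])
        total_w = w.sum()
        if total_w <= 0:
            continue
        probs = w / total_w
        for j, i in enumerate(emit_idx):
            if probs[j] > 0:
                truth_rows.append((tid, i, "decode", probs[j]))
            if probs[len(emit_idx) + j] > 0:
                truth_rows.append((tid, i, "post", probs[len(emit_idx) + j]))

        n_reads = int(rng.poisson(params.reads_per_gene_mean))
        n_reads_per_gene[tid] = n_reads
        n_utr = int(rng.binomial(n_reads, params.utr_noise_frac)) if n_reads else 0
        n_body = n_reads - n_utr
        n_spike = 0
        if params.mode == "cycloheximide" and n_body:
            n_spike = int(rng.binomial(n_body, params.start_peak_frac))
        cell_counts = rng.multinomial(n_body - n_spike, probs)

        if params.mode == "runoff":
            # thin reads near the start: keep probability i / runoff_codons
            for j, i in enumerate(emit_idx):
                if i < params.runoff_codons and cell_counts[j] + cell_counts[len(emit_idx) + j]:
                    keep = i / params.runoff_codons
                    for col in (j, len(emit_idx) + j):
                        if cell_counts[col]:
                            cell_counts[col] = rng.binomial(cell_counts[col], keep)

        for j, i in enumerate(emit_idx):
            cs = model.codon_start(i)
            for state, n_cell in (
                ("decode", int(cell_counts[j])),
                ("post", int(cell_counts[len(emit_idx) + j])),
            ):
                if n_cell == 0:
                    continue
                for length, offset, n in draw_length_offset(state, n_cell):
                    n_emitted += emit(tid, cs - offset, length, n)

        # cycloheximide start-codon spike: small reads with the start codon in
        # the A-site frame of reference (phenomenological, mechanism unmodeled)
        if n_spike:
            cs0 = model.codon_start(0)
            for length, offset, n in draw_length_offset("post_spike_small", n_spike):
                if cs0 - offset >= 0:
                    n_emitted += emit(tid, cs0 - offset, length, n)

        # uniform UTR background
        state_share_post = w_post.sum() / total_w
        for _ in range(n_utr):
            state = "post" if rng.random() < state_share_post else "decode"
            lens, p = (small_lens, small_p) if state == "post" else (large_lens, large_p)
            length = int(lens[rng.choice(len(lens), p=p)])
            regions = []
            if model.utr5_len >= length:
                regions.append((0, model.utr5_len - length))
            if model.utr3_len >= length:
                regions.append((model.cds_end, len(model) - length))
            if not regions:
                continue
            lo_pos, hi_pos = regions[int(rng.integers(len(regions)))]
            n_emitted += emit(tid, int(rng.integers(lo_pos, hi_pos + 1)), length, 1)

    reads = [
        FootprintRead(tid, fp, length, n)
        for (tid, fp, length), n in sorted(counts.items())
    ]
    truth = pd.DataFrame(truth_rows, columns=["transcript_id", "codon_index", "state", "share"])
    truth.attrs["n_reads_per_gene"] = n_reads_per_gene
    truth.attrs["n_emitted"] = n_emitted
    return reads, truth


def simulate(params: SimulationParams) -> tuple[dict[str, TranscriptModel], list[FootprintRead], pd.DataFrame]:
    """Convenience: transcriptome + footprints + truth table in one call."""
    transcripts = simulate_transcriptome(params)
    reads, truth = simulate_footprints(transcripts, params)
    return transcripts, reads, truth
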