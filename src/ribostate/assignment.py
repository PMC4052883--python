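"""Size-class assignment of footprints to A-site codons.

The ribosome protects two footprint populations: large (28–29 nt, decoding /
non-rotated state) and small (20–22 nt, post-peptide-bond / rotated state).
Both share the same 5' geometry — the 5' end sits 15–16 nt upstream of the
first nucleotide of the A-site codon — and differ at the 3' end (large
footprints extend ~10 nt past the A-site codon, small ones 2–3 nt).

The default size-class table therefore maps:

=======  ========  ======
length   5'offset  class
=======  ========  ======
28       15        large
29       16        large
20       15        small
21       15        small
21       16        small
22       16        small
=======  ========  ======

A read of tabled length is assigned iff exactly one of its candidate A-site
positions (``five_prime + offset``) is a codon start inside the CDS. The two
21-mer offsets differ by 1 and codon starts differ by 3, so at most one can
ever be in frame.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import numpy as np

from .io import FootprintRead, TranscriptModel, read_table

logger = logging.getLogger(__name__)

SizeClass = Literal["small", "large"]

DEFAULT_SIZE_CLASSES: tuple[tuple[int, int, str], ...] = (
    (28, 15, "large"),
    (29, 16, "large"),
    (20, 15, "small"),
    (21, 15, "small"),
    (21, 16, "small"),
    (22, 16, "small"),
)

#: First analyzed codon (0-based): the analysis window starts at the 51st
#: codon to avoid runoff depletion near the start.
WINDOW_START = 50


@dataclass(frozen=True)
class SizeClassTable:
    """Mapping (footprint length, 5' offset) -> size class."""

    entries: tuple[tuple[int, int, str], ...] = DEFAULT_SIZE_CLASSES

    def __post_init__(self) -> None:
        pairs = [(l, o) for l, o, _ in self.entries]
        if len(pairs) != len(set(pairs)):
            raise ValueError("duplicate (length, offset) pairs in size-class table")
        for l, o, c in self.entries:
            if c not in ("small", "large"):
                raise ValueError(f"unknown size class {c!r}")
            if l <= 0 or o < 0:
                raise ValueError(f"invalid size-class entry {(l, o, c)}")

    @property
    def lengths(self) -> set[int]:
        return {l for l, _, _ in self.entries}

    def candidates(self, length: int) -> list[tuple[int, str]]:
        """(offset, class) candidates for a read length."""
        return [(o, c) for l, o, c in self.entries if l == length]

    def offsets(self) -> set[int]:
        return {o for _, o, _ in self.entries}

    def three_prime_extension(self, length: int, offset: int) -> int:
        """Nucleotides a footprint extends past the 3' edge of its A-site codon.

        length − offset − 3: e.g. a 28-mer at offset 15 extends 10 nt past the
        A-site codon, a 20-mer at offset 15 extends 2 nt.
        """
        if (offset, ) not in [(o,) for l, o, _ in self.entries if l == length]:
            raise KeyError(f"({length}, {offset}) not in size-class table")
        return length - offset - 3

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SizeClassTable":
        df = read_table(path)
        return cls(
            tuple(
                (int(r.length), int(r.offset), str(r.size_class))
                for r in df.itertuples(index=False)
            )
        )


@dataclass(frozen=True)
class AssignedFootprint:
    transcript_id: str
    a_site_codon: int  # 0-based codon index from cds_start
    size_class: str
    count: int
    five_prime: int  # retained for mask bookkeeping


@dataclass(frozen=True)
class Rejection:
    reason: str  # length_unclassified | out_of_frame | outside_cds
    count: int


def assign(
    read: FootprintRead,
    model: TranscriptModel,
    table: SizeClassTable | None = None,
) -> AssignedFootprint | Rejection:
    """Resolve one read to a size class and A-site codon, or reject it.

    Pure function. For each (offset, class) row matching the read length, the
    candidate A-site start is ``five_prime + offset``; the read is assigned iff
    exactly one candidate is a codon start within the CDS. Rejection reasons:
    ``length_unclassified`` (length not in table), ``out_of_frame`` (no
    candidate on the codon grid), ``outside_cds`` (in frame but not a CDS
    codon).
    """
    table = table or SizeClassTable()
    cands = table.candidates(read.length)
    if not cands:
        return Rejection("length_unclassified", read.count)
    in_frame = [
        (offset, cls)
        for offset, cls in cands
        if (read.five_prime + offset - model.cds_start) % 3 == 0
    ]
    if not in_frame:
        return Rejection("out_of_frame", read.count)
    # offsets for one length differ by at most 1; codon starts differ by 3,
    # so at most one candidate is in frame
    offset, cls = in_frame[0]
    codon_index = (read.five_prime + offset - model.cds_start) // 3
    if not 0 <= codon_index < model.n_codons:
        return Rejection("outside_cds", read.count)
    return AssignedFootprint(read.transcript_id, codon_index, cls, read.count, read.five_prime)


def assign_reads(
    reads: Iterable[FootprintRead],
    transcripts: dict[str, TranscriptModel],
    table: SizeClassTable | None = None,
) -> tuple[list[AssignedFootprint], Counter]:
    """Assign a collection of reads; returns (assigned, rejection tallies).

    Conservation: total assigned + rejected counts equal total input counts.
    """
    table = table or SizeClassTable()
    assigned: list[AssignedFootprint] = []
    rejected: Counter = Counter()
    for read in reads:
        result = assign(read, transcripts[read.transcript_id], table)
        if isinstance(result, AssignedFootprint):
            assigned.append(result)
        else:
            rejected[result.reason] += result.count
    return assigned, rejected


# ---------------------------------------------------------------------------
# multimapping mask


@dataclass(frozen=True)
class MultimapMask:
    """Transcript positions whose k-mer is not unique in the transcriptome."""

    excluded: frozenset[tuple[str, int]]
    k: int = 20

    def __contains__(self, key: tuple[str, int]) -> bool:
        return key in self.excluded


def build_multimap_mask(
    transcripts: dict[str, TranscriptModel] | Iterable[TranscriptModel],
    k: int = 20,
) -> MultimapMask:
    """Mark every start position of a k-mer occurring >= 2 times (forward strand).

    Mirrors the mapping-based uniqueness filter: the transcriptome is split
    into all overlapping k-mers and any k-mer with more than one exact match
    has all of its start positions excluded. Transcripts shorter than ``k``
    contribute nothing.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    models = list(transcripts.values()) if isinstance(transcripts, dict) else list(transcripts)
    occurrences: dict[str, list[tuple[str, int]]] = defaultdict(list)
    for m in models:
        seq = m.sequence
        for i in range(len(seq) - k + 1):
            occurrences[seq[i : i + k]].append((m.transcript_id, i))
    excluded = frozenset(
        pos for locs in occurrences.values() if len(locs) >= 2 for pos in locs
    )
    return MultimapMask(excluded, k)


# ---------------------------------------------------------------------------
# per-gene codon count matrices


@dataclass
class CodonCountMatrix:
    """Per-codon small/large footprint counts for one gene.

    ``small``/``large`` are raw tallies over all codon indices (stop
    included); ``included`` flags the analyzable cells: inside the window
    [50, n_codons - 3], not multimap-masked, and only for genes passing the
    minimum-footprint filter.
    """

    transcript_id: str
    codons: list[str]
    small: np.ndarray
    large: np.ndarray
    included: np.ndarray

    @property
    def n_codons(self) -> int:
        return len(self.codons)

    def total_included(self) -> int:
        return int((self.small[self.included] + self.large[self.included]).sum())


def analysis_window(n_codons: int, start: int = WINDOW_START) -> tuple[int, int]:
    """Inclusive 0-based codon window [start, n_codons - 3].

    ``n_codons`` counts the stop codon; the window ends at the second codon
    before the stop, i.e. index n_codons - 3 (48 codons for a 100-codon CDS).
    """
    return start, n_codons - 3


def tally(
    assigned: Iterable[AssignedFootprint],
    transcripts: dict[str, TranscriptModel],
    mask: MultimapMask | None = None,
    min_gene_footprints: int = 10,
    window_start: int = WINDOW_START,
) -> dict[str, CodonCountMatrix]:
    """Tally assigned footprints into per-gene CodonCountMatrix objects.

    A codon cell is excluded when outside the analysis window, when either of
    its possible contributing 5'-end positions (codon_start − 15 or − 16) is a
    non-unique k-mer start, or when the gene's total included footprints fall
    below ``min_gene_footprints`` (the filter counts analyzable signal only).
    Excluded genes are reported in the log.
    """
    matrices: dict[str, CodonCountMatrix] = {}
    for tid, model in transcripts.items():
        n = model.n_codons
        lo, hi = analysis_window(n, window_start)
        included = np.zeros(n, dtype=bool)
        if hi >= lo:
            included[lo : hi + 1] = True
        if mask is not None:
            for i in np.nonzero(included)[0]:
                cs = model.codon_start(int(i))
                if (tid, cs - 15) in mask or (tid, cs - 16) in mask:
                    included[i] = False
        matrices[tid] = CodonCountMatrix(
            tid,
            [model.codon(i) for i in range(n)],
            np.zeros(n, dtype=np.int64),
            np.zeros(n, dtype=np.int64),
            included,
        )
    for fp in assigned:
        m = matrices.get(fp.transcript_id)
        if m is None:
            continue
        arr = m.small if fp.size_class == "small" else m.large
        arr[fp.a_site_codon] += fp.count

    dropped = []
    for tid, m in matrices.items():
        if m.total_included() < min_gene_footprints:
            m.included[:] = False
            dropped.append(tid)
    if dropped:
        logger.info(
            "tally: %d gene(s) excluded by <%d-footprint filter: %s",
            len(dropped), min_gene_footprints,
            ", ".join(dropped[:10]) + ("..." if len(dropped) > 10 else ""),
        )
    return matrices
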