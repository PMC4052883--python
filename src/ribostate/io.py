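"""Transcript models, footprint reads, and all file I/O.

Coordinate conventions owned here and used everywhere else:

* transcript coordinates are 0-based, half-open; SAM's 1-based POS is
  converted at the boundary;
* ``cds_start`` is the first nucleotide of the start codon, ``cds_end`` is one
  past the last nucleotide of the stop codon;
* codon index is 0-based from ``cds_start`` and counts the stop codon, so a
  CDS of 300 nt has codons 0..99 with the stop at index 99.

Tables are tab-separated UTF-8 with a single ``#``-prefixed header line and
``.`` as the decimal mark.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import pysam
from pyfaidx import Fasta

logger = logging.getLogger(__name__)


class AnnotationError(ValueError):
    """Malformed CDS coordinates for a named record."""


@dataclass(frozen=True)
class TranscriptModel:
    """One transcript: sequence plus CDS boundaries in transcript coordinates.

    Invariants are enforced at construction: the CDS length is a positive
    multiple of 3 and lies within the sequence. UTR lengths follow from the
    boundaries (5'UTR = ``cds_start``, 3'UTR = ``len(sequence) - cds_end``).
    """

    transcript_id: str
    sequence: str
    cds_start: int
    cds_end: int

    def __post_init__(self) -> None:
        n = len(self.sequence)
        if not (0 <= self.cds_start < self.cds_end <= n):
            raise AnnotationError(
                f"{self.transcript_id}: CDS [{self.cds_start}, {self.cds_end}) "
                f"outside transcript of length {n}"
            )
        cds_len = self.cds_end - self.cds_start
        if cds_len % 3 != 0:
            raise AnnotationError(
                f"{self.transcript_id}: CDS length {cds_len} is not a multiple of 3"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def n_codons(self) -> int:
        """Number of codons in the CDS, stop codon included."""
        return (self.cds_end - self.cds_start) // 3

    @property
    def utr5_len(self) -> int:
        return self.cds_start

    @property
    def utr3_len(self) -> int:
        return len(self.sequence) - self.cds_end

    def codon(self, index: int) -> str:
        """DNA codon at 0-based codon ``index`` from the CDS start."""
        if not 0 <= index < self.n_codons:
            raise IndexError(f"codon index {index} outside [0, {self.n_codons})")
        start = self.cds_start + 3 * index
        return self.sequence[start : start + 3]

    def codon_start(self, index: int) -> int:
        """Transcript coordinate of the first nucleotide of codon ``index``."""
        return self.cds_start + 3 * index


@dataclass(frozen=True)
class FootprintRead:
    """A mapped fragment: transcript, 5'-end position, length, multiplicity."""

    transcript_id: str
    five_prime: int
    length: int
    count: int = 1

    def __post_init__(self) -> None:
        if self.five_prime < 0 or self.length <= 0 or self.count <= 0:
            raise ValueError(f"invalid footprint read {self!r}")


def read_transcriptome(
    fasta_path: str | Path,
    annotation_path: str | Path,
    default_utr: int = 50,
) -> dict[str, TranscriptModel]:
    """Load transcript sequences and CDS annotations into TranscriptModels.

    The annotation is a BED-like TSV with columns ``transcript_id``,
    ``cds_start``, ``cds_end`` (0-based, half-open, transcript coordinates).
    A record whose annotation row has ``cds_start = -1`` is taken to have no
    UTR annotation: its whole FASTA sequence is treated as CDS and
    ``default_utr`` nt of flanking sequence is added on each side, so a 150 nt
    bare CDS with ``default_utr=50`` yields a 250 nt model with
    ``cds_start=50``.

    Records whose CDS length is not a multiple of 3 are reported and dropped;
    FASTA records missing from the annotation are skipped with a warning;
    coordinates outside the sequence raise :class:`AnnotationError`.
    """
    fasta = Fasta(str(fasta_path), as_raw=True, sequence_always_upper=True)
    ann = read_table(annotation_path)
    ann_map = {
        str(r.transcript_id): (int(r.cds_start), int(r.cds_end))
        for r in ann.itertuples(index=False)
    }
    models: dict[str, TranscriptModel] = {}
    for name in fasta.keys():
        seq = str(fasta[name][:])
        if name not in ann_map:
            warnings.warn(f"no annotation for FASTA record {name!r}; skipped")
            continue
        cds_start, cds_end = ann_map[name]
        if cds_start == -1:
            # no UTR annotated: whole record is CDS; add default flanks
            if len(seq) % 3 != 0:
                logger.warning(
                    "dropping %s: CDS length %d not a multiple of 3", name, len(seq)
                )
                continue
            models[name] = pad_cds_only_record(name, seq, default_utr)
            continue
        cds_len = cds_end - cds_start
        if cds_len > 0 and cds_len % 3 != 0:
            logger.warning(
                "dropping %s: CDS length %d not a multiple of 3", name, cds_len
            )
            continue
        models[name] = TranscriptModel(name, seq, cds_start, cds_end)
    return models


def pad_cds_only_record(
    transcript_id: str, cds_sequence: str, default_utr: int = 50, pad_base: str = "N"
) -> TranscriptModel:
    """Build a model from a bare CDS by adding default UTRs of ``default_utr`` nt.

    Used when a transcript has no UTR annotation: flanking sequence of the
    default length is appended on each side so downstream windows (metagene
    UTR panels, footprints hanging off the CDS edge) remain well-defined.
    """
    pad = pad_base * default_utr
    return TranscriptModel(
        transcript_id,
        pad + cds_sequence + pad,
        cds_start=default_utr,
        cds_end=default_utr + len(cds_sequence),
    )


def read_footprints(
    path: str | Path,
    fmt: str = "tsv",
    transcripts: dict[str, TranscriptModel] | None = None,
    on_unknown_reference: str = "warn",
    length_window: tuple[int, int] = (11, 36),
) -> list[FootprintRead]:
    """Read footprint alignments from a TSV or SAM file.

    TSV columns: ``transcript_id``, ``five_prime`` (0-based), ``length``,
    ``count``. SAM alignments must be in transcript coordinates; only primary,
    forward-strand, mapped records are used (length = aligned reference span,
    so soft clips do not count). Identical (transcript, position, length)
    records are aggregated by summing counts. Reads outside ``length_window``
    are dropped. Exclusions are tallied and logged.

    ``on_unknown_reference``: what to do with reads on transcripts absent from
    ``transcripts`` (if given) — ``"warn"`` skips them, ``"error"`` raises.
    """
    if fmt == "tsv":
        raw = _read_footprints_tsv(path)
    elif fmt == "sam":
        raw = _read_footprints_sam(path)
    else:
        raise ValueError(f"unknown footprint format {fmt!r}")

    lo, hi = length_window
    agg: dict[tuple[str, int, int], int] = {}
    excluded = {"unknown_reference": 0, "length_window": 0, "out_of_bounds": 0}
    for tid, fp, length, count in raw:
        if transcripts is not None and tid not in transcripts:
            if on_unknown_reference == "error":
                raise KeyError(f"read maps to unknown transcript {tid!r}")
            excluded["unknown_reference"] += count
            continue
        if not lo <= length <= hi:
            excluded["length_window"] += count
            continue
        if transcripts is not None and fp + length > len(transcripts[tid]):
            excluded["out_of_bounds"] += count
            continue
        agg[(tid, fp, length)] = agg.get((tid, fp, length), 0) + count
    if any(excluded.values()):
        logger.info("read_footprints exclusions: %s", excluded)
    return [
        FootprintRead(tid, fp, length, count)
        for (tid, fp, length), count in sorted(agg.items())
    ]


def _read_footprints_tsv(path: str | Path) -> Iterable[tuple[str, int, int, int]]:
    df = read_table(path)
    for r in df.itertuples(index=False):
        yield str(r.transcript_id), int(r.five_prime), int(r.length), int(r.count)


def _read_footprints_sam(path: str | Path) -> Iterable[tuple[str, int, int, int]]:
    n_skipped = 0
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped or rec.is_reverse or rec.is_secondary or rec.is_supplementary:
                n_skipped += 1
                continue
            span = rec.reference_length  # aligned reference span, soft clips excluded
            if span is None or span <= 0:
                n_skipped += 1
                continue
            yield rec.reference_name, rec.reference_start, span, 1
    if n_skipped:
        logger.info("SAM: excluded %d non-primary/reverse/unmapped records", n_skipped)


# ---------------------------------------------------------------------------
# generic TSV tables


def write_table(rows: pd.DataFrame | Sequence[dict], path: str | Path) -> None:
    """Write a table as TSV with a '#'-prefixed header, sorted by first column.

    Deterministic: the same input always produces byte-identical output.
    """
    df = pd.DataFrame(rows)
    if len(df.columns) == 0:
        raise ValueError("cannot write a table with no columns")
    if len(df) > 0:
        df = df.sort_values(list(df.columns[:1]), kind="mergesort").reset_index(drop=True)
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("#" + "\t".join(map(str, df.columns)) + "\n")
        if len(df) > 0:
            df.to_csv(fh, sep="\t", header=False, index=False, lineterminator="\n")


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV written by :func:`write_table` (header line starts with '#')."""
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise ValueError(f"{path}: expected '#'-prefixed header line")
        names = header.lstrip("#").rstrip("\n").split("\t")
        df = pd.read_csv(fh, sep="\t", names=names, header=None)
    return df


def write_fasta(models: Iterable[TranscriptModel], path: str | Path) -> None:
    """Write transcript sequences as FASTA (60-column wrapping)."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for m in models:
            fh.write(f">{m.transcript_id}\n")
            for i in range(0, len(m.sequence), 60):
                fh.write(m.sequence[i : i + 60] + "\n")


def write_annotation(models: Iterable[TranscriptModel], path: str | Path) -> None:
    """Write the BED-like CDS annotation table for a set of models."""
    write_table(
        [
            {
                "transcript_id": m.transcript_id,
                "cds_start": m.cds_start,
                "cds_end": m.cds_end,
                "length": len(m),
            }
            for m in models
        ],
        path,
    )


def write_reads_tsv(reads: Iterable[FootprintRead], path: str | Path) -> None:
    """Write footprint reads as the simplified TSV interchange format."""
    write_table(
        [
            {
                "transcript_id": r.transcript_id,
                "five_prime": r.five_prime,
                "length": r.length,
                "count": r.count,
            }
            for r in reads
        ],
        path,
    )


def write_sam(
    reads: Iterable[FootprintRead],
    transcripts: dict[str, TranscriptModel],
    path: str | Path,
) -> None:
    """Write reads as transcript-coordinate SAM (one record per unit of count)."""
    order = sorted(transcripts)
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": tid, "LN": len(transcripts[tid])} for tid in order],
    }
    tid_index = {tid: i for i, tid in enumerate(order)}
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for i, r in enumerate(sorted(reads, key=lambda r: (r.transcript_id, r.five_prime, r.length))):
            seq = transcripts[r.transcript_id].sequence[r.five_prime : r.five_prime + r.length]
            for j in range(r.count):
                a = pysam.AlignedSegment()
                a.query_name = f"read_{i}_{j}"
                a.query_sequence = seq
                a.flag = 0
                a.reference_id = tid_index[r.transcript_id]
                a.reference_start = r.five_prime
                a.mapping_quality = 255
                a.cigarstring = f"{r.length}M"
                out.write(a)
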