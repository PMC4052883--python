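"""Metagene grids, frame periodicity, and CDS/UTR partition.

The metagene grid tallies read 5'-end positions by fragment length (11–36 nt)
relative to a common anchor across genes, the standard visualization in which
the two footprint populations appear as distinct bands whose 5' profiles
coincide (both offset 15–16 nt upstream of the A-site codon).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .assignment import SizeClassTable
from .io import FootprintRead, TranscriptModel

LENGTH_MIN = 11
LENGTH_MAX = 36
#: start-anchored window: last 25 nt of 5'UTR through first 200 nt of CDS
START_WINDOW = (-25, 199)
#: stop-anchored window: last 100 nt of CDS through first 50 nt of 3'UTR
STOP_WINDOW = (-100, 49)
MIN_CDS_NT = 300


@dataclass
class MetageneGrid:
    """Counts of read 5' ends by (length, position relative to anchor)."""

    anchor: str  # "start" | "stop"
    lengths: np.ndarray  # 11..36
    positions: np.ndarray
    cells: np.ndarray  # shape (len(lengths), len(positions))

    def to_frame(self) -> pd.DataFrame:
        """Long-format (length, position, count) table."""
        ll, pp = np.meshgrid(self.lengths, self.positions, indexing="ij")
        return pd.DataFrame(
            {"length": ll.ravel(), "position": pp.ravel(), "count": self.cells.ravel()}
        )

    def column_mode(self, length: int) -> int:
        """Position of the maximum for one fragment length."""
        row = self.cells[int(np.nonzero(self.lengths == length)[0][0])]
        return int(self.positions[int(np.argmax(row))])


def metagene_grid(
    reads: Iterable[FootprintRead],
    transcripts: Mapping[str, TranscriptModel],
    anchor: str = "start",
) -> MetageneGrid:
    """Tabulate 11–36 nt footprints around the start or stop codon.

    Only genes with a CDS of at least 300 nt contribute. Each read adds its
    count at (length, five_prime − anchor_position); the anchor is the first
    nucleotide of the start codon or the first nucleotide past the stop codon.
    Additive over disjoint read sets.
    """
    if anchor not in ("start", "stop"):
        raise ValueError("anchor must be 'start' or 'stop'")
    lo, hi = START_WINDOW if anchor == "start" else STOP_WINDOW
    lengths = np.arange(LENGTH_MIN, LENGTH_MAX + 1)
    positions = np.arange(lo, hi + 1)
    cells = np.zeros((len(lengths), len(positions)), dtype=np.int64)
    for r in reads:
        model = transcripts.get(r.transcript_id)
        if model is None or (model.cds_end - model.cds_start) < MIN_CDS_NT:
            continue
        if not LENGTH_MIN <= r.length <= LENGTH_MAX:
            continue
        anchor_pos = model.cds_start if anchor == "start" else model.cds_end
        rel = r.five_prime - anchor_pos
        if lo <= rel <= hi:
            cells[r.length - LENGTH_MIN, rel - lo] += r.count
    return MetageneGrid(anchor, lengths, positions, cells)


def frame_profile(
    reads: Iterable[FootprintRead],
    transcripts: Mapping[str, TranscriptModel],
    lengths: set[int],
) -> dict[int, tuple[float, float, float] | None]:
    """Fraction of CDS-internal read 5' ends in each frame, per length.

    Frame is ``(five_prime − cds_start) mod 3``; only reads whose 5' end lies
    inside the CDS count. Lengths with no reads map to ``None`` rather than
    propagating NaNs.
    """
    if not lengths:
        raise ValueError("lengths must be non-empty")
    tallies = {l: np.zeros(3, dtype=np.int64) for l in lengths}
    for r in reads:
        if r.length not in tallies:
            continue
        model = transcripts.get(r.transcript_id)
        if model is None:
            continue
        if model.cds_start <= r.five_prime < model.cds_end:
            tallies[r.length][(r.five_prime - model.cds_start) % 3] += r.count
    out: dict[int, tuple[float, float, float] | None] = {}
    for l, t in tallies.items():
        total = t.sum()
        out[l] = None if total == 0 else tuple((t / total).tolist())
    return out


def region_partition(
    reads: Iterable[FootprintRead],
    transcripts: Mapping[str, TranscriptModel],
    lengths: set[int],
    table: SizeClassTable | None = None,
) -> dict[int, dict[str, float] | None]:
    """Fraction of reads attributed to 5'UTR / CDS / 3'UTR, per length.

    A read is attributed to the region containing its inferred A-site midpoint
    (``five_prime + offset + 1``) when its length is in the size-class table;
    for 21-mers the in-frame offset is preferred. Unclassifiable lengths use
    the read's own midpoint. Fractions sum to 1 per length.
    """
    if not lengths:
        raise ValueError("lengths must be non-empty")
    table = table or SizeClassTable()
    tallies = {l: {"utr5": 0, "cds": 0, "utr3": 0} for l in lengths}
    for r in reads:
        if r.length not in tallies:
            continue
        model = transcripts.get(r.transcript_id)
        if model is None:
            continue
        cands = table.candidates(r.length)
        if cands:
            offsets = [o for o, _ in cands]
            in_frame = [
                o for o in offsets if (r.five_prime + o - model.cds_start) % 3 == 0
            ]
            offset = in_frame[0] if in_frame else offsets[0]
            point = r.five_prime + offset + 1
        else:
            point = r.five_prime + r.length // 2
        if point < model.cds_start:
            region = "utr5"
        elif point < model.cds_end:
            region = "cds"
        else:
            region = "utr3"
        tallies[r.length][region] += r.count
    out: dict[int, dict[str, float] | None] = {}
    for l, t in tallies.items():
        total = sum(t.values())
        out[l] = None if total == 0 else {k: v / total for k, v in t.items()}
    return out
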