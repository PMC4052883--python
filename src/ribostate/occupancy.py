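"""Per-codon relative occupancy and class-specific footprint abundances.

The central statistic: at each analyzable position *i* of gene *g*, the
over- or under-representation of footprints is

    r_i = (small_i + large_i) / m_g,      m_g = mean over included positions
                                                of (small + large)

and the class-specific abundances use only one class in the numerator,

    s_i = small_i / m_g,   l_i = large_i / m_g,

so r_i = s_i + l_i exactly. Ratios are then averaged, unweighted, over every
included instance of each sense codon across the transcriptome, giving the
relative occupancy (a unitless proxy for the relative time a ribosome spends
with that codon in the A site) and the small/large abundances (relative
durations of the post-peptide-bond and decoding stages).

An occupancy table is a DataFrame indexed by the 61 sense codons with columns
``rel_occupancy``, ``small_abundance``, ``large_abundance``, ``n_positions``.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .assignment import CodonCountMatrix
from .codons import SENSE_CODONS, amino_acid

#: bulk elongation rate used to convert occupancy to predicted time, aa/s
BULK_RATE_AA_PER_S = 5.6

OccupancyTable = pd.DataFrame  # schema documented in the module docstring


def relative_occupancy(
    counts: Mapping[str, CodonCountMatrix] | Iterable[CodonCountMatrix],
    frame: str = "a_site",
) -> OccupancyTable:
    """Compute the per-codon occupancy table from one sample's count matrices.

    ``frame="a_site"`` attributes the ratio at position *i* to the codon at
    *i*; ``frame="downstream"`` attributes it to the codon at *i+1* (the codon
    that has not yet entered the decoding site), the control frame in which
    genuine A-site effects should compress. Genes with a zero mean over
    included positions are excluded; a sample with no included positions at
    all is an error.

    The per-gene mean of r_i over included positions is 1 by construction;
    this is asserted for every gene.
    """
    if frame not in ("a_site", "downstream"):
        raise ValueError("frame must be 'a_site' or 'downstream'")
    matrices = counts.values() if isinstance(counts, Mapping) else counts
    shift = 0 if frame == "a_site" else 1

    acc: dict[str, list[tuple[float, float, float]]] = {c: [] for c in SENSE_CODONS}
    any_positions = False
    for m in matrices:
        idx = np.nonzero(m.included)[0]
        if idx.size == 0:
            continue
        any_positions = True
        totals = m.small[idx] + m.large[idx]
        m_g = totals.mean()
        if m_g == 0:
            continue
        r = totals / m_g
        assert abs(r.mean() - 1.0) < 1e-9, f"{m.transcript_id}: gene mean != 1"
        s = m.small[idx] / m_g
        l = m.large[idx] / m_g
        for pos, ri, si, li in zip(idx, r, s, l):
            j = int(pos) + shift
            if j >= m.n_codons:
                continue
            codon = m.codons[j]
            if codon in acc:  # stop codons attributed nothing
                acc[codon].append((float(ri), float(si), float(li)))
    if not any_positions:
        raise ValueError("no included positions in any gene")

    rows = []
    for c in SENSE_CODONS:
        vals = np.array(acc[c], dtype=float).reshape(-1, 3)
        n = len(acc[c])
        means = vals.mean(axis=0) if n else (np.nan, np.nan, np.nan)
        rows.append(
            {
                "codon": c,
                "rel_occupancy": means[0],
                "small_abundance": means[1],
                "large_abundance": means[2],
                "n_positions": n,
            }
        )
    return pd.DataFrame(rows).set_index("codon")


def aggregate_replicates(tables: list[OccupancyTable]) -> OccupancyTable:
    """Combine replicate occupancy tables: per-codon mean ± sample sd.

    Output columns: per-replicate values (``rel_occupancy_rep1`` ...), the
    ``*_mean`` and ``*_sd`` for each quantity (sd = 0 for a single replicate),
    and pairwise replicate Spearman correlations of rel_occupancy in
    ``table.attrs["pairwise_spearman"]``.
    """
    if not tables:
        raise ValueError("need at least one replicate table")
    index = tables[0].index
    for t in tables[1:]:
        if not t.index.equals(index):
            raise ValueError("replicate tables must cover the same codon set")
    out = pd.DataFrame(index=index)
    quantities = ["rel_occupancy", "small_abundance", "large_abundance"]
    for q in quantities:
        reps = np.column_stack([t[q].to_numpy() for t in tables])
        for k in range(reps.shape[1]):
            out[f"{q}_rep{k + 1}"] = reps[:, k]
        out[f"{q}_mean"] = reps.mean(axis=1)
        out[f"{q}_sd"] = reps.std(axis=1, ddof=1) if reps.shape[1] > 1 else 0.0
    out["n_positions_mean"] = np.column_stack(
        [t["n_positions"].to_numpy() for t in tables]
    ).mean(axis=1)
    pairwise = {}
    for a in range(len(tables)):
        for b in range(a + 1, len(tables)):
            x = tables[a]["rel_occupancy"].to_numpy()
            y = tables[b]["rel_occupancy"].to_numpy()
            ok = np.isfinite(x) & np.isfinite(y)
            if ok.sum() < 2 or np.unique(x[ok]).size < 2 or np.unique(y[ok]).size < 2:
                pairwise[(a, b)] = float("nan")  # undefined, flagged not raised
                continue
            rho, _ = stats.spearmanr(x[ok], y[ok])
            pairwise[(a, b)] = float(rho)
    out.attrs["pairwise_spearman"] = pairwise
    return out


def small_fraction(
    counts: Mapping[str, CodonCountMatrix] | Iterable[CodonCountMatrix],
) -> pd.Series:
    """Pooled small/(small+large) per codon over all included instances.

    Codons with zero total footprints get NaN (flagged, not divided).
    """
    matrices = counts.values() if isinstance(counts, Mapping) else counts
    small = {c: 0 for c in SENSE_CODONS}
    total = {c: 0 for c in SENSE_CODONS}
    for m in matrices:
        for pos in np.nonzero(m.included)[0]:
            codon = m.codons[int(pos)]
            if codon in small:
                small[codon] += int(m.small[pos])
                total[codon] += int(m.small[pos] + m.large[pos])
    return pd.Series(
        {c: (small[c] / total[c] if total[c] else np.nan) for c in SENSE_CODONS},
        name="small_fraction",
    )


def predict_times(
    table: OccupancyTable, bulk_rate: float = BULK_RATE_AA_PER_S
) -> pd.Series:
    """Predicted mean elongation time per codon, seconds.

    Scales relative occupancy by the bulk elongation rate: a codon at the
    gene-average occupancy of 1.0 takes 1/bulk_rate ≈ 0.179 s; occupancy 2.6
    predicts ≈ 0.46 s.
    """
    if bulk_rate <= 0:
        raise ValueError("bulk_rate must be positive")
    col = "rel_occupancy_mean" if "rel_occupancy_mean" in table.columns else "rel_occupancy"
    occ = table[col]
    if (occ.dropna() <= 0).any():
        raise ValueError("occupancies must be positive to predict times")
    return (occ / bulk_rate).rename("predicted_time_s")


def condition_contrast(
    table_a: OccupancyTable,
    table_b: OccupancyTable,
    quantity: str = "occupancy",
    pseudocount: float | None = None,
    z_threshold: float = 3.5,
) -> pd.DataFrame:
    """Per-codon log2 contrast of two samples with robust outlier flags.

    ``quantity`` ∈ {occupancy, small, large}. Zeros are floored at a
    pseudocount (default: half the smallest nonzero value across both tables)
    before log2. The outlier flag marks codons whose log2 difference
    (b − a) deviates from the median by more than ``z_threshold`` robust
    z-units (MAD-based). Swapping the tables negates every difference.
    """
    colmap = {
        "occupancy": "rel_occupancy",
        "small": "small_abundance",
        "large": "large_abundance",
    }
    if quantity not in colmap:
        raise ValueError(f"quantity must be one of {sorted(colmap)}")
    col = colmap[quantity]

    def pick(t: OccupancyTable) -> pd.Series:
        return t[f"{col}_mean"] if f"{col}_mean" in t.columns else t[col]

    a, b = pick(table_a), pick(table_b)
    if not a.index.equals(b.index):
        raise ValueError("tables must cover the same codons")
    both = np.concatenate([a.to_numpy(), b.to_numpy()])
    nonzero = both[np.isfinite(both) & (both > 0)]
    if nonzero.size == 0:
        raise ValueError("no positive values to contrast")
    pc = pseudocount if pseudocount is not None else float(nonzero.min()) / 2.0
    log_a = np.log2(np.maximum(a.to_numpy(), pc))
    log_b = np.log2(np.maximum(b.to_numpy(), pc))
    diff = log_b - log_a
    med = np.nanmedian(diff)
    mad = np.nanmedian(np.abs(diff - med))
    scale = 1.4826 * mad
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (diff - med) / scale if scale > 0 else np.zeros_like(diff)
    return pd.DataFrame(
        {
            "log2_a": log_a,
            "log2_b": log_b,
            "log2_diff": diff,
            "robust_z": z,
            "outlier": np.abs(z) > z_threshold,
        },
        index=a.index,
    )


def amino_acid_of(codon: str) -> str:
    """Convenience re-export for grouping occupancy rows by amino acid."""
    return amino_acid(codon)
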