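"""Codon-level correlates: amino-acid polarity, tAI, tRNA copies, wobble pairs.

Rank correlations between per-codon footprint statistics and physicochemical
or tRNA-level annotations. Annotation tables ship with the package but are
plain TSVs a user can override:

* ``polarity_vapor_to_water.tsv`` — hydration potentials of amino-acid side
  chains (free energy of transfer from vapor to water, kcal/mol; Wolfenden et
  al. 1981, Biochemistry 20:849). Polar side chains are strongly negative.
  Rank correlations against any monotone transform of the equilibrium
  constant of transfer are identical up to sign. Proline has no independent
  side-chain value and is absent.
* ``tai_synthetic.tsv`` / ``trna_copies_synthetic.tsv`` — SYNTHETIC stand-in
  tables with the shape and rough magnitude of yeast tRNA adaptation indices
  and tRNA gene copy numbers; they exercise the correlation machinery and are
  not curated measurements. Supply real tables for real analyses.
* ``wobble_pairs.tsv`` — synonymous codon pairs decoded by the same tRNA,
  Watson-Crick partner vs wobble partner, curated from standard yeast
  decoding rules (G34 reads C/U, U34 reads A/G, inosine reads C/U/A).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .codons import GENETIC_CODE, SENSE_CODONS, amino_acid
from .io import read_table


def _data_path(name: str) -> Path:
    return Path(str(resources.files("ribostate").joinpath("data", name)))


def load_polarity() -> dict[str, float]:
    """Amino acid -> side-chain vapor-to-water transfer free energy (kcal/mol)."""
    df = read_table(_data_path("polarity_vapor_to_water.tsv"))
    return dict(zip(df["amino_acid"], df["dG_kcal_mol"].astype(float)))


def load_tai() -> dict[str, float]:
    """Codon -> tAI (synthetic stand-in table unless overridden)."""
    df = read_table(_data_path("tai_synthetic.tsv"))
    return dict(zip(df["codon"], df["tai"].astype(float)))


def load_trna_copies() -> dict[str, float]:
    """Codon -> tRNA gene copy number (synthetic stand-in table)."""
    df = read_table(_data_path("trna_copies_synthetic.tsv"))
    return dict(zip(df["codon"], df["copies"].astype(float)))


def load_wobble_pairs() -> pd.DataFrame:
    """Curated (wc_codon, wobble_codon, pairing) table."""
    return read_table(_data_path("wobble_pairs.tsv"))


@dataclass
class CodonAnnotation:
    """Bundle of the codon-level annotation tables used by Fig-6-style analyses."""

    polarity: dict[str, float] = field(default_factory=load_polarity)
    tai: dict[str, float] = field(default_factory=load_tai)
    trna_copies: dict[str, float] = field(default_factory=load_trna_copies)
    wobble_pairs: pd.DataFrame = field(default_factory=load_wobble_pairs)

    def __post_init__(self) -> None:
        for _, row in self.wobble_pairs.iterrows():
            a, b = row["wc_codon"], row["wobble_codon"]
            if GENETIC_CODE.get(a, "?") != GENETIC_CODE.get(b, "!"):
                raise ValueError(f"wobble pair {a}/{b} is not synonymous")


def correlate(
    stat: Mapping[str, float],
    annotation: Mapping[str, float],
    group_by: str = "codon",
) -> tuple[float, int]:
    """Spearman correlation between a per-codon statistic and an annotation.

    ``annotation`` may be keyed by codon or by amino acid. With
    ``group_by="amino_acid"`` the statistic (and a codon-keyed annotation) is
    first averaged over synonymous codons. Average ranks handle ties; being
    rank-based, the result is invariant under strictly monotone transforms of
    either variable. Returns (rho, number of paired groups); fewer than 3
    paired groups is an error.
    """
    if group_by not in ("codon", "amino_acid"):
        raise ValueError("group_by must be 'codon' or 'amino_acid'")
    ann_by_codon = any(k in GENETIC_CODE for k in annotation)

    if group_by == "codon":
        if not ann_by_codon:
            ann = {c: annotation.get(amino_acid(c)) for c in SENSE_CODONS}
        else:
            ann = dict(annotation)
        keys = [c for c in SENSE_CODONS if c in stat and ann.get(c) is not None]
        xs = [stat[c] for c in keys]
        ys = [ann[c] for c in keys]
    else:
        groups: dict[str, list[float]] = {}
        for c in SENSE_CODONS:
            if c in stat and np.isfinite(stat[c]):
                groups.setdefault(amino_acid(c), []).append(float(stat[c]))
        xs, ys, keys = [], [], []
        for aa, vals in sorted(groups.items()):
            if ann_by_codon:
                ann_vals = [
                    float(annotation[c])
                    for c in SENSE_CODONS
                    if amino_acid(c) == aa and c in annotation
                ]
                if not ann_vals:
                    continue
                y = float(np.mean(ann_vals))
            else:
                if aa not in annotation or annotation[aa] is None:
                    continue
                y = float(annotation[aa])
            keys.append(aa)
            xs.append(float(np.mean(vals)))
            ys.append(y)

    pairs = [(x, y) for x, y in zip(xs, ys) if np.isfinite(x) and np.isfinite(y)]
    if len(pairs) < 3:
        raise ValueError(f"need >= 3 paired groups, got {len(pairs)}")
    rho, _ = stats.spearmanr([p[0] for p in pairs], [p[1] for p in pairs])
    return float(rho), len(pairs)


def wobble_scatter(
    stat: Mapping[str, float], pairs: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Per wobble pair: statistic at the WC-paired vs wobble-paired codon.

    Returns one row per pair with the signed deviation (wobble − WC) from the
    y = x line expected if the statistic were determined solely by tRNA
    identity, sorted by absolute deviation (largest first). An empty pair
    table yields an empty result with a warning.
    """
    if pairs is None:
        pairs = load_wobble_pairs()
    cols = ["wc_codon", "wobble_codon", "pairing", "stat_wc", "stat_wobble", "deviation"]
    if len(pairs) == 0:
        warnings.warn("wobble pair table is empty; nothing to compare")
        return pd.DataFrame(columns=cols)
    rows = []
    for _, p in pairs.iterrows():
        wc, wb = p["wc_codon"], p["wobble_codon"]
        if wc not in stat or wb not in stat:
            continue
        s_wc, s_wb = float(stat[wc]), float(stat[wb])
        if not (np.isfinite(s_wc) and np.isfinite(s_wb)):
            continue
        rows.append(
            {
                "wc_codon": wc,
                "wobble_codon": wb,
                "pairing": p["pairing"],
                "stat_wc": s_wc,
                "stat_wobble": s_wb,
                "deviation": s_wb - s_wc,
            }
        )
    out = pd.DataFrame(rows, columns=cols)
    if len(out):
        out = out.reindex(
            out["deviation"].abs().sort_values(ascending=False, kind="mergesort").index
        ).reset_index(drop=True)
    return out
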