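# ribostate

Codon-resolution analysis of ribosome profiling data in which the ribosome
leaves **two distinct footprint sizes**: large fragments (28–29 nt) protected
by ribosomes in the decoding (non-rotated) stage of the elongation cycle, and
small fragments (20–22 nt) protected by post-peptide-bond (rotated)
ribosomes. Because both classes share the same 5′ geometry — the 5′ end sits
15–16 nt upstream of the A-site codon — each sequenced fragment can be
resolved to a size class *and* an A-site codon, and the balance of the two
classes per codon reads out the relative duration of the two stages of
elongation at single-codon resolution.

The package is for computational biologists working with transcript-coordinate
ribosome-profiling alignments (yeast-style data). It provides:

* **Size-class assignment** — classify each read by the (length, 5′ offset)
  table `{28↔15, 29↔16, 20↔15, 21↔15/16, 22↔16}` and infer its A-site codon;
  reads of other lengths, out-of-frame reads, and reads outside the CDS are
  rejected with counted reasons.
* **Per-codon occupancy statistics** — at each analyzable position *i* of
  gene *g* compute the footprint enrichment against the gene mean
  *m(g)*:

      r_i = (small_i + large_i) / m(g),
      s_i = small_i / m(g),   l_i = large_i / m(g),

  so that `r_i = s_i + l_i` exactly, then average each quantity (unweighted)
  over every instance of each of the 61 sense codons. `rel_occupancy` is a
  unitless proxy for relative A-site dwell time; `small_abundance` and
  `large_abundance` split it into the post-peptide-bond and decoding stages.
  Analysis is restricted to codons 51 through the second codon before the
  stop (runoff depletion affects the first ~50 codons), positions whose
  possible read 5′ ends are unique 20-mers in the transcriptome, and genes
  with at least 10 analyzable footprints.
* **Metagene grids** (fragment length × 5′ position around start/stop), frame
  periodicity profiles, and CDS/UTR partitions.
* **Inhibitor contrasts** — log2 comparisons between conditions with robust
  outlier flags (e.g. His codons under histidine starvation).
* **Codon correlates** — rank correlations with amino-acid polarity, tAI and
  tRNA gene copy number tables, and Watson-Crick vs wobble-decoded synonymous
  codon comparisons.
* **A synthetic two-state footprint simulator** with per-codon dwell weights
  for each state, inhibitor modes (cycloheximide, anisomycin, 3-AT, runoff),
  UTR background noise, and a truth table — so the entire pipeline is
  testable end-to-end with no sequencing data.

Occupancy converts to predicted elongation time through a bulk elongation
rate of 5.6 aa/s: `time(c) = rel_occupancy(c) / 5.6`.

## Worked example

Simulate 60 genes in which decoding at CCG is 5× slower than at every other
codon, then run assignment and occupancy estimation:

```python
import ribostate as rs

dec = rs.uniform_weights(); dec["CCG"] = 5.0
params = rs.SimulationParams(n_genes=60, cds_codon_range=(150, 250),
                             decode_weight=dec, reads_per_gene_mean=1500,
                             utr_noise_frac=0.0, seed=42)
transcripts, reads, truth = rs.simulate(params)
assigned, rejected = rs.assign_reads(reads, transcripts)
matrices = rs.tally(assigned, transcripts, rs.build_multimap_mask(transcripts))
occ = rs.relative_occupancy(matrices)
print(occ.loc[["CCG", "CCA", "GGT"]].round(3))
```

```
       rel_occupancy  small_abundance  large_abundance  n_positions
codon
CCG            2.893            0.492            2.401          129
CCA            0.940            0.476            0.465          153
GGT            1.007            0.491            0.517          125
```

All 89,909 reads assign cleanly (no UTR noise was simulated). CCG's
occupancy (2.89, vs a median of 0.98) is elevated specifically through its
`large_abundance` (2.40) while its `small_abundance` matches other codons
(~0.49) — the signature of a slow *decoding* step. Accordingly
`rs.small_fraction(matrices)["CCG"]` is 0.17 against a codon median of 0.50,
and `rs.predict_times(occ)["CCG"]` predicts 0.52 s at this codon versus
1/5.6 ≈ 0.18 s for an average codon.

The same pipeline runs from the shell:

```sh
ribostate run-all --seed 42 --out-dir runs/demo        # simulate → occupancy
ribostate assign --reads reads.tsv --transcriptome t.fa \
    --annotation ann.tsv --out counts.tsv              # real data, TSV or SAM
```

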