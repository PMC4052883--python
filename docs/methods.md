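# Methods

## Model and coordinate conventions

An elongating ribosome is observed in one of two conformations: the decoding
(non-rotated) state, which protects a large mRNA fragment, or the
post-peptide-bond (rotated) state, which protects a small fragment. Both
conformations leave the fragment 5′ end 15–16 nt upstream of the first
nucleotide of the A-site codon; the 3′ ends differ (≈10 nt past the A-site
codon for large fragments, 2–3 nt for small). Deep sequencing of protected
fragments therefore samples, at every codon, the relative time ribosomes
spend in each stage of the elongation cycle with that codon in the A site.

All coordinates are 0-based, half-open, transcript-relative; SAM's 1-based
`POS` is converted at the parsing boundary. Codon indices are 0-based from
the CDS start and count the stop codon, so the analysis window "codons 51
through the second codon before the stop" is the inclusive index range
`[50, n_codons − 3]`. Soft-clipped SAM bases are excluded: read length is the
aligned reference span.

## Size-class assignment

The default (length, 5′ offset → class) table is
`{(28,15,large), (29,16,large), (20,15,small), (21,15,small), (21,16,small),
(22,16,small)}`, overridable as a TSV. A read is assigned iff exactly one
candidate position `five_prime + offset` is a codon start inside the CDS;
otherwise it is rejected as `length_unclassified`, `out_of_frame`, or
`outside_cds`. Rejections are data (tallied and logged), not errors. Because
the two 21-mer offsets differ by 1 while codon starts differ by 3, at most
one candidate can be in frame; this makes the read-centric single pass
provably equivalent to the codon-centric formulation (for codon *i*: 28-mers
at *i*−15, 29-mers at *i*−16, 20/21-mers at *i*−15, 21/22-mers at *i*−16),
and the equivalence is enforced by a brute-force oracle test. The A-site
codon is located from the 5′ end only; 3′ ends are never consulted.

## Filters

* **Analysis window** `[50, n_codons − 3]`: ribosomes run off the first ~50
  codons when cells are harvested without elongation inhibitors, and the last
  two codons cannot hold a complete elongating geometry.
* **Uniqueness mask**: the transcriptome is split into all overlapping
  20-mers; every start position of a 20-mer with ≥2 exact forward-strand
  matches is excluded. A codon cell is masked when either of its possible
  contributing 5′ positions (codon start − 15 or − 16) is excluded. This is
  deterministic (independent of which reads were observed) and equivalent to
  masking cells fed by masked read positions for all tabled (length, offset)
  pairs.
* **Gene filter**: genes with fewer than 10 footprints are dropped. The count
  is taken over window-interior, unmasked positions so that the filter
  depends only on analyzable signal.

## Occupancy statistics

With `m_g` the mean of (small + large) over a gene's included positions
(zero-count positions included, masked positions not), the position ratios
are `r_i = (small_i + large_i)/m_g`, `s_i = small_i/m_g`, `l_i = large_i/m_g`.
Per-codon values are unweighted means over all included instances
genome-wide (each position counts once regardless of expression); an
expression-weighted variant is out of scope. Two identities hold by
construction and are asserted: the per-gene mean of `r_i` is exactly 1, and
`rel_occupancy = small_abundance + large_abundance` per codon (tolerance
1e−9 in tests; observed deviation is at machine precision). Genes with
`m_g = 0` are excluded; a sample with no included positions at all is an
error.

The `downstream` frame attributes each ratio to the codon at *i*+1 — a codon
that has not yet entered the decoding site — as a negative control: when
dwell genuinely depends on the A-site codon, the downstream-frame occupancy
spread must compress (on synthetic data with codon-specific dwells the
standard deviation drops by more than an order of magnitude).

`small_fraction` pools counts (`Σ small / Σ (small+large)` per codon) rather
than averaging per-position fractions; pooling is robust at low per-position
coverage and the choice is documented here because either reading is
defensible.

Replicates are combined by per-codon arithmetic mean and sample standard
deviation (ddof = 1; sd = 0 for a single replicate), with pairwise Spearman
correlations (average ranks) reported alongside. Condition contrasts are
log2 ratios with zeros floored at half the smallest nonzero abundance across
both tables (deterministic and scale-free); outliers are flagged at
|robust z| > 3.5, with z = (d − median)/(1.4826·MAD) on the per-codon log2
differences.

Occupancy converts to predicted elongation time via a bulk rate of 5.6
amino acids per second: `time(c) = rel_occupancy(c)/5.6`, so occupancy 1.0
corresponds to ≈0.179 s.

## Synthetic data generator

The simulator emulates the marginal statistical structure of a two-state
profiling experiment, not its mechanism. Per gene, a Poisson(`reads_per_gene_mean`)
read total is allocated multinomially over (codon, state) cells with
probability ∝ `decode_weight[codon]` or `post_weight[codon]`; emission
support is codon indices 1..n−2 (the start codon initializes in the P site;
stop codons are not decoded by an elongating ribosome). Each read draws its
length from the class-specific length distribution and sits at
`five_prime = codon_start − offset`, with offsets forced by the assignment
table (28→15, 29→16, 20→15, 22→16) and 21-mers drawing from `offset_probs`
(both 21-mer offsets keep the A site in frame by construction). States are
sampled independently per read — no correlated ribosome trajectories —
because the analysis consumes only marginal per-(codon, state) counts.

Defaults define the emulated study conditions: 5′/3′ UTRs of 50 nt, large
length distribution {28: 0.7, 29: 0.3}, small {20: 0.3, 21: 0.4, 22: 0.3},
21-mer offsets {15: 0.5, 16: 0.5}, 2000 reads per gene, 1% of reads placed
uniformly within UTRs (yielding ≈99% of fragments with A sites inside the
CDS, the observed range being 98.3–99.7%), and uniform dwell weights — the
global small:large balance varied between real replicates and is left as a
free parameter (the relative scale of `post_weight` vs `decode_weight`)
rather than asserted.

Inhibitor modes: `cycloheximide` zeroes the post-state weights and adds a
phenomenological spike of small reads at codon 0 (mass 0.05 of a gene's
reads; the start-peak mechanism is not modeled); `anisomycin` zeroes the
decode-state weights; `three_at` multiplies the decode weight of CAT/CAC by
`three_at_factor` (default 10), mimicking His-tRNA depletion; `runoff` thins
reads at codon *i* < 50 with keep probability *i*/50.

What the generator does **not** model — ligation/sequence bias, nuclease
cut-site preference, kinetic correlations along a transcript, overdispersed
per-gene totals, 16 nt truncated-mRNA fragments — bounds what passing tests
show: the pipeline recovers the statistics it targets from data matching its
geometric assumptions; robustness to library-preparation artifacts of real
data is untested by construction.

## Annotation tables

Amino-acid polarity ships as the side-chain vapor→water transfer free
energies (kcal/mol; Wolfenden et al. 1981, Biochemistry 20:849). Rank
correlations are invariant under monotone transforms, so any monotone
function of the transfer equilibrium constant gives the same |ρ| (sign flips
with direction). Proline has no independent side-chain value and is omitted
(19 amino-acid groups). The tAI and tRNA-gene-copy tables are **synthetic
stand-ins** (labelled so in their filenames): plausible in shape and
magnitude, present to exercise the correlation machinery, and meant to be
overridden with curated tables for real analyses. The wobble-pair list is
curated from standard yeast decoding rules (G34 reads C directly and U by
wobble; U34 reads A directly and G by wobble; inosine reads C directly and
U/A by wobble) and is likewise a user-replaceable input.

## Numerical choices and degenerate inputs

* Spearman correlations use average ranks for ties; pairwise replicate
  correlations are reported as NaN (flagged, not raised) when fewer than two
  distinct finite pairs exist.
* Empty read sets yield `None`-flagged frame/region profiles, never NaN
  arithmetic; empty tables round-trip as header-only TSVs.
* Table output is deterministic: rows sorted by first column (stable
  mergesort), fixed line endings — identical inputs give byte-identical
  files, and the pipeline is end-to-end deterministic under a fixed seed.
* Transcripts shorter than the k-mer contribute nothing to the mask; genes
  too short to place any footprint are skipped with a warning.
* CDS lengths not divisible by 3 are dropped at load time with a named
  diagnostic; out-of-range CDS coordinates are hard errors.

## Problem sizes

The test suite and the acceptance script size their simulations at 10–200
genes with 120–300-codon CDSs and ~2×10⁵ reads for recovery checks — deep
enough that dwell-weight recovery is stable (Spearman ρ ≈ 0.99 against truth,
comfortably above the 0.9 bar) while the whole suite runs in well under a
minute on one CPU. Genome-scale values from real data (occupancy range
0.48–2.6, replicate ρ = 0.81, polarity ρ = −0.75) depend on the full yeast
transcriptome and library depth and are not reproduced at desk scale; the
synthetic checks target the corresponding structural properties instead.

## Known limitations

* Occupancy is relative; absolute per-codon rates require an external bulk
  rate and inherit its uncertainty.
* The mask operates on transcriptome 20-mers, forward strand only; genome
  multimapping and spliced alignment are out of scope (inputs are
  transcript-coordinate alignments).
* P-site/E-site reference frames are not offered; the downstream-codon
  control is the only alternative frame.
* 16 nt truncated-mRNA footprints and footprints outside 11–36 nt are
  excluded at parsing.
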