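# Methods

`germscan` reimplements, as a tested library, a comparative two-tissue
pipeline for discovering high-copy satellite repeats that are present in a
germline genome and absent (or strongly depleted) from the corresponding
somatic genome — the sequence signature of programmed DNA elimination.
This note documents the model behind each stage, the parameters that
matter, what the synthetic data does and does not emulate, and the design
choices made where the procedure left genuine freedom.

## The discovery model

The pipeline treats "germline-restricted repeat family" as an operational
object defined by read data alone:

1. **Abundance.** Canonical k-mers (k = 31; the canonical form is the
   lexicographic minimum of a k-mer and its reverse complement) are counted
   in each tissue's reads. The modal copy number of the spectrum — the peak
   contributed by single-copy sequence, located after discarding counts
   below `error_peak_min` (default 5, the error valley) — standardizes the
   two libraries. K-mers with count ≥ 3× the mode in either tissue are
   "abundant". The ≥ comparison is inclusive so printed thresholds (e.g.
   165 = 3 × 55) are attainable exactly.
2. **Assembly.** Abundant k-mers are threaded onto a bidirected de Bruijn
   graph with node size 29. A tandem unit of period p appears as a cycle of
   exactly p nodes; maximal non-branching paths are compressed and pure
   cycles are linearized once (cut at the lexicographically smallest node,
   with node_k−1 wraparound bases) and flagged cyclic.
3. **Comparative coverage.** Both read sets are placed on the consensus
   library by canonical-k-mer seeds (single best placement per read).
   Per-sequence coverage is scanned into intervals of at least v = 5000
   eligible bases (a base is eligible when either tissue covers it at ≥ 10×;
   depths are capped at 12 × 10⁶), trailing intervals of any length are
   reported (l = 0), and each interval is scored
   `log2((mean₁/modal₁) / (max(mean₂, floor)/modal₂))` with the genomic
   span estimated as `length × mean₁/modal₁`. Candidates must have
   score > 5 **and** span > 40 kb, both strictly.
4. **Families.** Candidates are clustered greedily (identity ≥ 0.8,
   alignment covering ≥ 30% of both the shorter and the longer sequence,
   length-descending first-fit), then clusters linked by ≥ 4 cross-alignment
   hits are merged transitively. Each family is annotated with its tandem
   core unit, inverted cassettes, and best genomic scaffold.

## Numerical and algorithmic choices

**Relative coverage cutoff in assembly.** Recurrent variants inside a
high-copy array — a 1–3 bp indel at a unit junction, an inverted-cassette
boundary, or a substitution shared by a handful of copies — produce k-mers
whose counts easily clear 3× the single-copy mode, because the threshold is
set relative to unique sequence while the variants recur across thousands
of copies. Left in the graph, these arcs cut every unit cycle into short
chains. `prune_low_coverage` therefore applies a relative cutoff inside
each weakly-connected component: nodes below 5% of the component's maximum
k-mer count are dropped before compression. Consensus k-mers sit at
(copy number × per-copy k-mer coverage), variant arcs one to two orders of
magnitude lower, so the default separates them with a wide margin; genuine
subfamilies carried by more than ~5% of copies survive the cutoff, which is
the intended semantics. Coverage-cutoff assembly is standard practice for
de Bruijn assemblers.

**Unitig length floor.** The assembler's own default floor is 58 bp
(2 × node size), but a cut cycle of a p bp unit compresses to ~p + 26 bp,
so the pipeline profile uses 30 bp (node_k + 1) to keep single-unit
satellite fragments; a chain whose last node reconnects to its first is a
tandem cycle that was cut open by variant side-arms and keeps its cyclic
flag. Linear outputs below the floor are dropped and counted in the log.

**Circular mapping of tandem consensus.** A satellite consensus is a
rotation of its unit: mapping 100 bp reads onto a 41–85 bp linear sequence
would clip most read bases and underestimate spans ~2–3×. The mapping stage
therefore detects each library sequence's tandem period (self-match
statistic, threshold 0.8) and maps reads onto the circularized core unit:
placements wrap modulo the unit, every read base lands on the circle, and
the span formula uses the core length. Non-periodic sequences map linearly
with clipping. K-mer ownership in the mapping index gives circular targets
priority over linear ones, and shorter units priority over longer (the
smallest period is the elementary monomer; longer circular targets sharing
its k-mers are composite unit-plus-variant loops); remaining ties go to the
lexicographically smallest id, then leftmost position. Placement is
identical across the two samples, so ratios are unbiased.

**Modal depth for standardization.** The score standardizer (the analogue
of "modal sperm coverage") is recomputed by mapping each read set to the
genomic scaffolds when they are provided, because a pure repeat library
contains no single-copy sequence to anchor the mode; without scaffolds the
mode of the library profiles is used. The somatic mean depth is floored at
1 read-depth unit before standardization so that families entirely absent
from the soma receive a finite score (configurable `somatic_depth_floor`).

**Fold-change estimator.** Per-interval enrichment uses the ratio of mean
(capped, eligible-base) depths; a mean-of-per-base-ratios variant is
available via `fold_estimator="mean_of_ratios"`.

**Alignment.** All identity/coverage rules run on one seed-and-extend local
aligner: exact 11 bp word matches on both strands, clustered by diagonal
(tolerance 20, gap 60), each cluster extended by local Smith–Waterman
(match +1, mismatch −2, gap open −5, extend −2) on a padded window;
identity is matches / alignment columns with gaps counting as columns.
Cyclic consensus sequences are doubled before alignment so rotations match;
fractions are computed against the original length. In the
reference-merge rule ("> 90% identity over > 80% of their length") the 80%
is measured on the de novo sequence — the shorter, replaced party. A
self-versus-reverse-complement scan for inverted cassettes uses the +
strand only (the − strand is the trivial self-identity) and splits
self-overlapping palindromic hits at their center. Scaffold assignment
caps seed-cluster extensions at 3000 per strand; hit counts of massively
tandem regions saturate at that cap.

**Tandem period detection.** For each candidate period p (default range
5–200, at least 12 compared positions), the score is the fraction of
positions i with base(i) = base(i+p); the smallest qualifying p (≥ 0.8) is
reported, refined within ±2 bp, with a column-majority consensus. An exact
array also qualifies at every multiple of the unit; reporting the smallest
qualifying period is the documented convention. Random sequence scores
≈ 0.25, far below threshold.

## The synthetic scenario

The generator plants tandem satellite families into i.i.d. random backbone
chromosomes shared by both genomes; shared families are written at the same
coordinates in both genomes (identical realized arrays, so planted coverage
ratios are exact), and germline-restricted spans revert to backbone in the
soma. Arrays are built unit by unit: per-base substitutions, 1–3 bp
insertions or deletions at unit junctions, and cassettes of units emitted
in inverted orientation, with every placement recorded in a truth table.
The read simulator draws uniform (optionally paired) substitution-only
reads at fixed quality.

The packaged standard scenario uses two 2 Mb genomes of four 500 kb
chromosomes; three shared families (25/40/55 bp units at 2000/1200/900
copies in both genomes — the pericentromeric satellite complement and the
somatic-coverage ranking targets) and six restricted families spanning the
observed core-size range (13/21/30/38/47/57 bp units at copies chosen for
~66 kb planted spans each); reads are 100 bp paired at 40× per tissue with
0.1% substitution error. Noise rates (substitutions 1–2 × 10⁻⁴ per base,
junction indels 1–2% per junction, 5% inverted cassettes of 20 units)
model young, concertedly homogenized arrays with post-trimming Illumina
error. The truth table's expected score for a family is
`log2((copies_g × coverage) / max(copies_s × coverage, 1))`, the same floor
the scoring stage applies, so expectations are reproducible from the truth
table and scenario configuration alone.

**What passing does and does not show.** The scenario exercises the full
decision chain — thresholding, cycle assembly, comparative scoring, the
strict score/span filter, clustering and annotation — under realistic
copy numbers and read noise. It does not emulate deeply diverged satellite
subfamilies (> ~5–10% within-family divergence), higher-order repeat
structure, GC bias, PCR duplicates, read indels, or diploid
heterozygosity. In particular, heavily diverged families would fragment in
this v1 assembler (no bubble popping beyond the coverage cutoff), and a
family whose true genomic span is near the 40 kb filter edge can be lost
to sampling noise; the planted spans (~66 kb) sit away from the edge by
design of the scenario, not by tuning.

## Reproducibility and scale

Every random stage derives from one integer seed through fixed stream
offsets, so a rerun is byte-identical; the pipeline writes a JSON manifest
of parameters and stage outputs, and reruns with an unchanged manifest
reload the expensive early stages (counting, mapping) from disk. Problem
sizes in the tests — 400 kb genomes for module-level checks, the 2 Mb
standard scenario at five seeds for calibration — were chosen so the whole
suite runs comfortably on one CPU; a standard-scenario run takes about two
and a half minutes and well under 1 GB of memory.

## Known limitations

- Counting packs k-mers into one 64-bit word; k > 31 falls back to a slow
  dictionary path intended for small inputs only.
- The read mapper is seed-based best-hit placement, not a full aligner:
  no base-quality use, no proper-pair constraints, no fractional
  multi-mapping. Ties are resolved deterministically, identically across
  samples, which is what the ratio statistics require.
- Reported interval coordinates for circularized targets are on the core
  unit, not the (arbitrary) linearized consensus.
- `cross_merge` counts merged HSPs ≥ 50 bp at ≥ 0.8 identity as "hits";
  per-sequence-pair counting is available (`hit_counting="pair"`).
- The supplementary-data reproduction (published cluster counts, interval
  funnel) requires the study's deposited reads and sequence sets; it is
  wired as a test that runs only when those inputs are staged locally.
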