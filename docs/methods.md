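# Methods

## Signal model

Reverse transcriptase traversing a stable hairpin can switch templates
across the duplex, producing a cDNA with an internal deletion that aligners
encode exactly like a spliced-out intron. The package treats every
reference skip in a primary spliced long-read alignment as a *skip event*
and classifies 2500-nt genomic windows by the joint statistics of their
events. The discriminating assumptions are:

* splicing is frequent per locus (inclusion levels distribute bimodally),
  lands on fixed GT..AG junctions and repeats at base-identical coordinates;
* template switching is rare per molecule (a few per cent), is indifferent
  to sequence motifs, and its breakpoints scatter around the duplex ends
  from molecule to molecule.

Skips are read from the minimap2 `cs` difference string when present
(`~` items carry donor motif, length, acceptor motif) and from CIGAR `N`
operations otherwise; the `cs` tag wins when both exist because it is the
aligner's richer record of the same alignment. Secondary and supplementary
records are excluded — one molecule, one vote. Skips shorter than 20 nt
(configurable) are treated as deletions, not region-skipping; the floor
keeps indel noise out of the skip statistics and has no other role.

All coordinates are 0-based half-open. Editing catalogs arrive 1-based
(REDIportal convention) and are shifted on load.

## Features (38 per window)

A window qualifies when ≥ 6 reads overlap it by ≥ 1 nt and ≥ 1 of them has
a skip event *starting* inside it. Start-inside assignment gives each skip
exactly one home window even when it straddles a window edge.

* `skip_ratio` = skipping reads / total reads.
* `len_skip` = mean of (end − start) over skip events (per event, not per
  read; a rare two-skip read contributes both lengths).
* Boundary clustering: all skip starts (and, separately, ends) in the
  window are partitioned into groups such that within a group consecutive
  positions are ≤ 100 nt apart and both extremes lie strictly within
  100 nt of the group median. Among all contiguous partitions whose groups
  satisfy this, the one with the fewest groups is chosen (ties: each group
  greedily as long as the remaining minimum allows), computed by dynamic
  programming over the sorted positions. A minimal partition is preferred
  to any fixed splitting heuristic because it is order-invariant,
  deterministic, and testable against exhaustive enumeration; recursive
  largest-gap splitting can over-fragment (e.g. positions 0, 100, 101, 201
  admit two admissible groups but a largest-gap recursion yields three).
* `group_num` = mean of start-side and end-side group counts (half-integer
  when they differ); `std_start`/`std_end` = mean per-group *population*
  standard deviation (divisor n, so singleton groups contribute 0 rather
  than NaN).
* `gc_skip` and the 32 boundary dinucleotide frequencies are computed from
  the reference sequence of the skipped segment — the skipped bases are by
  definition absent from the read. The start dinucleotide is the first two
  skipped bases, the end dinucleotide the last two (GT…AG for an intron).
  Events with an ambiguous base in a boundary dinucleotide leave that
  side's denominator.

## Editing-based positive set

Regions with ≥ 3 known editing sites within any 50-nt span (strictly:
max − min < 50 among three consecutive sites) are editing-enriched; sites
on both strands are pooled. Overlapping seeds are unioned, then EERs within
1 kb of each other (gap = next.start − prev.end ≤ 1000) are merged.
Each merged region is folded; intervals shorter than 200 nt are padded
symmetrically to 200 nt so a 200-bp stem is representable at all, and
intervals above the folding limit (default 5000 nt) are skipped with a log
message. Regions pass curation with stem ≥ 200 bp, stem mismatch ≤ 20 %
and adjusted MFE ≤ −35 kcal/mol per 100 nt.

A site-cluster interval that covers only one arm of an inverted repeat
cannot fold into its stem and is dropped; padding to a full analysis
window was evaluated and rejected because the added background dilutes the
adjusted MFE below threshold for genuine hairpins.

## Structure metrics

Folding is delegated to ViennaRNA (`RNA.fold`) behind a one-function
adapter (sequence in, dot-bracket + MFE out), so tests can substitute a
fixture engine. T maps to U; N never pairs; sequences outside 10–5000 nt
are refused.

* **Adjusted MFE (AMFE)** = MFE / length × 100, kcal/mol per 100 nt. The
  acceptance threshold is −35.0 on this scale (equivalently −0.35 kcal/mol
  per nt). The alternative reading, −0.35 per 100 nt, would pass
  essentially every sequence with any structure and filter nothing, so it
  cannot be the intended cutoff; the threshold is exposed as a parameter.
* **Duplex stem**: helices (maximal stacks of nested pairs) are chained
  inward while consecutive helices are separated by interior loops or
  bulges of ≤ 30 nt per side (configurable). The chain maximising total
  pairs is the duplex; its *length* is that pair count. Its *span* is the
  two strands of the duplex only — outermost to innermost paired position
  on each side — and the mismatch fraction is (span − 2·pairs)/span. The
  enclosed terminal loop is deliberately not part of the span: a perfect
  300-bp hairpin with a 400-nt loop is a flawless stem, not a 40 %-
  mismatched one. Interruptions larger than the tolerance terminate the
  chain, which keeps meandering low-quality pairings in random sequence
  from accumulating into spuriously long "stems".
* **Classification**: novel long dsRNA iff stem ≥ 200 bp *and* mismatch
  ≤ 0.20 *and* AMFE ≤ −35.0, all bounds inclusive; otherwise structured
  RNA. The rule is monotone in each metric.

## Classifier

Random forest with fixed defaults: gini criterion, bootstrapped samples, no
depth limit, `min_samples_split` 2, `min_samples_leaf` 4, `max_features`
0.20, 100 trees, seeded. Remaining settings are scikit-learn defaults and
are embedded in the saved model artifact for provenance. Training sets are
balanced: one random control window per curated positive, uniform over the
genome, rejected on any overlap with a positive or on failing the
≥ 6-read/≥ 1-skip requirement (the same filter the positives must pass),
with a bounded resampling budget (100 × the required count).

Evaluation uses stratified 20-fold cross-validation with seeded shuffling;
per-fold accuracy plus one ROC AUC and one AUPRC from the pooled
out-of-fold probabilities. Feature contributions are permutation-based: the
baseline is the R² between the 0/1 label and the predicted positive-class
probability on held-out rows; each feature's score is the mean drop in R²
over 5 independent permutations of its column. R² against probabilities is
used because a forest's discrete class output would make R² degenerate.

## Synthetic corpus

The generator emulates the statistical structure the classifier relies on,
with every artifact byte-reproducible from the seed.

| parameter | default | meaning |
| --- | --- | --- |
| arm length | U(200, 600) nt | inverted-repeat arm of a planted hairpin |
| loop length | U(50, 500) nt | spacer between the arms |
| skip fraction | U(0.02, 0.2) | per-read probability of skipping the hairpin |
| boundary jitter | Normal, σ = 30 nt | molecule-to-molecule breakpoint scatter |
| splice inclusion | Beta(0.3, 0.3) | per-locus skip probability of the intron (bimodal) |
| exon / intron length | U(100, 300) / U(300, 1500) nt | splice locus geometry |
| coverage | Poisson(20) per locus | mean ≥ 6 so the candidate filter is satisfiable |
| noise skips | 0.03 per read, U(100, 1500) nt | error/variant-driven skipping present in all loci |
| aligner motif snap | ± 5 nt | see below |
| editing sites | U(10, 30) per hairpin, levels U(0.1, 0.5) | clustered in the arms, ≥ 1 triple within 50 nt |

Two generator behaviours model the *aligner's* view of the data rather
than the biochemistry, and matter for the feature structure:

* **Noise skips.** Real control regions contain internal skips that come
  from sequencing errors and genetic variants, not only from splicing, so
  a low per-read rate of motif-free skips is applied to every locus.
* **Motif snapping.** Spliced aligners score canonical junctions
  favourably, and the microhomology at a template-switch breakpoint
  (typically a few nt) lets the aligner shift a gap boundary at no
  alignment cost. Each jittered artifact boundary is therefore moved to a
  GT (start) / AG (end) within ± 5 nt when one exists. Without this, the
  boundary dinucleotides of simulated artifacts are uniformly random — a
  cleanliness real BAMs do not have — and the two splice-motif features
  become near-perfect separators, which inverts the observed importance
  ordering and inflates accuracy to ~0.99. With snapping at the
  microhomology scale, corpus-level behaviour sits where real data sits:
  20-fold CV accuracy ≈ 0.86–0.90, AUC ≈ 0.95–0.98, and the skipping
  ratio carries the largest permutation contribution.

Reads are emitted pre-aligned as coordinate-sorted SAM with consistent
CIGAR (`N`) and `cs` encodings generated independently from the same
ground truth, which gives the parser a non-trivial cross-check. Editing is
planted as A→G substitutions in the read bases at per-site Bernoulli
rates, so editing-index computation sees realistic pileups.

What the generator does *not* emulate: base-call errors outside planted
substitutions, ONT-specific artifacts, multi-intron genes, alternative
3'/5' splice sites, expression gradients, strand asymmetries, and real
repeat families. Passing tests demonstrate that the pipeline recovers the
signal it is designed for under its own stated assumptions — not
performance on any particular real dataset.

## Discovery

Chromosomes are tiled with 2500-nt windows at a 1250-nt stride; a trailing
partial window is kept only when strictly longer than one stride
(a shorter one covers no base the previous window missed), so every
covered base lies in one or two windows. Candidate windows (read filter as
above) are scored; windows with probability strictly > 0.5 that do not
overlap a curated positive by ≥ 1 nt are folded and classified. Adjacent
positive windows are reported as-is, not merged. A folding failure skips
that window with a warning rather than aborting the scan.

The editing index of a region pools catalog sites covered by more than
three aligned, non-deleted read bases: on the + strand, G reads at
reference-A sites count as edited; on the − strand the sequenced
complement (T→C) is counted. Reads are not strand-filtered because the
simulated (and typical PacBio cDNA) libraries are not reliably stranded.
The index is G/(A+G) pooled over qualifying sites, and reported as missing
— not zero — when no qualifying observation exists.

When measuring recovery of planted structure, recall and specificity are
computed over loci that produce at least one candidate window: a hairpin
whose reads never skip (≈ 17 % of loci at the default skip-fraction range
and coverage) is excluded by the candidate filter itself and says nothing
about the classifier.

## Problem sizes and numerical notes

Tests and the acceptance script use corpora of 100+100 loci for classifier
evaluation (~1.5 Mb genome, ~4000 reads, seconds per corpus) and 6–12 loci
per class when real folding is involved, since folding one 2500-nt window
costs several seconds; these sizes give stable statistics while keeping
full runs in minutes. Grouping is O(n²) in the skips of a window (n is
tens). Determinism: every stochastic step draws from
`numpy.random.default_rng` seeded from configuration; reruns are
byte-identical including SAM and FASTA output. Degenerate inputs are
errors, not silent zeros: empty windows at the feature stage, empty
position lists in grouping, single-class training sets, k exceeding the
row count in CV.

## Known limitations

* The stem/mismatch metrics are one concretisation of "stem length with
  ≤ 20 % mismatches" on RNAfold output; other readings (e.g. counting the
  terminal loop, or mismatches relative to pairs rather than span) shift
  the curated set at the margins.
* EER curation misses inverted repeats whose editing sites cluster in a
  single arm (the folded interval lacks the partner arm).
* The classifier's irreducible confusions are low-inclusion splice
  windows with one or two junction-snapped reads versus single-skip
  hairpin windows — both classes present identical feature vectors there.
* Editing-index strand handling trusts the catalog strand; no attempt is
  made to infer transcript strand from the reads.
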