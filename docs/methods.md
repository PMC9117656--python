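# Methods

This note documents the models, conventions and numerical choices behind
`plastcomp`, in the order a reader meets them in the pipeline.

## Coordinate and annotation model

All intervals are 0-based half-open internally; every report file uses
1-based inclusive coordinates (the GenBank convention). Features that wrap
the circular origin are stored as ordered part lists and their length is the
sum of part lengths. GenBank `join(...)` locations are split into exon parts,
and the gaps between consecutive exons of one CDS/tRNA/rRNA become derived
`intron` features on read. Intergenic spacers (IGS) are derived, not read:
genic extents (gene containers, or CDS/tRNA/rRNA when no `gene` features
exist) are merged in circular order and each gap becomes an IGS named
`geneA-geneB` after its flanks; by construction, merged genic span + IGS span
= genome length on every input, which is asserted as a test invariant.
N bases are accepted and excluded from both numerator and denominator of GC
content; GC is rounded half-up to one decimal using exact decimal arithmetic.

## Quadripartite partition

The inverted repeat is defined exactly: the reported IR pair is the longest
pair of disjoint intervals on the circle whose sequences are exact reverse
complements. Detection seeds on shared 25-mers between the sequence and its
reverse complement; the match diagonal is invariant under extension, so each
diagonal is extended once to its maximal run (vectorised over the whole
circle). Ties go to the larger IR, then the smaller start coordinate. The two
single-copy arcs become LSC (longer) and SSC (shorter); IRa is the copy that
follows the LSC in genome order. The exact-match definition fits
*Amaranthus*-like genomes, where the two IR copies are identical; genomes
whose copies have diverged would need a relaxed matcher and are out of scope.
The partition provably tiles the circle and all four lengths are invariant
under rotation of the input — both are tested properties.

Subgenus-level SSC summaries use the population SD (divide by *n*),
because that is the convention under which the published subgenus table is
reproduced exactly from the published per-genome lengths (the sample SD gives
3.69 where 3.37 is printed); both conventions are exercised in the tests.

## SSR scan

Perfect repeats only, MISA thresholds: minimum unit counts 10, 5, 4, 3, 3, 3
for periods 1–6. For each period, maximal tandem runs are located by a
vectorised shift-compare; a run is reported once, truncated to whole copies,
with its observed motif, and only if the motif is primitive (not itself a
tandem of a shorter unit) — primitivity is what prevents a poly-A run from
also surfacing as AA/AAA calls. Compound SSRs are not merged. Circular
genomes are scanned on a doubled sequence; calls are kept with start in
`[0, L)` and contained duplicates of wrapped calls removed. The scanner is
tested for set-equality against an exhaustive (start, period, extension)
oracle on hundreds of random sequences.

Marker-matrix keys normalise the motif to the lexicographic minimum over
rotations and reverse-complement rotations (so TA/AT/their complements share
one locus key), keyed together with the gene or IGS context. The
discriminating search reports, per sample pair, the smallest column set that
separates the pair (searched by increasing cardinality with lexicographic
tie-break — a singleton whenever the rows differ at all) and the pairs whose
full rows are identical (inseparable); a second routine finds the smallest
single set separating *all* separable pairs, the form in which "combinations
of markers distinguish the species" is usually meant.

## Dispersed repeats

Four kinds, all reduced to forward matching against a transformed copy of the
sequence: identical (forward), reverse complement (palindromic), reversed
(reverse), base-complemented (complement). Seeds are exact 12-mers under the
transform; extension along the diagonal uses an X-drop rule (match +1,
mismatch −3, drop 12, ties to the longer extent) and ends are trimmed to
matches; records must reach 30 bp at ≥ 90% identity. The mismatch model is
Hamming (substitutions only, no gaps) — chosen over edit distance so every
call can be re-verified by direct comparison, which the tests do for every
emitted record. Two consequences are inherent to seeded scanning and worth
stating: a repeat pair is only detectable if it contains one exact 12-mer
under its transform, and near-duplicate records from different seeds are
collapsed only when one contains the other. The structural IRa-vs-IRb hit
(which is the quadripartite structure, reported separately) is suppressed
when a partition is supplied.

Cross-sample loci are built by projecting each record's first arm through the
alignment onto a reference genome and single-linkage clustering with a 2 kb
gap threshold; a locus is *common* when every sample contributes and
*variable-length* when member lengths differ. The symmetry report maps arm
midpoints to angles on the circle; the antipodality score is
|180° − angular separation| (0° for diametrically opposite arms).

## Alignment variation

The consensus takes the most frequent non-gap base per column (ties
alphabetical, N only when a column holds nothing else); all-gap columns are
dropped and a column↔consensus coordinate map retained. Columns are assigned
one class by painting reference features onto reference coordinates with
precedence CDS > tRNA > rRNA > intron > IGS and letting each column inherit
the class of the reference base at or before it, so insertions relative to
the reference stay inside the surrounding feature and the five class lengths
always sum to the consensus length (a tested conservation law).

Two counting units are deliberately kept apart. Class tables count *sites*
(columns), the unit on which published variability tables are scaled; pairwise
species comparisons count *events* (maximal runs of columns in which exactly
one of the two samples is gapped), the unit behind statements like "144
InDels between two species". In pairwise mode, columns gapped in both samples
are removed before run extraction — they are material neither sample carries,
and keeping them would let an unrelated sample's insertion split a long
deletion in two. Outgroups are excluded from genus-level tallies via the
`ingroup` argument. All frequencies are true percentages.

## Hotspots

"Exhaustive" is implemented literally: window starts at every position
(step 1, configurable), circular wrap-around windows included, counting SNP
sites on the consensus coordinate system; a window qualifies at ≥ 11 sites
(strictly more than 10 per 1000 bp). Qualifying windows are unioned into
maximal regions and counts recomputed on the merged interval; merged regions
can legitimately fall below the 1.1% per-window density. Note an arithmetic
consequence of the study conditions: at a genome-wide SNP-site frequency near
1.8%, an *average* kilobase already exceeds the threshold, so on full-rate
data the scan merges most of the genome — hotspot *discovery* is therefore
demonstrated on a low-background preset (rates ÷ 10) with two planted
high-rate segments, which the scan recovers as exactly two regions. Screening
replaces ML bootstrap with *b* seeded site-resampling replicates (default
100): region columns are resampled with replacement, an NJ tree built per
replicate, and the fraction of replicates in which every labeled clade is
monophyletic reported as the recovery fraction. Regions under 100 bp are
skipped with a warning; zero-variation regions count as non-concordant.

## Neighbor joining

Textbook Saitou–Nei: the Q-matrix minimum is joined each round, with the
first (lowest-index) minimum taken so output is deterministic; negative
branch lengths are clamped to zero. NJ on an additive matrix recovers the
generating topology — tested on random additive trees up to 8 taxa and
cross-checked once against an independent reference implementation.
Monophyly is evaluated after rerooting a cloned tree on the named outgroup's
terminal edge. Gap/N columns are excluded pairwise (not listwise) from
p-distances. ML/Bayesian inference and bootstrap values are deliberately out
of scope; monophyly statements are the testable surface.

## Simulator

Only the "reduced" genome LSC + IRa + SSC evolves; the second IR copy is
emitted as the reverse complement of the current IRa. Every IR mutation is
thereby mirrored between the copies and each leaf keeps an exact IR pair —
the idealisation that matches both the exact-IR detector and the near-perfect
IR conservation seen within a genus. The four bases flanking the IR junctions
are pinned so the planted IR is exactly maximal at the configured boundaries.

Gene layout: special named genes (`rbcL`, `rpoC2-like`, `ycf2-like`,
`psbM-like`/`trnD-like`, rRNA operon genes in the IR, `ndhF-like`,
`ndhA-like`, `ycf1-like` in the SSC) placed first, then a repeating
CDS / intron-gene / tRNA filler unit, with the remainder as IGS; gene sizes
scale down proportionally for miniature test genomes. The spacer hosting a
planted long indel gets a widened gap and is excluded from SSR/repeat
planting so planted elements never collide. The default class mix yields a
genome-wide expected SNP-site frequency of ≈ 1.8%.

Every alignment column carries a persistent site key (ancestral sites `(i,)`;
an insertion after key *K* on branch *b* gets keys `K + (b, j)`, which sort
correctly by tuple order), so the emitted MSA is the true homology alignment
and no external aligner is involved. Branch lengths are per-site substitution
*probabilities*; the preset three-clade tree's ingroup branches sum to 1.0,
so a class's substitution parameter equals, to first order, the expected
fraction of polymorphic columns of that class — the scale on which
variability tables report. Defaults: IGS 0.0326, intron 0.0168, CDS 0.0129,
tRNA 0.0032, rRNA 0.0007. Indel events occur at half the class's target
gap-column frequency (defaults: IGS 0.0732, intron 0.0219, CDS 0.0107,
tRNA/rRNA 0) with geometric(½) lengths (mean 2), drawn as deletions or
insertions with equal probability; two planted long deletions (387 bp in
`ycf2-like` on the Acnida stem, 384 bp in the `psbM-like`–`trnD-like` spacer
on the Albersia stem) sit on top of that background, which is why measured
genome-wide indel frequencies run a few tenths of a percent above the
configured background. A saturation guard rejects per-branch substitution
probabilities above 0.5.

Exact recovery arithmetic used by the statistical tests: with per-class
gap-column target *f*, the measured indel-column frequency has expectation
`f / (1 + f/2)` (insertions enlarge the class-length denominator by f/2), and
its variance per site is `3f` (compound Poisson with E[L²] = 6 for
geometric(½) lengths) — the tests require agreement within 3 such standard
errors aggregated over 50 seeded replicates. SNP-frequency recovery is tested
on indel-free replicates, where columns are exactly ancestral sites and the
binomial expectation is the configured rate itself. Same-branch insertions
whose anchor site is deleted by a same-branch deletion are dropped (order
within a branch is otherwise ambiguous); the recorded per-branch mutation
ledger replays to byte-identical leaves, and identical config + seed gives
byte-identical output (both tested).

What the generator does *not* emulate — so what passing tests cannot show
about real data: codon structure and selection, rate heterogeneity beyond the
five-class model, IR boundary expansion/contraction, alignment error (the
true alignment is emitted, so aligner artefacts are absent by construction),
heterotachy, and base-composition effects beyond a global GC target.

## Problem sizes

The single end-to-end run in the acceptance script uses the full default
architecture (150.6 kb circle, 22 ingroup + 3 outgroup genomes). Replicate-
heavy statistics use miniature genomes by design: 11.5 kb reduced genomes
with 7 ingroup + 1 outgroup taxa for the 50-replicate parameter-recovery and
the monophyly-rate checks, and a 30 kb genome for the hotspot preset. These
sizes give the statistical tests standard errors tight enough to detect a few
percent of relative bias while keeping the whole suite fast.

## Known limitations

* The exact-match IR detector reports the largest *exact* pair; a genome with
  even one substitution between its IR copies will report slightly shortened
  IRs.
* The repeat scanner cannot see a repeat pair lacking an exact 12-mer seed
  under its transform, and reports maximal X-drop extents, which may trim a
  planted repeat's mutated ends.
* Per-pair discriminating marker sets are near-trivial (singletons) whenever
  any locus differs; the global minimal set is exponential in `max_size` and
  intended for matrices with tens of loci, not thousands.
* The hotspot count on full-rate data is dominated by merging (see above) and
  is not a stable summary statistic; the planted-segment recovery is.
* `screen_markers` resampling is a concordance heuristic, not a bootstrap
  over an inference model.
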