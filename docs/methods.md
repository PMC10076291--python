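# Methods

## Scope and data model

`spacerlink` links host MAGs to viral scaffolds through CRISPR
spacer→protospacer matches and layers network, conflict, provirus, Chi and
temporal analyses on top. Sequences are plain uppercase strings over
{A,C,G,T,N}; any comparison column involving an N counts as a mismatch
(conservative matching). All intervals are 0-based half-open in memory and
converted to 1-based inclusive only when writing GFF3. Scaffolds shorter
than 2500 bp are dropped at load (configurable; applied uniformly to host
and viral sequences).

## CRISPR array detection

Arrays are found with a CRT-style periodic-seed algorithm:

1. index all exact `seed_k`-mers (default k = 11);
2. chain occurrences recurring at periods within
   [repeat_min + spacer_min, repeat_max + spacer_max] (defaults: repeats
   21–48 bp, spacers 15–70 bp);
3. extend every chained occurrence column-by-column left and right while the
   per-column majority agreement across occurrences stays ≥ 0.8
   (1 − max_repeat_mismatch_frac);
4. inter-repeat gaps become spacers;
5. reject candidates whose repeat/spacer lengths leave the allowed ranges,
   whose repeats sit further than 20% from the consensus, or whose
   *adjacent* spacer pairs exceed 60% alignment identity (the tandem-repeat
   guard — tandem repeats always show near-identical adjacent "spacers";
   restricting the guard to adjacent pairs keeps it O(n) and avoids spurious
   rejections of very long arrays, where some pair among thousands will
   exceed the threshold by chance);
6. emit non-overlapping arrays, choosing the largest span first so fragment
   chains of an array can never shadow it, and reporting left to right.

Arrays keep up to 200 bp of flank on each side; arrays touching a scaffold
edge are flagged `partial`. Minimum two spacers per array. Detection
parameters emulate common CRISPR-finder conventions and are exposed in
`DetectParams`. Pre-annotated arrays can be loaded from GFF3
(`repeat_region` / `direct_repeat` / `spacer`) instead.

## Spacer→protospacer matching

Retention criteria: ≤ 1 substitution (no indels), query coverage ≥ 90%,
E ≤ 10⁻⁴. Sub-full coverage is realized only as contiguous clipping of at
most 10% of the spacer from one end — the only alignment shape compatible
with both thresholds at spacer lengths. The E-value uses the ungapped
Karlin–Altschul formula `E = K·m·n·exp(−λ·S)` with BLASTN-default reward
+2 / penalty −3, λ = 0.625, K = 0.41, m the spacer length and n the summed
target length over both strands; S = 2·matches − 3·mismatches. These
constants are configuration, not physics: they make the published E-value
filter computable without an external aligner.

The production search is exact by the pigeonhole principle: any admissible
core with ≤ 1 substitution contains an exact half, so looking up the k-mer
(k = 10) at the start of each half of every admissible clipping finds every
candidate; candidates are verified by direct Hamming count. Overlapping
admissible alignments at one locus (a full-length hit and its clipped
sub-alignments) are reduced to the single best-scoring one — ties broken by
length, then leftmost — so edge weights count *distinct protospacer loci*.
A brute-force sliding-window scan with identical retention and reduction
rules (`brute_match`) serves as the independent oracle; the suite asserts
set equality on randomized fixtures. Spacers too short for the seeded
guarantee (core below 2k) are refused with a pointer to the brute-force
path.

Matches with ≥ 50% of their interval inside a CRISPR array on the *target*
are flagged `in_array`: integrated spacers carry no adjacent PAM, are not
cleavable, and are excluded from virus–host edges.

## Networks, hyper-targeting, curation

MAGs enter the analysis only if completeness > 70% and contamination < 10%
(strict inequalities). Edges aggregate retained matches per (host, virus)
pair; weight = distinct target loci; "unique links" counts pairs. A pair is
hyper-targeted at ≥ 20 loci. Cross-taxon candidates are viruses whose linked
hosts differ at a chosen rank (hosts with an empty rank are flagged
unrankable and not counted). Curation applies: the MAG quality gate
(failing fails the candidate); an array-scaffold length floor of 10 kb
(flag-only — no published value exists for this cutoff, so it never
auto-fails); identical-spacer sharing between the implicated arrays
(≥ 5 shared spacers annotates possible horizontal transfer of the array,
also flag-only); and, when per-scaffold taxonomy is supplied, congruence
with the MAG lineage (incongruence fails).

## Interviral conflicts and proviruses

Spacers excised from virally-encoded arrays are searched against all viral
scaffolds (unclustered, to preserve array variation) with the same retention
rules; self-hits are dropped. A conflict is genuine only if at least one
supporting match lies outside the target's own arrays.

Provirus calling aligns CRISPR-encoding viral scaffolds to host-bin
scaffolds with an anchored banded aligner: exact 16-mer anchors, densest
co-linear diagonal window (width 32), then banded affine Smith–Waterman over
the band (match +1, mismatch −2; a gap of length g costs 5 + 2g). Identity
is matches over alignment columns, gaps counted as non-matches. Bit score
and E-value come from the same Karlin–Altschul constants as the matcher.
Calls require bit score ≥ 50, E ≤ 10⁻³, ≥ 2500 aligned columns and ≥ 70%
identity; alignments covering ≥ 90% of the host scaffold are classed
co-binned rather than integrated. The aligner reports one (best) locus per
scaffold pair; multiple independent insertions of the same virus into the
same scaffold are out of scope. On instances ≤ 20 kb the banded score is
required (and tested) to be within 1% of an exhaustive local DP
(Biopython's `PairwiseAligner` with the same scoring, used strictly as an
oracle).

Superinfection reporting classifies each host array as provirus-encoded
(≥ 50% of its span inside a called provirus interval) or host-native, then
attributes every host→virus match to its source array; pairs supported only
by `in_array` matches are flagged non-immunizing.

## Chi-site analysis

Chi density counts occurrences of the motif (default 5'-GCTGGTGG-3', the
canonical E. coli RecBCD attenuation site; the motif is configurable) with
overlaps allowed, on both strands by default (the strand convention is
recorded in the output metadata), normalized per 1000 bp. Per-virus targeting
intensity sums distinct loci over all supplied networks; subset means and
medians are reported rounded half-up to two decimals (0.115 → 0.12). The
density–targeting association uses Spearman rank correlation with a seeded
permutation p-value (default 10,000 permutations); with constant input the
correlation is reported as undefined rather than as a number.

## Temporal comparison

Viral populations: greedy longest-first clustering (ties by id) at global
identity c = 0.95, where identity = identical nucleotides in the best local
alignment (either strand, same aligner as above) divided by the shorter
sequence length. A word prefilter skips alignment for pairs sharing < 45% of
the candidate's 8-mers: a ≥ 95%-identity pair conserves ≥ ~57% of its words,
while unrelated 10-kb pairs share only ~26% through hash-space collisions.
The canonical greedy property (every member within c of its representative;
no representative within c of an earlier one) is audited by brute-force
all-pairs alignment in the tests.

MAG dereplication replaces a dRep-style pipeline with MinHash sketch ANI:
bottom-1000 sketches of canonical 21-mers, Mash ANI
`1 + ln(2j/(1+j))/k`, single-linkage components at ANI ≥ 0.95 (the
conventional species/population cutoff; configurable). Quality-filter
parameters of the original multi-tool pipeline are not reproducible and are
not attempted.

Cross-year reports count shared viral populations and MAG populations both
network-restricted and dataset-wide, plus shared (host-population,
viral-population) pairs; fractions print to one decimal percent. Array
comparison counts exactly identical spacers (either orientation), checks
whether shared spacers keep their relative order, and scans the 200-bp
flanks for a segment ≥ 60% identical to the consensus repeat over ≥ 50% of
its length — evidence of a partially degraded repeat and hence a shared
array origin even without shared spacers.

## Synthetic communities and what they do (not) show

The generator emits i.i.d. background sequence at a configurable GC and
plants arrays, protospacers, virally-encoded arrays (with optional shared
spacers), proviruses (integrated inserts or ≥ 90%-viral co-binned
scaffolds) and Chi motifs, recording everything in a JSON manifest. Three
constructions make recovery tests exact rather than statistical:

* spacers are drawn with pairwise Hamming separation ≥ 7 (and ≤ 0.55
  identity to their array neighbor), and a final verification pass searches
  every planted spacer community-wide, raising if it matches anywhere
  unplanned;
* protospacers planted with ≥ 2 mismatches place all substitutions in the
  interior that no admissible end-clipping can remove, so the one-mismatch
  pipeline recovers exactly the ≤ 1-mismatch links and none of the others;
* spacer edge characters are diversified at planning time so no repeat
  boundary column can reach the 80% agreement that would let repeat
  extension overrun into a spacer.

Default sizes (20 hosts × 2 scaffolds of 6–12 kb, 200 viruses of 8–15 kb,
arrays of 3–8 spacers of 25–45 bp with 23–40 bp repeats) are chosen to be
realistic for assembled metagenome fragments while keeping the full pipeline
under a few minutes on one CPU; the standard planted-link design
(`recovery_scenario_config`) plants 50 links at 0–1 mismatches and 10 at 2.

What passing these benchmarks does *not* show: the background has no gene
content, no repeats beyond the planted arrays, no strain microdiversity, no
chimeric or misassembled scaffolds, and no read-level noise — so perfect
recall here bounds only algorithmic correctness, not performance on real
assemblies, where array annotation quality and binning errors dominate.

## Numerical and degenerate-input conventions

Deterministic throughout: a single integer seed drives generation; detection,
matching, alignment and clustering are seed-free deterministic algorithms;
the only stochastic statistic (permutation p-value) takes an explicit seed.
Consensus ties break lexicographically. Empty networks summarize to zeros
and empty tables rather than errors. Mean/median rounding is half-up, not
banker's. Derived seeds stay below 2³¹.
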