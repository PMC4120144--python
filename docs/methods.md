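# Methods

## Model and procedure

`ranmap` aligns a single-end read *r* (|r| = m) to a reference genome *S*
under the assumption that *r* was sequenced, with errors, from a genome of
the same species: differences between *r* and its true locus are sparse and
well modelled as independent per-base events at a combined rate *b*
(sequencing error + polymorphism). The aligner reports the locus of a
substring of *S* within edit distance *t* of *r*, or declares the read
ambiguous/unaligned.

### Indexing

Two FM indices are kept: `backward` over *S* and `forward` over
reverse(*S*). Backward search over reverse(*S*) with the pattern consumed
left-to-right is exactly forward search over *S*; the pair gives maximal
exact extension in both directions from any read position at O(1) per
character. Suffix arrays are built by numpy prefix doubling (O(n log² n)),
which at the megabase scale this package targets is indistinguishable in
output from any linear-time construction — the construction algorithm
cannot affect results, only build time. The sentinel sorts before A; N is
retained in the indexed text so coordinates are preserved, but `N` never
matches during search, so seeds cannot span it. Occurrence (rank) tables
are stored as full cumulative counts per character — simple, O(1) rank, and
cheap at this scale; the suffix array is kept whole below 1 Mb and sampled
every 16 positions above, with LF-walking to recover unsampled entries.

### Seeding

For anchor *p* (2 ≤ p ≤ m): the maximal backward match is the longest
suffix of r[1..p−1] occurring in *S*, the maximal forward match the longest
prefix of r[p..m]; each side returns all its occurrences, capped at
`max_hits` (default 100, ascending positions) to bound worst-case repeats.
Only the maximal length is used — one length, many placements — rather than
all shorter co-matches; this keeps the candidate product small and is the
reading under which a seed is a single string with several genome
placements. Contiguity is tested with a position set (each forward start q
probes for a backward end at q−1) rather than a double loop; the result set
is identical. When one side has length zero, the other side alone is a
candidate seed. Seeds shorter than *W* are discarded.

At p = 1 the read is treated as circular: the maximal read *prefix* and
maximal read *suffix* are matched separately, and occurrence pairs whose
genome span differs from m by more than *t* are rejected — the gap between
the two blocks can absorb at most *t* indels. The span tolerance ±t is this
package's concretization; the conceptual description of the wrap-around
case fixes no bound. A prefix or suffix that alone reaches *W* also counts
as an ordinary seed. Because every read's first attempt uses p = 1, an
error-free read is resolved immediately by its full-length exact match.

### Parameters

With d ~ Binomial(m, b), µ = mb, σ² = mb(1−b):

| parameter | value | rounding | why |
|---|---|---|---|
| t (distance budget) | ⌈µ + c·σ⌉, c = 4 | up | conservative: P(d > t) < 1% across m ∈ [35,400], b ∈ [0.01,0.04] (verified by simulation) |
| W (min seed length) | ⌊m / max(t,1)⌋, ≥ 1 | down | permissive: never filters the expected block of length ≥ m/(d+1) |
| A (attempts) | a_multiplier·(t+1), default multiplier 1 | — | the longest error-free block (≥ m/(d+1) by pigeonhole) is anchored within d+1 ≤ t+1 uniform draws in expectation |

The formulas are real-valued; the integerization (ceil for t, floor for W,
and the max(t,1) guard at b = 0) is this package's choice, made so that a
larger budget never shrinks and a seed filter never tightens by rounding.
b defaults to 0.02 — the simulator's base error rate — and deliberately does
not add the polymorphism rate; users aligning real data should pass their
own b. Explicit `--t/--W/--A` overrides bypass derivation.

### Extension and the two-candidate rule

A seed matching r[i..j] at genome start g is extended by comparing
r[1..i−1] against the (i−1)-length genome stretch ending at g, and
r[j+1..m] against the (m−j)-length stretch following the seed; the right
comparison runs on the budget left by the left one (outcome-identical to
two independent budget-t tests, faster). Equal-length flanks are compared
by edit distance, so a small indel in a flank costs ~2 edits (the indel
plus the boundary shift) — absorbed by t in practice. A flank running past
a genome end is simply shorter, and the DP charges the length deficit one
edit per missing base. Wrapped seeds pin both read ends; the flank is the
gap interior between the two blocks, and overlapping placements
(genome span < matched length) are charged their overlap.

Within an attempt, candidates from both strands (the reverse complement is
aligned by the same machinery; positions refer to the forward genome) are
pooled and deduplicated by (genome start, strand), keeping the smaller
distance. One or two distinct candidates align the read — the primary is
the lower distance, ties broken leftmost then + strand, and the second is
emitted as a SAM secondary record. Three or more candidates fail the read
as ambiguous immediately; that threshold is deliberately literal (> 2).
Ambiguous and exhausted reads both emit unmapped records, distinguished by
a `ZS` tag, and both count as unaligned in evaluation.

### Pruned edit distance

`bound_edit_distance(x, y, t)` evaluates the standard Levenshtein DP
(d_{i,0} = i, d_{0,j} = j; +1 on mismatch) restricted to the band
|i−j| ≤ t, returning t+1 as soon as the active row's minimum exceeds t.
This is exact for the query d(x,y) ≤ t: inside the budget the value equals
the full DP's. Two deviations from a purely literal transcription of the
pruned algorithm are deliberate, and a `literal_init=True` option preserves
the transcribed variant for study: the zero-initialized first row/column
make d("", y) = 0 for any y, i.e. free end gaps, which would break the
flank budget (a read flank could be deleted for free); and the match
indicator must add 1 on *mismatch* — the inverted reading cannot reproduce
edit distance. `N` is never equal to anything, including itself, in both
the bounded and full DP.

## Synthetic data

The simulator emulates wgsim under its default settings, single haplotype:

| parameter | default | meaning |
|---|---|---|
| base_error_rate | 0.02 | per-base sequencing error, uniform substitution |
| mutation_rate | 0.001 | per-site polymorphism probability |
| indel_fraction | 0.15 | polymorphisms that are indels (ins/del equiprobable) |
| indel_ext | 0.3 | geometric continuation: P(L = l) = 0.7·0.3^(l−1), E[L] = 1/0.7 |
| read length | 35–400 bp | uniform start, uniform strand |

Truth is encoded in read names as `<source>_<start>_<end>_<strand>_<serial>`
with 1-based inclusive *reference* coordinates, mapped back through the
planted variants (a read starting inside an insertion is attributed to the
preceding reference base; the 20-bp evaluation tolerance absorbs that
ambiguity). Reads never span the genome end.

What the generator does *not* emulate: position- and quality-dependent
error profiles, platform-specific indel error (as opposed to polymorphism),
GC bias, coverage waviness, diploidy, and — most importantly — realistic
repeat structure. The benchmark genome is i.i.d. uniform ACGT, whose repeat
density at k = 35 is ~0. Passing benchmarks on it demonstrates the
machinery (seeding, budgets, strand handling, coordinate bookkeeping) under
the stated error model; it does not predict performance on repeat-rich
genomes, where ambiguity failures necessarily grow with D(S|k). The repeat
density statistic and its correlation with recall are exercised on
constructed repeat gradients instead.

## Evaluation conventions

Primary SAM records only; a read is *aligned* iff mapped, *correct* iff
aligned on the truth strand within 20 bp of the truth start (strand
agreement is enforced here even though the classic evaluation script's
behaviour on strand is undocumented). precision = correct/aligned (0 when
nothing aligned), recall = correct/total, misalignment = (aligned −
correct)/total, so misalignment + recall = aligned/total identically.
D(S|k) sums occurrence counts of *distinct* k-mers with f ≥ 2 over
N-free windows, forward strand only, no reverse-complement folding.

## Numerical and degenerate-input choices

- b = 0 derives t = 0, W = m, A = 1: pure exact matching.
- Empty seed set or all-rejected extensions simply advance the attempt loop.
- Candidate sets are deduplicated before the >2 test, so the same locus
  found via two seeds is one candidate.
- Anchor draws are uniform on {1..m} with replacement; repeats of a
  previously tried p are allowed (the sampling analysis behind A assumes
  this).
- Per-read RNG substreams are seeded from (seed, read ordinal), making
  results independent of batch partition and read order.
- CIGAR is emitted as `<m>M`: the method reports an interval and an edit
  distance, not a base-level operation trace; NM carries the distance.
- Multi-record FASTA: first record only, with a warning (single-genome
  scope); non-ACGT input characters become N.

## Problem sizes

The shipped tests and the acceptance script run on synthetic genomes of
20–100 kb with 10⁴ reads, 10⁵-trial parameter simulations, and exhaustive
small-string checks — sizes chosen so the whole suite re-runs in minutes on
one core while leaving every statistical check far from its Monte-Carlo
noise floor. The aligner itself is pure Python over numpy rank structures;
megabase genomes index in seconds, but aligning 10⁵+ reads against
multi-megabase references is outside the intended desk scale.

## Known limitations

- Mapping quality is not calibrated (MAPQ 255); downstream tools that
  weight by MAPQ should not consume this SAM blindly.
- No paired-end support, no clipping/local alignment: a read is either
  placed end-to-end within budget t or not at all.
- The seed-length filter W interacts with max_hits on highly repetitive
  genomes: a correct locus can be crowded out of a capped occurrence list.
  The cap (100/side) was chosen to bound worst-case work, not tuned.
- Reported positions can shift by the length of a flank indel; this is
  within the 20-bp correctness convention but matters for base-precise SNP
  calling.
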