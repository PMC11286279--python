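# Methods

## Model

A collection is an ordered multiset M = [T₁, …, T_k] of non-empty byte
strings (total length N_M, alphabet Σ of size σ). Two byte values are
reserved and rejected on input: `$` (0x24), the end-of-string separator,
and `#` (0x23), the terminator of the concatenated BWT. Conceptually
`# < $ < Σ`, and the multidollar construction uses k distinct dollars
`$₁ < ⋯ < $_k`; in every rendered output all sentinels appear as the
single glyph `$` (the normalized concBWT additionally strips the leading
separator contributed by the terminator rotation and renames `#` to `$`,
so that all separator-based outputs have the comparable length N_M + k).

The eBWT is built on the ω-order: S precedes T when S^ω <_lex T^ω, with
ties — equal infinite powers, equivalently equal primitive roots —
broken by smaller exponent. The comparator truncates the infinite
comparison at |S| + |T| symbols; by Fine and Wilf's periodicity theorem,
agreement to that depth forces equal roots, so the truncation is exact.

## Construction algorithms

**Separator-based variants** are computed as the last rotation column of
a suffix array over the sentinel-augmented concatenation. Sentinels are
never materialized as extra alphabet symbols: the concatenation is
encoded as integers with dollar i mapped to i (1…k) below every alphabet
byte (byte b ↦ b + k + 1); for concBWT, terminator ↦ 0, dollar ↦ 1,
byte ↦ b + 2. Because each concatenation ends in a globally unique
symbol ($_k resp. #), no suffix is a proper prefix of another, so the
suffix order equals the rotation order and BWT[i] = S[SA[i] − 1 mod n].
The suffix array is prefix doubling over numpy argsorts, O(n log² n) —
adequate at the package's target scale (up to ~10⁵–10⁶ characters);
engineering-scale construction (induced sorting, prefix-free parsing,
external memory) is deliberately out of scope.

**eBWT / dolEBWT** sort all conjugates of all members directly in
ω-order: each conjugate is keyed by its power expanded to twice the
maximum member length (sufficient for the truncated comparison), with
ties broken by exponent, then stably by (input index, offset). Tied
conjugates arise only from duplicated strings or non-primitive members
and contribute identical characters, so the stable tie-break fixes
provenance bookkeeping without affecting the text. dolEBWT goes through
this same conjugate sorter on the dollar-appended members — not through
the mdolBWT shortcut — so that the identity
`dolEBWT(M) = mdolBWT(lex(M))` remains a genuine cross-check between two
independent code paths, which the test suite asserts on hundreds of
random collections.

**colexBWT** sorts members by their reversed strings, stably (equal
strings keep input order; their rotations are identical, so the text is
unaffected and the permutation is deterministic).

**optBWT.** The run-minimizing order is constructed from the structure
of interesting intervals rather than by search. Within the interval of a
left-maximal shared suffix U, the BWT characters are the characters
preceding U in the members having suffix U (the separator when the
member *is* U), listed in the chosen global order; outside the
intervals the transform does not depend on the order at all. Two members
are ordered relative to one another exactly once, at the interval of
their longest common suffix — at every shallower interval they share the
next character and sit inside the same block. Consequently an order is
optimal iff, in every interval, members are grouped into one block per
distinct character (one run each), with the only remaining freedom being
which block comes first and which last, used to merge the border runs
with the context outside the interval. Intervals that are positionally
adjacent share a border, so each maximal chain of adjacent intervals is
resolved by a small dynamic program over (first, last) block choices;
isolated intervals are chains of length one. The resulting per-interval
block ranks induce a total order via a pairwise comparator (falling back
to input index on equal strings). The construction is validated against
the exhaustive minimum over all k! input orders on hundreds of seeded
instances with k ≤ 6, including binary alphabets, duplicated members and
forced shared suffixes.

## Interesting intervals

Intervals are enumerated on the multidollar rotation matrix: every
rotation starting at a suffix U of Tᵢ (including U = ε, the rotation
starting at $ᵢ) is mapped to (U, preceding character), rows are grouped
by U, and groups with ≥ 2 rows and ≥ 2 distinct preceding characters are
reported with their 1-based rank range [b, e]. Contiguity of each group
and pairwise disjointness are asserted on every output, and invariance
of the coordinates under input permutation is property-tested. The
preceding character of a whole-member suffix (U = Tᵢ) is the separator;
this makes {GT, AGT} produce an interesting interval for U = GT,
consistent with the separator character that actually appears at that
row of the transform.

The per-interval run bound takes the interval's Parikh vector
(separators pooled as one symbol, since all render as `$`): with n_a the
dominant multiplicity and N_a the rest, the maximum run count over all
arrangements is the full width when n_a − 1 ≤ N_a, else 2·N_a + 1. The
variability of a collection is Σ bounds / Σ widths over its intervals;
with no intervals it is reported as 0 with an explicit `defined=False`
flag (never NaN), keeping downstream tabulation robust while preserving
the distinction.

Both denominators of the "fraction of positions in interesting
intervals" are reported — the separator-based transform length N_M + k
(the headline value, sharing a denominator with the normalized Hamming
distances) and the raw dataset length N_M — since either convention is
defensible.

## Inversion

Separator-based texts are inverted by backward LF walks from each of the
first k rows (the dollar-initial rotations), collecting characters until
a separator is met. These walks step only through ordinary characters,
whose LF mapping is independent of dollar-rank conventions, so one
procedure inverts mdolBWT, colexBWT, optBWT and dolEBWT texts alike,
recovering the members in concatenation order; re-transforming in that
order reproduces the text bit-exactly. Malformed texts (walks that do
not terminate, cycles that do not cover the text) raise errors.

A raw concBWT (containing a literal `#`) is a single-string BWT and is
inverted by the textbook cycle walk anchored at the terminator row. For
a *normalized* concBWT the terminator's position is not recoverable in
closed form, so inversion tries each separator occurrence as the renamed
terminator and accepts the candidate whose re-transform equals the
candidate text — O(k) single-string inversions, cheap at this scale.

eBWT inversion decomposes the LF permutation into cycles, one per
primitive conjugacy class occurrence; without ranks, classes are
reported as their lexicographically least rotations, sorted (the
transform encodes no input order, so a canonical order is the honest
output). With the conjugate-rank sidecar each member is recovered
exactly. Limitation: a non-primitive member U^m is indistinguishable
from m copies of U (their eBWTs are identical), so exact recovery is
guaranteed only for collections of primitive members; class mode folds
to roots with multiplicity in all cases, preserving total length.

## Synthetic collections

The generator produces deterministic collections from (spec, seed) via
numpy's PCG64; no global random state is touched. Modes:

- `iid` — uniform characters, lengths uniform in a range; a low-overlap
  baseline.
- `mutated-copies` (default) — one random ancestor; each member is a
  copy with per-site substitutions (default rate 0.02, roughly one
  difference per 50 bp, a realistic within-collection divergence for
  amplicon or closely related read data) and optional indels. Many short
  similar members maximize shared suffixes and hence interesting-interval
  coverage — the regime where the variants differ most.
- `shared-suffix` — random bodies with explicit suffix blocks appended,
  forcing interesting intervals at known suffixes.

The generator emulates the *combinatorial* structure that drives variant
divergence (shared suffixes, similarity, duplicates). It does not model
sequencing error profiles, quality strings, coverage biases, or genome-
scale repeat structure, so passing tests demonstrate correctness of the
transforms and bounds, not performance claims about real datasets.

## Test-scale choices and numerical notes

Randomized suites run at desk scale: oracle-equivalence and identity
checks on ~200 collections of total length ≤ 200; exhaustive optimality
on 100+ collections with k ≤ 6 (member length ≤ 5, so 6! rotation sorts
stay cheap); interval bound enumeration for widths ≤ 8. Oracle caps
(naive sorts ≤ 500 characters, exhaustive order search k ≤ 7, multiset
enumeration width ≤ 10) are arguments, not constants, and tests raise
them where an example needs it (the 8-string example at k = 8). All
arithmetic on counts and ratios uses exact integers and `Fraction`;
floats appear only in serialized reports.

## Known limitations

- O(n log² n) construction and pure-Python conjugate sorting bound
  practical inputs to a few megabytes.
- The optBWT order is canonical but not unique; other orders attain the
  same minimum run count, so optBWT *texts* from different tools may
  differ even at equal r.
- Normalized-concBWT inversion assumes the text is a genuine concBWT; a
  multidollar text that happens to lack a valid terminator placement is
  rejected rather than reinterpreted.
- gzip input is supported for FASTA/FASTQ/lines; no SAM/BAM/VCF
  ingestion.
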