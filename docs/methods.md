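# Methods

## Model and problem statements

A weighted string assigns every position a probability distribution
over a finite alphabet; a concrete word is a factor when all its
letters have positive probability at the corresponding positions, and
is *valid* at the cumulative weight threshold 1/z ∈ (0, 1] when the
product of those probabilities reaches 1/z. The model is position-wise
independent: the probability of a word is always the plain product of
per-position letter probabilities. That is the right abstraction for
IUPAC ambiguity codes and per-base quality uncertainty, and the wrong
one for haplotype-linked variation, where letter choices at different
positions are correlated — a caveat inherited by everything below.

A repetition v = u^e (e ≥ 2) must have a primitive root u, and is
reported as (i, p, b, e), where b fixes the letters of u at the
branching (black) positions of its first copy. Two variants are
solved:

* **every-copy validity** (`solve_problem1`): each occurrence of u in
  v is valid at 1/z. This is the headline problem; a long repeat
  tract qualifies even though its total probability decays
  geometrically with e.
* **whole-span validity** (`solve_problem2`): the entire u^e is valid
  at 1/z. This is the sub-problem the composition machinery is built
  on, and is independently useful when the whole tract must be
  believable at once.

## Pipeline

1. **Filter** (`filter_letters`): letters with probability below 1/z
   cannot take part in any valid factor and are dropped. Surviving
   probabilities are *not* renormalised — validity always refers to
   the original distribution. Filtering is idempotent; raw-input sum
   validation (±1e-6) happens on ingest and at the solver entry
   points, not inside the filter.
2. **Split** (`split_unsupported`): positions left empty by the filter
   cannot support any valid factor, so the string is cut around them
   and segments are processed independently, with outputs mapped back
   to original coordinates.
3. **Colour** (`colour`): a position is WHITE when a letter is certain,
   GREY when exactly one letter exceeds 1 − 1/z (its competitors are
   then all below 1/z and have already been filtered away, so grey
   positions hold exactly one letter), and BLACK otherwise. Black
   positions are the only places a valid factor can choose between
   letters. A probability of exactly 1 − 1/z is *not* "greater than",
   so such positions are black; for z < 2 no position can be black.
4. **Generate** (`generate_extended_factors`): concrete strings are
   grown left to right so that every valid factor occurs in at least
   one of them. One seed starts at the segment start; each black
   position seeds one factor per stored letter plus one empty factor
   starting just after it. Grey positions contribute their single
   letter and are treated as certain (probability 1) during
   generation; only black-letter probabilities enter the running
   product, and a factor stops at the black position whose inclusion
   would drop that product below the working threshold. Factors are
   de-duplicated on (start, letters). A valid factor can contain at
   most ℓ = log z / log(z/(z−1)) black positions, which bounds both
   the branching depth and (by the counting argument tested in the
   suite) the number of factors covering any position by z^ℓ(2ℓ+1).
5. **Partition** (`maximal_repetitions`): all maximal repetitions of
   each extended factor, translated back to original coordinates.
6. **Break or compose**:
   * whole-span: the LF array (below) bounds the longest valid factor
     at every start; scanning the occurrence starts of each maximal
     extended repetition left to right, the longest valid repetition
     at each start is emitted, and an emission whose span is contained
     in its predecessor's is suppressed as redundant.
   * every-copy: the machinery runs at the relaxed threshold 1/z²
     (any square whose halves are valid at 1/z has whole-span
     probability ≥ 1/z²), maximal extended repetitions are split into
     their overlapping squares, squares are kept when LF′ — the LF
     array at 1/z on the same factor — certifies both halves
     (LF′[i] ≥ p and LF′[i+p] ≥ p), and surviving squares are chained:
     a square extends a repetition when it starts one period later
     with the same period and agrees with it on the black letters of
     the overlap. Scanning starts in ascending order and deleting
     squares as they are consumed makes every chain left-maximal and
     consumes each square exactly once (asserted at run time). The
     default report expands each maximal chain into the repetition
     starting at every copy, with b recomputed per copy; a
     maximal-only mode is available.

**LF arrays** (`compute_lf`): LF[i] is the length of the longest
prefix of the suffix at i whose cumulative probability — now using the
*actual* probability at every position, grey included — meets the
threshold. Because extending a window only multiplies by values ≤ 1,
end positions never move left and a two-pointer sweep with a sliding
product computes the array in linear time.

## b-sets and reconstruction

b records (offset, letter) for the black positions inside the first
copy of u; every other offset is forced either by a non-black position
in some copy or is black in the first copy but non-black in a later
one. `reconstruct_v` inverts the quadruple accordingly. For the
every-copy solver, "black" refers to the colouring at the working
threshold 1/z² — the positions where the square machinery actually had
a choice; the brute-force oracle follows the same convention so the
two routes are comparable field by field.

## Numerical choices

* Probability comparisons use a relative tolerance of 1e-9: a value
  within tolerance of a bound meets "≥" and fails a strict "<". The
  grey/black boundary (exactly 1 − 1/z ⇒ black) is enforced under the
  same rule.
* The sliding product in `compute_lf` is recomputed from scratch over
  the current window after 64 divisions, bounding float drift without
  changing the linear-time behaviour.
* Thresholds are stored as z; the relaxed threshold is z², computed
  once, so 1/z² is exact in floating point whenever 1/z is.

## Partitioner

The plain-string partitioner computes all maximal repetitions — maximal
integer powers of primitive roots — via divide and conquer over maximal
periodic regions: periodicities crossing a window midpoint are found
with longest-common-extension queries (Z-arrays anchored at the
midpoint), candidates are re-extended in the full string so clipping by
window boundaries cannot truncate a region, and each region of length L
and period p contributes one repetition per phase d < p with
⌊(L−d)/p⌋ ≥ 2 copies whose root is primitive (roots of
non-smallest-period regions are proper powers and drop out). Windows of
24 positions or fewer use a direct quadratic scan, which is faster than
the recursion at that scale. A wholly independent naive enumerator —
per-start square scan, left-maximality check, exponent extension —
serves as the oracle; the two agree on all binary strings to length 12
and on random strings to length 200 over alphabets of 2–4 letters.

## Oracles and what "equivalent" means

`brute_force_problem1` and `brute_force_valid_repetitions` enumerate
candidates directly from the definitions (all concrete roots from the
filtered letters, exponent maximality by extension). Every-copy
results match the solver *exactly* as quadruple sets. Whole-span
results match up to the break-up reporting convention: the solver may
additionally emit a repetition that is right-maximal only within a
threshold-truncated extended factor (a shorter echo of a longer valid
repetition it also reports); the suite therefore checks that every
solver emission is valid per the oracle's predicate and that every
oracle repetition's span and root are covered by an emission of the
same period and phase. Exponent maximality and left-maximality in the
whole-span oracle are taken with respect to *valid* occurrences, which
is what the LF-bounded break-up computes; whether a merely-occurring
(positive-probability but invalid) flanking copy should instead block
maximality is a modelling choice the definitions leave open.

## Synthetic data

`synthesize` emulates the intended use case at test scale: a uniform
random background over the alphabet, planted (period, exponent)
repeats at random non-overlapping starts with primitive random roots,
guard letters immediately flanking each plant chosen to break the
periodicity (so planted start and exponent are exact ground truth),
and branching positions (two letters at 0.5/0.5) inserted at a
requested density, capped inside planted spans so every copy stays
valid at the requested threshold and never placed on guards. It is
deterministic under its seed. What it does not emulate: correlated
(haplotype) uncertainty, skewed branching distributions, indel
divergence between copies, and alphabet-nonuniform background
composition — so 100% recall on these fixtures demonstrates the
solver's correctness on the model's own terms, not robustness to
model violations.

## Problem sizes used by the test suite

Exhaustive checks run all binary strings to length 12 (partitioner)
and all 87 360 weighted strings of the small distribution family
(certain a, certain b, 0.5/0.5, 0.75/0.25 per position) to length 8 at
thresholds 1/2 and 1/4 (both solvers, ~175k pipeline+oracle runs);
random checks add 200 instances to length 12. The generation bounds
(ℓ, z^ℓ(2ℓ+1) coverage, total length) are verified on 100 random
four-letter strings of length 1000 — 50 per threshold — with a
70/15/10/5 mix of certain, balanced, skewed and three-letter
positions. These sizes keep the full suite at a few minutes while the
exhaustive families make the correctness argument where it matters:
the combinatorial interplay of branching, truncation and composition
is fully explored at small n.

## Known limitations

* Runtime grows steeply with z through the z^ℓ factor-generation
  constant; the method is intended for constant, modest thresholds
  (z of a few), exactly as the existing art assumes.
* No runs-style compact representation: the output enumerates
  repetitions, which is Θ(n log n)-sized in the worst case.
* Probabilities must sum to 1 per position on input; don't-care
  letters and renormalisation are deliberately out of scope.
* FASTA input is a lossy convenience path (uniform expansion of
  ambiguity codes); exact per-base probabilities require the native
  matrix format.
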