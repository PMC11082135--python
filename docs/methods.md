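# Methods

## Grid and conventions

Worms move on the integer lattice with 8-connectivity (Chebyshev
neighbours).  Absolute directions are numbered 0–7 clockwise with
0 = (1, 0); odd directions are diagonals.  Relative turns add to the
heading modulo 8, so turn 2 from an eastward heading points south.  The
absolute convention is arbitrary — only relative turns are observable — and
the mirror-equivalence tests confirm outcome-independence from chirality:
running a code and its digit-mirrored twin (d ↦ 8 − d) produces reflected
paths with identical category, population and rule count.

Edges are undirected and stored sparsely as canonical endpoint pairs; the
grid is unbounded.  Two diagonals of the same unit cell may both be
traversed — geometric crossing is not an obstruction, only re-use of an
identical edge is.  This choice is empirically pinned by the recursive
census: forbidding crossings changes the depth-1..5 census to
3/20/103/486/2200, while allowing them yields 3/21/106/475/1902 with the
category split (1816 N, 15 T, 71 L) that the acceptance suite asserts.

## The run loop

Order of checks per iteration, fixed by the category minima it produces:

1. population ≥ limit → run loop detection; `L` if found else `R`
   (so a worm with limit 1 is `R` at population 1, before any decision);
2. sense; zero free paths → `T` (parity forces this to the origin);
3. one free path → take it, recording the step but creating no rule;
4. otherwise consult rule memory; on a miss ask the decision source —
   exhausted → `N`, unavailable digit → `I`, else store and apply.

Rule memory is keyed on the *relative* 7-bit availability pattern
(rotation-invariant).  Absolute keying is refuted by the census: it would
give 24 worms at depth 2 instead of the observed 21, because the all-free
pattern would not re-fire at rotated positions.

Two invariants are asserted across all test runs: the traversed multigraph
always has exactly two odd-degree vertices (origin and head) or none when
the head is at the origin, and consequently the number of free paths is odd
everywhere except at the origin, where it is even.  Dead ends can therefore
only occur at the origin, and the origin can demand a fresh rule at most
three times (6, 4, 2 paths free), which yields the 60-rule bound.

## Loop detection

Looping worms settle into a periodic tail of decisions.  The detector runs
on the **rule-activation record** — the subsequence of steps where a stored
or new rule fired, excluding forced single-path moves.  Forced moves are
deterministic consequences of the geometry; excluding them makes the
reported loop length count the decision cycle rather than the line cycle
(the long looper `50275752501275776276353217` has a 484-activation cycle
that spans 509 lines, 25 of them forced).

Detection is suffix-anchored: a period `p` qualifies if
`min_block ≤ p ≤ n / min_repeats` (defaults 6 and 4) and the maximal
`p`-periodic suffix contains at least `min_repeats` complete copies,
optionally ending in a partial copy.  The `min_block` window guards against
transient repetition (five copies of a five-digit block are not a loop),
but genuinely tight loops exist — `337` has primitive period 4 — so the
*reported* block is the primitive period of the detected suffix, which may
be shorter than the window.  The scan uses a Z-array on the reversed
sequence (O(n) per candidate sweep); a naive try-every-period-and-start
oracle cross-checks it exactly on hundreds of random and constructed
sequences.

By default classification happens once, at the population limit, making
results independent of check timing.  `LoopConfig.cadence` enables periodic
early checks that stop long loopers sooner; this can only convert late `L`
into early `L`, never change a `T` or `R` verdict at the same limit.

## Generators and study conditions

* **Preset codes** may start with any digit (how category `I` minima are
  demonstrated).
* **Random policies** pick uniformly among free turns, with the first rule
  drawn from {1, 2, 3} so random worms are mirror-canonical; they can only
  end `T`, `L` or `R`.  Batches derive one 31-bit sub-seed per worm from the
  batch seed.
* **Recursive enumeration** roots at first digits {1, 2, 3} and expands only
  category-`N` nodes, one child per turn free at the stalling point, in
  ascending digit order — deterministic and pruned (no `I` worms are ever
  generated).
* **Brute force** yields every code with first digit in {1, 2, 3} and later
  digits in {0..7}\{4}: 3·7^(k−1) codes of length k, Σ 3·7ⁿ in total.

Study conditions used by tests and the acceptance script: the census runs
to depth 5 at population limit 250,000 (the full 1,902-worm table; deeper
censuses use the identical code path but grow ~4× per level).  The random
study runs 1,000 worms at limit 100,000 with a fixed seed, plus 200-worm
sweeps at limits 10³/10⁴/10⁵ for the category-flow trend; at these sizes
only qualitative claims are asserted (R falls and T rises with the limit,
even rule counts are commoner than odd, first rule 1 is commonest among
enumerated worms).  Point estimates such as exact category percentages need
order-of-magnitude larger batches and limits and are not asserted.

## Numerical and display choices

All combinatorial quantities use exact integer arithmetic.  The worm-count
product 3·6·5²¹·3³⁵·4·2 = 48·5²¹·3³⁶ is checked for exact equality of both
factorisations; the exact 34-digit value begins 3.435393…×10³³, so it
truncates to 3.43×10³³ and rounds (half-even, 3 s.f.) to 3.44×10³³ — the
`scientific` field reports the rounded form.  The layer formula 24n − 16 (outward edges into Chebyshev
ring n) is validated against direct geometric enumeration for n = 1..10.

SVG rendering flips the y axis for screen coordinates, draws one line per
traversed edge and marks the origin; output is byte-identical for identical
input and style.

## Known limitations

* The minimal terminating population is 14, attained by six five-rule worms
  (31071, 33053, 36106, 36306, 36506, 36706).  The classic five-rule
  example `26326` is sometimes quoted with population 14, but under the
  semantics that reproduce the full census it draws 16 lines (two squares
  plus two three-line origin returns; the 14-line worms open with a
  triangle instead).  No digit relabeling reconciles a 14-line `26326`
  with the census, so the package reports 16.
* The detector cannot see "shape growers" whose repeating pattern grows
  each cycle (e.g. `16566`); they stay in category `R`.  Deep censuses are
  known to contain such worms, so the L/R split at depths ≥ 7 is
  detector-dependent even though L+R is not.
* Loop detection is string-based; it does not verify the loop geometrically
  (e.g. by a translation vector), so a sufficiently long coincidental
  repetition of decisions would be misreported.  The ≥ 4-repeat,
  ≥ 6-activation window makes this unlikely in practice.
* Pure-Python stepping handles ~10⁵ lines/s per worm; populations beyond
  ~10⁷ lines or censuses beyond depth ~7 need acceleration (e.g. hashlife-
  style macro-stepping), which is out of scope.
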