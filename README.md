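# octoworm

Paterson's worms on a square grid with diagonals: an agent-based lattice
simulator for the feeding trails of sediment-burrowing worms, together with
the enumeration machinery and combinatorial bounds for its code space.

Benthic invertebrates leave meandering feeding trails (preserved in trace
fossils) that avoid ground already grazed.  The classic Paterson's-worms
model captures this on a hexagonal grid; `octoworm` implements the richer
eight-direction variant: worms walk an unbounded square lattice where each
point has four axis and four diagonal neighbours, never re-traverse an edge,
and remember one decision per sensed situation.

## The model

A worm starts at the origin with one line toward +x.  At each point it
senses which of the 7 non-reverse relative directions `{0,1,2,3,5,6,7}` are
free (`0` = straight on, `2` = 90° right, `4` = reverse — always blocked,
`6` = 90° left).  The 7-bit availability pattern is the key of the worm's
rule memory: the first time a pattern occurs the worm picks a free turn and
stores it as a rule; every recurrence repeats that decision.  A single free
path is taken automatically without a rule.  The worm's *code* is the digit
string of its rules in creation order (its genotype), and its *population*
is the number of lines drawn.

Each run ends in one of five categories:

| | |
|---|---|
| `T` | terminated — no free path (only possible back at the origin) |
| `L` | a repeating loop was detected in the rule-activation record |
| `R` | still running at the population limit, no loop found |
| `I` | a preset rule named an already-traversed path |
| `N` | a new rule was needed but the code was exhausted |

Counting sensor states bounds the genome: of the 2⁷ = 128 patterns, 64 have
an odd number of free paths (1×7, 21×5, 35×3, 7×1); single-path states need
no rule and even states occur only at the origin (at most three times, with
6, 4 and 2 paths free), so no worm can set more than
64 − 7 + 3 = **60 rules**, and the number of distinct 60-rule worms is at
most 3·6·5²¹·3³⁵·4·2 = 48·5²¹·3³⁶ ≈ 3.4×10³³.

## Worked example

```pycon
>>> from octoworm import run_worm, replay, mirror_code
>>> r = run_worm("26326")
>>> r.category.value, r.population, r.rules_used
('T', 16, 5)
>>> replay(r.activation_sequence).position   # dead end back at the origin
(0, 0)
>>> run_worm("36306").population             # a minimal terminating worm
14
>>> mirror_code("26326")                     # its reflection twin
'62562'
>>> r = run_worm("337")                      # the shortest looper
>>> r.category.value, r.loop.block_length
('L', 4)
```

Worm `26326` draws a square, returns to the origin, and keeps re-using its
first rule until all eight origin edges are consumed: four origin visits, 16
lines, five rules.  The smallest possible terminating population is 14,
reached by six five-rule worms such as `36306`.  Worm `337` settles into a
tight loop whose primitive repeating segment is 4 rule activations long.

From the shell:

```bash
octoworm run --code 26326 --svg worm.svg
# {"code": "26326", "category": "T", "population": 16, "rules_used": 5, ...}
octoworm enumerate --depth 5 --limit 250000 --csv census.csv
octoworm random --n 1000 --limit 100000 --seed 42
octoworm bounds
octoworm interactive          # pick each new rule yourself
```

The depth-5 census (`--depth 5 --limit 250000`) enumerates all 1,902 valid
worms with up to five rules: 1,816 stall needing more rules (`N`), 15
terminate (`T`), and all 71 worms that reach the limit are recognised as
loops (`L`).

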