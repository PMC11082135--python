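"""Exact counting arguments for the eight-direction grid.

These are the closed-form bounds on the worm "genome": how many distinct
sensor states exist, how many rules a single worm can ever set, and how many
distinct worms the grid can host.  Everything is computed with exact integer
arithmetic; floating point appears only when formatting the final display.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from decimal import Decimal
from typing import NamedTuple

__all__ = [
    "StateCensus",
    "sensor_state_census",
    "max_rules_bound",
    "Eq1Result",
    "eq1_max_worms",
    "upper_bound_worms",
    "layer_outward_paths",
    "bounds_summary",
]


@dataclass(frozen=True)
class StateCensus:
    """Tally of the 2^7 = 128 availability states by free-path count."""

    counts: dict  # available-path count (0-7) -> number of states

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def odd_total(self) -> int:
        return sum(v for k, v in self.counts.items() if k % 2 == 1)

    @property
    def even_total(self) -> int:
        return sum(v for k, v in self.counts.items() if k % 2 == 0)


def sensor_state_census() -> StateCensus:
    """Enumerate all 128 7-bit availability states and tally by free count.

    Away from the origin the number of free paths is always odd; of the 64
    odd states, 1 has 7 free paths, 21 have 5, 35 have 3 and 7 have 1.
    """
    counts: dict[int, int] = {k: 0 for k in range(8)}
    for bits in itertools.product((False, True), repeat=7):
        counts[sum(bits)] += 1
    return StateCensus(counts)


def max_rules_bound() -> int:
    """Upper bound on the rules a single worm can set: 60.

    Odd-availability states can host rules except the seven single-path
    states (those moves are taken automatically): 64 - 7 = 57.  Even
    availabilities occur only at the origin, which can demand a fresh rule at
    most three times (with 6, 4 and 2 paths free), adding 3.
    """
    census = sensor_state_census()
    odd_rule_states = census.odd_total - census.counts[1]
    even_origin_rules = 3  # origin visits with 6, 4, 2 paths free
    return odd_rule_states + even_origin_rules


class Eq1Result(NamedTuple):
    exact: int
    scientific: str  # 3 significant figures, e.g. "3.43E+33"


def eq1_max_worms() -> Eq1Result:
    """Maximum number of distinct 60-rule worms.

    One choice of 3 for the first rule, 6 for the second (origin, six paths
    free), 5 for each of the 21 five-path states, 3 for each of the 35
    three-path states, and 4 and 2 for the two remaining origin visits:
    3*6*5^21*3^35*4*2, which factors as 48*5^21*3^36.  Both factorisations
    are computed exactly and must agree.
    """
    product = 3 * 6 * 5**21 * 3**35 * 4 * 2
    factored = 48 * 5**21 * 3**36
    if product != factored:
        raise AssertionError("factorisations of the worm-count bound disagree")
    scientific = f"{Decimal(product):.2E}"
    return Eq1Result(exact=product, scientific=scientific)


def upper_bound_worms(i: int, cumulative: bool = False) -> int:
    """Upper bound on unique worms of rule length exactly ``i``.

    3 for length 1; thereafter 3 first-rule choices, 6 second-rule choices at
    the origin, and at most 5 choices for every later rule: 3*6*5^(i-2).
    With ``cumulative=True``, sums the bound over lengths 1..i (70,311 for
    i = 7).
    """
    if i < 1:
        raise ValueError("rule length must be >= 1")
    if cumulative:
        return sum(upper_bound_worms(k) for k in range(1, i + 1))
    if i == 1:
        return 3
    return 3 * 6 * 5 ** (i - 2)


def layer_outward_paths(n: int) -> int:
    """Edges leading outward from Chebyshev layer ``n - 1`` into layer ``n``.

    Layers are rings of constant Chebyshev distance from the origin; layer 1
    receives the origin's 8 incident edges, and each further layer receives
    24n - 16.  The count is always even, which is why a worm always keeps a
    return path toward the origin.
    """
    if n < 1:
        raise ValueError("layer number must be >= 1")
    return 24 * n - 16


def bounds_summary() -> dict:
    """All closed-form quantities in one JSON-friendly mapping."""
    census = sensor_state_census()
    eq1 = eq1_max_worms()
    return {
        "sensor_states": census.total,
        "odd_states": census.odd_total,
        "odd_states_by_paths": {
            k: census.counts[k] for k in (1, 3, 5, 7)
        },
        "max_rules": max_rules_bound(),
        "max_worms_60_rules_exact": eq1.exact,
        "max_worms_60_rules": eq1.scientific,
        "unique_worms_length_7": upper_bound_worms(7),
        "unique_worms_lengths_1_to_7": upper_bound_worms(7, cumulative=True),
        "layer_outward_paths_formula": "24n-16",
    }
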