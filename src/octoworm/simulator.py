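"""The worm lifecycle: rule memory, stepping, categories, and the run loop.

A worm starts with a single line from the origin toward +x.  At every
subsequent point it senses which of the seven non-reverse directions are
still free (:mod:`octoworm.grid_core`) and acts:

* no free path: it is boxed in and dies (category ``T``; by the parity of the
  traversed-edge graph this can only happen back at the origin);
* exactly one free path: it is taken automatically, without creating a rule;
* otherwise the availability pattern is looked up in the worm's rule memory.
  A known pattern repeats its stored decision; an unknown pattern requires a
  new decision from the worm's decision source, which is stored as a rule and
  becomes the next digit of the worm's code.

The run ends in one of five categories: ``T`` (terminated at a dead end),
``L`` (a repeating loop was detected at the population limit), ``R`` (still
running at the limit, no loop found), ``I`` (a preset rule named a path that
is already traversed), or ``N`` (a new rule was needed but the code or policy
had nothing more to give).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional, Protocol, Sequence, Union, runtime_checkable

from .grid_core import (
    DIRECTION_VECTORS,
    SensorState,
    availability,
)
from .loop_detection import DEFAULT_LOOP_CONFIG, LoopConfig, LoopInfo, detect_loop

__all__ = [
    "Category",
    "DecisionSource",
    "RuleTable",
    "WormState",
    "WormResult",
    "run_worm",
    "replay",
    "InvalidDigitError",
    "ReplayError",
    "MAX_RULES",
]

#: No worm on this grid can set more than 60 rules (57 odd-availability
#: states plus at most three even-availability states, met only at the
#: origin).  Exceeding this would indicate an engine defect.
MAX_RULES = 60


class InvalidDigitError(ValueError):
    """A decision source produced something outside the digit range 0-7."""


class ReplayError(RuntimeError):
    """An activation sequence named an unavailable path during replay."""

    def __init__(self, step: int, digit: int):
        self.step = step
        self.digit = digit
        super().__init__(f"turn {digit} unavailable at step {step}")


class Category(enum.Enum):
    """Why a worm's run ended."""

    T = "T"  #: terminated: no paths available (always back at the origin)
    L = "L"  #: repeating infinite loop detected
    R = "R"  #: still running at the population limit, no loop detected
    I = "I"  #: invalid: a preset rule chose an already-traversed path
    N = "N"  #: needs more rules than the code/policy supplied

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@runtime_checkable
class DecisionSource(Protocol):
    """Anything that can supply the next rule digit on demand.

    ``next_rule`` is called only when an unseen availability pattern needs a
    decision; it returns a turn digit 0-7, or ``None`` when exhausted (the
    worm then ends in category ``N``).
    """

    def next_rule(
        self, state: SensorState, available: tuple[int, ...]
    ) -> Optional[int]: ...


class RuleTable:
    """Ordered association from availability pattern to turn digit."""

    def __init__(self) -> None:
        self._rules: dict[tuple[bool, ...], int] = {}

    def lookup(self, key: tuple[bool, ...]) -> Optional[int]:
        return self._rules.get(key)

    def store(self, key: tuple[bool, ...], turn: int) -> None:
        self._rules[key] = turn
        if len(self._rules) > MAX_RULES:
            raise AssertionError("rule table exceeded the 60-rule bound")

    def __len__(self) -> int:
        return len(self._rules)

    def items(self) -> tuple[tuple[SensorState, int], ...]:
        return tuple((SensorState(k), v) for k, v in self._rules.items())


@dataclass
class WormState:
    """Geometric state of a worm after replaying an activation sequence."""

    position: tuple[int, int]
    heading: int
    traversed: set
    activation_sequence: str

    @property
    def population(self) -> int:
        """Lines drawn: the initial line plus one per recorded turn."""
        return len(self.activation_sequence) + 1


@dataclass(frozen=True)
class WormResult:
    """Outcome of a single worm run.

    ``code`` lists the rules in creation order (for preset codes, the preset
    digits as given).  ``activation_sequence`` records the turn taken at
    every step including forced single-path moves; ``rule_activation_sequence``
    is the subsequence of steps where a rule (stored or new) fired, which is
    what the loop detector inspects.
    """

    code: str
    category: Category
    population: int
    rules_used: int
    limit: int
    loop: Optional[LoopInfo] = None
    seed: Optional[int] = None
    activation_sequence: str = ""
    rule_activation_sequence: str = ""
    rules: tuple[tuple[SensorState, int], ...] = ()
    pending_turns: tuple[int, ...] = field(default=(), repr=False)

    def to_record(self) -> dict:
        """Flat JSON-friendly summary (one run-log line)."""
        return {
            "code": self.code,
            "category": self.category.value,
            "population": self.population,
            "rules_used": self.rules_used,
            "loop_length": self.loop.block_length if self.loop else None,
            "seed": self.seed,
            "limit": self.limit,
        }


def _as_source(source) -> "DecisionSource":
    if isinstance(source, (str, list, tuple)):
        from .generators import RuleProgram  # simulator is imported by generators

        return RuleProgram(source)
    if isinstance(source, DecisionSource):
        return source
    raise TypeError(f"not a decision source: {source!r}")


def run_worm(
    decision_source: Union[str, Sequence[int], "DecisionSource"],
    population_limit: int = 250_000,
    loop_config: LoopConfig = DEFAULT_LOOP_CONFIG,
) -> WormResult:
    """Run one worm until it terminates, loops, stalls, or hits the limit.

    The population limit is checked immediately after each line is drawn and
    before any further decision, so ``run_worm("1", population_limit=1)`` is
    category ``R`` at population 1.
    """
    if population_limit < 1:
        raise ValueError("population_limit must be >= 1")
    source = _as_source(decision_source)

    vecs = DIRECTION_VECTORS
    x, y, heading = 1, 0, 0
    traversed: set = {((0, 0), (1, 0))}
    rules = RuleTable()
    seq: list[int] = []
    rule_seq: list[int] = []
    population = 1
    cadence = loop_config.cadence

    category: Category
    loop_info: Optional[LoopInfo] = None
    pending: tuple[int, ...] = ()

    while True:
        if population >= population_limit:
            loop_info = detect_loop(rule_seq, loop_config)
            category = Category.L if loop_info else Category.R
            break
        key, avail = availability(x, y, heading, traversed)
        n_avail = len(avail)
        if n_avail == 0:
            category = Category.T
            break
        if n_avail == 1:
            turn = avail[0]
            forced = True
        else:
            forced = False
            stored = rules.lookup(key)
            if stored is None:
                choice = source.next_rule(SensorState(key), tuple(avail))
                if choice is None:
                    category = Category.N
                    pending = tuple(avail)
                    break
                if not isinstance(choice, int) or not 0 <= choice <= 7:
                    raise InvalidDigitError(f"decision source returned {choice!r}")
                if choice not in avail:
                    category = Category.I
                    break
                rules.store(key, choice)
                turn = choice
            else:
                turn = stored
        heading = (heading + turn) & 7
        dx, dy = vecs[heading]
        p = (x, y)
        q = (x + dx, y + dy)
        traversed.add((p, q) if p <= q else (q, p))
        x, y = q
        population += 1
        seq.append(turn)
        if not forced:
            rule_seq.append(turn)
        if cadence is not None and population % cadence == 0:
            loop_info = detect_loop(rule_seq, loop_config)
            if loop_info is not None:
                category = Category.L
                break

    stored_rules = rules.items()
    from .generators import RuleProgram

    if isinstance(source, RuleProgram):
        code = source.code
    else:
        code = "".join(str(t) for _, t in stored_rules)
    return WormResult(
        code=code,
        category=category,
        population=population,
        rules_used=len(rules),
        limit=population_limit,
        loop=loop_info,
        seed=getattr(source, "seed", None),
        activation_sequence="".join(map(str, seq)),
        rule_activation_sequence="".join(map(str, rule_seq)),
        rules=stored_rules,
        pending_turns=pending,
    )


def replay(activation_sequence: Union[str, Sequence[int]]) -> WormState:
    """Rebuild the geometric state reached by a recorded activation sequence.

    Deterministic reconstruction for rendering and tests: draws the initial
    line, then applies one turn per digit, verifying that each named path is
    actually free.  Raises :class:`ReplayError` with the failing step index
    otherwise.
    """
    digits = [int(d) for d in activation_sequence]
    x, y, heading = 1, 0, 0
    traversed: set = {((0, 0), (1, 0))}
    for i, turn in enumerate(digits):
        if not 0 <= turn <= 7:
            raise InvalidDigitError(f"digit {turn!r} at step {i}")
        key, avail = availability(x, y, heading, traversed)
        if turn not in avail:
            raise ReplayError(i, turn)
        heading = (heading + turn) & 7
        dx, dy = DIRECTION_VECTORS[heading]
        p = (x, y)
        q = (x + dx, y + dy)
        traversed.add((p, q) if p <= q else (q, p))
        x, y = q
    return WormState(
        position=(x, y),
        heading=heading,
        traversed=traversed,
        activation_sequence="".join(map(str, digits)),
    )
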