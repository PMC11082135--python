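"""Ways of producing worm decisions: preset codes, random policies,
recursive enumeration with pruning, brute-force code generation, and
interactive choice; plus mirror canonicalization.

Every worm has a mirror twin obtained by reflecting its path across the
initial line; in code space the reflection maps each rule digit ``d >= 1``
to ``8 - d`` (``0`` is its own mirror).  Enumeration and random generation
restrict the first rule to {1, 2, 3}, which excludes exactly one member of
every mirror pair (and the degenerate straight-ahead and reverse openings).
"""

from __future__ import annotations

import random
from typing import Callable, Iterator, Optional, Sequence, Union

from .grid_core import SensorState
from .loop_detection import DEFAULT_LOOP_CONFIG, LoopConfig
from .simulator import Category, InvalidDigitError, WormResult, run_worm

__all__ = [
    "RuleProgram",
    "RandomPolicy",
    "InteractivePolicy",
    "mirror_code",
    "random_policy",
    "interactive_policy",
    "recursive_enumerate",
    "brute_force_codes",
    "brute_force_code_count",
    "FIRST_RULE_DIGITS",
]

#: Allowed first digits when generating canonical (mirror-free) codes.
FIRST_RULE_DIGITS = (1, 2, 3)

_VALID_DIGITS = frozenset(range(8))


def _parse_digits(code: Union[str, Sequence[int]]) -> tuple[int, ...]:
    try:
        digits = tuple(int(d) for d in code)
    except (TypeError, ValueError) as exc:
        raise InvalidDigitError(f"worm code digits must be 0..7: {code!r}") from exc
    if any(d not in _VALID_DIGITS for d in digits):
        raise InvalidDigitError(f"worm code digits must be 0..7: {code!r}")
    return digits


class RuleProgram:
    """A preset worm code consumed one digit per new rule.

    An empty program is valid: its worm ends in category ``N`` at the first
    decision.  Preset codes may start with any digit (so ``"4"`` demonstrates
    category ``I``); only the generators restrict first digits to {1, 2, 3}.
    """

    def __init__(self, code: Union[str, Sequence[int]] = "") -> None:
        self.digits = _parse_digits(code)
        self.cursor = 0

    @property
    def code(self) -> str:
        return "".join(map(str, self.digits))

    def next_rule(
        self, state: SensorState, available: tuple[int, ...]
    ) -> Optional[int]:
        if self.cursor >= len(self.digits):
            return None
        digit = self.digits[self.cursor]
        self.cursor += 1
        return digit


class RandomPolicy:
    """Choose uniformly among available turns; reproducible from ``seed``.

    The first rule is drawn uniformly from {1, 2, 3} so that random worms are
    mirror-canonical.  Every later choice is made among the turns that are
    actually free, so a random worm can never end in category ``I`` or ``N``;
    its runs always finish as ``T``, ``L`` or ``R``.
    """

    def __init__(self, seed: int) -> None:
        self.seed = seed
        self._rng = random.Random(seed)
        self._calls = 0

    def next_rule(
        self, state: SensorState, available: tuple[int, ...]
    ) -> Optional[int]:
        if self._calls == 0:
            choice = self._rng.choice(FIRST_RULE_DIGITS)
        else:
            choice = self._rng.choice(available)
        self._calls += 1
        return choice


def random_policy(seed: int) -> RandomPolicy:
    """Decision source that invents rules at run time (see :class:`RandomPolicy`)."""
    return RandomPolicy(seed)


class InteractivePolicy:
    """Rule selection by a human at run time (interactive evolutionary search).

    ``prompt`` receives the sensor state and the free turn digits and must
    return the raw reply.  An unavailable choice re-prompts without changing
    state; an empty reply / ``q`` / EOF aborts, emitting the partial code as
    a category-``N`` run.
    """

    def __init__(
        self,
        prompt: Callable[[SensorState, tuple[int, ...]], str],
        echo: Optional[Callable[[str], None]] = None,
    ) -> None:
        self._prompt = prompt
        self._echo = echo or (lambda s: None)

    def next_rule(
        self, state: SensorState, available: tuple[int, ...]
    ) -> Optional[int]:
        while True:
            try:
                reply = self._prompt(state, available)
            except EOFError:
                return None
            if reply is None or reply.strip() in ("", "q", "quit"):
                return None
            reply = reply.strip()
            if reply.isdigit() and int(reply) in available:
                return int(reply)
            self._echo(f"path {reply} is not available; choose from {available}")


def interactive_policy(
    prompt: Callable[[SensorState, tuple[int, ...]], str],
    echo: Optional[Callable[[str], None]] = None,
) -> InteractivePolicy:
    return InteractivePolicy(prompt, echo)


def mirror_code(code: Union[str, Sequence[int]]) -> str:
    """Mirror-image code: digit ``d`` maps to ``0`` if ``d == 0`` else ``8 - d``.

    So 1, 2, 3 become 7, 6, 5 respectively (and vice versa); ``"26326"``
    mirrors to ``"62562"``.
    """
    digits = _parse_digits(code)
    return "".join("0" if d == 0 else str(8 - d) for d in digits)


def recursive_enumerate(
    max_rule_length: int,
    population_limit: int = 250_000,
    loop_config: LoopConfig = DEFAULT_LOOP_CONFIG,
) -> Iterator[WormResult]:
    """Depth-first enumeration of all valid worms up to a rule-length limit.

    Roots are the canonical first digits 1, 2, 3.  Each node's worm runs to
    completion; only category-``N`` worms (which stalled asking for one more
    rule) are expanded, with one child per turn that was available at the
    stalling point, in ascending digit order.  Every node - parents included -
    is emitted exactly once, so the stream is deterministic and pruned: no
    category-``I`` worm is ever generated.
    """
    if max_rule_length < 1:
        raise ValueError("max_rule_length must be >= 1")

    def walk(code: str) -> Iterator[WormResult]:
        result = run_worm(code, population_limit, loop_config)
        yield result
        if result.category is Category.N and len(code) < max_rule_length:
            for turn in result.pending_turns:
                yield from walk(code + str(turn))

    for root in FIRST_RULE_DIGITS:
        yield from walk(str(root))


def brute_force_codes(max_length: int) -> Iterator[str]:
    """Every code with first digit in {1, 2, 3}, later digits in {0..7}\\{4}.

    Digit 4 never extends a code (the reverse path is always traversed, so it
    would be invalid at first use); many of the generated codes are still
    invalid at run time.  Exactly ``3 * 7**(k-1)`` codes of length ``k`` are
    yielded, lengths 1..``max_length``, in lexicographic order per length.
    """
    if max_length < 1:
        raise ValueError("max_length must be >= 1")
    extensions = (0, 1, 2, 3, 5, 6, 7)
    frontier = [str(d) for d in FIRST_RULE_DIGITS]
    for _ in range(max_length):
        next_frontier = []
        for code in frontier:
            yield code
            next_frontier.extend(code + str(e) for e in extensions)
        frontier = next_frontier


def brute_force_code_count(max_length: int) -> int:
    """Closed form for the brute-force stream size: sum of 3*7^n, n=0..i-1."""
    if max_length < 1:
        raise ValueError("max_length must be >= 1")
    return sum(3 * 7**n for n in range(max_length))
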