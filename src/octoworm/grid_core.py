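"""Lattice geometry for the eight-direction square grid.

Worms move between integer grid points that are Chebyshev-adjacent: the four
axis neighbours plus the four diagonal neighbours.  Headings are absolute
directions 0-7; moves are expressed as *relative turns* 0-7 measured clockwise
from the current heading (0 = straight ahead, 2 = 90 deg right, 4 = reverse,
6 = 90 deg left).  A worm may never re-traverse an edge, so the reverse turn 4
is always unavailable and a worm senses only the seven remaining directions.

The grid is unbounded; traversed edges are kept in a sparse set of canonical
(undirected) endpoint pairs.  Two diagonals of the same unit cell may both be
traversed - only re-use of an identical edge is forbidden.
"""

from __future__ import annotations

from typing import Iterable, NamedTuple

__all__ = [
    "DIRECTION_VECTORS",
    "TURN_ORDER",
    "direction_vector",
    "opposite",
    "turn_to_heading",
    "canonical_edge",
    "SensorState",
    "sense",
    "availability",
]

#: Unit offsets for absolute directions 0-7, clockwise from +x.
#: 0 = (1,0) (east, the initial heading); odd indices are diagonals.
DIRECTION_VECTORS: tuple[tuple[int, int], ...] = (
    (1, 0), (1, -1), (0, -1), (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1),
)

#: Relative turns a worm can sense, in ascending digit order (4 = reverse is
#: excluded: that edge was traversed on the previous step).
TURN_ORDER: tuple[int, ...] = (0, 1, 2, 3, 5, 6, 7)

Point = tuple[int, int]
Edge = tuple[Point, Point]


def direction_vector(d: int) -> tuple[int, int]:
    """Unit offset for absolute direction ``d`` (0-7)."""
    if not 0 <= d <= 7:
        raise ValueError(f"absolute direction must be in 0..7, got {d!r}")
    return DIRECTION_VECTORS[d]


def opposite(d: int) -> int:
    """The reverse of absolute direction ``d``."""
    if not 0 <= d <= 7:
        raise ValueError(f"absolute direction must be in 0..7, got {d!r}")
    return (d + 4) & 7


def turn_to_heading(heading: int, turn: int) -> int:
    """Absolute direction after applying relative ``turn`` to ``heading``.

    Turn digits increase clockwise from straight ahead, so ``turn=2`` from an
    eastward heading yields south.
    """
    if not 0 <= heading <= 7:
        raise ValueError(f"heading must be in 0..7, got {heading!r}")
    if not 0 <= turn <= 7:
        raise ValueError(f"turn must be in 0..7, got {turn!r}")
    return (heading + turn) & 7


def canonical_edge(p: Point, q: Point) -> Edge:
    """Orientation-independent form of the edge between adjacent points.

    ``canonical_edge(p, q) == canonical_edge(q, p)``.  Raises if the points
    are not Chebyshev-adjacent.
    """
    if max(abs(p[0] - q[0]), abs(p[1] - q[1])) != 1:
        raise ValueError(f"points {p} and {q} are not grid neighbours")
    return (p, q) if p <= q else (q, p)


class SensorState(NamedTuple):
    """Which relative turns are free, ordered as :data:`TURN_ORDER`.

    This 7-bit pattern is the key of a worm's rule memory: whenever the same
    pattern recurs, the worm must repeat its earlier decision.
    """

    availability: tuple[bool, ...]

    @property
    def available_turns(self) -> tuple[int, ...]:
        return tuple(t for t, free in zip(TURN_ORDER, self.availability) if free)

    @property
    def n_available(self) -> int:
        return sum(self.availability)

    def to_notation(self) -> str:
        """8-character traversed-bit string, one char per turn digit 0-7.

        '1' marks a traversed (unavailable) path; position 4 is always '1'.
        The all-available state renders as ``"00001000"``.
        """
        bits = ["1"] * 8
        for t, free in zip(TURN_ORDER, self.availability):
            bits[t] = "0" if free else "1"
        return "".join(bits)

    @classmethod
    def from_notation(cls, s: str) -> "SensorState":
        if len(s) != 8 or set(s) - {"0", "1"}:
            raise ValueError(f"notation must be 8 binary characters, got {s!r}")
        if s[4] != "1":
            raise ValueError("position 4 (the reverse path) must read '1'")
        return cls(tuple(s[t] == "0" for t in TURN_ORDER))


# All seven sensed paths free: the state every worm meets on its first decision.
ALL_AVAILABLE = SensorState((True,) * 7)


def availability(
    x: int, y: int, heading: int, traversed: set
) -> tuple[tuple[bool, ...], list[int]]:
    """Availability pattern and free turns at ``(x, y)`` facing ``heading``.

    Returns ``(key, turns)`` where ``key`` is the 7-bool pattern over
    :data:`TURN_ORDER` (the rule-memory key) and ``turns`` lists the free
    relative turns in ascending order.  This is the single sensing primitive
    shared by the simulator, :func:`sense` and replay; it sits on the hot
    path, so it avoids any object construction beyond small tuples.
    """
    p = (x, y)
    key = []
    turns = []
    vecs = DIRECTION_VECTORS
    for t in TURN_ORDER:
        dx, dy = vecs[(heading + t) & 7]
        q = (x + dx, y + dy)
        free = ((p, q) if p <= q else (q, p)) not in traversed
        key.append(free)
        if free:
            turns.append(t)
    return tuple(key), turns


def sense(position: Point, heading: int, traversed: Iterable[Edge]) -> SensorState:
    """Sense which of the seven non-reverse paths are untraversed."""
    if not 0 <= heading <= 7:
        raise ValueError(f"heading must be in 0..7, got {heading!r}")
    edges = traversed if isinstance(traversed, set) else set(traversed)
    key, _ = availability(position[0], position[1], heading, edges)
    return SensorState(key)
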