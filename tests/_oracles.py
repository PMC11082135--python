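"""Independent brute-force oracles used to cross-check the implementation.

Everything here recomputes quantities from first principles (linear scans,
explicit enumeration, naive string matching) without touching the code paths
it is used to verify.
"""

from __future__ import annotations

from octoworm import DIRECTION_VECTORS, TURN_ORDER, LoopConfig, LoopInfo


def sense_oracle(position, heading, edges):
    """Availability recomputed by scanning the raw edge collection.

    Returns the 7-bool pattern over TURN_ORDER.  Edges may be any iterable of
    endpoint pairs in either orientation.
    """
    edge_list = [tuple(e) for e in edges]
    x, y = position
    pattern = []
    for t in TURN_ORDER:
        dx, dy = DIRECTION_VECTORS[(heading + t) % 8]
        q = (x + dx, y + dy)
        hit = any(
            (a == position and b == q) or (a == q and b == position)
            for a, b in edge_list
        )
        pattern.append(not hit)
    return tuple(pattern)


def loop_oracle(sequence, config: LoopConfig):
    """Naive periodic-suffix search: try every period and start index.

    A period ``p`` (min_block <= p <= n // min_repeats) qualifies when the
    sequence from some start index onward equals consecutive copies of its
    leading ``p`` digits (with an optional partial copy at the end) and at
    least ``min_repeats`` complete copies fit.  The smallest qualifying
    period is reduced to the primitive period of its periodic suffix.
    """
    s = list(sequence)
    n = len(s)

    def min_periodic_start(q, upto):
        """Smallest start <= upto from which s is q-periodic to the end."""
        for st in range(0, min(upto, n - q) + 1):
            block = s[st : st + q]
            if all(s[i] == block[(i - st) % q] for i in range(st, n)):
                return st
        return None

    for p in range(config.min_block, n // config.min_repeats + 1):
        start = min_periodic_start(p, n - p)
        if start is None or (n - start) // p < config.min_repeats:
            continue
        for q in range(1, p + 1):
            st_q = min_periodic_start(q, start)
            if st_q is not None:
                return LoopInfo(q, (n - st_q) // q, st_q)
    return None


def chebyshev_outward_edge_count(n: int) -> int:
    """Count lattice edges joining Chebyshev ring n-1 to ring n by enumeration."""

    def ring(k):
        return {
            (x, y)
            for x in range(-k, k + 1)
            for y in range(-k, k + 1)
            if max(abs(x), abs(y)) == k
        }

    inner, outer = ring(n - 1), ring(n)
    count = 0
    for (x, y) in inner:
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                if (dx, dy) != (0, 0) and (x + dx, y + dy) in outer:
                    count += 1
    return count
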