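"""Detection of repeating (looping) behaviour in a worm's decision record.

A looping worm eventually settles into a periodic tail: the same block of
turn digits repeats over and over.  Detection is anchored at the end of the
sequence: we look for a suffix that consists of at least ``min_repeats``
consecutive copies of some block (optionally followed by a partial copy cut
off mid-cycle).  To avoid flagging short transient repetition, a candidate
repeating segment must be at least ``min_block`` digits long; once a loop is
confirmed, the reported block is the *primitive* period of the periodic
suffix, which may be shorter than ``min_block`` (tight 4-digit loops exist
and are reported as such).

The scan uses a Z-array on the reversed sequence, so a single O(n) pass
yields the maximal periodic-suffix length for every candidate period.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

__all__ = ["LoopConfig", "LoopInfo", "detect_loop", "DEFAULT_LOOP_CONFIG"]


@dataclass(frozen=True)
class LoopConfig:
    """Loop-detector settings.

    min_block
        Minimum length of the repeating segment that triggers detection.
    min_repeats
        Minimum number of consecutive copies required.
    cadence
        If set, the simulator additionally checks for a loop every ``cadence``
        lines during the run (early stopping for long loopers); by default
        classification happens only once, at the population limit, which keeps
        results independent of when checks occur.
    """

    min_block: int = 6
    min_repeats: int = 4
    cadence: Optional[int] = None

    def __post_init__(self) -> None:
        if self.min_block < 1:
            raise ValueError("min_block must be >= 1")
        if self.min_repeats < 2:
            raise ValueError("min_repeats must be >= 2")
        if self.cadence is not None and self.cadence < 1:
            raise ValueError("cadence must be >= 1 when set")


DEFAULT_LOOP_CONFIG = LoopConfig()


@dataclass(frozen=True)
class LoopInfo:
    """A detected periodic tail.

    block_length
        Length of one primitive repeating segment.
    repeats
        Number of complete consecutive copies observed.
    start_index
        Index where the final repeated run begins; from here to the end the
        sequence equals ``repeats`` copies of the block plus an optional
        proper prefix of it.
    """

    block_length: int
    repeats: int
    start_index: int


def _z_array(s: Sequence) -> list[int]:
    """z[i] = length of the longest common prefix of s and s[i:]."""
    n = len(s)
    z = [0] * n
    if n == 0:
        return z
    z[0] = n
    left = right = 0
    for i in range(1, n):
        if i < right:
            z[i] = min(right - i, z[i - left])
        while i + z[i] < n and s[z[i]] == s[i + z[i]]:
            z[i] += 1
        if i + z[i] > right:
            left, right = i, i + z[i]
    return z


def detect_loop(
    sequence: Sequence, config: LoopConfig = DEFAULT_LOOP_CONFIG
) -> Optional[LoopInfo]:
    """Find a periodic tail in ``sequence`` (a digit string or int sequence).

    A period ``p`` qualifies when ``min_block <= p`` and the maximal
    ``p``-periodic suffix contains at least ``min_repeats`` complete copies.
    The smallest qualifying period is then reduced to the primitive period of
    that suffix, which is what :class:`LoopInfo` reports.  Returns ``None``
    when no period qualifies.
    """
    s = list(sequence)
    n = len(s)
    if n < config.min_block * config.min_repeats:
        return None
    z = _z_array(s[::-1])
    # z[p] + p == length of the maximal suffix satisfying s[i] == s[i + p].
    for p in range(config.min_block, n // config.min_repeats + 1):
        suffix_len = z[p] + p
        if suffix_len // p < config.min_repeats:
            continue
        # Primitive period of that suffix: smallest q whose own maximal
        # periodic suffix covers it entirely.
        q = next(q for q in range(1, p + 1) if z[q] + q >= suffix_len)
        q_suffix_len = z[q] + q
        return LoopInfo(
            block_length=q,
            repeats=q_suffix_len // q,
            start_index=n - q_suffix_len,
        )
    return None
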