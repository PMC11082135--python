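"""Shared fixtures: the expensive enumeration and random-batch runs are done
once per session and reduced to lightweight records."""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import pytest
from hypothesis import HealthCheck, settings

from octoworm import Category, recursive_enumerate, run_random_worms
from octoworm.census_io import census_from_results

settings.register_profile(
    "octoworm",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("octoworm")

CENSUS_DEPTH = 5
CENSUS_LIMIT = 250_000
RANDOM_N = 1_000
RANDOM_LIMIT = 100_000
RANDOM_SEED = 20_240_509
SWEEP_LIMITS = (1_000, 10_000, 100_000)
SWEEP_N = 200
SWEEP_SEED = 777


@dataclass(frozen=True)
class LiteResult:
    """Memory-light stand-in for WormResult (big sequences dropped)."""

    code: str
    category: Category
    population: int
    rules_used: int
    loop_length: int | None
    rules: tuple = ()


def _lite(r, keep_rules=False):
    return LiteResult(
        code=r.code,
        category=r.category,
        population=r.population,
        rules_used=r.rules_used,
        loop_length=r.loop.block_length if r.loop else None,
        rules=r.rules if keep_rules else (),
    )


@pytest.fixture(scope="session")
def depth5_records():
    """Every worm of the depth-5 recursive enumeration, limit 250,000."""
    return [_lite(r) for r in recursive_enumerate(CENSUS_DEPTH, CENSUS_LIMIT)]


@pytest.fixture(scope="session")
def depth5_census(depth5_records):
    return census_from_results(depth5_records, CENSUS_DEPTH)


@pytest.fixture(scope="session")
def random_records():
    """1,000 runtime-random worms at population limit 100,000, fixed seed."""
    return [
        _lite(r, keep_rules=True)
        for r in run_random_worms(RANDOM_N, RANDOM_LIMIT, seed=RANDOM_SEED)
    ]


@pytest.fixture(scope="session")
def limit_sweep():
    """Category tallies for the same 200 seeded worms at three limits."""
    sweep = {}
    for limit in SWEEP_LIMITS:
        cats = Counter(
            r.category.value
            for r in run_random_worms(SWEEP_N, limit, seed=SWEEP_SEED)
        )
        sweep[limit] = cats
    return sweep
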