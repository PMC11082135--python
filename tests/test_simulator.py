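"""Worm lifecycle: categories, rule memory, replay, and trail invariants."""

from collections import Counter

import pytest

from octoworm import (
    Category,
    InvalidDigitError,
    LoopConfig,
    ReplayError,
    mirror_code,
    replay,
    run_worm,
    run_random_worms,
)
from octoworm.grid_core import availability


@pytest.mark.parametrize(
    "code,category,population,rules_used",
    [
        # the five-rule square-drawing worm: four origin returns, dead end
        ("26326", Category.T, 16, 5),
        # the minimal terminating worms: population 14 with 5 rules
        ("36306", Category.T, 14, 5),
        ("31071", Category.T, 14, 5),
        # invalid first rule: path 4 is the just-traversed line
        ("4", Category.I, 1, 0),
        # no rules at all: stalls at the first decision
        ("", Category.N, 1, 0),
    ],
)
def test_preset_code_outcomes(code, category, population, rules_used):
    result = run_worm(code)
    assert result.category is category
    assert result.population == population
    assert result.rules_used == rules_used


def test_limit_check_precedes_decisions():
    """With limit 1 the initial line already ends the run as category R."""
    result = run_worm("1", population_limit=1)
    assert result.category is Category.R
    assert result.population == 1


@pytest.mark.parametrize("code", ["337", "377"])
def test_three_rule_loopers(code):
    """The shortest looping worms have three rules."""
    result = run_worm(code, population_limit=5_000)
    assert result.category is Category.L
    assert result.rules_used == 3
    assert result.loop is not None


def test_cadence_stops_loopers_early():
    looping = run_worm("337", population_limit=250_000,
                       loop_config=LoopConfig(cadence=500))
    assert looping.category is Category.L
    assert looping.population < 5_000


def test_invalid_digit_is_an_error_not_category_I():
    class Bad:
        def next_rule(self, state, available):
            return 9

    with pytest.raises(InvalidDigitError):
        run_worm(Bad())
    with pytest.raises(InvalidDigitError):
        run_worm("29")


def test_population_counts_lines():
    result = run_worm("26326")
    state = replay(result.activation_sequence)
    assert result.population == len(state.traversed)
    assert result.population == len(result.activation_sequence) + 1


def test_replay_roundtrip_and_errors():
    assert replay("").position == (1, 0)
    square = replay("222")
    assert square.position == (0, 0) and square.population == 4
    with pytest.raises(ReplayError) as exc:
        replay("2224")  # the reverse of the square's last line is traversed
    assert exc.value.step == 3


def test_terminated_worms_end_at_the_origin(depth5_records):
    """Category T can only happen where the trail started (parity argument)."""
    t_codes = [r.code for r in depth5_records if r.category is Category.T]
    assert t_codes  # depth 5 contains terminating worms
    for code in t_codes:
        result = run_worm(code)
        assert replay(result.activation_sequence).position == (0, 0)


def test_rule_memory_structure(random_records):
    """Rule-count bounds: <=60 rules, <=3 even-availability rules, and the
    second rule always fires at the origin with six paths free."""
    assert random_records
    for rec in random_records:
        assert rec.rules_used <= 60
        keys = [state for state, _ in rec.rules]
        even = [s for s in keys if s.n_available % 2 == 0]
        assert len(even) <= 3
        if len(keys) >= 1:
            assert keys[0].n_available == 7  # first decision in open space
        if len(keys) >= 2:
            assert keys[1].n_available == 6  # back at the origin
        for state, turn in rec.rules:
            assert turn in state.available_turns


def _mirror_edges(traversed):
    out = set()
    for (a, b) in traversed:
        p, q = (a[0], -a[1]), (b[0], -b[1])
        out.add((p, q) if p <= q else (q, p))
    return out


def test_mirror_equivalence_on_random_codes():
    """A worm and its mirror share category, population and rule count, and
    trace reflections of each other across the initial line."""
    checked = 0
    for r in run_random_worms(200, population_limit=2_000, seed=4242):
        twin = run_worm(mirror_code(r.code), population_limit=2_000)
        assert twin.category is r.category
        assert twin.population == r.population
        assert twin.rules_used == r.rules_used
        state = replay(r.activation_sequence)
        twin_state = replay(twin.activation_sequence)
        assert twin_state.traversed == _mirror_edges(state.traversed)
        checked += 1
    assert checked == 200


def test_trail_parity_invariants():
    """After every step the traversed multigraph has exactly two odd-degree
    vertices (origin and head) or none when the worm stands at the origin;
    equivalently the head sees an odd number of free paths except at the
    origin, where the count is even."""
    from octoworm import DIRECTION_VECTORS as vecs

    for r in run_random_worms(200, population_limit=600, seed=1357):
        x, y, heading = 1, 0, 0
        traversed = {((0, 0), (1, 0))}
        degree = Counter({(0, 0): 1, (1, 0): 1})
        for digit in r.activation_sequence:
            odd = {v for v, d in degree.items() if d % 2 == 1}
            assert odd == (set() if (x, y) == (0, 0) else {(0, 0), (x, y)})
            _, avail = availability(x, y, heading, traversed)
            expected_parity = 0 if (x, y) == (0, 0) else 1
            assert len(avail) % 2 == expected_parity
            assert len(avail) > 0 or (x, y) == (0, 0)  # dead ends only at origin
            heading = (heading + int(digit)) % 8
            dx, dy = vecs[heading]
            p, q = (x, y), (x + dx, y + dy)
            traversed.add((p, q) if p <= q else (q, p))
            degree[p] += 1
            degree[q] += 1
            x, y = q


def test_forced_moves_draw_lines_but_set_no_rules():
    """Single-choice moves appear in the step record, not the rule record."""
    result = run_worm("50275752501275776276353217", population_limit=2_000)
    assert len(result.activation_sequence) == result.population - 1
    assert len(result.rule_activation_sequence) < len(result.activation_sequence)
    # every rule-record digit also appears at the corresponding step
    assert Counter(result.rule_activation_sequence) <= Counter(
        result.activation_sequence
    )
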