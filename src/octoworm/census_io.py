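"""Batch experiments and reporting: recursive censuses, random-worm batches,
summary statistics, CSV/JSON-lines output and SVG rendering."""

from __future__ import annotations

import csv
import json
import statistics
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence, Union

from .generators import RandomPolicy, recursive_enumerate
from .loop_detection import DEFAULT_LOOP_CONFIG, LoopConfig
from .simulator import Category, WormResult, WormState, replay, run_worm

__all__ = [
    "CensusTable",
    "BatchStats",
    "SvgStyle",
    "census_from_results",
    "run_recursive_census",
    "run_random_worms",
    "run_random_batch",
    "first_rule_distribution",
    "render_svg",
    "write_census_csv",
    "read_census_csv",
    "write_runlog",
    "read_runlog",
]

_CATEGORIES = ("N", "T", "L", "R")


@dataclass(frozen=True)
class CensusTable:
    """Cumulative category counts by rule length.

    ``rows[i]`` counts every enumerated worm whose code length is <= i, split
    by category, so each column dominates the previous one cell-wise and the
    per-length total equals the sum of its four category counts.
    """

    depth: int
    rows: dict  # rule_length -> {"N":, "T":, "L":, "R":, "total":}

    def count(self, rule_length: int, category: Union[str, Category]) -> int:
        label = category.value if isinstance(category, Category) else category
        return self.rows[rule_length][label]

    def total(self, rule_length: int) -> int:
        return self.rows[rule_length]["total"]


def census_from_results(
    results: Iterable, depth: int
) -> CensusTable:
    """Aggregate an enumeration stream into a cumulative census table.

    Accepts :class:`WormResult` objects or any items with ``code`` and
    ``category`` attributes.
    """
    exact: dict[int, dict[str, int]] = {
        i: {c: 0 for c in _CATEGORIES} for i in range(1, depth + 1)
    }
    for res in results:
        label = res.category.value
        if label not in _CATEGORIES:
            raise ValueError(f"unexpected category {label} in enumeration stream")
        exact[len(res.code)][label] += 1
    rows: dict[int, dict[str, int]] = {}
    running = {c: 0 for c in _CATEGORIES}
    for i in range(1, depth + 1):
        for c in _CATEGORIES:
            running[c] += exact[i][c]
        rows[i] = dict(running)
        rows[i]["total"] = sum(running.values())
    return CensusTable(depth=depth, rows=rows)


def run_recursive_census(
    depth: int,
    population_limit: int = 250_000,
    loop_config: LoopConfig = DEFAULT_LOOP_CONFIG,
) -> CensusTable:
    """Enumerate all worms to ``depth`` rules and tabulate their categories."""
    if depth < 1:
        raise ValueError("depth must be >= 1")
    return census_from_results(
        recursive_enumerate(depth, population_limit, loop_config), depth
    )


@dataclass(frozen=True)
class BatchStats:
    """Aggregate characteristics of a batch of completed worms."""

    n_worms: int
    proportions: dict  # category label -> fraction
    population_min: int
    population_max: int
    population_mean: float
    rules_min: int
    rules_max: int
    rules_mean: float
    first_digit_percent: dict  # first code digit -> percentage
    odd_rules_proportion: float
    odd_population_proportion: float

    @classmethod
    def from_results(cls, results: Sequence[WormResult]) -> "BatchStats":
        if not results:
            raise ValueError("cannot summarise an empty batch")
        n = len(results)
        cats = [r.category.value for r in results]
        pops = [r.population for r in results]
        rules = [r.rules_used for r in results]
        firsts = [int(r.code[0]) for r in results if r.code]
        first_pct = {
            d: 100.0 * sum(1 for f in firsts if f == d) / len(firsts)
            for d in sorted(set(firsts))
        }
        return cls(
            n_worms=n,
            proportions={c: cats.count(c) / n for c in sorted(set(cats))},
            population_min=min(pops),
            population_max=max(pops),
            population_mean=statistics.fmean(pops),
            rules_min=min(rules),
            rules_max=max(rules),
            rules_mean=statistics.fmean(rules),
            first_digit_percent=first_pct,
            odd_rules_proportion=sum(1 for r in rules if r % 2 == 1) / n,
            odd_population_proportion=sum(1 for p in pops if p % 2 == 1) / n,
        )

    def to_dict(self) -> dict:
        return {
            "n_worms": self.n_worms,
            "proportions": self.proportions,
            "population": {
                "min": self.population_min,
                "max": self.population_max,
                "mean": self.population_mean,
            },
            "rules": {
                "min": self.rules_min,
                "max": self.rules_max,
                "mean": self.rules_mean,
            },
            "first_digit_percent": self.first_digit_percent,
            "odd_rules_proportion": self.odd_rules_proportion,
            "odd_population_proportion": self.odd_population_proportion,
        }


def run_random_worms(
    n: int,
    population_limit: int,
    seed: int,
    loop_config: LoopConfig = DEFAULT_LOOP_CONFIG,
) -> Iterator[WormResult]:
    """Yield ``n`` independent runtime-random worms, reproducible from ``seed``.

    Each worm gets its own sub-seed derived from the batch seed, so a batch
    is reproducible as a whole and each member individually re-runnable.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    import random as _random

    seeder = _random.Random(seed)
    for _ in range(n):
        worm_seed = seeder.randrange(2**31)
        yield run_worm(RandomPolicy(worm_seed), population_limit, loop_config)


def run_random_batch(
    n: int,
    population_limit: int,
    seed: int,
    loop_config: LoopConfig = DEFAULT_LOOP_CONFIG,
) -> BatchStats:
    """Run ``n`` seeded random worms and summarise them."""
    return BatchStats.from_results(
        list(run_random_worms(n, population_limit, seed, loop_config))
    )


def first_rule_distribution(results: Iterable[WormResult]) -> tuple[float, float, float]:
    """Percentages of codes whose first rule is 1, 2 and 3 respectively."""
    counts = {1: 0, 2: 0, 3: 0}
    total = 0
    for res in results:
        if not res.code:
            continue
        first = int(res.code[0])
        if first in counts:
            counts[first] += 1
        total += 1
    if total == 0:
        raise ValueError("first_rule_distribution requires a non-empty stream")
    return tuple(100.0 * counts[d] / total for d in (1, 2, 3))  # type: ignore[return-value]


@dataclass(frozen=True)
class SvgStyle:
    """Rendering parameters for worm-path SVG output."""

    scale: int = 16
    margin: int = 16
    stroke: str = "#1f2937"
    stroke_width: float = 2.0
    origin_fill: str = "#dc2626"
    origin_radius: float = 3.0
    background: Optional[str] = "#ffffff"


def _path_points(sequence: str) -> list:
    from .grid_core import DIRECTION_VECTORS

    x, y, heading = 1, 0, 0
    pts = [(0, 0), (1, 0)]
    for d in sequence:
        heading = (heading + int(d)) & 7
        dx, dy = DIRECTION_VECTORS[heading]
        x, y = x + dx, y + dy
        pts.append((x, y))
    return pts


def render_svg(
    worm: Union[WormResult, WormState, str], style: SvgStyle = SvgStyle()
) -> str:
    """Render a worm path as an SVG document (one line per traversed edge).

    Accepts a :class:`WormResult`, a :class:`WormState` or a raw activation
    sequence.  The y axis is flipped for screen coordinates and the origin is
    marked with a dot.  Output is byte-identical for identical input/style.
    """
    if isinstance(worm, WormResult):
        sequence = worm.activation_sequence
    elif isinstance(worm, WormState):
        sequence = worm.activation_sequence
    else:
        sequence = str(worm)
        replay(sequence)  # validate before drawing
    pts = _path_points(sequence)
    s, m = style.scale, style.margin
    xs = [p[0] for p in pts]
    ys = [-p[1] for p in pts]
    minx, miny = min(xs), min(ys)
    width = (max(xs) - minx) * s + 2 * m
    height = (max(ys) - miny) * s + 2 * m

    def sx(p):
        return (p[0] - minx) * s + m

    def sy(p):
        return (-p[1] - miny) * s + m

    lines = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{width}" height="{height}" '
        f'viewBox="0 0 {width} {height}">'
    ]
    if style.background is not None:
        lines.append(
            f'<rect width="{width}" height="{height}" fill="{style.background}"/>'
        )
    lines.append(
        f'<g stroke="{style.stroke}" stroke-width="{style.stroke_width}" '
        'stroke-linecap="round">'
    )
    for a, b in zip(pts, pts[1:]):
        lines.append(
            f'<line x1="{sx(a)}" y1="{sy(a)}" x2="{sx(b)}" y2="{sy(b)}"/>'
        )
    lines.append("</g>")
    origin = (0, 0)
    lines.append(
        f'<circle cx="{sx(origin)}" cy="{sy(origin)}" r="{style.origin_radius}" '
        f'fill="{style.origin_fill}"/>'
    )
    lines.append("</svg>")
    return "\n".join(lines) + "\n"


def write_census_csv(table: CensusTable, path: Union[str, Path]) -> None:
    """Write a census table as CSV with header rule_length,N,T,L,R,total."""
    path = Path(path)
    try:
        with path.open("w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["rule_length", "N", "T", "L", "R", "total"])
            for i in range(1, table.depth + 1):
                row = table.rows[i]
                writer.writerow([i] + [row[c] for c in _CATEGORIES] + [row["total"]])
    except OSError as exc:
        raise OSError(f"cannot write census table to {path}: {exc}") from exc


def read_census_csv(path: Union[str, Path]) -> CensusTable:
    path = Path(path)
    try:
        with path.open(newline="") as fh:
            reader = csv.DictReader(fh)
            rows: dict[int, dict[str, int]] = {}
            for rec in reader:
                i = int(rec["rule_length"])
                rows[i] = {c: int(rec[c]) for c in _CATEGORIES}
                rows[i]["total"] = int(rec["total"])
    except OSError as exc:
        raise OSError(f"cannot read census table from {path}: {exc}") from exc
    if not rows:
        raise ValueError(f"no census rows in {path}")
    return CensusTable(depth=max(rows), rows=rows)


def write_runlog(results: Iterable[WormResult], path: Union[str, Path]) -> None:
    """Write one JSON record per worm (the run-log format)."""
    path = Path(path)
    try:
        with path.open("w") as fh:
            for res in results:
                fh.write(json.dumps(res.to_record()) + "\n")
    except OSError as exc:
        raise OSError(f"cannot write run log to {path}: {exc}") from exc


def read_runlog(path: Union[str, Path]) -> list:
    path = Path(path)
    try:
        with path.open() as fh:
            return [json.loads(line) for line in fh if line.strip()]
    except OSError as exc:
        raise OSError(f"cannot read run log from {path}: {exc}") from exc
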