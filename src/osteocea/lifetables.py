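"""Life tables: synthetic mortality stand-in and CSV input/output.

The simulation consumes annual death probabilities (qx) by single year of
age.  The intended production input is a national female life table supplied
as a two-column CSV (``age,qx``).  Because no external table ships with the
package, :func:`make_synthetic_life_table` generates a calibrated
Gompertz-Makeham schedule — a synthetic fixture, not an estimate of any real
population's mortality — under which essentially everyone starting at ages
70-80 is dead by age 105, so the whole pipeline runs and is testable offline.

Abridged (5-year band) tables are expanded to single years by assuming a
constant qx within each band.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path

from .params import ParameterSet, default_parameters

__all__ = [
    "LifeTable",
    "make_synthetic_life_table",
    "read_life_table",
    "write_life_table",
    "make_fixture_cohort_params",
]

# invented Gompertz-Makeham fixture calibration (not Japanese vital statistics)
DEFAULT_GOMPERTZ_A = 1.0e-5
DEFAULT_GOMPERTZ_B = 0.11
DEFAULT_MAKEHAM_C = 2.0e-4


@dataclass(frozen=True)
class LifeTable:
    """Annual death probabilities qx over a contiguous range of ages."""

    ages: tuple[int, ...]
    qx: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.ages) != len(self.qx):
            raise ValueError("ages and qx must have equal length")
        if any(b - a != 1 for a, b in zip(self.ages, self.ages[1:])):
            raise ValueError("ages must be contiguous single years, strictly increasing")
        if any(not 0 < q <= 1 for q in self.qx):
            raise ValueError("every qx must lie in (0, 1]")

    @property
    def min_age(self) -> int:
        return self.ages[0]

    @property
    def max_age(self) -> int:
        return self.ages[-1]

    def lookup(self, age: int) -> float:
        if not self.min_age <= age <= self.max_age:
            raise ValueError(f"age {age} outside life table range "
                             f"[{self.min_age}, {self.max_age}]")
        return self.qx[age - self.min_age]

    def require_coverage(self, lo: int, hi: int) -> None:
        if self.min_age > lo or self.max_age < hi:
            raise ValueError(
                f"life table covers ages [{self.min_age}, {self.max_age}], "
                f"needs [{lo}, {hi}]"
            )

    def survival(self, start_age: int, end_age: int) -> float:
        """Probability of surviving from start_age to end_age (exclusive of
        death during the end_age year)."""
        p = 1.0
        for a in range(start_age, end_age):
            p *= 1.0 - self.lookup(a)
        return p


def make_synthetic_life_table(
    a: float = DEFAULT_GOMPERTZ_A,
    b: float = DEFAULT_GOMPERTZ_B,
    c: float = DEFAULT_MAKEHAM_C,
    age_range: tuple[int, int] = (60, 105),
) -> LifeTable:
    """Gompertz-Makeham annual death probabilities.

    qx(age) = 1 - exp(-(c + a * e^(b*age))), clipped to (0, 1].  With the
    default calibration the probability of dying before 105 from any starting
    age in 70-80 exceeds 99%, matching the direction of the model-validation
    claim while remaining an invented fixture.
    """
    if a <= 0 or b <= 0:
        raise ValueError("Gompertz parameters a and b must be positive")
    if c < 0:
        raise ValueError("Makeham constant c must be non-negative")
    lo, hi = age_range
    ages = tuple(range(lo, hi + 1))
    qx = []
    for age in ages:
        h = c + a * math.exp(b * age)
        q = 1.0 - math.exp(-h)
        qx.append(min(max(q, 1e-12), 1.0))
    return LifeTable(ages=ages, qx=tuple(qx))


def write_life_table(table: LifeTable, path: str | Path) -> None:
    """Write a life table as an ``age,qx`` CSV (UTF-8, full float precision)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["age", "qx"])
        for age, q in zip(table.ages, table.qx):
            writer.writerow([age, repr(q)])


def read_life_table(path: str | Path, required_range: tuple[int, int] = (70, 105)) -> LifeTable:
    """Read an ``age,qx`` CSV.

    Single-year tables are used as-is.  A table whose ages step by a constant
    width > 1 is treated as abridged and expanded by repeating each band's qx
    for every year in the band.  Gaps, non-monotone ages, qx outside (0, 1],
    or missing coverage of ``required_range`` raise ``ValueError``.
    """
    rows: list[tuple[int, float]] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip().lower() for h in header[:2]] != ["age", "qx"]:
            raise ValueError(f"{path}: expected header 'age,qx', got {header}")
        for lineno, row in enumerate(reader, start=2):
            if not row or not "".join(row).strip():
                continue
            try:
                rows.append((int(row[0]), float(row[1])))
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed row {row}") from exc
    if not rows:
        raise ValueError(f"{path}: no data rows")
    ages = [a for a, _ in rows]
    if any(b <= a for a, b in zip(ages, ages[1:])):
        raise ValueError(f"{path}: ages must be strictly increasing")
    steps = {b - a for a, b in zip(ages, ages[1:])}
    if steps and steps != {1}:
        if len(steps) == 1:
            width = steps.pop()
            expanded: list[tuple[int, float]] = []
            for a, q in rows:
                expanded.extend((a + k, q) for k in range(width))
            rows = expanded
            ages = [a for a, _ in rows]
        else:
            raise ValueError(f"{path}: ages have mixed steps {sorted(steps)}; "
                             "supply single-year or uniformly abridged ages")
    table = LifeTable(ages=tuple(ages), qx=tuple(q for _, q in rows))
    table.require_coverage(*required_range)
    return table


def make_fixture_cohort_params(scale: float = 1.0) -> ParameterSet:
    """Default parameters with both fracture incidence tables multiplied by
    ``scale`` (used by tests and the incidence sweep)."""
    if scale <= 0:
        raise ValueError("scale must be positive")
    ps = default_parameters()
    ps.epidemiology.hip_rates = ps.epidemiology.hip_rates.scaled(scale)
    ps.epidemiology.vert_rates = ps.epidemiology.vert_rates.scaled(scale)
    return ps
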