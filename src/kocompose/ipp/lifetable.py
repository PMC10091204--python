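"""Life tables and mortality schedules.

A life table maps (sex, race) strata to age-indexed annual mortality
probabilities q_a for ages 0..100, with q_100 = 1 as closure. A mortality
schedule is the age-ordered slice an individual's life-expectancy estimate
runs over. CSV interchange uses columns ``sex, race, age, q``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

__all__ = [
    "MAX_AGE",
    "LifeTable",
    "MortalitySchedule",
    "read_life_table",
    "write_life_table",
    "mortality_schedule",
]

MAX_AGE = 100


@dataclass(frozen=True)
class MortalitySchedule:
    """Age-ordered annual mortality probabilities starting at ``start_age``."""

    start_age: int
    rates: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "rates", tuple(float(q) for q in self.rates))
        if not self.rates:
            raise ValueError("mortality schedule must be nonempty")
        for q in self.rates:
            if not 0.0 <= q <= 1.0:
                raise ValueError(f"mortality probability {q} outside [0, 1]")


@dataclass
class LifeTable:
    """Annual mortality probabilities by (sex, race) stratum, ages 0..100."""

    strata: dict[tuple[str, str], tuple[float, ...]]

    def __post_init__(self) -> None:
        for (sex, race), rates in self.strata.items():
            rates = tuple(float(q) for q in rates)
            if len(rates) != MAX_AGE + 1:
                raise ValueError(
                    f"stratum ({sex}, {race}) has {len(rates)} ages, need {MAX_AGE + 1}"
                )
            for q in rates:
                if not 0.0 <= q <= 1.0:
                    raise ValueError(f"stratum ({sex}, {race}) has q={q} outside [0, 1]")
            if rates[MAX_AGE] != 1.0:
                raise ValueError(f"stratum ({sex}, {race}) must close with q_100 = 1")
            self.strata[(sex, race)] = rates

    def as_nested_dict(self) -> dict[str, dict[str, list[float]]]:
        """sex -> race -> rates; the form embedded in the life-table KO payload."""
        nested: dict[str, dict[str, list[float]]] = {}
        for (sex, race), rates in sorted(self.strata.items()):
            nested.setdefault(sex, {})[race] = list(rates)
        return nested


def read_life_table(path: str | Path) -> LifeTable:
    frame = pd.read_csv(path, float_precision="round_trip")
    strata: dict[tuple[str, str], tuple[float, ...]] = {}
    for (sex, race), group in frame.groupby(["sex", "race"], sort=True):
        group = group.sort_values("age")
        ages = group["age"].tolist()
        if ages != list(range(MAX_AGE + 1)):
            raise ValueError(f"stratum ({sex}, {race}) does not cover ages 0..{MAX_AGE}")
        strata[(str(sex), str(race))] = tuple(group["q"].astype(float))
    return LifeTable(strata)


def write_life_table(table: LifeTable, path: str | Path) -> Path:
    rows = [
        # repr keeps the shortest round-tripping decimal form of each q
        {"sex": sex, "race": race, "age": age, "q": repr(q)}
        for (sex, race), rates in sorted(table.strata.items())
        for age, q in enumerate(rates)
    ]
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def mortality_schedule(
    table: LifeTable, age: int, sex: str, race: str, horizon: int
) -> MortalitySchedule:
    """Slice a stratum's rates for ages ``age..min(age + horizon, 100)``."""
    key = (sex, race)
    if key not in table.strata:
        raise LookupError(f"life table has no stratum for (sex={sex!r}, race={race!r})")
    if not 0 <= age <= MAX_AGE:
        raise ValueError(f"age {age} outside table range 0..{MAX_AGE}")
    if horizon < 0:
        raise ValueError("horizon must be nonnegative")
    stop = min(age + horizon, MAX_AGE)
    return MortalitySchedule(start_age=age, rates=table.strata[key][age : stop + 1])
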