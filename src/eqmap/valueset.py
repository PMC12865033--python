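"""EQ-5D-5L health states and value-set scoring.

An EQ-5D-5L health state is a profile of five ordinal levels (1 = no
problems .. 5 = extreme problems) over mobility (``mo``), self-care
(``sc``), usual activities (``ua``), pain/discomfort (``pd``) and
anxiety/depression (``ad``).  A *value set* attaches a societal utility
(index value) to each of the 3125 states.  This module uses the additive
representation shared by most published EQ-5D-5L tariffs::

    index(state) = 1 - sum of per-dimension, per-level decrements

with the level-1 decrement fixed at 0, so full health (11111) scores
exactly 1.  The bundled set (``data/value_set_synthetic.csv``) is a
synthetic, illustrative tariff calibrated so that the worst state 55555
scores -0.848 and the minimal clinically important difference (MCID) is
0.066, matching the published Hungarian anchor points; the real Hungarian
coefficients are not bundled and can be supplied as a CSV/JSON file.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "DIMENSIONS",
    "DEFAULT_MCID",
    "HealthState",
    "ValueSet",
    "ValueSetFormatError",
    "ValueSetValidationError",
    "load_value_set",
    "default_value_set",
    "index_from_state",
    "index_range",
]

#: dimension codes in canonical EQ-5D order
DIMENSIONS: tuple[str, ...] = ("mo", "sc", "ua", "pd", "ad")
LEVELS: tuple[int, ...] = (1, 2, 3, 4, 5)

#: minimal clinically important difference of the EQ-5D-5L index
DEFAULT_MCID: float = 0.066


class ValueSetFormatError(ValueError):
    """A value-set source is structurally incomplete or malformed."""


class ValueSetValidationError(ValueError):
    """A value-set violates a semantic invariant (monotonicity, anchors)."""


@dataclass(frozen=True)
class HealthState:
    """One EQ-5D-5L health state: five levels, each in 1..5."""

    mo: int
    sc: int
    ua: int
    pd: int
    ad: int

    def __post_init__(self) -> None:
        for dim in DIMENSIONS:
            lvl = getattr(self, dim)
            if lvl not in LEVELS:
                raise ValueError(
                    f"dimension {dim!r} level must be in 1..5, got {lvl!r}"
                )

    @property
    def levels(self) -> tuple[int, int, int, int, int]:
        return (self.mo, self.sc, self.ua, self.pd, self.ad)

    def __str__(self) -> str:  # e.g. "21345"
        return "".join(str(v) for v in self.levels)


@dataclass(frozen=True)
class ValueSet:
    """Additive EQ-5D-5L tariff: per-dimension, per-level disutility decrements.

    ``decrements[dim][level]`` holds the disutility of reporting ``level``
    on ``dim``; level 1 always contributes 0.  The index of a state is
    ``1 - sum(decrements)``, so the floor of the index range is the score
    of state 55555.
    """

    name: str
    decrements: Mapping[str, Mapping[int, float]]
    mcid: float = DEFAULT_MCID
    _lookup: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.mcid > 0:
            raise ValueSetValidationError(f"mcid must be > 0, got {self.mcid}")
        lookup = np.zeros((len(DIMENSIONS), 6))
        for d, dim in enumerate(DIMENSIONS):
            if dim not in self.decrements:
                raise ValueSetFormatError(f"missing dimension {dim!r}")
            prev = 0.0
            for lvl in (2, 3, 4, 5):
                try:
                    dec = float(self.decrements[dim][lvl])
                except KeyError:
                    raise ValueSetFormatError(
                        f"missing decrement for dimension {dim!r} level {lvl}"
                    ) from None
                if dec < 0:
                    raise ValueSetValidationError(
                        f"negative decrement for {dim!r} level {lvl}: {dec}"
                    )
                if dec < prev:
                    raise ValueSetValidationError(
                        f"decrement for {dim!r} decreases from level "
                        f"{lvl - 1} ({prev}) to level {lvl} ({dec})"
                    )
                lookup[d, lvl] = dec
                prev = dec
        object.__setattr__(self, "_lookup", lookup)

    # -- scoring -----------------------------------------------------------

    def index(self, state: "HealthState | Iterable[int]") -> float:
        """Index value of one health state: ``1 - sum(decrements)``."""
        levels = state.levels if isinstance(state, HealthState) else tuple(state)
        if len(levels) != 5 or any(v not in LEVELS for v in levels):
            raise ValueError(f"invalid health state {levels!r}")
        return float(1.0 - sum(self._lookup[d, lvl] for d, lvl in enumerate(levels)))

    def index_array(self, levels: np.ndarray) -> np.ndarray:
        """Vectorised scoring of an (n, 5) integer level matrix."""
        levels = np.asarray(levels)
        if levels.ndim != 2 or levels.shape[1] != 5:
            raise ValueError("levels must be an (n, 5) matrix")
        if levels.min() < 1 or levels.max() > 5:
            raise ValueError("levels must be in 1..5")
        dec = np.zeros(len(levels))
        for d in range(5):
            dec += self._lookup[d, levels[:, d]]
        return 1.0 - dec

    @property
    def floor(self) -> float:
        """Index of the worst state (5,5,5,5,5)."""
        return float(1.0 - self._lookup[:, 5].sum())

    @property
    def range_width(self) -> float:
        return 1.0 - self.floor

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"dimension": dim, "level": lvl, "decrement": self._lookup[d, lvl]}
            for d, dim in enumerate(DIMENSIONS)
            for lvl in (2, 3, 4, 5)
        ]
        return pd.DataFrame(rows)


def load_value_set(
    source: "str | Path | pd.DataFrame | Mapping",
    name: str | None = None,
    mcid: float = DEFAULT_MCID,
) -> ValueSet:
    """Load and validate a value set from CSV, JSON, DataFrame or mapping.

    CSV/DataFrame sources need columns ``dimension`` (mo|sc|ua|pd|ad),
    ``level`` (2..5) and ``decrement``; JSON/mapping sources are nested
    ``{dimension: {level: decrement}}``.
    """
    if isinstance(source, (str, Path)):
        path = Path(source)
        if path.suffix.lower() == ".json":
            with open(path) as fh:
                return load_value_set(json.load(fh), name=name or path.stem, mcid=mcid)
        source = pd.read_csv(path)
        name = name or path.stem
    if isinstance(source, pd.DataFrame):
        required = {"dimension", "level", "decrement"}
        if not required.issubset(source.columns):
            raise ValueSetFormatError(
                f"value-set table needs columns {sorted(required)}, "
                f"got {list(source.columns)}"
            )
        nested: dict[str, dict[int, float]] = {}
        for _, row in source.iterrows():
            nested.setdefault(str(row["dimension"]), {})[int(row["level"])] = float(
                row["decrement"]
            )
        source = nested
    decrements = {
        str(dim): {int(lvl): float(dec) for lvl, dec in levels.items()}
        for dim, levels in source.items()
    }
    vs = ValueSet(name=name or "value_set", decrements=decrements, mcid=mcid)
    if abs(vs.index((1, 1, 1, 1, 1)) - 1.0) > 1e-12:
        raise ValueSetValidationError("index(1,1,1,1,1) must equal 1 exactly")
    return vs


def default_value_set() -> ValueSet:
    """The bundled synthetic illustrative tariff (floor -0.848, MCID 0.066)."""
    with resources.as_file(
        resources.files("eqmap").joinpath("data/value_set_synthetic.csv")
    ) as path:
        return load_value_set(path, name="synthetic-illustrative")


def index_from_state(state: "HealthState | Iterable[int]", vs: ValueSet) -> float:
    """Score a single health state with ``vs`` (1 - sum of decrements)."""
    return vs.index(state)


def index_range(vs: ValueSet) -> tuple[float, float]:
    """(floor, 1.0): the endpoints of the index scale under ``vs``."""
    return (vs.floor, 1.0)
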