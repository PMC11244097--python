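"""Face-centered central composite designs and emulgel formulation completion.

The experimental layout is a two-factor face-centered CCD (axial distance
α = 1, equivalently a 3² factorial without replicated center runs): four
factorial corners, four axial face points, one center point — nine runs.
Factor levels are carried in two parameterizations: *actual* values in
% w/w and *coded* levels on the −1..+1 scale about the design center,

    coded = (actual − center) / half_range.

Each run is completed into a full emulgel recipe: the gelling-agent
(poloxamer 407) share follows a linear rule in the oil content, the
active (ciclopirox olamine) is fixed, and purified water takes the
balance to 100 %.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FactorSpace",
    "DesignRun",
    "DesignTable",
    "FormulationRule",
    "generate_ccd",
    "complete_formulation",
    "EMULGEL_FACTOR_SPACE",
]

OIL = "mineral_oil"
POLYSORBATE = "polysorbate_80"

#: Components of a completed formulation, in reporting order.
COMPONENTS = ("mineral_oil", "polysorbate_80", "poloxamer_407", "purified_water", "ciclopirox_olamine")


@dataclass(frozen=True)
class FactorSpace:
    """Ranges of the independent variables with the coded↔actual affine map."""

    names: tuple[str, ...]
    low: tuple[float, ...]
    high: tuple[float, ...]

    def __post_init__(self) -> None:
        if not (len(self.names) == len(self.low) == len(self.high)):
            raise ValueError("names, low and high must have equal length")
        for name, lo, hi in zip(self.names, self.low, self.high):
            if not lo < hi:
                raise ValueError(f"factor {name!r}: low must be strictly below high")

    @property
    def k(self) -> int:
        return len(self.names)

    @property
    def center(self) -> tuple[float, ...]:
        return tuple((lo + hi) / 2.0 for lo, hi in zip(self.low, self.high))

    @property
    def half_range(self) -> tuple[float, ...]:
        return tuple((hi - lo) / 2.0 for lo, hi in zip(self.low, self.high))

    def _index(self, factor: str) -> int:
        try:
            return self.names.index(factor)
        except ValueError:
            raise KeyError(f"unknown factor label {factor!r}; have {list(self.names)}") from None

    def to_coded(self, actual, factor: str | None = None):
        """Coded level(s) for actual value(s); vectorized over all factors when
        ``factor`` is None.  Values outside [−1, +1] are returned as-is
        (extrapolation is the caller's concern)."""
        if factor is not None:
            i = self._index(factor)
            return (np.asarray(actual, dtype=float) - self.center[i]) / self.half_range[i]
        a = np.asarray(actual, dtype=float)
        return (a - np.asarray(self.center)) / np.asarray(self.half_range)

    def from_coded(self, coded, factor: str | None = None):
        """Inverse of :meth:`to_coded`."""
        if factor is not None:
            i = self._index(factor)
            return np.asarray(coded, dtype=float) * self.half_range[i] + self.center[i]
        c = np.asarray(coded, dtype=float)
        return c * np.asarray(self.half_range) + np.asarray(self.center)


#: Factor space of the reference emulgel study: 10–50 % mineral oil, 0–10 % polysorbate 80.
EMULGEL_FACTOR_SPACE = FactorSpace(names=(OIL, POLYSORBATE), low=(10.0, 0.0), high=(50.0, 10.0))


@dataclass(frozen=True)
class FormulationRule:
    """Linear rule completing factor levels into a full recipe.

    poloxamer_407 = intercept + slope * oil;  active fixed; water = balance.
    Defaults reproduce the reference compositions (22.5/17.5/12.5 % poloxamer
    at 10/30/50 % oil with 1 % ciclopirox olamine).
    """

    poloxamer_intercept: float = 25.0
    poloxamer_slope: float = -0.25
    api_pct: float = 1.0


def complete_formulation(
    oil: float, polysorbate: float, rule: FormulationRule = FormulationRule()
) -> dict[str, float]:
    """Complete (oil, polysorbate) into the five-component recipe in % w/w.

    Raises ``ValueError`` naming the offending component if any share
    would be negative.
    """
    poloxamer = rule.poloxamer_intercept + rule.poloxamer_slope * oil
    water = 100.0 - oil - polysorbate - poloxamer - rule.api_pct
    recipe = {
        "mineral_oil": float(oil),
        "polysorbate_80": float(polysorbate),
        "poloxamer_407": poloxamer,
        "purified_water": water,
        "ciclopirox_olamine": rule.api_pct,
    }
    for component, pct in recipe.items():
        if pct < 0:
            raise ValueError(f"negative formulation share for {component}: {pct:.4f} %")
    return recipe


def hydrogel_share(recipe: Mapping[str, float]) -> float:
    """Hydrogel fraction = poloxamer + water + active = 100 − oil − polysorbate."""
    return recipe["poloxamer_407"] + recipe["purified_water"] + recipe["ciclopirox_olamine"]


@dataclass(frozen=True)
class DesignRun:
    run_id: str
    coded: tuple[float, ...]
    actual: tuple[float, ...]
    formulation: dict[str, float] | None = None


@dataclass(frozen=True)
class DesignTable:
    factor_space: FactorSpace
    runs: tuple[DesignRun, ...]

    def __post_init__(self) -> None:
        ids = [r.run_id for r in self.runs]
        if len(set(ids)) != len(ids):
            raise ValueError("run_ids must be unique")

    def __len__(self) -> int:
        return len(self.runs)

    def __iter__(self):
        return iter(self.runs)

    @property
    def coded_matrix(self) -> np.ndarray:
        return np.array([r.coded for r in self.runs], dtype=float)

    @property
    def actual_matrix(self) -> np.ndarray:
        return np.array([r.actual for r in self.runs], dtype=float)

    @property
    def run_ids(self) -> tuple[str, ...]:
        return tuple(r.run_id for r in self.runs)

    def run(self, run_id: str) -> DesignRun:
        for r in self.runs:
            if r.run_id == run_id:
                return r
        raise KeyError(f"no run {run_id!r}")

    def to_frame(self) -> pd.DataFrame:
        """Design as a DataFrame in the package's CSV dialect."""
        rows = []
        for r in self.runs:
            row = {
                "run_id": r.run_id,
                "oil_pct": r.actual[0],
                "polysorbate_pct": r.actual[1],
                "coded_A": r.coded[0],
                "coded_B": r.coded[1],
            }
            if r.formulation is not None:
                row["poloxamer_pct"] = r.formulation["poloxamer_407"]
                row["water_pct"] = r.formulation["purified_water"]
                row["cpo_pct"] = r.formulation["ciclopirox_olamine"]
            rows.append(row)
        return pd.DataFrame(rows)


# Coded (A, B) levels of the nine-run design in the reference run order
# E-1 … E-9 (axial, factorial and center points interleaved as printed).
_REFERENCE_CODED_ORDER: tuple[tuple[float, float], ...] = (
    (0.0, -1.0),   # E-1 (30, 0)
    (-1.0, -1.0),  # E-2 (10, 0)
    (-1.0, 0.0),   # E-3 (10, 5)
    (0.0, 1.0),    # E-4 (30, 10)
    (1.0, 1.0),    # E-5 (50, 10)
    (-1.0, 1.0),   # E-6 (10, 10)
    (1.0, 0.0),    # E-7 (50, 5)
    (1.0, -1.0),   # E-8 (50, 0)
    (0.0, 0.0),    # E-9 (30, 5)
)


def _canonical_coded_points(k: int) -> list[tuple[float, ...]]:
    """Factorial corners, axial face points, then the center (α = 1)."""
    points: list[tuple[float, ...]] = []
    # 2^k factorial corners, last factor fastest
    for idx in range(2**k):
        corner = tuple(1.0 if (idx >> (k - 1 - j)) & 1 else -1.0 for j in range(k))
        points.append(corner)
    # 2k axial points on the faces
    for j in range(k):
        for level in (-1.0, 1.0):
            pt = [0.0] * k
            pt[j] = level
            points.append(tuple(pt))
    points.append(tuple([0.0] * k))
    return points


def generate_ccd(
    factor_space: FactorSpace,
    formulation_rule: FormulationRule | None = None,
    center_replicates: int = 0,
) -> DesignTable:
    """Face-centered central composite design over ``factor_space``.

    For k factors: 2^k factorial + 2k axial + 1 center point, all coded
    levels in {−1, 0, +1}.  When the factor space is the reference emulgel
    space the runs are emitted in the reference order with E-labels;
    otherwise in canonical factorial/axial/center order with R-labels.
    ``center_replicates`` appends that many extra center runs (for users
    needing a pure-error estimate; the reference design has none).

    Formulation completion is applied when ``formulation_rule`` is given,
    or by default when the factors are the emulgel pair (oil, polysorbate).
    """
    for name, hr in zip(factor_space.names, factor_space.half_range):
        if hr <= 0 or not math.isfinite(hr):
            raise ValueError(f"degenerate factor {name!r}: half_range must be positive and finite")

    k = factor_space.k
    is_reference = factor_space.names == (OIL, POLYSORBATE)
    if k == 2 and is_reference:
        coded_points = list(_REFERENCE_CODED_ORDER)
        labels = [f"E-{i + 1}" for i in range(len(coded_points))]
    else:
        coded_points = _canonical_coded_points(k)
        labels = [f"R-{i + 1}" for i in range(len(coded_points))]

    for i in range(center_replicates):
        coded_points.append(tuple([0.0] * k))
        labels.append(f"C-{i + 1}")

    if formulation_rule is None and is_reference:
        formulation_rule = FormulationRule()

    runs = []
    for label, coded in zip(labels, coded_points):
        actual = tuple(float(v) for v in factor_space.from_coded(np.array(coded)))
        formulation = None
        if formulation_rule is not None:
            formulation = complete_formulation(actual[0], actual[1], formulation_rule)
        runs.append(DesignRun(run_id=label, coded=coded, actual=actual, formulation=formulation))
    return DesignTable(factor_space=factor_space, runs=tuple(runs))
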