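"""Per-subcategory greenhouse-gas emission coefficients from literature data.

Literature data points (kg CO2e per kg of food, one or more per indicator
product) are averaged into indicator means, indicator means are averaged
into subcategory coefficients, and descriptive uncertainty ranges are
attached following a point-count-dependent rule. Ranges are reporting-only:
the optimization uses the mean coefficients.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import registry
from .errors import CoverageError, SchemaError, ValidationError

logger = logging.getLogger(__name__)

#: 100-year global warming potentials, kg CO2e per kg of gas.
DEFAULT_GWP_FACTORS: dict[str, float] = {"CO2": 1.0, "CH4": 25.0, "N2O": 298.0}

#: Default quartile interpolation (numpy "linear" == R type 7).
DEFAULT_QUARTILE_METHOD = "linear"


@dataclass(frozen=True)
class GWPFactors:
    """Gas-to-CO2e multipliers over a 100-year horizon."""

    factors: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_GWP_FACTORS)
    )

    def __post_init__(self) -> None:
        if self.factors.get("CO2") != 1.0:
            raise ValidationError("CO2 factor must be exactly 1")
        if any(v <= 0 for v in self.factors.values()):
            raise ValidationError("all GWP factors must be > 0")

    def __getitem__(self, gas: str) -> float:
        try:
            return self.factors[gas]
        except KeyError:
            raise KeyError(f"unknown greenhouse gas {gas!r}") from None


def gwp_to_co2e(mass_kg: float, gas: str, factors: GWPFactors | None = None) -> float:
    """Convert a gas mass in kg to kg CO2 equivalents."""
    if mass_kg < 0:
        raise ValidationError(f"mass must be >= 0, got {mass_kg}")
    factors = factors or GWPFactors()
    return mass_kg * factors[gas]


@dataclass(frozen=True)
class GHGEDataPoint:
    """One literature emission value for an indicator product."""

    indicator_id: int
    value: float  # kg CO2e per kg food
    national_reliable: bool = False
    source: str = ""

    def __post_init__(self) -> None:
        if not np.isfinite(self.value) or self.value <= 0:
            raise ValidationError(
                f"indicator {self.indicator_id}: value must be > 0, got {self.value}"
            )


@dataclass(frozen=True)
class IndicatorProduct:
    indicator_id: int
    subcategory_ids: tuple[int, ...]
    mean: float  # kg CO2e / kg
    lo: float
    hi: float
    rule_used: str  # quartiles | minmax | pm50 | pm25
    n_points: int

    def __post_init__(self) -> None:
        if not (self.lo <= self.mean <= self.hi):
            raise ValidationError(
                f"indicator {self.indicator_id}: range ({self.lo}, {self.hi}) "
                f"does not contain mean {self.mean}"
            )


def indicator_mean(points: Sequence[GHGEDataPoint]) -> float:
    """Arithmetic mean of the data-point values, kg CO2e/kg."""
    if not points:
        raise ValidationError("indicator_mean requires at least one data point")
    return float(np.mean([p.value for p in points]))


def uncertainty_range(
    points: Sequence[GHGEDataPoint],
    national_reliable: bool = False,
    quartile_method: str = DEFAULT_QUARTILE_METHOD,
) -> tuple[float, float]:
    """Descriptive (lo, hi) range in kg CO2e/kg by point-count rule.

    >=4 points: lower/upper quartile; 2-3 points: min/max; single point:
    -50%/+50%, narrowed to -25%/+25% when the single estimate is a
    reliable national evaluation.
    """
    if not points:
        raise ValidationError("uncertainty_range requires at least one data point")
    values = np.array([p.value for p in points], dtype=float)
    if len(values) >= 4:
        lo, hi = np.percentile(values, [25, 75], method=quartile_method)
        # skewed point sets can put the mean outside the interquartile
        # range; widen so the range always contains the mean
        lo, hi = min(lo, values.mean()), max(hi, values.mean())
    elif len(values) >= 2:
        lo, hi = values.min(), values.max()
    else:
        v = float(values[0])
        frac = 0.25 if national_reliable else 0.5
        lo, hi = v * (1 - frac), v * (1 + frac)
    return float(lo), float(hi)


def range_rule(n_points: int, national_reliable: bool = False) -> str:
    if n_points >= 4:
        return "quartiles"
    if n_points >= 2:
        return "minmax"
    if n_points == 1:
        return "pm25" if national_reliable else "pm50"
    raise ValidationError("need at least one data point")


def subcategory_ghge(indicator_means: Sequence[float]) -> float:
    """Subcategory coefficient in kg CO2e per gram of food."""
    if len(indicator_means) == 0:
        raise CoverageError("subcategory has no indicator products")
    return float(np.mean(indicator_means)) / 1000.0


@dataclass
class GHGETable:
    """Emission coefficients per subcategory, kg CO2e per gram.

    ``frame`` is indexed by subcategory_id with columns
    c_kgco2e_per_g, lo, hi, rule, n_points; lo/hi are in the same per-gram
    units as the coefficient. ``indicators`` maps subcategory_id to the
    contributing indicator ids.
    """

    frame: pd.DataFrame
    indicators: dict[int, tuple[int, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = self.frame[~(self.frame["c_kgco2e_per_g"] > 0)]
        if len(bad):
            raise ValidationError(
                f"non-positive coefficient for subcategory {int(bad.index[0])}"
            )
        contain = (self.frame["lo"] <= self.frame["c_kgco2e_per_g"] + 1e-12) & (
            self.frame["c_kgco2e_per_g"] <= self.frame["hi"] + 1e-12
        )
        if not contain.all():
            k = int(self.frame.index[~contain][0])
            raise ValidationError(f"range does not contain mean for subcategory {k}")

    @property
    def subcategory_ids(self) -> list[int]:
        return [int(k) for k in self.frame.index]

    def coefficients(
        self, subcategory_ids: Iterable[int] | None = None
    ) -> np.ndarray:
        """Coefficient vector (kg CO2e/g) over the requested subcategories."""
        ids = list(
            subcategory_ids
            if subcategory_ids is not None
            else range(1, registry.N_SUBCATEGORIES + 1)
        )
        missing = [k for k in ids if k not in self.frame.index]
        if missing:
            raise CoverageError(f"no GHGE coefficient for subcategories {missing}")
        return self.frame.loc[ids, "c_kgco2e_per_g"].to_numpy(dtype=float)

    def to_csv(self, path: str | Path) -> None:
        out = self.frame.reset_index().rename(columns={"index": "subcategory_id"})
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "GHGETable":
        df = pd.read_csv(path)
        required = {"subcategory_id", "c_kgco2e_per_g", "lo", "hi", "rule", "n_points"}
        missing = required - set(df.columns)
        if missing:
            raise SchemaError(f"GHGE table missing columns: {sorted(missing)}")
        return cls(df.set_index("subcategory_id"))


def build_indicators(
    points: pd.DataFrame,
    mapping: pd.DataFrame,
    quartile_method: str = DEFAULT_QUARTILE_METHOD,
) -> list[IndicatorProduct]:
    """Aggregate raw data points into indicator products.

    ``points`` columns: indicator_id, value_kgco2e_per_kg, national_reliable,
    source. ``mapping`` columns: indicator_id, subcategory_id (an indicator
    may serve several subcategories and several items within one).
    """
    for col in ("indicator_id", "value_kgco2e_per_kg"):
        if col not in points.columns:
            raise SchemaError(f"points table missing column {col!r}")
    for col in ("indicator_id", "subcategory_id"):
        if col not in mapping.columns:
            raise SchemaError(f"mapping table missing column {col!r}")

    sub_of: dict[int, list[int]] = {}
    for _, row in mapping.iterrows():
        sub_of.setdefault(int(row["indicator_id"]), []).append(
            int(row["subcategory_id"])
        )

    indicators = []
    for ind_id, grp in points.groupby("indicator_id", sort=True):
        pts = [
            GHGEDataPoint(
                indicator_id=int(ind_id),
                value=float(r["value_kgco2e_per_kg"]),
                national_reliable=bool(r.get("national_reliable", False)),
                source=str(r.get("source", "")),
            )
            for _, r in grp.iterrows()
        ]
        reliable = all(p.national_reliable for p in pts)
        mean = indicator_mean(pts)
        lo, hi = uncertainty_range(pts, reliable, quartile_method)
        indicators.append(
            IndicatorProduct(
                indicator_id=int(ind_id),
                subcategory_ids=tuple(sorted(sub_of.get(int(ind_id), ()))),
                mean=mean,
                lo=lo,
                hi=hi,
                rule_used=range_rule(len(pts), reliable),
                n_points=len(pts),
            )
        )
    return indicators


def build_ghge_table(
    points: pd.DataFrame,
    mapping: pd.DataFrame,
    required_subcategories: Iterable[int] | None = None,
    quartile_method: str = DEFAULT_QUARTILE_METHOD,
) -> GHGETable:
    """Compose the per-subcategory coefficient table.

    ``required_subcategories`` (default: all 55) must each be covered by at
    least one indicator, otherwise a :class:`CoverageError` lists them.
    """
    indicators = build_indicators(points, mapping, quartile_method)
    required = sorted(
        set(
            required_subcategories
            if required_subcategories is not None
            else range(1, registry.N_SUBCATEGORIES + 1)
        )
    )

    by_sub: dict[int, list[IndicatorProduct]] = {}
    for ind in indicators:
        for k in ind.subcategory_ids:
            by_sub.setdefault(k, []).append(ind)

    uncovered = [k for k in required if k not in by_sub]
    if uncovered:
        raise CoverageError(
            f"subcategories without GHGE indicator: {uncovered}"
        )

    rows, contrib = [], {}
    for k in sorted(by_sub):
        inds = by_sub[k]
        c = subcategory_ghge([i.mean for i in inds])
        lo = float(np.mean([i.lo for i in inds])) / 1000.0
        hi = float(np.mean([i.hi for i in inds])) / 1000.0
        rules = sorted({i.rule_used for i in inds})
        rows.append(
            {
                "subcategory_id": k,
                "c_kgco2e_per_g": c,
                "lo": lo,
                "hi": hi,
                "rule": rules[0] if len(rules) == 1 else "mixed",
                "n_points": int(sum(i.n_points for i in inds)),
            }
        )
        contrib[k] = tuple(i.indicator_id for i in inds)
    frame = pd.DataFrame(rows).set_index("subcategory_id")
    return GHGETable(frame, contrib)


__all__ = [
    "DEFAULT_GWP_FACTORS",
    "GWPFactors",
    "GHGEDataPoint",
    "IndicatorProduct",
    "GHGETable",
    "gwp_to_co2e",
    "indicator_mean",
    "uncertainty_range",
    "range_rule",
    "subcategory_ghge",
    "build_indicators",
    "build_ghge_table",
]
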