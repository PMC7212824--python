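"""Assembly of the three constraint families and the LP objective.

Constraints are linear in the 55 subcategory amounts x_k (g/day):
``lb_j <= sum_k a_jk x_k <= ub_j``. Nutritional bounds come from a
per-sex config (absolute per-day units, or percent-of-energy bounds
linearized exactly in homogeneous form), acceptability bounds from the
observed population statistics, and healthy bounds from policy targets on
food-group membership sets.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field as dc_field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import registry
from .errors import InfeasibleBoxError, ValidationError
from .ghge_db import GHGETable
from .survey import PopulationStats

#: Content fields (per 100 g) backing each constrainable nutrient.
NUTRIENT_CONTENT_FIELDS: dict[str, tuple[str, ...]] = {
    "energy": ("energy_kcal",),
    "protein": ("protein_g",),
    "total_fat": ("total_fat_g",),
    "sfa": ("sfa_g",),
    "pufa": ("pufa_g",),
    "carbohydrate": ("carb_g",),
    "total_sugar": ("free_sugar_g", "intrinsic_sugar_g"),
    "free_sugar": ("free_sugar_g",),
    "cholesterol": ("cholesterol_mg",),
    "fiber": ("fiber_g",),
    "calcium": ("calcium_mg",),
    "iron": ("iron_mg",),
    "zinc": ("zinc_mg",),
    "vitamin_b12": ("vitamin_b12_ug",),
    "alcohol": ("alcohol_g",),
}

#: Percent-energy nutrients -> (content fields, energy-factor attribute).
PERCENT_ENERGY_NUTRIENTS: dict[str, tuple[tuple[str, ...], str]] = {
    "total_fat": (("total_fat_g",), "fat"),
    "sfa": (("sfa_g",), "fat"),
    "pufa": (("pufa_g",), "fat"),
    "carbohydrate": (("carb_g",), "carbohydrate"),
    "total_sugar": (("free_sugar_g", "intrinsic_sugar_g"), "carbohydrate"),
    "free_sugar": (("free_sugar_g",), "carbohydrate"),
}


@dataclass(frozen=True)
class EnergyFactors:
    """Metabolizable energy, kcal per gram of nutrient."""

    fat: float = 9.0
    protein: float = 4.0
    carbohydrate: float = 4.0
    alcohol: float = 7.0

    def __post_init__(self) -> None:
        if min(self.fat, self.protein, self.carbohydrate, self.alcohol) <= 0:
            raise ValidationError("energy factors must be > 0")


@dataclass
class Constraint:
    """One labeled linear constraint over the subcategory amounts."""

    label: str
    kind: str  # nutritional | acceptability | healthy
    coeffs: np.ndarray
    lb: float | None = None
    ub: float | None = None
    meta: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        if self.kind not in ("nutritional", "acceptability", "healthy"):
            raise ValidationError(f"{self.label}: unknown kind {self.kind!r}")
        if self.lb is None and self.ub is None:
            raise ValidationError(f"{self.label}: at least one bound required")
        if self.lb is not None and self.ub is not None and self.lb > self.ub:
            raise ValidationError(f"{self.label}: lb {self.lb} > ub {self.ub}")

    def value(self, x: np.ndarray) -> float:
        return float(self.coeffs @ x)

    def satisfied(self, x: np.ndarray, tol: float = 1e-8) -> bool:
        v = self.value(x)
        scale = max(1.0, abs(v))
        if self.lb is not None and v < self.lb - tol * max(scale, abs(self.lb)):
            return False
        if self.ub is not None and v > self.ub + tol * max(scale, abs(self.ub)):
            return False
        return True

    @property
    def is_box(self) -> bool:
        """True for single-variable constraints with unit coefficient."""
        nz = np.nonzero(self.coeffs)[0]
        return len(nz) == 1 and self.coeffs[nz[0]] == 1.0


@dataclass
class LPProblem:
    """Objective plus labeled constraints over non-negative amounts."""

    objective: np.ndarray  # kg CO2e per g, length n_vars
    constraints: list[Constraint]
    sex: str = "M"
    content: pd.DataFrame | None = None  # per 100 g, index 1..n_vars
    factors: EnergyFactors = dc_field(default_factory=EnergyFactors)
    n_vars: int = registry.N_SUBCATEGORIES
    meta: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        self.objective = np.asarray(self.objective, dtype=float)
        if self.objective.shape != (self.n_vars,):
            raise ValidationError("objective length does not match n_vars")
        for c in self.constraints:
            if c.coeffs.shape != (self.n_vars,):
                raise ValidationError(f"{c.label}: coefficient length mismatch")

    def labels(self) -> list[str]:
        return [c.label for c in self.constraints]

    def drop(self, labels: Iterable[str]) -> "LPProblem":
        """Copy of the problem without the named constraints."""
        drop = set(labels)
        kept = [copy.deepcopy(c) for c in self.constraints if c.label not in drop]
        return LPProblem(
            objective=self.objective.copy(),
            constraints=kept,
            sex=self.sex,
            content=self.content,
            factors=self.factors,
            n_vars=self.n_vars,
            meta=dict(self.meta),
        )

    def with_constraints(self, extra: Sequence[Constraint]) -> "LPProblem":
        return LPProblem(
            objective=self.objective.copy(),
            constraints=[copy.deepcopy(c) for c in self.constraints] + list(extra),
            sex=self.sex,
            content=self.content,
            factors=self.factors,
            n_vars=self.n_vars,
            meta=dict(self.meta),
        )


def default_config() -> dict:
    """Shipped bounds/policy configuration (deep copy, safe to mutate)."""
    text = resources.files("dietopt").joinpath("data/default_bounds.yaml").read_text()
    return yaml.safe_load(text)


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def nutrient_row(
    nutrient: str, content: pd.DataFrame, factors: EnergyFactors | None = None
) -> np.ndarray:
    """Per-gram coefficient vector of a nutrient over the subcategories."""
    try:
        fields = NUTRIENT_CONTENT_FIELDS[nutrient]
    except KeyError:
        raise ValidationError(f"unknown nutrient {nutrient!r}") from None
    per100 = sum(content[f].to_numpy(dtype=float) for f in fields)
    return per100 / 100.0


def nutrient_constraints(
    bounds_config: Mapping[str, Mapping],
    content: pd.DataFrame,
    factors: EnergyFactors | None = None,
) -> list[Constraint]:
    """Nutritional constraints from a per-nutrient bounds mapping.

    Absolute (``per_day``) bounds become one constraint per nutrient.
    Percent-of-energy bounds are linearized exactly and homogeneously:
    with f_k the nutrient grams per g of subcategory k, e_k the energy per
    g, E the kcal-per-gram factor of the nutrient and p the bound in
    percent, ``sum_k (E f_k - (p/100) e_k) x_k >= 0`` (lower) and ``<= 0``
    (upper). Validity does not depend on the total energy level.
    """
    factors = factors or EnergyFactors()
    if len(content) != registry.N_SUBCATEGORIES:
        raise ValidationError("content matrix must cover all 55 subcategories")
    energy_per_g = nutrient_row("energy", content)

    out: list[Constraint] = []
    for name, spec in bounds_config.items():
        if spec is None or ("lb" not in spec and "ub" not in spec):
            raise ValidationError(f"nutrient {name!r}: missing bound entry")
        lb, ub = spec.get("lb"), spec.get("ub")
        if lb is not None and ub is not None and lb > ub:
            raise ValidationError(f"nutrient {name!r}: lb {lb} > ub {ub}")
        unit = spec.get("unit", "per_day")
        if unit == "per_day":
            out.append(
                Constraint(
                    label=f"nutritional:{name}",
                    kind="nutritional",
                    coeffs=nutrient_row(name, content, factors),
                    lb=lb,
                    ub=ub,
                    meta={"nutrient": name, "unit": unit, "lb": lb, "ub": ub},
                )
            )
        elif unit == "percent_energy":
            fields, factor_attr = PERCENT_ENERGY_NUTRIENTS[name]
            grams_per_g = sum(content[f].to_numpy(dtype=float) for f in fields) / 100.0
            factor = getattr(factors, factor_attr)
            meta = {
                "nutrient": name,
                "unit": unit,
                "percent_lb": lb,
                "percent_ub": ub,
            }
            if lb is not None:
                out.append(
                    Constraint(
                        label=f"nutritional:{name}:pctE_lb",
                        kind="nutritional",
                        coeffs=factor * grams_per_g - (lb / 100.0) * energy_per_g,
                        lb=0.0,
                        meta=dict(meta),
                    )
                )
            if ub is not None:
                out.append(
                    Constraint(
                        label=f"nutritional:{name}:pctE_ub",
                        kind="nutritional",
                        coeffs=factor * grams_per_g - (ub / 100.0) * energy_per_g,
                        ub=0.0,
                        meta=dict(meta),
                    )
                )
        else:
            raise ValidationError(f"nutrient {name!r}: unknown unit {unit!r}")
    return out


def acceptability_constraints(
    stats: PopulationStats,
    weight_range: tuple[float, float] = (0.8, 1.4),
    overrides: Mapping[int, tuple[float | None, float | None]] | None = None,
    include_category_level: bool = True,
) -> list[Constraint]:
    """Total-weight band plus per-subcategory (and category) percentile boxes.

    Subcategories whose 5th and 90th percentile are both zero are fixed at
    zero. ``overrides`` replaces the (lb, ub) of selected subcategory boxes.
    """
    lo, hi = weight_range
    if not (0 < lo <= hi):
        raise ValidationError(f"bad weight range {weight_range}")
    overrides = overrides or {}

    out = [
        Constraint(
            label="acceptability:total_weight",
            kind="acceptability",
            coeffs=np.ones(registry.N_SUBCATEGORIES),
            lb=lo * stats.mean_total_weight,
            ub=hi * stats.mean_total_weight,
            meta={
                "mean_total_weight": stats.mean_total_weight,
                "weight_range": (lo, hi),
            },
        )
    ]
    for k in range(1, registry.N_SUBCATEGORIES + 1):
        lb, ub = float(stats.p5[k - 1]), float(stats.p90[k - 1])
        fixed_zero = lb == 0.0 and ub == 0.0
        if k in overrides:
            lb, ub = overrides[k]
            fixed_zero = lb == 0.0 and ub == 0.0
        coeffs = np.zeros(registry.N_SUBCATEGORIES)
        coeffs[k - 1] = 1.0
        out.append(
            Constraint(
                label=f"acceptability:subcat:{k}",
                kind="acceptability",
                coeffs=coeffs,
                lb=lb,
                ub=ub,
                meta={"subcategory_id": k, "fixed_zero": fixed_zero},
            )
        )
    if include_category_level:
        for cat, subs in registry.CATEGORY_TO_SUBCATEGORIES.items():
            coeffs = np.zeros(registry.N_SUBCATEGORIES)
            coeffs[[s - 1 for s in subs]] = 1.0
            out.append(
                Constraint(
                    label=f"acceptability:category:{cat}",
                    kind="acceptability",
                    coeffs=coeffs,
                    lb=float(stats.cat_p5[cat - 1]),
                    ub=float(stats.cat_p90[cat - 1]),
                    meta={"category_id": cat},
                )
            )
    return out


_DEFAULT_POLICY_SUBCATS: dict[str, frozenset[int]] = {
    "red_meat": registry.RED_MEAT_SUBCATS,
    "processed_meat": registry.PROCESSED_MEAT_SUBCATS,
    "alcoholic_beverages": registry.ALCOHOL_SUBCATS,
    "fruit_veg": registry.FRUIT_VEG_SUBCATS,
    "pulses": registry.PULSE_SUBCATS,
    "fish": registry.FISH_SUBCATS,
}


def healthy_constraints(
    stats: PopulationStats | None = None,
    policy_config: Mapping[str, Mapping] | None = None,
) -> list[Constraint]:
    """Food-group policy constraints (dietary-guideline bounds).

    Defaults: red meat in [10, 30] g/day, processed meat and alcoholic
    beverages fixed at zero, fruit & vegetables (excluding pulses and
    juices) in [400, 500] g/day, pulses and fish at least 20 g/day. The
    >=20 lower bounds deliberately override percentile lower bounds at
    assembly time.
    """
    policy_config = policy_config or default_config()["policy"]
    out = []
    for name, spec in policy_config.items():
        subs = spec.get("subcategories", _DEFAULT_POLICY_SUBCATS.get(name))
        if subs is None:
            raise ValidationError(f"policy {name!r}: no subcategory membership")
        unknown = set(subs) - set(registry.SUBCATEGORY_TO_CATEGORY)
        if unknown:
            raise ValidationError(
                f"policy {name!r}: unknown subcategories {sorted(unknown)}"
            )
        coeffs = np.zeros(registry.N_SUBCATEGORIES)
        coeffs[[s - 1 for s in subs]] = 1.0
        out.append(
            Constraint(
                label=f"healthy:{name}",
                kind="healthy",
                coeffs=coeffs,
                lb=spec.get("lb"),
                ub=spec.get("ub"),
                meta={"policy": name, "subcategories": sorted(subs)},
            )
        )
    return out


def assemble_problem(
    ghge: GHGETable,
    constraint_lists: Sequence[Sequence[Constraint]],
    sex: str = "M",
    content: pd.DataFrame | None = None,
    factors: EnergyFactors | None = None,
    meta: dict | None = None,
) -> LPProblem:
    """Concatenate constraint families into a solvable problem.

    Single-variable box constraints sharing a variable are tightened to
    their intersection (each keeps its label; original bounds go to meta).
    A syntactically empty intersection raises immediately, naming the
    subcategory.
    """
    constraints = [copy.deepcopy(c) for lst in constraint_lists for c in lst]
    labels = [c.label for c in constraints]
    if len(set(labels)) != len(labels):
        dup = sorted({l for l in labels if labels.count(l) > 1})
        raise ValidationError(f"duplicate constraint labels: {dup}")

    boxes: dict[int, list[Constraint]] = {}
    for c in constraints:
        if c.is_box:
            var = int(np.nonzero(c.coeffs)[0][0])
            boxes.setdefault(var, []).append(c)
    for var, group in boxes.items():
        if len(group) < 2:
            continue
        lbs = [c.lb for c in group if c.lb is not None]
        ubs = [c.ub for c in group if c.ub is not None]
        lb = max(lbs) if lbs else None
        ub = min(ubs) if ubs else None
        if lb is not None and ub is not None and lb > ub:
            raise InfeasibleBoxError(var + 1, lb, ub)
        for c in group:
            c.meta.setdefault("original_bounds", (c.lb, c.ub))
            c.lb, c.ub = lb, ub

    return LPProblem(
        objective=ghge.coefficients(),
        constraints=constraints,
        sex=sex,
        content=content,
        factors=factors or EnergyFactors(),
        meta=meta or {},
    )


def build_problem(
    stats: PopulationStats,
    ghge: GHGETable,
    config: Mapping | None = None,
    include_optional_nutrients: bool = False,
    include_category_level: bool | None = None,
) -> LPProblem:
    """Convenience: full problem for one sex from stats + GHGE table."""
    config = config or default_config()
    sex = stats.sex
    factors = EnergyFactors(**config.get("energy_factors", {}))
    bounds = dict(config["sexes"][sex]["nutritional"])
    if include_optional_nutrients:
        bounds.update(config["sexes"][sex].get("optional_nutritional", {}))
    acc_cfg = config.get("acceptability", {})
    if include_category_level is None:
        include_category_level = acc_cfg.get("include_category_level", True)
    nut = nutrient_constraints(bounds, stats.content, factors)
    acc = acceptability_constraints(
        stats,
        weight_range=tuple(acc_cfg.get("weight_range", (0.8, 1.4))),
        include_category_level=include_category_level,
    )
    healthy = healthy_constraints(stats, config.get("policy"))
    return assemble_problem(
        ghge,
        [nut, acc, healthy],
        sex=sex,
        content=stats.content,
        factors=factors,
        meta={"include_optional_nutrients": include_optional_nutrients},
    )


__all__ = [
    "NUTRIENT_CONTENT_FIELDS",
    "PERCENT_ENERGY_NUTRIENTS",
    "EnergyFactors",
    "Constraint",
    "LPProblem",
    "default_config",
    "load_config",
    "nutrient_row",
    "nutrient_constraints",
    "acceptability_constraints",
    "healthy_constraints",
    "assemble_problem",
    "build_problem",
]
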