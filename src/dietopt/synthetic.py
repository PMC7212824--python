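"""Synthetic catalogs, emission data points and survey diaries.

The generator emulates the structural features the pipeline depends on:
a catalog partitioned into the 15/55 taxonomy, indicator products with
1-6 literature data points each, and zero-inflated log-normal 3-day
diaries. Feasibility of the resulting optimization problem is obtained by
construction ("plant then perturb"): a target diet satisfying the shipped
nutritional and healthy constraints is computed for each sex and a
fraction of the synthetic population eats a noisy version of it, so the
population percentile boxes bracket the planted diet.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from . import registry
from .constraints import (
    Constraint,
    EnergyFactors,
    LPProblem,
    default_config,
    healthy_constraints,
    nutrient_constraints,
)
from .errors import DietOptError, ValidationError
from .food_model import (
    NUTRIENT_FIELDS,
    CATALOG_COLUMNS,
    FoodCatalog,
    catalog_from_frame,
)
from .ghge_db import GHGETable, build_ghge_table

# --------------------------------------------------------------------------
# Per-subcategory base data (per 100 g composition; GHGE in kg CO2e per kg).
# Columns: energy kcal, protein g, fat g, sfa g, pufa g, carb g, sugar g,
# cholesterol mg, fiber g, calcium mg, iron mg, zinc mg, b12 ug, alcohol g.
# --------------------------------------------------------------------------

_BASE_COMPOSITION: dict[int, tuple[float, ...]] = {
    1: (270, 9, 1.5, 0.3, 0.6, 55, 2, 0, 3.5, 20, 1.0, 1.0, 0, 0),
    2: (250, 9, 8, 3, 1.5, 33, 3, 10, 2.0, 150, 1.0, 1.2, 0.3, 0),
    3: (370, 8, 3, 0.6, 1.2, 80, 20, 0, 7, 30, 8.0, 2.0, 1.0, 0),
    4: (280, 11, 7, 3, 0.8, 42, 2, 30, 2, 80, 1.2, 1.5, 0.3, 0),
    5: (350, 12, 1.5, 0.3, 0.6, 72, 3, 0, 3, 20, 1.3, 1.5, 0, 0),
    6: (360, 7, 0.6, 0.15, 0.2, 80, 0.2, 0, 1.5, 10, 0.5, 1.3, 0, 0),
    7: (450, 7, 15, 7, 1.5, 70, 25, 20, 3, 30, 1.5, 1.0, 0.1, 0),
    8: (400, 6, 18, 8, 2, 55, 30, 60, 2, 50, 1.2, 0.8, 0.2, 0),
    9: (420, 9, 20, 8, 2.5, 50, 3, 10, 2.5, 60, 1.2, 1.0, 0.1, 0),
    10: (100, 7.5, 0.6, 0.1, 0.3, 14, 1.5, 0, 7.5, 45, 2.2, 1.2, 0, 0),
    11: (25, 1.5, 0.3, 0.05, 0.15, 4, 2.5, 0, 2.5, 40, 0.9, 0.4, 0, 0),
    12: (35, 1.2, 0.2, 0.04, 0.1, 7, 4, 0, 2.2, 35, 0.5, 0.3, 0, 0),
    13: (60, 2, 2.5, 0.4, 1.2, 7, 3.5, 0, 2.8, 40, 1.0, 0.5, 0, 0),
    14: (60, 3, 1.5, 0.3, 0.6, 10, 1, 0, 8, 200, 5.0, 1.0, 0, 0),
    15: (85, 2, 0.1, 0.03, 0.05, 19, 0.8, 0, 1.8, 10, 0.6, 0.4, 0, 0),
    16: (530, 6, 33, 12, 8, 50, 0.5, 0, 4.5, 30, 1.5, 1.0, 0, 0),
    17: (50, 0.7, 0.2, 0.04, 0.1, 12, 9, 0, 1.2, 15, 0.3, 0.1, 0, 0),
    18: (65, 1, 0.3, 0.1, 0.1, 15, 12, 0, 2.2, 12, 0.4, 0.2, 0, 0),
    19: (600, 15, 55, 6, 20, 12, 4, 0, 7, 100, 3.0, 3.0, 0, 0),
    20: (80, 0.4, 0.1, 0.02, 0.04, 19, 17, 0, 1.2, 10, 0.3, 0.1, 0, 0),
    21: (180, 21, 10, 4, 0.5, 0, 0, 70, 0, 10, 2.2, 4.5, 2.0, 0),
    22: (220, 19, 16, 6, 1.5, 0, 0, 70, 0, 8, 1.0, 2.5, 0.8, 0),
    23: (150, 21, 7, 2, 1.5, 0, 0, 75, 0, 12, 0.8, 1.5, 0.4, 0),
    24: (300, 16, 26, 10, 2.5, 1, 0.5, 70, 0, 15, 1.2, 2.2, 0.9, 0),
    25: (160, 21, 8, 3, 0.6, 0, 0, 75, 0, 10, 3.5, 3.8, 2.5, 0),
    26: (180, 17, 9, 1.2, 4.5, 8, 1, 0, 4, 100, 2.5, 1.5, 0, 0),
    27: (130, 19, 5, 1.7, 0.8, 2, 0, 300, 0, 10, 7.5, 4.0, 25, 0),
    28: (85, 16, 1.5, 0.3, 0.5, 2, 0, 120, 0, 50, 3.0, 2.5, 8, 0),
    29: (120, 19, 5, 1.2, 1.5, 0, 0, 60, 0, 25, 1.0, 0.8, 3, 0),
    30: (190, 23, 10, 2, 3, 0, 0, 60, 0, 15, 1.2, 1.0, 4, 0),
    31: (55, 3.3, 2.5, 1.6, 0.1, 5, 5, 10, 0, 120, 0.05, 0.4, 0.4, 0),
    32: (70, 4, 3, 1.9, 0.1, 6, 6, 10, 0, 140, 0.1, 0.5, 0.3, 0),
    33: (140, 4, 5, 3, 0.2, 20, 18, 20, 0.3, 120, 0.3, 0.5, 0.3, 0),
    34: (370, 25, 29, 18, 1, 1.5, 0.5, 90, 0, 800, 0.4, 3.5, 1.5, 0),
    35: (884, 0, 100, 14, 10, 0, 0, 0, 0, 0, 0, 0, 0, 0),
    36: (884, 0, 100, 11, 60, 0, 0, 0, 0, 0, 0, 0, 0, 0),
    37: (750, 0.7, 83, 52, 2.5, 0.6, 0.6, 230, 0, 15, 0, 0.1, 0.2, 0),
    38: (700, 0.5, 78, 30, 15, 1, 0.5, 80, 0, 5, 0, 0.1, 0, 0),
    39: (210, 3.5, 11, 7, 0.4, 25, 21, 30, 0.5, 110, 0.2, 0.4, 0.3, 0),
    40: (540, 7, 31, 19, 1, 57, 50, 10, 7, 60, 2.4, 1.5, 0.3, 0),
    41: (390, 0, 0, 0, 0, 99, 99, 0, 0, 2, 0.1, 0, 0, 0),
    42: (280, 0.5, 0.5, 0.2, 0.1, 68, 60, 0, 1, 10, 0.3, 0.1, 0, 0),
    43: (350, 20, 14, 8, 0.4, 20, 1, 0, 30, 130, 14, 7, 0, 0),
    44: (20, 0, 0, 0, 0, 5, 0, 0, 0, 0, 0, 0, 0, 0),
    45: (400, 20, 12, 3, 3, 50, 30, 5, 5, 300, 5, 4, 1, 0),
    46: (143, 12.5, 9.5, 3.1, 1.9, 0.7, 0.3, 370, 0, 55, 1.8, 1.3, 1.1, 0),
    47: (0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0),
    48: (0, 0, 0, 0, 0, 0, 0, 0, 0, 15, 0, 0, 0, 0),
    49: (2, 0.2, 0, 0, 0, 0.3, 0, 0, 0, 5, 0.05, 0.05, 0, 0),
    50: (45, 0.4, 0.1, 0.02, 0.03, 10.5, 10, 0, 0.2, 10, 0.2, 0.05, 0, 0),
    51: (40, 0, 0, 0, 0, 10, 10, 0, 0, 5, 0, 0, 0, 0),
    52: (150, 5, 8, 2.5, 2, 15, 5, 10, 1.5, 40, 1.0, 0.8, 0.2, 0),
    53: (75, 0.1, 0, 0, 0, 2, 0.5, 0, 0, 8, 0.5, 0.1, 0, 10.5),
    54: (250, 0, 0, 0, 0, 10, 8, 0, 0, 5, 0.1, 0, 0, 30),
    55: (43, 0.5, 0, 0, 0, 3.5, 0.2, 0, 0, 4, 0.02, 0.05, 0.05, 4.7),
}

_BASE_GHGE_PER_KG: dict[int, float] = {
    1: 1.1, 2: 2.2, 3: 1.6, 4: 2.5, 5: 1.4, 6: 2.9, 7: 2.2, 8: 2.8, 9: 2.5,
    10: 0.9, 11: 1.0, 12: 0.6, 13: 1.6, 14: 1.2, 15: 0.5, 16: 2.5, 17: 0.6,
    18: 1.3, 19: 2.0, 20: 1.4, 21: 16.0, 22: 5.5, 23: 3.8, 24: 7.0, 25: 13.0,
    26: 2.5, 27: 6.0, 28: 7.0, 29: 4.5, 30: 5.0, 31: 1.3, 32: 1.8, 33: 2.5,
    34: 8.5, 35: 3.5, 36: 2.8, 37: 9.0, 38: 4.0, 39: 2.8, 40: 4.5, 41: 1.0,
    42: 2.0, 43: 4.0, 44: 1.0, 45: 3.0, 46: 3.6, 47: 0.02, 48: 0.25, 49: 0.4,
    50: 1.1, 51: 0.5, 52: 2.0, 53: 1.4, 54: 2.5, 55: 0.9,
}

#: Anchor diet (g/day) for the planted-diet search, male scale.
_ANCHOR_DIET_M: dict[int, float] = {
    1: 150, 2: 30, 3: 3, 4: 8, 5: 80, 6: 15, 7: 15, 8: 20, 9: 6,
    10: 25, 11: 220, 12: 35, 13: 45, 14: 4, 15: 50, 16: 0, 17: 220,
    18: 20, 19: 8, 20: 0, 21: 45, 22: 15, 23: 25, 24: 35, 25: 6,
    26: 0, 27: 0, 28: 15, 29: 25, 30: 8, 31: 100, 32: 20, 33: 0,
    34: 45, 35: 30, 36: 4, 37: 5, 38: 1, 39: 10, 40: 3, 41: 18,
    42: 4, 43: 0, 44: 0, 45: 0, 46: 25, 47: 180, 48: 480, 49: 140,
    50: 30, 51: 40, 52: 3, 53: 100, 54: 4, 55: 55,
}

#: Subcategories that the planted diet must avoid entirely; their observed
#: 90th percentile is engineered to be zero, exercising fixed-at-zero boxes.
VERY_RARE_SUBCATS = frozenset({16, 20, 26, 27, 33, 43, 44, 45})

#: High-participation staples (5th percentile ends up positive).
_STAPLE_SUBCATS = frozenset({1, 5, 11, 17, 31, 35, 47, 48, 49})


@dataclass(frozen=True)
class Scenario:
    """Named, fully-seeded synthetic-data configuration."""

    name: str
    seed: int = 0
    n_subjects: int = 2098
    n_items: int = 1119
    n_infant_formula: int = 198
    n_supplement: int = 0
    n_days: int = 3
    planted_fraction: float = 0.6
    participation_default: float = 0.45
    lognorm_sigma_day: float = 0.25
    lognorm_sigma_casual: float = 0.45
    iron_scale: float = 1.0
    ghge_scale: Mapping[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_items < registry.N_SUBCATEGORIES:
            raise ValidationError("n_items must cover the 55 subcategories")
        if not 0 < self.planted_fraction <= 1:
            raise ValidationError("planted_fraction must be in (0, 1]")


_PRESETS: dict[str, dict] = {
    "default_feasible": {},
    "iron_scarce": {"iron_scale": 0.85},
    # Red-meat emissions scaled up, fruit & vegetables made markedly
    # cheaper, so the optimum pushes red meat to its policy lower bound
    # and fruit & vegetables to the 500 g/day upper bound.
    "red_meat_dominated": {
        "ghge_scale": {21: 1.5, 22: 1.5, 25: 1.5, 11: 0.05, 12: 0.05, 13: 0.05,
                       17: 0.05, 18: 0.05, 20: 0.05, 6: 0.4},
    },
    "minimal_toy": {"n_subjects": 30, "n_items": 55, "n_infant_formula": 0,
                    "n_supplement": 0},
}


def scenario(name: str, seed: int = 0, **overrides) -> Scenario:
    """Build a named preset scenario, optionally overriding dials."""
    if name not in _PRESETS:
        raise ValidationError(
            f"unknown scenario {name!r}; choose from {sorted(_PRESETS)}"
        )
    params = dict(_PRESETS[name])
    params.update(overrides)
    return Scenario(name=name, seed=seed, **params)


def base_content_per_100g(iron_scale: float = 1.0) -> pd.DataFrame:
    """Subcategory composition table (per 100 g) used by the generator."""
    rows = np.zeros((registry.N_SUBCATEGORIES, len(NUTRIENT_FIELDS)))
    for k, vals in _BASE_COMPOSITION.items():
        (energy, protein, fat, sfa, pufa, carb, sugar, chol, fiber, ca, fe,
         zn, b12, alc) = vals
        free = sugar if k in registry.FREE_SUGAR_SUBCATS else 0.0
        intrinsic = sugar - free
        rows[k - 1] = [energy, protein, fat, sfa, pufa, carb, free, intrinsic,
                       chol, fiber, ca, fe * iron_scale, zn, b12, alc]
    return pd.DataFrame(
        rows,
        index=np.arange(1, registry.N_SUBCATEGORIES + 1),
        columns=list(NUTRIENT_FIELDS),
    )


def _flags_for_subcat(k: int) -> str:
    tokens = []
    if k in registry.RED_MEAT_SUBCATS:
        tokens.append("red_meat")
    if k in registry.PROCESSED_MEAT_SUBCATS:
        tokens.append("processed_meat")
    if k in registry.ALCOHOL_SUBCATS:
        tokens.append("alcoholic")
    if k in registry.FRUIT_VEG_SUBCATS:
        tokens.append("fruit_veg")
    if k in registry.PULSE_SUBCATS:
        tokens.append("pulse")
    if k in registry.FISH_SUBCATS:
        tokens.append("fish")
    if k in registry.FREE_SUGAR_SUBCATS:
        tokens.append("free_sugar_class")
    return ";".join(tokens)


def generate_catalog(scn: Scenario) -> FoodCatalog:
    """Catalog with ``n_items`` items spread over all 55 subcategories.

    Items within a subcategory share the subcategory's base composition,
    so survey-weighted content equals the base table exactly and planted
    feasibility carries over to the assembled problem. The configured
    counts of infant-formula and supplement items are appended at the end.
    """
    rng = np.random.default_rng(scn.seed)
    content = base_content_per_100g(scn.iron_scale)
    n_regular = scn.n_items - scn.n_infant_formula - scn.n_supplement
    if n_regular < registry.N_SUBCATEGORIES:
        raise ValidationError("not enough regular items to cover all subcategories")

    # one item per subcategory, remainder distributed at random
    counts = np.ones(registry.N_SUBCATEGORIES, dtype=int)
    extra = rng.choice(
        registry.N_SUBCATEGORIES, size=n_regular - registry.N_SUBCATEGORIES
    )
    np.add.at(counts, extra, 1)

    rows = []
    item_id = itertools.count(1)
    for k in range(1, registry.N_SUBCATEGORIES + 1):
        comp = content.loc[k]
        for j in range(counts[k - 1]):
            iid = next(item_id)
            rows.append(
                {
                    "item_id": iid,
                    "name": f"{registry.SUBCATEGORY_LABELS[k]} #{j + 1}",
                    "category_id": registry.category_of(k),
                    "subcategory_id": k,
                    "energy_kcal": comp["energy_kcal"],
                    "protein_g": comp["protein_g"],
                    "fat_g": comp["total_fat_g"],
                    "sfa_g": comp["sfa_g"],
                    "pufa_g": comp["pufa_g"],
                    "carb_g": comp["carb_g"],
                    "sugar_g": comp["free_sugar_g"] + comp["intrinsic_sugar_g"],
                    "cholesterol_mg": comp["cholesterol_mg"],
                    "fiber_g": comp["fiber_g"],
                    "calcium_mg": comp["calcium_mg"],
                    "iron_mg": comp["iron_mg"],
                    "zinc_mg": comp["zinc_mg"],
                    "vitb12_ug": comp["vitamin_b12_ug"],
                    "alcohol_g": comp["alcohol_g"],
                    "flags": _flags_for_subcat(k),
                }
            )
    for n, flag in ((scn.n_infant_formula, "infant_formula"),
                    (scn.n_supplement, "supplement")):
        for j in range(n):
            iid = next(item_id)
            rows.append(
                {
                    "item_id": iid,
                    "name": f"{flag} #{j + 1}",
                    "category_id": 8,
                    "subcategory_id": 31,
                    "energy_kcal": 500.0, "protein_g": 12.0, "fat_g": 25.0,
                    "sfa_g": 11.0, "pufa_g": 5.0, "carb_g": 57.0,
                    "sugar_g": 40.0, "cholesterol_mg": 10.0, "fiber_g": 0.0,
                    "calcium_mg": 400.0, "iron_mg": 5.0, "zinc_mg": 3.0,
                    "vitb12_ug": 1.5, "alcohol_g": 0.0,
                    "flags": flag,
                }
            )
    df = pd.DataFrame(rows, columns=list(CATALOG_COLUMNS))
    return catalog_from_frame(df)


def generate_ghge_points(
    catalog: FoodCatalog, scn: Scenario, n_indicators: int = 102
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Literature-style data points plus the indicator->subcategory map.

    Every subcategory gets at least one indicator; point counts per
    indicator span 1-6 so all three uncertainty-range rules are exercised.
    """
    rng = np.random.default_rng(scn.seed + 1)
    n_extra = max(0, n_indicators - registry.N_SUBCATEGORIES)
    extra_subs = rng.choice(registry.N_SUBCATEGORIES, size=n_extra) + 1

    per_sub = {k: 1 for k in range(1, registry.N_SUBCATEGORIES + 1)}
    for k in extra_subs:
        per_sub[int(k)] += 1

    points_rows, map_rows = [], []
    ind_id = itertools.count(1)
    # cycle point counts deterministically so 1..6 all occur
    count_cycle = itertools.cycle([1, 2, 3, 4, 1, 5, 2, 1, 6, 3])
    for k in range(1, registry.N_SUBCATEGORIES + 1):
        base = _BASE_GHGE_PER_KG[k] * scn.ghge_scale.get(k, 1.0)
        for _ in range(per_sub[k]):
            iid = next(ind_id)
            map_rows.append({"indicator_id": iid, "subcategory_id": k})
            n_pts = next(count_cycle)
            center = base * rng.lognormal(0.0, 0.10)
            values = center * rng.lognormal(0.0, 0.15, size=n_pts)
            reliable = bool(rng.random() < 0.3)
            for v, src in zip(values, itertools.count(1)):
                points_rows.append(
                    {
                        "indicator_id": iid,
                        "value_kgco2e_per_kg": round(float(v), 4),
                        "national_reliable": reliable,
                        "source": f"synthetic-study-{iid}-{src}",
                    }
                )
    return pd.DataFrame(points_rows), pd.DataFrame(map_rows)


def _planted_diet(scn: Scenario, sex: str, config: dict) -> np.ndarray:
    """Target diet satisfying the sex's nutritional + healthy constraints.

    Found as the L1-closest diet to the anchor subject to those
    constraints, with very-rare subcategories pinned at zero. Raises if no
    such diet exists for the generated compositions.
    """
    n = registry.N_SUBCATEGORIES
    content = base_content_per_100g(scn.iron_scale)
    factors = EnergyFactors(**config.get("energy_factors", {}))
    bounds_cfg = config["sexes"][sex]["nutritional"]
    cons = nutrient_constraints(bounds_cfg, content, factors)
    cons += healthy_constraints(None, config.get("policy"))

    scale = 1.0 if sex == "M" else 0.82
    anchor = np.zeros(n)
    for k, v in _ANCHOR_DIET_M.items():
        # fruit & vegetable targets are sex-independent (400-500 g/day for
        # everyone), so their anchor is not scaled down for females
        s = 1.0 if k in registry.FRUIT_VEG_SUBCATS else scale
        anchor[k - 1] = v * s
    # healthy policy forbids these entirely; anchor must agree
    for k in registry.PROCESSED_MEAT_SUBCATS | registry.ALCOHOL_SUBCATS:
        anchor[k - 1] = 0.0

    caps = np.where(anchor > 0, 3.0 * anchor + 50.0, 0.0)
    for k in VERY_RARE_SUBCATS:
        caps[k - 1] = 0.0

    prob = LPProblem(
        objective=np.zeros(n),
        constraints=cons,
        sex=sex,
        content=content,
        factors=factors,
    )
    from .optimizer import _matrices  # solver-internal matrix builder

    A_ub, b_ub, A_eq, b_eq = _matrices(prob)

    # variables [x, t]; minimize sum t with t >= |x - anchor|
    eye = np.eye(n)
    dev_rows = np.block([[eye, -eye], [-eye, -eye]])
    dev_rhs = np.concatenate([anchor, -anchor])
    A_ub_full = dev_rows if A_ub is None else np.vstack(
        [np.hstack([A_ub, np.zeros((A_ub.shape[0], n))]), dev_rows]
    )
    b_ub_full = dev_rhs if b_ub is None else np.concatenate([b_ub, dev_rhs])
    A_eq_full = None if A_eq is None else np.hstack(
        [A_eq, np.zeros((A_eq.shape[0], n))]
    )
    c = np.concatenate([np.zeros(n), np.ones(n)])
    var_bounds = [(0.0, float(caps[i])) for i in range(n)] + [(0.0, None)] * n
    res = linprog(
        c, A_ub=A_ub_full, b_ub=b_ub_full, A_eq=A_eq_full, b_eq=b_eq,
        bounds=var_bounds, method="highs-ds",
    )
    if res.status != 0:
        raise DietOptError(
            f"no planted diet exists for sex {sex} under scenario {scn.name!r}: "
            f"{res.message}"
        )
    x = np.asarray(res.x[:n], dtype=float)
    x[x < 1e-9] = 0.0
    return x


def _participation(scn: Scenario) -> np.ndarray:
    pi = np.full(registry.N_SUBCATEGORIES, scn.participation_default)
    for k in _STAPLE_SUBCATS:
        pi[k - 1] = 0.95
    for k in VERY_RARE_SUBCATS:
        pi[k - 1] = 0.01
    return pi


def generate_survey(
    catalog: FoodCatalog, scn: Scenario, config: dict | None = None
) -> tuple[pd.DataFrame, dict[str, np.ndarray]]:
    """Zero-inflated log-normal 3-day diaries with a planted sub-population.

    Returns the diary table and the per-sex planted diets. A
    ``planted_fraction`` share of subjects eats a log-normal perturbation
    of the planted diet; the rest eat zero-inflated log-normal amounts
    around the anchor, giving many subcategories a zero 5th percentile and
    the very rare ones a zero 90th percentile.
    """
    config = config or default_config()
    rng = np.random.default_rng(scn.seed + 2)
    n, nsub = scn.n_subjects, registry.N_SUBCATEGORIES

    planted = {sex: _planted_diet(scn, sex, config) for sex in ("M", "F")}
    anchor = {
        "M": np.array([_ANCHOR_DIET_M.get(k, 0.0) for k in range(1, nsub + 1)]),
    }
    anchor["F"] = anchor["M"] * 0.82

    sexes = np.where(np.arange(n) % 2 == 0, "M", "F")
    ages = rng.integers(18, 61, size=n)
    is_planted = rng.random(n) < scn.planted_fraction
    pi = _participation(scn)

    target = np.zeros((n, nsub))
    for sex in ("M", "F"):
        target[(sexes == sex) & is_planted] = planted[sex]
    casual_level = rng.lognormal(-0.25, scn.lognorm_sigma_casual, size=(n, nsub))
    participates = rng.random((n, nsub)) < pi
    for sex in ("M", "F"):
        mask = (sexes == sex) & ~is_planted
        target[mask] = anchor[sex] * casual_level[mask] * participates[mask]

    sigma = scn.lognorm_sigma_day
    day_noise = rng.lognormal(-sigma**2 / 2, sigma, size=(n, scn.n_days, nsub))
    amounts = target[:, None, :] * day_noise  # (n, days, 55)
    amounts = np.round(amounts, 1)

    # deterministic item choice among the subcategory's analysis items
    items_by_sub = {
        k: np.array(
            [it.item_id for it in catalog.subcategory_items(k) if not it.excluded]
        )
        for k in range(1, nsub + 1)
    }
    item_pick = rng.random((n, scn.n_days, nsub))

    sid, did, kid = np.nonzero(amounts)
    item_ids = np.empty(len(sid), dtype=int)
    for idx, (d_, k_) in enumerate(zip(did, kid)):
        pool = items_by_sub[int(k_) + 1]
        item_ids[idx] = pool[int(item_pick[sid[idx], d_, k_] * len(pool))]

    diary = pd.DataFrame(
        {
            "subject_id": sid + 1,
            "sex": sexes[sid],
            "age": ages[sid],
            "day": did + 1,
            "item_id": item_ids,
            "amount_g": amounts[sid, did, kid],
        }
    )
    return diary, planted


@dataclass
class SyntheticDataset:
    """Everything one scenario generates, ready to feed the pipeline."""

    scenario: Scenario
    catalog: FoodCatalog
    points: pd.DataFrame
    mapping: pd.DataFrame
    diary: pd.DataFrame
    planted: dict[str, np.ndarray]

    def ghge_table(self) -> GHGETable:
        return build_ghge_table(self.points, self.mapping)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.catalog.to_frame().to_csv(outdir / "catalog.csv", index=False)
        self.points.to_csv(outdir / "ghge_points.csv", index=False)
        self.mapping.to_csv(outdir / "mapping.csv", index=False)
        self.diary.to_csv(outdir / "diary.csv", index=False)
        manifest = {
            "scenario": self.scenario.name,
            "seed": self.scenario.seed,
            "n_subjects": self.scenario.n_subjects,
            "n_items": self.scenario.n_items,
            "planted_fraction": self.scenario.planted_fraction,
            "iron_scale": self.scenario.iron_scale,
        }
        pd.Series(manifest).to_json(outdir / "manifest.json", indent=2)


def generate_dataset(scn: Scenario, config: dict | None = None) -> SyntheticDataset:
    catalog = generate_catalog(scn)
    points, mapping = generate_ghge_points(catalog, scn)
    diary, planted = generate_survey(catalog, scn, config)
    return SyntheticDataset(
        scenario=scn,
        catalog=catalog,
        points=points,
        mapping=mapping,
        diary=diary,
        planted=planted,
    )


# --------------------------------------------------------------------------
# Toy problems and the exhaustive vertex-enumeration oracle
# --------------------------------------------------------------------------


def enumerate_vertex_optimum(
    problem: LPProblem,
    objective: np.ndarray | None = None,
    sense: str = "min",
    tol: float = 1e-9,
) -> tuple[float, np.ndarray] | None:
    """Brute-force LP solve by enumerating constraint-intersection vertices.

    Intended for fixtures with few variables; independent of the simplex
    backend. Returns (objective, x) or None when no feasible vertex exists
    (for a bounded feasible LP the optimum is attained at a vertex).
    """
    n = problem.n_vars
    c = problem.objective if objective is None else np.asarray(objective, float)
    planes: list[tuple[np.ndarray, float]] = []
    for con in problem.constraints:
        if con.lb is not None:
            planes.append((con.coeffs, con.lb))
        if con.ub is not None and con.ub != con.lb:
            planes.append((con.coeffs, con.ub))
    for i in range(n):
        e = np.zeros(n)
        e[i] = 1.0
        planes.append((e, 0.0))

    best: tuple[float, np.ndarray] | None = None
    for combo in itertools.combinations(range(len(planes)), n):
        A = np.stack([planes[i][0] for i in combo])
        b = np.array([planes[i][1] for i in combo])
        if abs(np.linalg.det(A)) < 1e-12:
            continue
        x = np.linalg.solve(A, b)
        if (x < -tol).any():
            continue
        if not all(con.satisfied(x, tol=tol) for con in problem.constraints):
            continue
        val = float(c @ x)
        if best is None or (val < best[0] if sense == "min" else val > best[0]):
            best = (val, np.clip(x, 0.0, None))
    return best


def make_toy_problem() -> tuple[LPProblem, tuple[float, np.ndarray]]:
    """Hand-auditable 3-variable problem plus its enumeration-oracle optimum.

    minimize 3 x1 + x2 + 2 x3  subject to
        0.5 <= x1 <= 4,  6 <= x1+x2+x3 <= 10,  2 x1 + x2 >= 5,  x3 <= 3.
    """
    cons = [
        Constraint("box:x1", "acceptability", np.array([1.0, 0, 0]), 0.5, 4.0),
        Constraint("sum", "acceptability", np.array([1.0, 1, 1]), 6.0, 10.0),
        Constraint("mix", "nutritional", np.array([2.0, 1, 0]), 5.0, None),
        Constraint("x3cap", "healthy", np.array([0.0, 0, 1]), None, 3.0),
    ]
    problem = LPProblem(
        objective=np.array([3.0, 1.0, 2.0]), constraints=cons, n_vars=3
    )
    oracle = enumerate_vertex_optimum(problem)
    assert oracle is not None
    return problem, oracle


__all__ = [
    "Scenario",
    "scenario",
    "SyntheticDataset",
    "VERY_RARE_SUBCATS",
    "base_content_per_100g",
    "generate_catalog",
    "generate_ghge_points",
    "generate_survey",
    "generate_dataset",
    "enumerate_vertex_optimum",
    "make_toy_problem",
]
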