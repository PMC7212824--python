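"""Domain types for foods and nutrient compositions, plus catalog I/O.

A :class:`FoodCatalog` holds item-level compositions per 100 g edible
portion together with classification flags. The optimization itself works
on subcategory aggregates; the catalog is the item-level source feeding
the survey processing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

from . import registry
from .errors import SchemaError, ValidationError

logger = logging.getLogger(__name__)

_EPS = 1e-9

#: Canonical nutrient field order used everywhere a vector is needed.
NUTRIENT_FIELDS: tuple[str, ...] = (
    "energy_kcal",
    "protein_g",
    "total_fat_g",
    "sfa_g",
    "pufa_g",
    "carb_g",
    "free_sugar_g",
    "intrinsic_sugar_g",
    "cholesterol_mg",
    "fiber_g",
    "calcium_mg",
    "iron_mg",
    "zinc_mg",
    "vitamin_b12_ug",
    "alcohol_g",
)


@dataclass(frozen=True)
class NutrientVector:
    """Nutrient composition per 100 g edible portion."""

    energy_kcal: float = 0.0
    protein_g: float = 0.0
    total_fat_g: float = 0.0
    sfa_g: float = 0.0
    pufa_g: float = 0.0
    carb_g: float = 0.0
    free_sugar_g: float = 0.0
    intrinsic_sugar_g: float = 0.0
    cholesterol_mg: float = 0.0
    fiber_g: float = 0.0
    calcium_mg: float = 0.0
    iron_mg: float = 0.0
    zinc_mg: float = 0.0
    vitamin_b12_ug: float = 0.0
    alcohol_g: float = 0.0

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v) or v < 0:
                raise ValidationError(f"{f.name} must be finite and >= 0, got {v}")
        if self.sfa_g + self.pufa_g > self.total_fat_g + _EPS:
            raise ValidationError(
                f"sfa + pufa ({self.sfa_g + self.pufa_g}) exceeds total fat "
                f"({self.total_fat_g})"
            )
        if self.free_sugar_g + self.intrinsic_sugar_g > self.carb_g + _EPS:
            raise ValidationError(
                f"sugars ({self.free_sugar_g + self.intrinsic_sugar_g}) exceed "
                f"carbohydrate ({self.carb_g})"
            )

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in NUTRIENT_FIELDS], dtype=float)

    @classmethod
    def from_array(cls, values: np.ndarray) -> "NutrientVector":
        return cls(**dict(zip(NUTRIENT_FIELDS, map(float, values))))


#: Flag tokens accepted in the catalog CSV "flags" column.
FLAG_NAMES: tuple[str, ...] = (
    "red_meat",
    "processed_meat",
    "alcoholic",
    "fruit_veg",
    "pulse",
    "fish",
    "infant_formula",
    "supplement",
    "free_sugar_class",
)


@dataclass(frozen=True)
class ItemFlags:
    red_meat: bool = False
    processed_meat: bool = False
    alcoholic: bool = False
    fruit_veg: bool = False
    pulse: bool = False
    fish: bool = False
    infant_formula: bool = False
    supplement: bool = False
    free_sugar_class: bool = False

    def __post_init__(self) -> None:
        meaty = self.red_meat or self.processed_meat
        if meaty and (self.fruit_veg or self.pulse):
            raise ValidationError("an item cannot be both meat and fruit/vegetable")

    @classmethod
    def from_tokens(cls, tokens: str) -> "ItemFlags":
        names = [t.strip() for t in str(tokens).split(";") if t.strip()]
        unknown = set(names) - set(FLAG_NAMES)
        if unknown:
            raise SchemaError(f"unknown flag tokens: {sorted(unknown)}")
        return cls(**{n: True for n in names})

    def to_tokens(self) -> str:
        return ";".join(n for n in FLAG_NAMES if getattr(self, n))


def classify_sugars(total_sugar: float, flags: ItemFlags) -> tuple[float, float]:
    """Partition total sugar into (free, intrinsic) grams per 100 g.

    Items of the free-sugar classes (sweet bakery, confectionery,
    sweetened drinks, juices, alcoholic beverages, ...) carry only free
    sugars; everything else — in particular fresh fruit and vegetables,
    milk and plain yogurt — carries only intrinsic sugars. The partition
    always sums exactly to ``total_sugar``.
    """
    if not np.isfinite(total_sugar) or total_sugar < 0:
        raise ValidationError(f"total_sugar must be finite and >= 0, got {total_sugar}")
    if flags.free_sugar_class:
        return float(total_sugar), 0.0
    return 0.0, float(total_sugar)


@dataclass(frozen=True)
class FoodItem:
    item_id: int
    name: str
    category_id: int
    subcategory_id: int
    composition: NutrientVector
    flags: ItemFlags = field(default_factory=ItemFlags)

    def __post_init__(self) -> None:
        expected = registry.SUBCATEGORY_TO_CATEGORY.get(self.subcategory_id)
        if expected is None:
            raise ValidationError(
                f"item {self.item_id}: unknown subcategory {self.subcategory_id}"
            )
        if expected != self.category_id:
            raise ValidationError(
                f"item {self.item_id}: subcategory {self.subcategory_id} belongs to "
                f"category {expected}, not {self.category_id}"
            )

    @property
    def excluded(self) -> bool:
        """True for items excluded from analysis (infant formula, supplements)."""
        return self.flags.infant_formula or self.flags.supplement


#: CSV schema of the catalog file, in column order.
CATALOG_COLUMNS: tuple[str, ...] = (
    "item_id",
    "name",
    "category_id",
    "subcategory_id",
    "energy_kcal",
    "protein_g",
    "fat_g",
    "sfa_g",
    "pufa_g",
    "carb_g",
    "sugar_g",
    "cholesterol_mg",
    "fiber_g",
    "calcium_mg",
    "iron_mg",
    "zinc_mg",
    "vitb12_ug",
    "alcohol_g",
    "flags",
)

_NUMERIC_COLUMNS = CATALOG_COLUMNS[4:18]


class FoodCatalog:
    """Ordered collection of :class:`FoodItem` plus label registries."""

    def __init__(
        self,
        items: Iterable[FoodItem],
        category_labels: dict[int, str] | None = None,
        subcategory_labels: dict[int, str] | None = None,
    ):
        self.items: list[FoodItem] = list(items)
        self.category_labels = dict(category_labels or registry.CATEGORY_LABELS)
        self.subcategory_labels = dict(
            subcategory_labels or registry.SUBCATEGORY_LABELS
        )
        seen: set[int] = set()
        for it in self.items:
            if it.item_id in seen:
                raise ValidationError(f"duplicate item_id {it.item_id}")
            seen.add(it.item_id)
        missing = set(range(1, registry.N_SUBCATEGORIES + 1)) - set(
            self.subcategory_labels
        )
        if missing:
            raise ValidationError(f"subcategory registry incomplete: {sorted(missing)}")
        self._by_id = {it.item_id: it for it in self.items}

    def __len__(self) -> int:
        return len(self.items)

    def __iter__(self) -> Iterator[FoodItem]:
        return iter(self.items)

    def get(self, item_id: int) -> FoodItem:
        try:
            return self._by_id[item_id]
        except KeyError:
            raise KeyError(f"unknown item_id {item_id}") from None

    def __contains__(self, item_id: int) -> bool:
        return item_id in self._by_id

    def subcategory_items(self, subcategory_id: int) -> list[FoodItem]:
        return [it for it in self.items if it.subcategory_id == subcategory_id]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for it in self.items:
            c = it.composition
            rows.append(
                {
                    "item_id": it.item_id,
                    "name": it.name,
                    "category_id": it.category_id,
                    "subcategory_id": it.subcategory_id,
                    "energy_kcal": c.energy_kcal,
                    "protein_g": c.protein_g,
                    "fat_g": c.total_fat_g,
                    "sfa_g": c.sfa_g,
                    "pufa_g": c.pufa_g,
                    "carb_g": c.carb_g,
                    "sugar_g": c.free_sugar_g + c.intrinsic_sugar_g,
                    "cholesterol_mg": c.cholesterol_mg,
                    "fiber_g": c.fiber_g,
                    "calcium_mg": c.calcium_mg,
                    "iron_mg": c.iron_mg,
                    "zinc_mg": c.zinc_mg,
                    "vitb12_ug": c.vitamin_b12_ug,
                    "alcohol_g": c.alcohol_g,
                    "flags": it.flags.to_tokens(),
                }
            )
        return pd.DataFrame(rows, columns=list(CATALOG_COLUMNS))


def _item_from_row(row: pd.Series) -> FoodItem:
    flags = ItemFlags.from_tokens(row["flags"] if pd.notna(row["flags"]) else "")
    free, intrinsic = classify_sugars(float(row["sugar_g"]), flags)
    comp = NutrientVector(
        energy_kcal=float(row["energy_kcal"]),
        protein_g=float(row["protein_g"]),
        total_fat_g=float(row["fat_g"]),
        sfa_g=float(row["sfa_g"]),
        pufa_g=float(row["pufa_g"]),
        carb_g=float(row["carb_g"]),
        free_sugar_g=free,
        intrinsic_sugar_g=intrinsic,
        cholesterol_mg=float(row["cholesterol_mg"]),
        fiber_g=float(row["fiber_g"]),
        calcium_mg=float(row["calcium_mg"]),
        iron_mg=float(row["iron_mg"]),
        zinc_mg=float(row["zinc_mg"]),
        vitamin_b12_ug=float(row["vitb12_ug"]),
        alcohol_g=float(row["alcohol_g"]),
    )
    return FoodItem(
        item_id=int(row["item_id"]),
        name=str(row["name"]),
        category_id=int(row["category_id"]),
        subcategory_id=int(row["subcategory_id"]),
        composition=comp,
        flags=flags,
    )


def catalog_from_frame(df: pd.DataFrame) -> FoodCatalog:
    missing = set(CATALOG_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"catalog missing columns: {sorted(missing)}")
    for col in _NUMERIC_COLUMNS:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals.isna()]
        if len(bad):
            raise SchemaError(f"non-numeric {col!r} at row {bad[0]}")
        df = df.assign(**{col: vals})
    dup = df["item_id"][df["item_id"].duplicated()]
    if len(dup):
        raise SchemaError(f"duplicate item_id {int(dup.iloc[0])}")
    items = []
    for idx, row in df.iterrows():
        try:
            items.append(_item_from_row(row))
        except (ValidationError, SchemaError) as exc:
            raise type(exc)(f"row {idx}: {exc}") from exc
    return FoodCatalog(items)


def load_catalog(path: str | Path) -> FoodCatalog:
    """Load a food catalog CSV (see :data:`CATALOG_COLUMNS`)."""
    df = pd.read_csv(path, dtype={"flags": str}, keep_default_na=False,
                     na_values=[""])
    return catalog_from_frame(df)


def write_catalog(catalog: FoodCatalog, path: str | Path) -> None:
    catalog.to_frame().to_csv(path, index=False)


def filter_catalog(catalog: FoodCatalog) -> FoodCatalog:
    """Drop items flagged infant_formula or supplement, preserving order."""
    retained = [it for it in catalog if not it.excluded]
    n_excluded = len(catalog) - len(retained)
    logger.info(
        "catalog filter: retained %d, excluded %d", len(retained), n_excluded
    )
    if not retained:
        logger.warning("catalog filter produced an empty catalog")
    return FoodCatalog(
        retained, catalog.category_labels, catalog.subcategory_labels
    )


__all__ = [
    "NUTRIENT_FIELDS",
    "NutrientVector",
    "ItemFlags",
    "FoodItem",
    "FoodCatalog",
    "CATALOG_COLUMNS",
    "classify_sugars",
    "catalog_from_frame",
    "load_catalog",
    "write_catalog",
    "filter_catalog",
]
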