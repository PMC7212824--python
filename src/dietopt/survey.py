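"""Food-consumption-survey processing.

Turns 3-day diary records into per-subject mean daily intakes over the 55
subcategories, sex-stratified population statistics (mean, 5th and 90th
percentile, non-consumers included), and consumption-weighted nutrient
content per 100 g of each subcategory.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from . import registry
from .errors import SchemaError, ValidationError
from .food_model import NUTRIENT_FIELDS, FoodCatalog

logger = logging.getLogger(__name__)

#: Empirical-CDF-with-averaging percentile definition (SAS PCTLDEF 5 analogue).
DEFAULT_PERCENTILE_METHOD = "averaged_inverted_cdf"

DIARY_COLUMNS = ("subject_id", "sex", "age", "day", "item_id", "amount_g")

_ALL_SUBCATS = np.arange(1, registry.N_SUBCATEGORIES + 1)
_ALL_CATS = np.arange(1, registry.N_CATEGORIES + 1)


def validate_diary(diary: pd.DataFrame) -> pd.DataFrame:
    missing = set(DIARY_COLUMNS) - set(diary.columns)
    if missing:
        raise SchemaError(f"diary missing columns: {sorted(missing)}")
    if (diary["amount_g"] < 0).any():
        raise ValidationError("diary contains negative amounts")
    bad_sex = set(diary["sex"].unique()) - {"M", "F"}
    if bad_sex:
        raise ValidationError(f"unknown sex codes: {sorted(bad_sex)}")
    return diary


def filter_age(diary: pd.DataFrame, lo: int = 18, hi: int = 60) -> pd.DataFrame:
    """Keep subjects aged ``lo``..``hi`` inclusive on both ends."""
    return diary[(diary["age"] >= lo) & (diary["age"] <= hi)]


@dataclass
class SubjectIntake:
    """Mean daily intake in g/day over the 55 subcategories for one subject."""

    subject_id: int
    sex: str
    intake: np.ndarray  # (55,), g/day, index k-1 -> subcategory k

    def __post_init__(self) -> None:
        self.intake = np.asarray(self.intake, dtype=float)
        if self.intake.shape != (registry.N_SUBCATEGORIES,):
            raise ValidationError("intake vector must have length 55")
        if (self.intake < 0).any():
            raise ValidationError("intake entries must be >= 0")

    @property
    def total(self) -> float:
        return float(self.intake.sum())

    def category_totals(self) -> np.ndarray:
        out = np.zeros(registry.N_CATEGORIES)
        for cat, subs in registry.CATEGORY_TO_SUBCATEGORIES.items():
            out[cat - 1] = self.intake[[s - 1 for s in subs]].sum()
        return out


def subject_daily_intake(
    records: pd.DataFrame, catalog: FoodCatalog, n_days: int | None = None
) -> SubjectIntake:
    """Aggregate one subject's diary into mean daily subcategory amounts.

    ``n_days`` defaults to the number of distinct diary days recorded for
    the subject. Items flagged infant_formula/supplement contribute
    nothing; unknown item ids raise.
    """
    if records.empty:
        raise ValidationError("empty diary records for subject")
    subject_ids = records["subject_id"].unique()
    if len(subject_ids) != 1:
        raise ValidationError("records span more than one subject")
    days = n_days if n_days is not None else records["day"].nunique()
    if days < 1:
        raise ValidationError("diary must cover at least one day")

    totals = np.zeros(registry.N_SUBCATEGORIES)
    for item_id, amount in zip(records["item_id"], records["amount_g"]):
        item = catalog.get(int(item_id))  # KeyError names the id
        if item.excluded:
            continue
        totals[item.subcategory_id - 1] += float(amount)
    return SubjectIntake(
        subject_id=int(subject_ids[0]),
        sex=str(records["sex"].iloc[0]),
        intake=totals / days,
    )


def compute_subject_intakes(
    diary: pd.DataFrame, catalog: FoodCatalog
) -> list[SubjectIntake]:
    """Vectorized per-subject aggregation over a whole diary table."""
    validate_diary(diary)
    if diary.empty:
        return []
    sub_map = {it.item_id: it.subcategory_id for it in catalog if not it.excluded}
    known = {it.item_id for it in catalog}
    unknown = set(diary["item_id"].unique()) - known
    if unknown:
        raise KeyError(f"unknown item_id {sorted(unknown)[0]}")

    df = diary.copy()
    df["subcategory_id"] = df["item_id"].map(sub_map)  # excluded -> NaN
    days = df.groupby("subject_id")["day"].nunique()
    sex = df.groupby("subject_id")["sex"].first()

    consumed = df.dropna(subset=["subcategory_id"])
    pivot = consumed.pivot_table(
        index="subject_id",
        columns="subcategory_id",
        values="amount_g",
        aggfunc="sum",
        fill_value=0.0,
    )
    pivot = pivot.reindex(columns=_ALL_SUBCATS, fill_value=0.0)
    pivot = pivot.reindex(index=days.index, fill_value=0.0)

    out = []
    for sid in days.index:
        out.append(
            SubjectIntake(
                subject_id=int(sid),
                sex=str(sex.loc[sid]),
                intake=pivot.loc[sid].to_numpy(dtype=float) / int(days.loc[sid]),
            )
        )
    return out


@dataclass
class PopulationStats:
    """Sex-stratified subcategory statistics of the observed diet."""

    sex: str
    mean: np.ndarray  # (55,) g/day
    p5: np.ndarray
    p90: np.ndarray
    mean_total_weight: float
    cat_mean: np.ndarray  # (15,)
    cat_p5: np.ndarray
    cat_p90: np.ndarray
    n_subjects: int
    content: pd.DataFrame | None = None  # per 100 g, index 1..55
    percentile_method: str = DEFAULT_PERCENTILE_METHOD

    def __post_init__(self) -> None:
        for name in ("mean", "p5", "p90"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (registry.N_SUBCATEGORIES,):
                raise ValidationError(f"{name} must have length 55")
            if (arr < 0).any():
                raise ValidationError(f"{name} entries must be >= 0")
            setattr(self, name, arr)
        if (self.p5 > self.p90 + 1e-12).any():
            raise ValidationError("p5 exceeds p90 for some subcategory")

    def content_per_g(self) -> pd.DataFrame:
        if self.content is None:
            raise ValidationError("stats carry no nutrient content")
        return self.content / 100.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sex": self.sex,
                "subcategory_id": _ALL_SUBCATS,
                "mean": self.mean,
                "p5": self.p5,
                "p90": self.p90,
            }
        )


def percentile(
    values: Sequence[float], q: float, method: str = DEFAULT_PERCENTILE_METHOD
) -> float:
    return float(np.percentile(np.asarray(values, dtype=float), q, method=method))


def population_stats(
    intakes: Sequence[SubjectIntake],
    sex: str,
    method: str = DEFAULT_PERCENTILE_METHOD,
    content: pd.DataFrame | None = None,
) -> PopulationStats:
    """Mean/p5/p90 per subcategory and category for one sex stratum.

    Non-consumers are included: a subject with zero intake of a
    subcategory contributes a zero to its distribution.
    """
    strat = [s for s in intakes if s.sex == sex]
    if not strat:
        raise ValidationError(f"no subjects of sex {sex!r}")
    mat = np.stack([s.intake for s in strat])  # (n, 55)
    cat_mat = np.stack([s.category_totals() for s in strat])  # (n, 15)
    return PopulationStats(
        sex=sex,
        mean=mat.mean(axis=0),
        p5=np.percentile(mat, 5, axis=0, method=method),
        p90=np.percentile(mat, 90, axis=0, method=method),
        mean_total_weight=float(mat.sum(axis=1).mean()),
        cat_mean=cat_mat.mean(axis=0),
        cat_p5=np.percentile(cat_mat, 5, axis=0, method=method),
        cat_p90=np.percentile(cat_mat, 90, axis=0, method=method),
        n_subjects=len(strat),
        content=content,
        percentile_method=method,
    )


def weighted_nutrient_content(
    diary: pd.DataFrame, catalog: FoodCatalog, sex: str | None = None
) -> pd.DataFrame:
    """Consumption-weighted nutrient content per 100 g, per subcategory.

    Weights are the total amounts consumed across the (optionally
    sex-restricted) stratum. Subcategories never consumed fall back to the
    unweighted mean of their member items, with a warning.
    """
    validate_diary(diary)
    df = diary if sex is None else diary[diary["sex"] == sex]
    weights: dict[int, float] = (
        df.groupby("item_id")["amount_g"].sum().to_dict() if len(df) else {}
    )

    rows = np.zeros((registry.N_SUBCATEGORIES, len(NUTRIENT_FIELDS)))
    for k in _ALL_SUBCATS:
        members = [it for it in catalog.subcategory_items(int(k)) if not it.excluded]
        if not members:
            logger.warning("subcategory %d has no items; content set to zero", k)
            continue
        w = np.array([weights.get(it.item_id, 0.0) for it in members])
        comp = np.stack([it.composition.as_array() for it in members])
        if w.sum() > 0:
            rows[k - 1] = (w[:, None] * comp).sum(axis=0) / w.sum()
        else:
            logger.warning(
                "subcategory %d never consumed; using unweighted item mean", k
            )
            rows[k - 1] = comp.mean(axis=0)
    return pd.DataFrame(rows, index=_ALL_SUBCATS.copy(), columns=list(NUTRIENT_FIELDS))


def build_population_stats(
    diary: pd.DataFrame,
    catalog: FoodCatalog,
    sex: str,
    method: str = DEFAULT_PERCENTILE_METHOD,
    age_range: tuple[int, int] | None = (18, 60),
) -> PopulationStats:
    """Diary table -> complete PopulationStats (statistics + content)."""
    validate_diary(diary)
    if age_range is not None:
        diary = filter_age(diary, *age_range)
    intakes = compute_subject_intakes(diary, catalog)
    content = weighted_nutrient_content(diary, catalog, sex=sex)
    return population_stats(intakes, sex, method=method, content=content)


def observed_summary(stats: PopulationStats, ghge, factors=None) -> dict[str, float]:
    """Nutrient totals and GHGE of the mean observed diet.

    Returns per-day totals for every nutrient field, total GHGE
    (``ghge_kgco2e``), total weight, and percent-of-energy figures
    (``pct_energy_*``) computed with the declared energy factors.
    """
    from .constraints import EnergyFactors, PERCENT_ENERGY_NUTRIENTS

    factors = factors or EnergyFactors()
    content_per_g = stats.content_per_g()
    if len(content_per_g) != registry.N_SUBCATEGORIES:
        raise ValidationError("content matrix does not cover the 55 subcategories")
    totals = stats.mean @ content_per_g.to_numpy()
    out = dict(zip(NUTRIENT_FIELDS, map(float, totals)))
    out["total_weight_g"] = float(stats.mean.sum())
    out["ghge_kgco2e"] = float(ghge.coefficients() @ stats.mean)
    energy = out["energy_kcal"]
    for name, (fields_, factor_name) in PERCENT_ENERGY_NUTRIENTS.items():
        grams = sum(out[f] for f in fields_)
        out[f"pct_energy_{name}"] = (
            100.0 * getattr(factors, factor_name) * grams / energy if energy > 0 else 0.0
        )
    return out


__all__ = [
    "DIARY_COLUMNS",
    "DEFAULT_PERCENTILE_METHOD",
    "SubjectIntake",
    "PopulationStats",
    "validate_diary",
    "filter_age",
    "subject_daily_intake",
    "compute_subject_intakes",
    "population_stats",
    "percentile",
    "weighted_nutrient_content",
    "build_population_stats",
    "observed_summary",
]
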