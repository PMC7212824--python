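import logging

import pandas as pd
import pytest

from dietopt import synthetic
from dietopt.food_model import FoodCatalog, FoodItem, ItemFlags, NutrientVector
from dietopt.food_model import filter_catalog
from dietopt.ghge_db import build_ghge_table
from dietopt.survey import build_population_stats

logging.disable(logging.WARNING)

# Scaled-down subject count so end-to-end fixtures stay in the seconds range.
N_SUBJECTS = 300
SEED = 1


def make_item(
    item_id: int,
    subcategory_id: int = 1,
    name: str = "item",
    flags: ItemFlags | None = None,
    **composition,
) -> FoodItem:
    from dietopt import registry

    return FoodItem(
        item_id=item_id,
        name=name,
        category_id=registry.category_of(subcategory_id),
        subcategory_id=subcategory_id,
        composition=NutrientVector(**composition),
        flags=flags or ItemFlags(),
    )


@pytest.fixture(scope="session")
def default_dataset():
    return synthetic.generate_dataset(
        synthetic.scenario("default_feasible", seed=SEED, n_subjects=N_SUBJECTS)
    )


@pytest.fixture(scope="session")
def default_pipeline(default_dataset):
    """(dataset, filtered catalog, ghge table, stats by sex) for reuse."""
    ds = default_dataset
    catalog = filter_catalog(ds.catalog)
    table = build_ghge_table(ds.points, ds.mapping)
    stats = {
        sex: build_population_stats(ds.diary, catalog, sex) for sex in ("M", "F")
    }
    return ds, catalog, table, stats


@pytest.fixture(scope="session")
def iron_scarce_dataset():
    return synthetic.generate_dataset(
        synthetic.scenario("iron_scarce", seed=SEED, n_subjects=N_SUBJECTS)
    )


@pytest.fixture(scope="session")
def red_meat_dataset():
    return synthetic.generate_dataset(
        synthetic.scenario("red_meat_dominated", seed=SEED, n_subjects=N_SUBJECTS)
    )


@pytest.fixture
def tiny_catalog():
    """Three plain items in distinct subcategories, hand-auditable."""
    items = [
        make_item(1, subcategory_id=1, name="loaf", energy_kcal=270, protein_g=9,
                  carb_g=55, fiber_g=3.5, iron_mg=1.0),
        make_item(2, subcategory_id=17, name="apple", energy_kcal=50,
                  carb_g=12, intrinsic_sugar_g=9, fiber_g=2.0,
                  flags=ItemFlags(fruit_veg=True)),
        make_item(3, subcategory_id=31, name="milk", energy_kcal=55, protein_g=3.3,
                  total_fat_g=2.5, sfa_g=1.6, carb_g=5, intrinsic_sugar_g=5,
                  calcium_mg=120),
    ]
    return FoodCatalog(items)


def diary_frame(rows):
    return pd.DataFrame(
        rows, columns=["subject_id", "sex", "age", "day", "item_id", "amount_g"]
    )
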