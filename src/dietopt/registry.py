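"""Food taxonomy: 15 categories partitioned into 55 subcategories.

The registry is fixed for a given analysis; decision variables of the
optimization are the 55 subcategory amounts. Policy membership sets
(red meat, pulses, ...) are defined here so that constraint assembly and
the synthetic generator agree on them.
"""

from __future__ import annotations

N_CATEGORIES = 15
N_SUBCATEGORIES = 55

CATEGORY_LABELS: dict[int, str] = {
    1: "cereals and cereal products",
    2: "pulses",
    3: "vegetables",
    4: "potatoes and tubers",
    5: "fruit",
    6: "meat and meat products",
    7: "fish and seafood",
    8: "milk and dairy products",
    9: "oils and fats",
    10: "sweet products",
    11: "meal replacements",
    12: "eggs",
    13: "non-alcoholic beverages",
    14: "miscellaneous",
    15: "alcoholic beverages",
}

SUBCATEGORY_LABELS: dict[int, str] = {
    1: "bread and flour",
    2: "savory flatbreads",
    3: "breakfast cereals",
    4: "filled pasta",
    5: "pasta and substitutes",
    6: "rice",
    7: "biscuits",
    8: "cakes and sweet snacks",
    9: "savory bakery products",
    10: "pulses, fresh or processed",
    11: "leafy and fruiting vegetables",
    12: "root vegetables and onions",
    13: "processed vegetables",
    14: "herbs and spices",
    15: "potatoes and tuber dishes",
    16: "potato crisps",
    17: "fresh fruit",
    18: "exotic fruit",
    19: "nuts, seeds and dried fruit",
    20: "canned fruit",
    21: "beef and veal",
    22: "pork, unprocessed",
    23: "poultry and game",
    24: "processed meat",
    25: "other red meats",
    26: "meat substitutes",
    27: "offal and blood products",
    28: "crustaceans and shellfish",
    29: "fresh fish",
    30: "preserved fish",
    31: "milk and milk beverages",
    32: "yogurt and fermented milk",
    33: "milk-based desserts",
    34: "cheese",
    35: "olive oil",
    36: "seed oils",
    37: "butter and cream",
    38: "other fats",
    39: "ice cream",
    40: "chocolate",
    41: "sugar and honey",
    42: "candies and jams",
    43: "cocoa powder",
    44: "artificial sweeteners",
    45: "meal replacement products",
    46: "eggs",
    47: "tap water",
    48: "mineral water",
    49: "coffee, tea and infusions",
    50: "fruit and vegetable juices",
    51: "soft drinks",
    52: "miscellaneous",
    53: "wine",
    54: "fortified wine and spirits",
    55: "beer and cider",
}

# Contiguous subcategory blocks per category.
_CATEGORY_BLOCKS: dict[int, range] = {
    1: range(1, 10),
    2: range(10, 11),
    3: range(11, 15),
    4: range(15, 17),
    5: range(17, 21),
    6: range(21, 28),
    7: range(28, 31),
    8: range(31, 35),
    9: range(35, 39),
    10: range(39, 45),
    11: range(45, 46),
    12: range(46, 47),
    13: range(47, 52),
    14: range(52, 53),
    15: range(53, 56),
}

SUBCATEGORY_TO_CATEGORY: dict[int, int] = {
    sub: cat for cat, block in _CATEGORY_BLOCKS.items() for sub in block
}

CATEGORY_TO_SUBCATEGORIES: dict[int, tuple[int, ...]] = {
    cat: tuple(block) for cat, block in _CATEGORY_BLOCKS.items()
}

# Policy membership sets used by the healthy constraints.
RED_MEAT_SUBCATS = frozenset({21, 22, 25})
PROCESSED_MEAT_SUBCATS = frozenset({24})
ALCOHOL_SUBCATS = frozenset({53, 54, 55})
PULSE_SUBCATS = frozenset({10})
FISH_SUBCATS = frozenset({28, 29, 30})
# Fruit & vegetables exclude pulses, fruit juices, nuts, herbs and potatoes.
FRUIT_VEG_SUBCATS = frozenset({11, 12, 13, 17, 18, 20})

# Sugar classification at subcategory level: members of FREE_SUGAR_SUBCATS
# carry only free sugars; everything else carries intrinsic sugars.
FREE_SUGAR_SUBCATS = frozenset({7, 8, 20, 33, 39, 40, 41, 42, 50, 51, 53, 54, 55})

# Sanity checks run at import time; the registry is static data.
assert set(SUBCATEGORY_TO_CATEGORY) == set(range(1, N_SUBCATEGORIES + 1))
assert set(CATEGORY_TO_SUBCATEGORIES) == set(range(1, N_CATEGORIES + 1))
assert not (RED_MEAT_SUBCATS & FRUIT_VEG_SUBCATS)


def category_of(subcategory_id: int) -> int:
    """Category a subcategory belongs to; raises KeyError if unknown."""
    return SUBCATEGORY_TO_CATEGORY[subcategory_id]
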