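import copy

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from dietopt import registry
from dietopt.constraints import (
    Constraint,
    EnergyFactors,
    acceptability_constraints,
    assemble_problem,
    build_problem,
    default_config,
    healthy_constraints,
    nutrient_constraints,
)
from dietopt.errors import InfeasibleBoxError, ValidationError
from dietopt.food_model import NUTRIENT_FIELDS
from dietopt.survey import PopulationStats


def flat_content(entries=None):
    """Content matrix of zeros with selected {(subcat, field): value} set."""
    content = pd.DataFrame(
        np.zeros((55, len(NUTRIENT_FIELDS))),
        index=range(1, 56),
        columns=list(NUTRIENT_FIELDS),
    )
    for (k, field), value in (entries or {}).items():
        content.loc[k, field] = value
    return content


def make_stats(mean=None, p5=None, p90=None, content=None, sex="M"):
    mean = np.zeros(55) if mean is None else mean
    p5 = np.zeros(55) if p5 is None else p5
    p90 = np.full(55, 1000.0) if p90 is None else p90
    cat = np.zeros(15)
    return PopulationStats(
        sex=sex,
        mean=mean,
        p5=p5,
        p90=p90,
        mean_total_weight=float(mean.sum()),
        cat_mean=cat,
        cat_p5=cat,
        cat_p90=cat + 1e5,
        n_subjects=10,
        content=content,
    )


class TestNutrientConstraints:
    def test_male_energy_bounds_from_default_config(self, default_pipeline):
        _, _, _, stats = default_pipeline
        config = default_config()
        cons = nutrient_constraints(
            config["sexes"]["M"]["nutritional"], stats["M"].content
        )
        energy = next(c for c in cons if c.label == "nutritional:energy")
        assert (energy.lb, energy.ub) == (2400, 2460)

    def test_all_printed_bounds_present_exactly_once(self, default_pipeline):
        _, _, _, stats = default_pipeline
        config = default_config()
        expected = {
            "M": {
                "energy": (2400, 2460), "protein": (60, 92),
                "total_fat": (24.5, 30.8), "sfa": (7.0, 10.1),
                "pufa": (4.8, 10.1), "cholesterol": (250, 300),
                "carbohydrate": (46.8, 65.7), "total_sugar": (10.4, 16.3),
                "free_sugar": (4.2, 5.5), "fiber": (24, 26),
                "calcium": (900, 1100), "iron": (9, 11), "zinc": (11, 13),
                "vitamin_b12": (2, 3), "alcohol": (0, 0),
            },
            "F": {
                "energy": (1900, 1982), "protein": (52, 73),
                "total_fat": (24.1, 31.3), "sfa": (6.4, 10.4),
                "pufa": (4.5, 10.4), "cholesterol": (250, 300),
                "carbohydrate": (46.0, 66.7), "total_sugar": (10.3, 16.6),
                "free_sugar": (4.0, 5.5), "fiber": (24, 26),
                "calcium": (900, 1100), "zinc": (8, 10),
                "vitamin_b12": (2, 3), "alcohol": (0, 0),
            },
        }
        for sex, bounds in expected.items():
            cons = nutrient_constraints(
                config["sexes"][sex]["nutritional"], stats[sex].content
            )
            for nutrient, (lb, ub) in bounds.items():
                matching = [c for c in cons if c.meta["nutrient"] == nutrient]
                if matching[0].meta["unit"] == "percent_energy":
                    assert {
                        (c.meta["percent_lb"], c.meta["percent_ub"])
                        for c in matching
                    } == {(lb, ub)}
                    assert len(matching) == 2  # homogeneous pair
                else:
                    assert len(matching) == 1
                    assert (matching[0].lb, matching[0].ub) == (lb, ub)
        # female default excludes iron; the optional block carries 17-19
        f_cons = nutrient_constraints(
            config["sexes"]["F"]["nutritional"], stats["F"].content
        )
        assert not any(c.meta["nutrient"] == "iron" for c in f_cons)
        opt = config["sexes"]["F"]["optional_nutritional"]["iron"]
        assert (opt["lb"], opt["ub"]) == (17, 19)

    def test_percent_energy_homogeneity_single_food(self):
        # food supplying exactly 30% of energy from fat: fat ub 30.8 holds
        # at any amount, fat ub 29 fails at any amount
        content = flat_content(
            {(1, "energy_kcal"): 300.0, (1, "total_fat_g"): 10.0}
        )
        x = np.zeros(55)
        for amount in (1.0, 10.0, 1234.5):
            x[0] = amount
            ok = nutrient_constraints(
                {"total_fat": {"lb": 10, "ub": 30.8, "unit": "percent_energy"}},
                content,
            )
            assert all(c.satisfied(x) for c in ok)
            tight = nutrient_constraints(
                {"total_fat": {"lb": 10, "ub": 29, "unit": "percent_energy"}},
                content,
            )
            assert not all(c.satisfied(x) for c in tight)

    @given(
        amounts=st.lists(st.floats(0, 500), min_size=55, max_size=55),
        lam=st.floats(0.01, 100),
    )
    @settings(max_examples=40, deadline=None)
    def test_homogeneity_under_scaling(self, amounts, lam, default_pipeline):
        _, _, _, stats = default_pipeline
        config = default_config()
        cons = [
            c
            for c in nutrient_constraints(
                config["sexes"]["M"]["nutritional"], stats["M"].content
            )
            if c.meta["unit"] == "percent_energy"
        ]
        x = np.array(amounts)
        for c in cons:
            assert c.satisfied(x, tol=1e-9) == c.satisfied(
                lam * x, tol=1e-9
            ) or np.isclose(c.value(x), 0.0, atol=1e-6)

    def test_hand_computed_two_subcategory_matrix(self):
        # subcat 1: 200 kcal, 5 g fat per 100 g; subcat 2: 100 kcal, 1 g fat
        content = flat_content(
            {
                (1, "energy_kcal"): 200.0,
                (1, "total_fat_g"): 5.0,
                (2, "energy_kcal"): 100.0,
                (2, "total_fat_g"): 1.0,
            }
        )
        cons = nutrient_constraints(
            {"total_fat": {"lb": 20, "ub": 30, "unit": "percent_energy"}},
            content,
        )
        lower = next(c for c in cons if c.label.endswith("pctE_lb"))
        upper = next(c for c in cons if c.label.endswith("pctE_ub"))
        # lower row: 9*fat_per_g - 0.20*energy_per_g
        assert lower.coeffs[0] == pytest.approx(9 * 0.05 - 0.20 * 2.0)
        assert lower.coeffs[1] == pytest.approx(9 * 0.01 - 0.20 * 1.0)
        assert upper.coeffs[0] == pytest.approx(9 * 0.05 - 0.30 * 2.0)
        assert upper.coeffs[1] == pytest.approx(9 * 0.01 - 0.30 * 1.0)

    def test_missing_bound_entry(self):
        with pytest.raises(ValidationError):
            nutrient_constraints({"iron": {}}, flat_content())

    def test_lb_above_ub(self):
        with pytest.raises(ValidationError):
            nutrient_constraints(
                {"iron": {"lb": 5, "ub": 3, "unit": "per_day"}}, flat_content()
            )


class TestAcceptabilityConstraints:
    def test_male_total_weight_band(self):
        mean = np.zeros(55)
        mean[0] = 2281.0
        cons = acceptability_constraints(make_stats(mean=mean))
        total = next(c for c in cons if c.label == "acceptability:total_weight")
        assert round(total.lb) == 1825
        assert round(total.ub) == 3193

    def test_female_upper_bound(self):
        mean = np.zeros(55)
        mean[0] = 2088.0
        cons = acceptability_constraints(make_stats(mean=mean, sex="F"))
        total = next(c for c in cons if c.label == "acceptability:total_weight")
        assert round(total.ub) == 2923

    def test_zero_percentiles_fix_subcategory_to_zero(self):
        p5, p90 = np.zeros(55), np.full(55, 100.0)
        p90[43] = 0.0  # subcategory 44
        cons = acceptability_constraints(make_stats(p5=p5, p90=p90))
        box = next(c for c in cons if c.label == "acceptability:subcat:44")
        assert (box.lb, box.ub) == (0.0, 0.0)
        assert box.meta["fixed_zero"]

    def test_boxes_cover_all_subcategories(self):
        cons = acceptability_constraints(make_stats(), include_category_level=False)
        boxes = [c for c in cons if c.label.startswith("acceptability:subcat:")]
        assert len(boxes) == 55

    def test_category_level_sums_emitted(self):
        cons = acceptability_constraints(make_stats(), include_category_level=True)
        cats = [c for c in cons if c.label.startswith("acceptability:category:")]
        assert len(cats) == 15
        cat1 = next(c for c in cats if c.meta["category_id"] == 1)
        assert cat1.coeffs[:9].sum() == 9.0 and cat1.coeffs[9:].sum() == 0.0


class TestHealthyConstraints:
    def test_default_policy_bounds(self):
        cons = {c.meta["policy"]: c for c in healthy_constraints()}
        assert (cons["red_meat"].lb, cons["red_meat"].ub) == (10, 30)
        assert (cons["processed_meat"].lb, cons["processed_meat"].ub) == (0, 0)
        assert (cons["alcoholic_beverages"].lb, cons["alcoholic_beverages"].ub) == (0, 0)
        assert (cons["fruit_veg"].lb, cons["fruit_veg"].ub) == (400, 500)
        assert cons["pulses"].lb == 20 and cons["pulses"].ub is None
        assert cons["fish"].lb == 20 and cons["fish"].ub is None

    def test_membership_vectors(self):
        cons = {c.meta["policy"]: c for c in healthy_constraints()}
        rm = cons["red_meat"].coeffs
        assert {i + 1 for i in np.nonzero(rm)[0]} == set(registry.RED_MEAT_SUBCATS)
        fv = cons["fruit_veg"].coeffs
        assert {i + 1 for i in np.nonzero(fv)[0]} == set(registry.FRUIT_VEG_SUBCATS)

    def test_unknown_subcategory_in_policy(self):
        with pytest.raises(ValidationError):
            healthy_constraints(
                policy_config={"custom": {"lb": 1, "subcategories": [99]}}
            )


class TestAssembleProblem:
    def _ghge_table(self):
        from dietopt.ghge_db import GHGETable

        frame = pd.DataFrame(
            {
                "subcategory_id": range(1, 56),
                "c_kgco2e_per_g": 0.002,
                "lo": 0.001,
                "hi": 0.003,
                "rule": "pm50",
                "n_points": 1,
            }
        ).set_index("subcategory_id")
        return GHGETable(frame)

    def test_constraint_count_preserved(self):
        stats = make_stats()
        nut = nutrient_constraints(
            {"iron": {"lb": 1, "ub": 20, "unit": "per_day"}},
            flat_content({(1, "iron_mg"): 10.0}),
        )
        acc = acceptability_constraints(stats, include_category_level=False)
        healthy = healthy_constraints()
        problem = assemble_problem(self._ghge_table(), [nut, acc, healthy])
        assert len(problem.constraints) == len(nut) + len(acc) + len(healthy)

    def test_pulses_box_intersection(self):
        p90 = np.full(55, 1000.0)
        p90[9] = 36.9  # pulses subcategory 10
        stats = make_stats(p90=p90)
        acc = acceptability_constraints(stats, include_category_level=False)
        healthy = healthy_constraints()
        problem = assemble_problem(self._ghge_table(), [acc, healthy])
        box = next(
            c for c in problem.constraints if c.label == "acceptability:subcat:10"
        )
        assert (box.lb, box.ub) == (20.0, 36.9)

    def test_fixed_zero_vs_policy_lower_bound_conflict(self):
        p90 = np.full(55, 1000.0)
        p90[9] = 0.0  # pulses never consumed -> fixed zero
        stats = make_stats(p90=p90)
        acc = acceptability_constraints(stats, include_category_level=False)
        healthy = healthy_constraints()
        with pytest.raises(InfeasibleBoxError, match="10"):
            assemble_problem(self._ghge_table(), [acc, healthy])

    def test_duplicate_labels_rejected(self):
        c = Constraint("dup", "healthy", np.ones(55), lb=0)
        with pytest.raises(ValidationError):
            assemble_problem(self._ghge_table(), [[c], [copy.deepcopy(c)]])

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_intersection_never_enlarges_feasible_set(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(1, 56))
        coeffs = np.zeros(55)
        coeffs[k - 1] = 1.0
        b1 = sorted(rng.uniform(0, 100, 2))
        b2 = sorted(rng.uniform(0, 100, 2))
        c1 = Constraint("a", "acceptability", coeffs.copy(), *b1)
        c2 = Constraint("b", "healthy", coeffs.copy(), *b2)
        try:
            problem = assemble_problem(self._ghge_table(), [[c1], [c2]])
        except InfeasibleBoxError:
            assert max(b1[0], b2[0]) > min(b1[1], b2[1])
            return
        for x_val in rng.uniform(0, 120, 50):
            x = np.zeros(55)
            x[k - 1] = x_val
            if all(c.satisfied(x) for c in problem.constraints):
                assert c1.lb - 1e-9 <= x_val <= c1.ub + 1e-9
                assert c2.lb - 1e-9 <= x_val <= c2.ub + 1e-9

    def test_build_problem_end_to_end(self, default_pipeline):
        _, _, table, stats = default_pipeline
        problem = build_problem(stats["M"], table)
        assert problem.objective.shape == (55,)
        labels = problem.labels()
        assert len(labels) == len(set(labels))
        kinds = {c.kind for c in problem.constraints}
        assert kinds == {"nutritional", "acceptability", "healthy"}


class TestEnergyFactors:
    def test_defaults(self):
        f = EnergyFactors()
        assert (f.fat, f.protein, f.carbohydrate, f.alcohol) == (9, 4, 4, 7)

    def test_positive_required(self):
        with pytest.raises(ValidationError):
            EnergyFactors(fat=0)
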