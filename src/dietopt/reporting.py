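"""Observed-vs-optimized comparison tables and nutrient-source analysis."""

from __future__ import annotations

import math
from dataclasses import dataclass
import numpy as np
import pandas as pd

from . import registry
from .constraints import LPProblem, nutrient_row, NUTRIENT_CONTENT_FIELDS
from .errors import ValidationError
from .ghge_db import GHGETable
from .optimizer import DietSolution
from .survey import PopulationStats, observed_summary


def percent_change(observed: float, optimized: float) -> int | None:
    """Signed integer percent change, rounded half-away-from-zero.

    Undefined (``None``) when the observed value is not positive.
    """
    if observed <= 0:
        return None
    raw = 100.0 * (optimized - observed) / observed
    return int(math.copysign(math.floor(abs(raw) + 0.5), raw)) if raw != 0 else 0


def ghge_of_diet(x: np.ndarray, ghge: GHGETable) -> float:
    """Total emissions of a diet, kg CO2e/day."""
    c = ghge.coefficients()
    x = np.asarray(x, dtype=float)
    if x.shape != c.shape:
        raise ValidationError(f"diet vector has shape {x.shape}, expected {c.shape}")
    return float(c @ x)


def category_contributions(
    x: np.ndarray, content: pd.DataFrame, nutrient: str
) -> np.ndarray:
    """Percent contribution of the 15 categories to a nutrient's total.

    Shares sum to 100 whenever the total is positive; a zero total raises.
    """
    row = nutrient_row(nutrient, content)
    per_sub = row * np.asarray(x, dtype=float)
    total = per_sub.sum()
    if total <= 0:
        raise ValidationError(f"total {nutrient} intake is zero; shares undefined")
    out = np.zeros(registry.N_CATEGORIES)
    for cat, subs in registry.CATEGORY_TO_SUBCATEGORIES.items():
        out[cat - 1] = 100.0 * per_sub[[s - 1 for s in subs]].sum() / total
    return out


def contributions_frame(
    x: np.ndarray, content: pd.DataFrame, nutrients: list[str]
) -> pd.DataFrame:
    rows = []
    for nut in nutrients:
        shares = category_contributions(x, content, nut)
        for cat in range(1, registry.N_CATEGORIES + 1):
            rows.append(
                {
                    "category_id": cat,
                    "category": registry.CATEGORY_LABELS[cat],
                    "nutrient": nut,
                    "percent": shares[cat - 1],
                }
            )
    return pd.DataFrame(rows)


#: Table-3-style footnote markers.
ANNOTATION_AT_P90 = "b"
ANNOTATION_AT_P5 = "c"
ANNOTATION_FIXED_ZERO = "d"
ANNOTATION_POLICY_ZERO = "e"


@dataclass
class DietComparison:
    """Observed vs optimized diet, per nutrient and per subcategory."""

    sex: str
    nutrients: pd.DataFrame  # nutrient, observed, optimized, percent_change
    subcategories: pd.DataFrame  # per-subcategory amounts + annotations
    ghge_observed: float
    ghge_optimized: float

    @property
    def ghge_percent_change(self) -> int | None:
        return percent_change(self.ghge_observed, self.ghge_optimized)

    def render(self) -> str:
        head = (
            f"sex: {self.sex}\n"
            f"GHGE observed {self.ghge_observed:.1f} -> optimized "
            f"{self.ghge_optimized:.1f} kg CO2e/day "
            f"({self.ghge_percent_change:+d}%)\n"
        )
        nut = self.nutrients.to_string(index=False, float_format=lambda v: f"{v:.1f}")
        sub = self.subcategories.to_string(
            index=False, float_format=lambda v: f"{v:.1f}"
        )
        return f"{head}\n{nut}\n\n{sub}\n"


def _policy_zero_subcats(problem: LPProblem) -> set[int]:
    out: set[int] = set()
    for c in problem.constraints:
        if c.kind == "healthy" and c.ub == 0:
            out.update(c.meta.get("subcategories", ()))
    return out


def comparison_report(
    stats: PopulationStats,
    solution: DietSolution,
    problem: LPProblem,
    ghge: GHGETable,
    rel_tol: float = 1e-6,
) -> DietComparison:
    """Build the full observed-vs-optimized comparison.

    Subcategory annotations: at the 90th-percentile bound ("b"), at a
    positive 5th-percentile bound ("c"), fixed at zero because both
    observed percentiles are zero ("d"), or zero by healthy policy ("e").
    """
    if not solution.optimal:
        raise ValidationError("comparison requires an optimal solution")
    x = solution.x
    obs = observed_summary(stats, ghge, problem.factors)

    nut_rows = []
    for name in NUTRIENT_CONTENT_FIELDS:
        fields = NUTRIENT_CONTENT_FIELDS[name]
        observed_val = sum(obs[f] for f in fields)
        optimized_val = solution.nutrient_totals.get(name, float("nan"))
        nut_rows.append(
            {
                "nutrient": name,
                "observed": observed_val,
                "optimized": optimized_val,
                "percent_change": percent_change(observed_val, optimized_val),
            }
        )
    nutrients = pd.DataFrame(nut_rows)

    policy_zero = _policy_zero_subcats(problem)
    sub_rows = []
    for k in range(1, registry.N_SUBCATEGORIES + 1):
        xk, p5k, p90k = float(x[k - 1]), float(stats.p5[k - 1]), float(stats.p90[k - 1])
        tol = max(1e-9, rel_tol * max(1.0, p90k))
        if k in policy_zero:
            ann = ANNOTATION_POLICY_ZERO
        elif p5k == 0.0 and p90k == 0.0:
            ann = ANNOTATION_FIXED_ZERO
        elif xk >= p90k - tol:
            ann = ANNOTATION_AT_P90
        elif p5k > 0 and xk <= p5k + tol:
            ann = ANNOTATION_AT_P5
        else:
            ann = ""
        sub_rows.append(
            {
                "subcategory_id": k,
                "subcategory": registry.SUBCATEGORY_LABELS[k],
                "observed_mean": float(stats.mean[k - 1]),
                "p5": p5k,
                "p90": p90k,
                "optimized": xk,
                "percent_change": percent_change(float(stats.mean[k - 1]), xk),
                "annotation": ann,
            }
        )
    subcategories = pd.DataFrame(sub_rows)

    return DietComparison(
        sex=stats.sex,
        nutrients=nutrients,
        subcategories=subcategories,
        ghge_observed=obs["ghge_kgco2e"],
        ghge_optimized=ghge_of_diet(x, ghge),
    )


def plot_contributions(
    frame: pd.DataFrame, path: str, title: str = "Category contributions"
) -> None:
    """Stacked-bar plot of category contribution shares (optional extra)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pivot = frame.pivot(index="nutrient", columns="category_id", values="percent")
    ax = pivot.plot(kind="bar", stacked=True, figsize=(9, 5), colormap="tab20")
    ax.set_ylabel("% of total intake")
    ax.set_title(title)
    ax.legend(fontsize=6, ncol=2)
    plt.tight_layout()
    plt.savefig(path, dpi=150)
    plt.close()


__all__ = [
    "percent_change",
    "ghge_of_diet",
    "category_contributions",
    "contributions_frame",
    "DietComparison",
    "comparison_report",
    "plot_contributions",
]
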