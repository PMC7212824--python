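"""LP solving: GHGE minimization, nutrient extremization, infeasibility
diagnosis and binding-constraint reporting.

The backend is scipy's HiGHS dual simplex, which is deterministic for a
fixed problem; no randomness enters the solve.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import linprog

from .constraints import (
    NUTRIENT_CONTENT_FIELDS,
    PERCENT_ENERGY_NUTRIENTS,
    LPProblem,
    nutrient_row,
)
from .errors import ValidationError

logger = logging.getLogger(__name__)

#: Relative tolerance (with absolute floor) for calling a constraint binding.
BINDING_REL_TOL = 1e-6
BINDING_ABS_TOL = 1e-9

_STATUS = {0: "optimal", 1: "error", 2: "infeasible", 3: "unbounded", 4: "error"}


@dataclass
class Binding:
    label: str
    side: str  # "lower" | "upper"
    value: float
    bound: float
    subcategory_id: int | None = None


@dataclass
class DietSolution:
    """Outcome of one LP solve."""

    status: str  # optimal | infeasible | unbounded | error
    x: np.ndarray | None  # (n_vars,) g/day
    objective: float | None  # kg CO2e/day (for GHGE solves)
    bindings: list[Binding] = field(default_factory=list)
    nutrient_totals: dict[str, float] = field(default_factory=dict)
    message: str = ""

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


def _matrices(problem: LPProblem):
    A_ub, b_ub, A_eq, b_eq = [], [], [], []
    for c in problem.constraints:
        if c.lb is not None and c.ub is not None and c.lb == c.ub:
            A_eq.append(c.coeffs)
            b_eq.append(c.lb)
            continue
        if c.ub is not None:
            A_ub.append(c.coeffs)
            b_ub.append(c.ub)
        if c.lb is not None:
            A_ub.append(-c.coeffs)
            b_ub.append(-c.lb)
    to = lambda rows: np.array(rows, dtype=float) if rows else None
    return to(A_ub), to(b_ub), to(A_eq), to(b_eq)


def _solve(problem: LPProblem, c: np.ndarray, maximize: bool = False):
    A_ub, b_ub, A_eq, b_eq = _matrices(problem)
    res = linprog(
        -c if maximize else c,
        A_ub=A_ub,
        b_ub=b_ub,
        A_eq=A_eq,
        b_eq=b_eq,
        bounds=[(0, None)] * problem.n_vars,
        method="highs-ds",
    )
    status = _STATUS.get(res.status, "error")
    return status, res


def nutrient_totals(problem: LPProblem, x: np.ndarray) -> dict[str, float]:
    """Per-day nutrient totals and percent-energy figures of a diet."""
    if problem.content is None:
        return {}
    out = {}
    for name in NUTRIENT_CONTENT_FIELDS:
        out[name] = float(nutrient_row(name, problem.content) @ x)
    energy = out["energy"]
    for name, (_, factor_attr) in PERCENT_ENERGY_NUTRIENTS.items():
        factor = getattr(problem.factors, factor_attr)
        out[f"pct_energy_{name}"] = (
            100.0 * factor * out[name] / energy if energy > 0 else 0.0
        )
    out["total_weight"] = float(x.sum())
    return out


def active_constraints(
    problem: LPProblem,
    x: np.ndarray,
    rel_tol: float = BINDING_REL_TOL,
    abs_tol: float = BINDING_ABS_TOL,
) -> list[Binding]:
    """Constraints satisfied with (near-)equality at ``x``.

    A constraint is binding-low when its value is within tolerance of its
    lower bound, binding-high analogously; single-variable boxes carry
    their subcategory id for per-food annotation.
    """
    out = []
    for c in problem.constraints:
        v = c.value(x)
        sub = c.meta.get("subcategory_id")
        if c.lb is not None:
            tol = max(abs_tol, rel_tol * max(1.0, abs(c.lb)))
            if v <= c.lb + tol:
                out.append(Binding(c.label, "lower", v, c.lb, sub))
        if c.ub is not None:
            tol = max(abs_tol, rel_tol * max(1.0, abs(c.ub)))
            if v >= c.ub - tol:
                out.append(Binding(c.label, "upper", v, c.ub, sub))
    return out


def solve_min_ghge(problem: LPProblem) -> DietSolution:
    """Minimize total GHGE subject to all constraints of the problem."""
    status, res = _solve(problem, problem.objective)
    if status != "optimal":
        return DietSolution(status=status, x=None, objective=None, message=res.message)
    x = np.asarray(res.x, dtype=float)
    x[x < 0] = 0.0  # clip solver noise
    sol = DietSolution(
        status="optimal",
        x=x,
        objective=float(problem.objective @ x),
        bindings=active_constraints(problem, x),
        nutrient_totals=nutrient_totals(problem, x),
        message=res.message,
    )
    bad = [c.label for c in problem.constraints if not c.satisfied(x, tol=1e-6)]
    if bad:  # should not happen with a successful solve
        logger.warning("solution violates constraints: %s", bad)
    return sol


def _drop_nutrient(problem: LPProblem, nutrient: str) -> LPProblem:
    labels = [
        c.label
        for c in problem.constraints
        if c.kind == "nutritional" and c.meta.get("nutrient") == nutrient
    ]
    return problem.drop(labels)


def optimize_nutrient(
    problem: LPProblem, nutrient: str, direction: str = "max"
) -> tuple[float | None, DietSolution]:
    """Extremize a nutrient's intake over the remaining feasible set.

    The nutrient's own bound constraints (if any) are removed first; all
    other constraints stay. Returns the achievable extremum and one
    witness diet, or ``(None, infeasible solution)``.
    """
    if direction not in ("max", "min"):
        raise ValidationError(f"direction must be 'max' or 'min', got {direction!r}")
    if problem.content is None:
        raise ValidationError("problem carries no nutrient content matrix")
    reduced = _drop_nutrient(problem, nutrient)
    row = nutrient_row(nutrient, problem.content)
    status, res = _solve(reduced, row, maximize=direction == "max")
    if status != "optimal":
        return None, DietSolution(
            status=status, x=None, objective=None, message=res.message
        )
    x = np.asarray(res.x, dtype=float)
    x[x < 0] = 0.0
    value = float(row @ x)
    sol = DietSolution(
        status="optimal",
        x=x,
        objective=float(problem.objective @ x),
        bindings=active_constraints(reduced, x),
        nutrient_totals=nutrient_totals(problem, x),
    )
    return value, sol


@dataclass
class SuspectDiagnosis:
    suspect: str
    restores_feasibility: bool
    achievable_min: float | None = None
    achievable_max: float | None = None
    original_lb: float | None = None
    original_ub: float | None = None
    gap: float | None = None  # distance from bound to achievable range


@dataclass
class InfeasibilityReport:
    feasible: bool  # True when the problem was feasible to begin with
    entries: list[SuspectDiagnosis] = field(default_factory=list)
    note: str = ""


def diagnose_infeasibility(
    problem: LPProblem, suspects: Sequence[str]
) -> InfeasibilityReport:
    """For each suspect nutrient/label: does removing it restore feasibility?

    Suspects are nutrient names (matched against constraint metadata) or
    exact constraint labels. For each removal that restores feasibility,
    the achievable [min, max] of the suspect quantity over the remaining
    feasible set is computed, together with the gap to the original bound.
    """
    base = solve_min_ghge(problem)
    if base.optimal:
        return InfeasibilityReport(
            feasible=True, note="problem is feasible; nothing to diagnose"
        )

    entries = []
    for suspect in suspects:
        removed = [
            c
            for c in problem.constraints
            if c.label == suspect or c.meta.get("nutrient") == suspect
        ]
        if not removed:
            entries.append(SuspectDiagnosis(suspect=suspect, restores_feasibility=False))
            continue
        reduced = problem.drop([c.label for c in removed])
        status, _ = _solve(reduced, np.zeros(problem.n_vars))
        if status != "optimal":
            entries.append(SuspectDiagnosis(suspect=suspect, restores_feasibility=False))
            continue

        lbs = [c.lb for c in removed if c.lb is not None]
        ubs = [c.ub for c in removed if c.ub is not None]
        entry = SuspectDiagnosis(
            suspect=suspect,
            restores_feasibility=True,
            original_lb=max(lbs) if lbs else None,
            original_ub=min(ubs) if ubs else None,
        )
        if suspect in NUTRIENT_CONTENT_FIELDS and problem.content is not None:
            lo, _ = optimize_nutrient(problem, suspect, "min")
            hi, _ = optimize_nutrient(problem, suspect, "max")
            entry.achievable_min, entry.achievable_max = lo, hi
            if entry.original_lb is not None and hi is not None and hi < entry.original_lb:
                entry.gap = entry.original_lb - hi
            elif entry.original_ub is not None and lo is not None and lo > entry.original_ub:
                entry.gap = lo - entry.original_ub
        entries.append(entry)
    return InfeasibilityReport(feasible=False, entries=entries)


__all__ = [
    "Binding",
    "DietSolution",
    "SuspectDiagnosis",
    "InfeasibilityReport",
    "nutrient_totals",
    "active_constraints",
    "solve_min_ghge",
    "optimize_nutrient",
    "diagnose_infeasibility",
]
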