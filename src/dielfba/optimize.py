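"""The three-stage optimization cascade on a diel model.

Stage 1 maximizes the flux through the single active biomass drain. Stage 2
is a modified parsimonious FBA: with biomass pinned at its optimum, the sum
of all inter-TPM transfer fluxes is minimized, which suppresses
thermodynamically infeasible cycling around the closed TPM loop and yields
the transfer budget f. Stage 3 is flux variability analysis under both the
biomass equality and the cap (sum of transfers) <= f, giving min/max
envelopes that quantify alternate optima.

LPs (and the MILP variant when mutual-exclusion switches are present) are
built with optlang on GLPK.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

from optlang.glpk_interface import Constraint, Model as GLPKModel, Objective, Variable

from .assemble import DielModel
from .model import BaseGSM, SolverError

logger = logging.getLogger(__name__)

#: zero-flux tolerance used by every downstream classification,
#: mmol gDW^-1 hr^-1
TAU = 1e-6

#: relative slack applied to the biomass equality when the pinned problem is
#: numerically infeasible
BIOMASS_SLACK = 1e-6


@dataclass
class FluxSolution:
    status: str  # optimal | infeasible | unbounded | <solver token>
    objective_value: float | None
    fluxes: dict[str, float] = field(default_factory=dict)
    binaries: dict[str, int] = field(default_factory=dict)

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


@dataclass
class TransferBudget:
    f: float

    def __post_init__(self) -> None:
        if self.f < -TAU:
            raise ValueError(f"negative transfer budget {self.f}")
        self.f = max(self.f, 0.0)


class FluxRange(dict):
    """Mapping reaction-instance id -> (min, max), plus per-target failures."""

    def __init__(self, *args, **kwargs):
        super().__init__(*args, **kwargs)
        self.failures: dict[str, str] = {}


@dataclass
class CascadeResult:
    biomass: FluxSolution
    budget: TransferBudget | None = None
    pfba: FluxSolution | None = None
    ranges: FluxRange | None = None


# ---------------------------------------------------------------------------
# Problem construction
# ---------------------------------------------------------------------------

def _status(problem: GLPKModel) -> str:
    status = problem.status
    if status in ("optimal", "infeasible", "unbounded"):
        return status
    # GLPK reports "undefined" for problems proven infeasible by presolve
    return "infeasible" if status == "undefined" else status


def build_problem(
    model: DielModel, with_binaries: bool = True
) -> tuple[GLPKModel, dict[str, Variable], dict[str, Variable]]:
    """Translate a DielModel into an optlang problem.

    Returns (problem, flux variables by instance id, binary variables by
    name). Switch constraints with a ``fixed`` incumbent are applied as plain
    bound tightenings; unfixed switches become big-M rows with binaries when
    ``with_binaries`` is set, and are an error otherwise.
    """
    problem = GLPKModel(name="diel")
    variables = {
        r.id: Variable(r.id, lb=r.lower_bound, ub=r.upper_bound)
        for r in model.reactions.values()
    }
    constraints = []

    balance_terms: dict[str, list] = {m: [] for m in model.metabolites}
    for r in model.reactions.values():
        var = variables[r.id]
        for met, coef in r.stoichiometry.items():
            balance_terms[met].append(coef * var)
    for met, terms in balance_terms.items():
        if terms:
            constraints.append(
                Constraint(sum(terms), lb=0, ub=0, name=f"mb_{met}")
            )

    for i, row in enumerate(model.coupling_rows):
        expr = variables[row.photo_instance_id]
        half_mc = 0.5 * row.m_c
        for rid, coef in row.synthesis_terms.items():
            expr = expr - half_mc * coef * variables[rid]
        constraints.append(
            Constraint(expr, ub=0, name=f"pig_{i}_{row.photo_instance_id}")
        )

    binaries: dict[str, Variable] = {}
    for sw in model.switches:
        v_fix = variables[sw.fixation_instance_id]
        v_o2 = variables[sw.o2_transfer_id]
        if sw.fixed is not None:
            y_n2, y_o2 = sw.fixed
            fl, fu = sw.fixation_bounds
            ol, ou = sw.o2_bounds
            v_fix.lb, v_fix.ub = fl * y_n2, fu * y_n2
            v_o2.lb, v_o2.ub = ol * y_o2, ou * y_o2
            continue
        if not with_binaries:
            raise SolverError(
                "model has unfixed mutual-exclusion switches; solve the MILP "
                "first or request binaries"
            )
        y_n2 = Variable(f"y_n2_tpm{sw.tpm}", type="binary")
        y_o2 = Variable(f"y_o2_tpm{sw.tpm}", type="binary")
        binaries[y_n2.name] = y_n2
        binaries[y_o2.name] = y_o2
        fl, fu = sw.fixation_bounds
        ol, ou = sw.o2_bounds
        constraints += [
            Constraint(v_fix - fu * y_n2, ub=0, name=f"sw_fix_ub_tpm{sw.tpm}"),
            Constraint(v_fix - fl * y_n2, lb=0, name=f"sw_fix_lb_tpm{sw.tpm}"),
            Constraint(v_o2 - ou * y_o2, ub=0, name=f"sw_o2_ub_tpm{sw.tpm}"),
            Constraint(v_o2 - ol * y_o2, lb=0, name=f"sw_o2_lb_tpm{sw.tpm}"),
            Constraint(y_n2 + y_o2, ub=1, name=f"sw_excl_tpm{sw.tpm}"),
        ]

    problem.add(list(variables.values()) + list(binaries.values()) + constraints)
    problem.update()
    return problem, variables, binaries


def _extract(problem: GLPKModel, variables, binaries) -> FluxSolution:
    status = _status(problem)
    if status != "optimal":
        return FluxSolution(status=status, objective_value=None)
    return FluxSolution(
        status="optimal",
        objective_value=float(problem.objective.value),
        fluxes={rid: float(v.primal) for rid, v in variables.items()},
        binaries={name: int(round(v.primal)) for name, v in binaries.items()},
    )


def _transfer_sum(model: DielModel, variables):
    terms = [variables[r.id] for r in model.transfer_reactions]
    return sum(terms) if terms else None


# ---------------------------------------------------------------------------
# Cascade stages
# ---------------------------------------------------------------------------

def maximize_biomass(model: DielModel) -> FluxSolution:
    """Stage 1: maximize flux through the active biomass instance.

    If unfixed mutual-exclusion switches are present the problem is solved
    as a MILP. Non-optimal solver outcomes are propagated in the status,
    never as silent zeros.
    """
    if model.biomass_instance_id is None:
        raise SolverError("no biomass instance placed; run place_biomass first")
    problem, variables, binaries = build_problem(model, with_binaries=True)
    problem.objective = Objective(
        variables[model.biomass_instance_id], direction="max"
    )
    problem.optimize()
    solution = _extract(problem, variables, binaries)
    logger.info("maximize_biomass: %s objective=%s",
                solution.status, solution.objective_value)
    return solution


def minimize_transfers(
    model: DielModel, biomass_max: float
) -> tuple[TransferBudget, FluxSolution]:
    """Stage 2: pin biomass at its maximum, minimize the total transfer flux."""
    problem, variables, binaries = build_problem(model, with_binaries=False)
    bio = variables[model.biomass_instance_id]
    pin = Constraint(1.0 * bio, lb=biomass_max, ub=biomass_max, name="pin_biomass")
    problem.add([pin])
    total = _transfer_sum(model, variables)
    if total is None:
        problem.objective = Objective(0 * bio, direction="min")
    else:
        problem.objective = Objective(total, direction="min")
    problem.optimize()
    if _status(problem) != "optimal":
        slack = abs(biomass_max) * BIOMASS_SLACK
        warnings.warn(
            "biomass equality numerically infeasible; retrying with relative "
            f"slack {BIOMASS_SLACK:g}",
            RuntimeWarning,
            stacklevel=2,
        )
        pin.lb, pin.ub = biomass_max - slack, biomass_max + slack
        problem.optimize()
    solution = _extract(problem, variables, binaries)
    if not solution.optimal:
        return TransferBudget(0.0), solution
    budget = TransferBudget(float(solution.objective_value))
    logger.info("minimize_transfers: f=%s", budget.f)
    return budget, solution


def fva(
    model: DielModel,
    biomass_max: float,
    f: float,
    targets: list[str] | None = None,
) -> FluxRange:
    """Stage 3: per-target min/max flux under pinned biomass and capped
    transfer flow. Defaults to all transfer reactions. Per-target solver
    failures are recorded in ``result.failures``; other targets proceed.
    Results are order-independent.
    """
    if targets is None:
        targets = [r.id for r in model.transfer_reactions]
    problem, variables, binaries = build_problem(model, with_binaries=False)
    bio = variables[model.biomass_instance_id]
    problem.add([
        Constraint(1.0 * bio, lb=biomass_max, ub=biomass_max, name="pin_biomass")
    ])
    total = _transfer_sum(model, variables)
    if total is not None:
        problem.add([Constraint(total, ub=f, name="transfer_budget")])
    problem.update()

    result = FluxRange()
    for target in targets:
        var = variables[target]
        bounds = []
        failed = None
        for direction in ("min", "max"):
            problem.objective = Objective(1.0 * var, direction=direction)
            problem.optimize()
            if _status(problem) != "optimal":
                failed = _status(problem)
                break
            bounds.append(float(problem.objective.value))
        if failed is not None:
            result.failures[target] = failed
            continue
        lo, hi = bounds
        result[target] = (min(lo, hi), max(lo, hi))
    return result


def solve_cascade(
    model: DielModel, fva_targets: list[str] | None = None, run_fva: bool = True
) -> CascadeResult:
    """Run stages 1-3 in order; halts early on non-optimal stages."""
    biomass = maximize_biomass(model)
    if not biomass.optimal:
        return CascadeResult(biomass=biomass)
    budget, pfba = minimize_transfers(model, biomass.objective_value)
    if not pfba.optimal:
        return CascadeResult(biomass=biomass, budget=budget, pfba=pfba)
    ranges = None
    if run_fva:
        ranges = fva(model, biomass.objective_value, budget.f, fva_targets)
    return CascadeResult(biomass=biomass, budget=budget, pfba=pfba, ranges=ranges)


# ---------------------------------------------------------------------------
# Base-model loop audit
# ---------------------------------------------------------------------------

def check_unbounded_loops(base: BaseGSM, tau: float = TAU) -> list[str]:
    """Flag reactions able to carry flux with every exchange closed.

    FVA on the base model with all exchange bounds at zero; any internal
    reaction that can still reach |flux| > tau sits on a thermodynamically
    infeasible cycle. The returned list is sorted (order-independent).
    """
    base.validate()
    problem = GLPKModel(name="loops")
    exchanges = set(base.exchange_ids)
    variables = {}
    for r in base.reactions:
        lb, ub = (0.0, 0.0) if r.id in exchanges else (r.lower_bound, r.upper_bound)
        variables[r.id] = Variable(r.id, lb=lb, ub=ub)
    balance: dict[str, list] = {m.id: [] for m in base.metabolites}
    for r in base.reactions:
        for met, coef in r.stoichiometry.items():
            balance[met].append(coef * variables[r.id])
    constraints = [
        Constraint(sum(terms), lb=0, ub=0, name=f"mb_{met}")
        for met, terms in balance.items() if terms
    ]
    problem.add(list(variables.values()) + constraints)
    problem.update()

    flagged = set()
    for r in base.reactions:
        if r.id in exchanges:
            continue
        for direction in ("max", "min"):
            problem.objective = Objective(1.0 * variables[r.id], direction=direction)
            problem.optimize()
            if _status(problem) == "optimal" and abs(problem.objective.value) > tau:
                flagged.add(r.id)
                break
    return sorted(flagged)
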