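"""Independent dense-matrix LP oracle for the diel optimization cascade.

Builds the constraint matrices of a DielModel from scratch (plain numpy
arrays, no optlang) and solves them with scipy's HiGHS interface. Used by
the tests as an implementation-independent reference for biomass
maximization, transfer-minimizing pFBA, FVA, and (by exhaustive binary
enumeration) the fixation/oxygen mutual-exclusion MILP.
"""

from __future__ import annotations

from itertools import product

import numpy as np
from scipy.optimize import linprog


def _matrices(model):
    rids = list(model.reactions)
    idx = {r: i for i, r in enumerate(rids)}
    mets = list(model.metabolites)
    midx = {m: i for i, m in enumerate(mets)}
    a_eq = np.zeros((len(mets), len(rids)))
    for rxn in model.reactions.values():
        for met, coef in rxn.stoichiometry.items():
            a_eq[midx[met], idx[rxn.id]] = coef
    a_ub_rows, b_ub = [], []
    for row in model.coupling_rows:
        arow = np.zeros(len(rids))
        arow[idx[row.photo_instance_id]] += 1.0
        for rid, coef in row.synthesis_terms.items():
            arow[idx[rid]] -= 0.5 * row.m_c * coef
        a_ub_rows.append(arow)
        b_ub.append(0.0)
    bounds = [
        [rxn.lower_bound, rxn.upper_bound] for rxn in model.reactions.values()
    ]
    for sw in model.switches:
        if sw.fixed is None:
            raise ValueError("oracle LP needs fixed switch binaries")
        y_n2, y_o2 = sw.fixed
        i = idx[sw.fixation_instance_id]
        bounds[i] = [sw.fixation_bounds[0] * y_n2, sw.fixation_bounds[1] * y_n2]
        j = idx[sw.o2_transfer_id]
        bounds[j] = [sw.o2_bounds[0] * y_o2, sw.o2_bounds[1] * y_o2]
    return rids, idx, a_eq, a_ub_rows, b_ub, bounds


def oracle_solve(
    model,
    objective_id: str,
    sense: str = "max",
    biomass_pin: float | None = None,
    transfer_cap: float | None = None,
):
    """Solve one LP over the diel constraints; returns (status, value, fluxes)."""
    rids, idx, a_eq, a_ub_rows, b_ub, bounds = _matrices(model)
    b_eq = np.zeros(a_eq.shape[0])
    a_ub_rows = list(a_ub_rows)
    b_ub = list(b_ub)

    if biomass_pin is not None:
        row = np.zeros(len(rids))
        row[idx[model.biomass_instance_id]] = 1.0
        a_eq = np.vstack([a_eq, row])
        b_eq = np.append(b_eq, biomass_pin)
    if transfer_cap is not None:
        row = np.zeros(len(rids))
        for rxn in model.transfer_reactions:
            row[idx[rxn.id]] = 1.0
        a_ub_rows.append(row)
        b_ub.append(transfer_cap)

    c = np.zeros(len(rids))
    c[idx[objective_id]] = -1.0 if sense == "max" else 1.0
    res = linprog(
        c,
        A_ub=np.array(a_ub_rows) if a_ub_rows else None,
        b_ub=np.array(b_ub) if b_ub else None,
        A_eq=a_eq,
        b_eq=b_eq,
        bounds=bounds,
        method="highs",
    )
    if not res.success:
        status = "infeasible" if res.status == 2 else (
            "unbounded" if res.status == 3 else "failed"
        )
        return status, None, {}
    value = -res.fun if sense == "max" else res.fun
    return "optimal", float(value), dict(zip(rids, map(float, res.x)))


def oracle_min_transfer_sum(model, biomass_pin: float):
    """Minimize the total transfer flux at pinned biomass."""
    rids, idx, a_eq, a_ub_rows, b_ub, bounds = _matrices(model)
    b_eq = np.zeros(a_eq.shape[0])
    row = np.zeros(len(rids))
    row[idx[model.biomass_instance_id]] = 1.0
    a_eq = np.vstack([a_eq, row])
    b_eq = np.append(b_eq, biomass_pin)
    c = np.zeros(len(rids))
    for rxn in model.transfer_reactions:
        c[idx[rxn.id]] = 1.0
    res = linprog(
        c,
        A_ub=np.array(a_ub_rows) if a_ub_rows else None,
        b_ub=np.array(b_ub) if b_ub else None,
        A_eq=a_eq,
        b_eq=b_eq,
        bounds=bounds,
        method="highs",
    )
    if not res.success:
        return "infeasible", None
    return "optimal", float(res.fun)


def oracle_fva(model, biomass_pin: float, transfer_cap: float, targets):
    """Per-target min/max under pinned biomass and capped transfer sum."""
    out = {}
    for target in targets:
        _, lo, _ = oracle_solve(
            model, target, "min", biomass_pin=biomass_pin, transfer_cap=transfer_cap
        )
        _, hi, _ = oracle_solve(
            model, target, "max", biomass_pin=biomass_pin, transfer_cap=transfer_cap
        )
        out[target] = (lo, hi)
    return out


def oracle_enumerate_milp(model):
    """Best biomass over all feasible binary patterns (y_n2, y_o2 per TPM).

    Exhaustively tries every per-TPM combination allowed by the exclusion
    y_n2 + y_o2 <= 1 and solves the induced LP; returns (best value or None,
    best pattern). The model's switches are restored to their prior state.
    """
    prior = [sw.fixed for sw in model.switches]
    best_value, best_pattern = None, None
    options = [(0, 0), (1, 0), (0, 1)]
    try:
        for pattern in product(options, repeat=len(model.switches)):
            for sw, fix in zip(model.switches, pattern):
                sw.fixed = fix
            status, value, _ = oracle_solve(model, model.biomass_instance_id, "max")
            if status == "optimal" and (best_value is None or value > best_value):
                best_value, best_pattern = value, pattern
    finally:
        for sw, fix in zip(model.switches, prior):
            sw.fixed = fix
    return best_value, best_pattern
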