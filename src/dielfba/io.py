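"""Reading and writing base models: SBML (canonical) and a tabular dialect.

SBML goes through python-libsbml (for line-numbered parse errors and
referential checks) and COBRApy (for the model mapping, Level 3 + fbc
preferred, Level 2 with notes tolerated). The tabular dialect is two TSV
files — a reaction table (id, equation, lower_bound, upper_bound, gpr,
subsystem) and a metabolite table (id, name, compartment) — used for small
fixtures; SBML remains the interchange format.
"""

from __future__ import annotations

import math
import os
import re
from pathlib import Path

import pandas as pd

from .model import (
    DEFAULT_BOUND,
    BaseGSM,
    ConfigurationError,
    Metabolite,
    Reaction,
    SBMLParseError,
)

_ARROWS = ("<=>", "<->", "-->", "->", "=>")


# ---------------------------------------------------------------------------
# SBML
# ---------------------------------------------------------------------------

def _check_sbml_document(path: str | os.PathLike) -> None:
    """Parse with libsbml and raise on XML errors or undeclared species."""
    import libsbml

    doc = libsbml.readSBML(str(path))
    errors = []
    for i in range(doc.getNumErrors()):
        err = doc.getError(i)
        if err.getSeverity() >= libsbml.LIBSBML_SEV_ERROR:
            errors.append(f"line {err.getLine()}: {err.getMessage().strip()}")
    if errors:
        raise SBMLParseError(
            f"{path}: malformed SBML:\n" + "\n".join(errors)
        )
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise SBMLParseError(f"{path}: no <model> element found")
    declared = {sbml_model.getSpecies(i).getId()
                for i in range(sbml_model.getNumSpecies())}
    for i in range(sbml_model.getNumReactions()):
        rxn = sbml_model.getReaction(i)
        refs = [rxn.getReactant(j).getSpecies() for j in range(rxn.getNumReactants())]
        refs += [rxn.getProduct(j).getSpecies() for j in range(rxn.getNumProducts())]
        missing = sorted(set(refs) - declared)
        if missing:
            raise SBMLParseError(
                f"{path}: reaction {rxn.getId()!r} references undeclared "
                f"species: {missing}"
            )


def read_sbml(path: str | os.PathLike) -> BaseGSM:
    """Read an SBML file (Level 2 or 3, fbc or note-encoded bounds).

    Unspecified bounds default to +/-10,000 mmol gDW^-1 hr^-1. The biomass
    reaction is the model objective; a model without one raises
    ConfigurationError.
    """
    import cobra
    from cobra.io import read_sbml_model

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _check_sbml_document(path)

    config = cobra.Configuration()
    old_bounds = config.bounds
    config.bounds = (-DEFAULT_BOUND, DEFAULT_BOUND)
    try:
        cmodel = read_sbml_model(str(path))
    except Exception as exc:  # cobra wraps libsbml failures
        raise SBMLParseError(f"{path}: {exc}") from exc
    finally:
        config.bounds = old_bounds

    metabolites = [
        Metabolite(id=m.id, name=m.name or "", compartment=m.compartment or "c")
        for m in cmodel.metabolites
    ]
    reactions = []
    for r in cmodel.reactions:
        lb = -DEFAULT_BOUND if math.isinf(r.lower_bound) else float(r.lower_bound)
        ub = DEFAULT_BOUND if math.isinf(r.upper_bound) else float(r.upper_bound)
        reactions.append(
            Reaction(
                id=r.id,
                stoichiometry={m.id: float(c) for m, c in r.metabolites.items()},
                lower_bound=lb,
                upper_bound=ub,
                gpr=r.gene_reaction_rule or "",
                subsystem=r.subsystem or "",
                name=r.name or "",
            )
        )
    biomass = [r.id for r in cmodel.reactions if r.objective_coefficient]
    if not biomass:
        raise ConfigurationError(
            f"{path}: no reaction is flagged as the objective (biomass)"
        )
    exchange_ids = [r.id for r in cmodel.reactions if len(r.metabolites) == 1]
    model = BaseGSM(
        metabolites=metabolites,
        reactions=reactions,
        biomass_reaction_id=biomass[0],
        exchange_ids=exchange_ids,
        sink_ids=set(),
    )
    model.validate()
    return model


def write_sbml(model: BaseGSM, path: str | os.PathLike) -> None:
    """Serialize a BaseGSM to SBML Level 3 + fbc.

    The emitted file re-reads to a structurally identical model. Refuses to
    serialize a model without reactions.
    """
    import cobra
    from cobra.io import write_sbml_model

    if not model.reactions:
        raise ConfigurationError("refusing to serialize a model with no reactions")
    model.validate()

    cmodel = cobra.Model("model")
    cmets = {
        m.id: cobra.Metabolite(m.id, name=m.name, compartment=m.compartment)
        for m in model.metabolites
    }
    crxns = []
    for r in model.reactions:
        cr = cobra.Reaction(r.id, name=r.name, subsystem=r.subsystem)
        cr.lower_bound = r.lower_bound
        cr.upper_bound = r.upper_bound
        crxns.append(cr)
    cmodel.add_reactions(crxns)
    for r, cr in zip(model.reactions, crxns):
        cr.add_metabolites({cmets[m]: c for m, c in r.stoichiometry.items()})
        if r.gpr.strip():
            cr.gene_reaction_rule = r.gpr
    cmodel.objective = cmodel.reactions.get_by_id(model.biomass_reaction_id)
    write_sbml_model(cmodel, str(path))


# ---------------------------------------------------------------------------
# Tabular dialect
# ---------------------------------------------------------------------------

def parse_equation(equation: str) -> dict[str, float]:
    """Parse ``2 atp + hexose --> glycogen`` into signed stoichiometry.

    Either side may be empty (exchange / sink notation). Coefficients are
    optional and default to 1.
    """
    arrow = next((a for a in _ARROWS if a in equation), None)
    if arrow is None:
        raise ConfigurationError(f"no reaction arrow in equation {equation!r}")
    left, right = equation.split(arrow, 1)

    def parse_side(side: str, sign: float, stoich: dict[str, float]) -> None:
        side = side.strip()
        if not side:
            return
        for term in re.split(r"\s+\+\s+", side):
            parts = term.strip().split()
            if len(parts) == 2:
                coef, met = float(parts[0]), parts[1]
            elif len(parts) == 1:
                coef, met = 1.0, parts[0]
            else:
                raise ConfigurationError(f"cannot parse term {term!r} in {equation!r}")
            stoich[met] = stoich.get(met, 0.0) + sign * coef

    stoich: dict[str, float] = {}
    parse_side(left, -1.0, stoich)
    parse_side(right, +1.0, stoich)
    return {m: c for m, c in stoich.items() if c != 0.0}


def format_equation(stoichiometry: dict[str, float]) -> str:
    def side(items):
        return " + ".join(
            met if coef == 1 else f"{coef:g} {met}" for met, coef in items
        )

    lhs = [(m, -c) for m, c in sorted(stoichiometry.items()) if c < 0]
    rhs = [(m, c) for m, c in sorted(stoichiometry.items()) if c > 0]
    return f"{side(lhs)} --> {side(rhs)}"


def read_tabular(
    reactions_path: str | os.PathLike,
    metabolites_path: str | os.PathLike,
    biomass_reaction_id: str,
) -> BaseGSM:
    """Read the TSV dialect (reaction table + metabolite table)."""
    rxn_df = pd.read_csv(reactions_path, sep="\t", dtype=str).fillna("")
    met_df = pd.read_csv(metabolites_path, sep="\t", dtype=str).fillna("")
    metabolites = [
        Metabolite(id=row["id"], name=row.get("name", ""),
                   compartment=row["compartment"])
        for _, row in met_df.iterrows()
    ]
    reactions = []
    for _, row in rxn_df.iterrows():
        lb = float(row["lower_bound"]) if row["lower_bound"] != "" else -DEFAULT_BOUND
        ub = float(row["upper_bound"]) if row["upper_bound"] != "" else DEFAULT_BOUND
        reactions.append(
            Reaction(
                id=row["id"],
                stoichiometry=parse_equation(row["equation"]),
                lower_bound=lb,
                upper_bound=ub,
                gpr=row.get("gpr", ""),
                subsystem=row.get("subsystem", ""),
            )
        )
    exchange_ids = [r.id for r in reactions if len(r.stoichiometry) == 1]
    model = BaseGSM(
        metabolites=metabolites,
        reactions=reactions,
        biomass_reaction_id=biomass_reaction_id,
        exchange_ids=exchange_ids,
    )
    model.validate()
    return model


def write_tabular(
    model: BaseGSM,
    reactions_path: str | os.PathLike,
    metabolites_path: str | os.PathLike,
) -> None:
    rxn_df = pd.DataFrame(
        {
            "id": [r.id for r in model.reactions],
            "equation": [format_equation(r.stoichiometry) for r in model.reactions],
            "lower_bound": [r.lower_bound for r in model.reactions],
            "upper_bound": [r.upper_bound for r in model.reactions],
            "gpr": [r.gpr for r in model.reactions],
            "subsystem": [r.subsystem for r in model.reactions],
        }
    )
    met_df = pd.DataFrame(
        {
            "id": [m.id for m in model.metabolites],
            "name": [m.name for m in model.metabolites],
            "compartment": [m.compartment for m in model.metabolites],
        }
    )
    rxn_df.to_csv(reactions_path, sep="\t", index=False)
    met_df.to_csv(metabolites_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Result exports
# ---------------------------------------------------------------------------

def write_solution_tsv(solution, path: str | os.PathLike) -> None:
    """Write a point solution as TSV (reaction_instance, tpm, flux)."""
    rows = [(rid, _tpm_of(rid), v) for rid, v in solution.fluxes.items()]
    pd.DataFrame(rows, columns=["reaction_instance", "tpm", "flux"]).to_csv(
        path, sep="\t", index=False
    )


def write_ranges_tsv(ranges, path: str | os.PathLike) -> None:
    """Write FVA ranges as TSV (reaction_instance, tpm, min, max)."""
    rows = [(rid, _tpm_of(rid), lo, hi) for rid, (lo, hi) in ranges.items()]
    pd.DataFrame(rows, columns=["reaction_instance", "tpm", "min", "max"]).to_csv(
        path, sep="\t", index=False
    )


def _tpm_of(instance_id: str) -> int | None:
    m = re.search(r"_tpm(\d+)(?:_|$)", instance_id)
    return int(m.group(1)) if m else None
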