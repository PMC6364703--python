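"""Core data types for genome-scale stoichiometric models.

A :class:`BaseGSM` is the time-invariant scaffold: metabolites, reactions
with signed stoichiometry and flux bounds (mmol gDW^-1 hr^-1), boolean
gene-protein-reaction (GPR) rules, a designated biomass reaction, and the
set of exchange reactions that connect the network to the environment.
Everything downstream (diel assembly, optimization, transcript constraints)
consumes these types.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from . import gpr as gpr_mod

#: default magnitude for "effectively unbounded" fluxes, mmol gDW^-1 hr^-1
DEFAULT_BOUND = 10_000.0


class ConfigurationError(ValueError):
    """A model, config, or argument set is inconsistent."""


class SBMLParseError(ValueError):
    """SBML input could not be parsed or failed referential checks."""


class SolverError(RuntimeError):
    """The LP/MILP solver failed in a way that cannot be reported as a status."""


@dataclass(frozen=True)
class Metabolite:
    """A chemical species located in one compartment.

    Compartment tokens are free-form (e.g. ``c`` cytosol, ``cx`` carboxysome,
    ``e`` extracellular, ``p`` periplasm, ``t`` thylakoid) but must be used
    consistently within a model: transfer eligibility is decided per token.
    """

    id: str
    name: str = ""
    compartment: str = "c"


@dataclass
class Reaction:
    """A stoichiometric reaction with bounds and an optional GPR rule.

    ``stoichiometry`` maps metabolite id -> signed coefficient (negative =
    consumed). ``gpr`` is a boolean expression over gene ids using
    case-insensitive ``and`` / ``or`` with parentheses; empty means no gene
    association.
    """

    id: str
    stoichiometry: dict[str, float]
    lower_bound: float = -DEFAULT_BOUND
    upper_bound: float = DEFAULT_BOUND
    gpr: str = ""
    subsystem: str = ""
    name: str = ""

    def genes(self) -> set[str]:
        if not self.gpr.strip():
            return set()
        return gpr_mod.genes(gpr_mod.parse_gpr(self.gpr))

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0 < self.upper_bound


@dataclass
class ModelStats:
    n_reactions: int
    n_metabolites: int
    n_genes: int
    n_exchanges: int


@dataclass
class BaseGSM:
    """A validated base genome-scale model."""

    metabolites: list[Metabolite]
    reactions: list[Reaction]
    biomass_reaction_id: str
    exchange_ids: list[str] = field(default_factory=list)
    gene_ids: set[str] = field(default_factory=set)
    #: reaction ids that are declared demand/sink placeholders and are allowed
    #: to have single-metabolite stoichiometry without being exchanges
    sink_ids: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self._met_index = {m.id: m for m in self.metabolites}
        self._rxn_index = {r.id: r for r in self.reactions}
        if not self.gene_ids:
            self.gene_ids = set()
            for r in self.reactions:
                self.gene_ids |= r.genes()

    # -- lookups ---------------------------------------------------------
    def metabolite(self, met_id: str) -> Metabolite:
        return self._met_index[met_id]

    def reaction(self, rxn_id: str) -> Reaction:
        return self._rxn_index[rxn_id]

    def has_metabolite(self, met_id: str) -> bool:
        return met_id in self._met_index

    def has_reaction(self, rxn_id: str) -> bool:
        return rxn_id in self._rxn_index

    @property
    def compartments(self) -> set[str]:
        return {m.compartment for m in self.metabolites}

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        """Enforce the structural invariants; raise ConfigurationError."""
        met_ids = [m.id for m in self.metabolites]
        if len(met_ids) != len(set(met_ids)):
            dupes = sorted({m for m in met_ids if met_ids.count(m) > 1})
            raise ConfigurationError(f"duplicate metabolite ids: {dupes}")
        rxn_ids = [r.id for r in self.reactions]
        if len(rxn_ids) != len(set(rxn_ids)):
            dupes = sorted({r for r in rxn_ids if rxn_ids.count(r) > 1})
            raise ConfigurationError(f"duplicate reaction ids: {dupes}")
        for r in self.reactions:
            if r.lower_bound > r.upper_bound:
                raise ConfigurationError(
                    f"reaction {r.id}: lower bound {r.lower_bound} exceeds "
                    f"upper bound {r.upper_bound}"
                )
            unresolved = [m for m in r.stoichiometry if m not in self._met_index]
            if unresolved:
                raise ConfigurationError(
                    f"reaction {r.id} references undeclared metabolites: "
                    f"{sorted(unresolved)}"
                )
            if not r.stoichiometry and r.id not in self.sink_ids:
                raise ConfigurationError(
                    f"reaction {r.id} has empty stoichiometry and is not a "
                    "declared sink"
                )
            if r.gpr.strip():
                gpr_mod.parse_gpr(r.gpr)  # raises GPRParseError if malformed
        if self.biomass_reaction_id not in self._rxn_index:
            raise ConfigurationError(
                f"biomass reaction {self.biomass_reaction_id!r} not in model"
            )
        for ex in self.exchange_ids:
            if ex not in self._rxn_index:
                raise ConfigurationError(f"exchange reaction {ex!r} not in model")
            n_mets = len(self._rxn_index[ex].stoichiometry)
            if n_mets != 1:
                raise ConfigurationError(
                    f"exchange reaction {ex} touches {n_mets} metabolites "
                    "(must touch exactly one)"
                )


def model_stats(model: BaseGSM) -> ModelStats:
    """Counts of unique entities in a base model (not a diel replica)."""
    return ModelStats(
        n_reactions=len(model.reactions),
        n_metabolites=len(model.metabolites),
        n_genes=len(model.gene_ids),
        n_exchanges=len(model.exchange_ids),
    )
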