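"""Assembly of a cyclic diel model from a base genome-scale model.

A light/dark cycle is discretized into K time-point models (TPMs), each an
independent pseudo-steady-state copy of the base network. Copies are linked
by irreversible transfer pseudo-reactions that carry a metabolite's surplus
from TPM k to TPM k+1 (and from K back to 1 when the cycle is closed),
so a metabolite may only be consumed if it was produced in the current or an
earlier TPM. Only metabolites in designated compartments (cytosol and
carboxysome in the reference organism) are transferable; photons and protons
never are — a proton gradient carried across time points would be an
untenable energy store.

Additional structure imposed here:

* phase bounds — CO2 and photon uptake are only open during the light TPMs;
  a basal ATP maintenance demand applies to every TPM;
* biomass placement — a single biomass drain is active in one TPM (the last
  dark TPM by default), so precursors made earlier must be carried forward;
* pigment coupling — flux through each photosynthetic reaction in TPM k is
  capped by the average pigment (chlorophyll) present during that TPM,
  approximated from the difference between the pigment transfer flux leaving
  and entering the TPM:  v_photo,k <= 1/2 (t_out,k - t_in,k) * M_C.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .model import BaseGSM, ConfigurationError


def instance_id(base_id: str, tpm: int) -> str:
    return f"{base_id}_tpm{tpm}"


def metabolite_instance_id(met_id: str, tpm: int) -> str:
    return f"{met_id}[tpm{tpm}]"


def transfer_id(met_id: str, source_tpm: int, target_tpm: int) -> str:
    return f"TF_{met_id}_tpm{source_tpm}_tpm{target_tpm}"


@dataclass
class TPMConfig:
    """Configuration of the diel discretization and its bounds.

    Defaults are the organism-scale reference conditions: a 24 h cycle cut
    into 12 two-hour TPMs, the first 6 lit; CO2 uptake capped at 1.1 and
    photons at 60 mmol gDW^-1 hr^-1 during light; 10 mmol gDW^-1 hr^-1 ATP
    maintenance in every TPM; pigment-coupling constant M_C = 1000; transfer
    fluxes capped at 10,000.
    """

    co2_uptake_id: str
    photon_uptake_id: str
    atp_maintenance_id: str
    n_tpm: int = 12
    n_light: int = 6
    hours_per_tpm: float = 2.0
    co2_uptake_ub: float = 1.1
    photon_uptake_ub: float = 60.0
    atp_maintenance_lb: float = 10.0
    m_c: float = 1000.0
    transfer_ub: float = 10_000.0
    transfer_compartments: frozenset[str] = frozenset({"c", "cx"})
    non_transfer_metabolites: frozenset[str] = frozenset()
    pigment_metabolite_ids: frozenset[str] = frozenset()
    photosynthesis_reaction_ids: frozenset[str] = frozenset()
    biomass_tpm: int | None = None  # defaults to the last TPM
    wrap_around: bool = True

    def __post_init__(self) -> None:
        self.transfer_compartments = frozenset(self.transfer_compartments)
        self.non_transfer_metabolites = frozenset(self.non_transfer_metabolites)
        self.pigment_metabolite_ids = frozenset(self.pigment_metabolite_ids)
        self.photosynthesis_reaction_ids = frozenset(self.photosynthesis_reaction_ids)
        if self.biomass_tpm is None:
            self.biomass_tpm = self.n_tpm
        if not (1 <= self.n_light <= self.n_tpm):
            raise ConfigurationError(
                f"n_light={self.n_light} outside 1..n_tpm={self.n_tpm}"
            )
        if self.m_c <= 0:
            raise ConfigurationError("M_C must be positive")

    def validate_against(self, base: BaseGSM) -> None:
        offenders = []
        for rid in (self.co2_uptake_id, self.photon_uptake_id,
                    self.atp_maintenance_id):
            if not base.has_reaction(rid):
                offenders.append(f"reaction {rid!r}")
        for rid in sorted(self.photosynthesis_reaction_ids):
            if not base.has_reaction(rid):
                offenders.append(f"photosynthesis reaction {rid!r}")
        for mid in sorted(self.pigment_metabolite_ids):
            if not base.has_metabolite(mid):
                offenders.append(f"pigment metabolite {mid!r}")
        for mid in sorted(self.non_transfer_metabolites):
            if not base.has_metabolite(mid):
                offenders.append(f"non-transfer metabolite {mid!r}")
        if offenders:
            raise ConfigurationError(
                "config ids not in base model: " + ", ".join(offenders)
            )
        if not (1 <= self.biomass_tpm <= self.n_tpm):
            raise ConfigurationError(
                f"biomass_tpm={self.biomass_tpm} outside 1..{self.n_tpm}"
            )


@dataclass
class MetaboliteInstance:
    id: str
    base_id: str
    tpm: int
    compartment: str


@dataclass
class ReactionInstance:
    """One reaction copy in one TPM, or one transfer pseudo-reaction."""

    id: str
    base_id: str          # base reaction id, or metabolite id for transfers
    tpm: int              # source TPM for transfers
    stoichiometry: dict[str, float]
    lower_bound: float
    upper_bound: float
    kind: str = "core"    # "core" | "transfer"
    gpr: str = ""
    subsystem: str = ""
    exchange: bool = False
    base_lower: float = 0.0   # unsegmented base-model bounds (E-flux reference)
    base_upper: float = 0.0
    target_tpm: int | None = None  # transfers only


@dataclass
class CouplingRow:
    """Pigment-availability cap on one photosynthesis instance.

    Encodes  v_photo <= 1/2 * m_c * (net pigment synthesis in the TPM),
    summed over all configured pigment species. ``synthesis_terms`` maps
    reaction-instance id -> net pigment stoichiometric coefficient over the
    TPM's core reactions, excluding the biomass drain. Through the pigment
    mass balance this equals the difference between the pigment transfer
    leaving and entering the TPM wherever no drain is active, which is the
    transfer-difference form of the same cap.
    """

    photo_instance_id: str
    tpm: int
    synthesis_terms: dict[str, float]
    m_c: float


@dataclass
class SwitchConstraint:
    """Mutual exclusion between nitrogen fixation and oxygen carry-over.

    Per TPM k, binary y_n2 activates the fixation instance and y_o2 the
    oxygen transfer k -> k+1; big-M rows LB*y <= v <= UB*y use each governed
    reaction's own bounds, and y_n2 + y_o2 <= 1 enforces exclusion. ``fixed``
    holds the incumbent binary pattern after the MILP is solved.
    """

    tpm: int
    fixation_instance_id: str
    o2_transfer_id: str
    fixation_bounds: tuple[float, float]
    o2_bounds: tuple[float, float]
    fixed: tuple[int, int] | None = None


@dataclass
class DielModel:
    """The K-replicated model with transfers, phase bounds, and coupling."""

    base: BaseGSM
    config: TPMConfig
    tpm_count: int
    reactions: dict[str, ReactionInstance] = field(default_factory=dict)
    metabolites: dict[str, MetaboliteInstance] = field(default_factory=dict)
    coupling_rows: list[CouplingRow] = field(default_factory=list)
    switches: list[SwitchConstraint] = field(default_factory=list)
    biomass_instance_id: str | None = None
    transfers_added: bool = False
    phase_bounds_applied: bool = False
    #: pre-scaling upper bounds, filled by the E-flux application
    unscaled_upper: dict[str, float] = field(default_factory=dict)

    # -- accessors ---------------------------------------------------------
    @property
    def transfer_reactions(self) -> list[ReactionInstance]:
        return [r for r in self.reactions.values() if r.kind == "transfer"]

    @property
    def core_reactions(self) -> list[ReactionInstance]:
        return [r for r in self.reactions.values() if r.kind == "core"]

    def instance(self, base_id: str, tpm: int) -> ReactionInstance:
        return self.reactions[instance_id(base_id, tpm)]

    def transfer(self, met_id: str, source_tpm: int) -> ReactionInstance | None:
        target = source_tpm % self.tpm_count + 1
        return self.reactions.get(transfer_id(met_id, source_tpm, target))

    def transfers_of(self, met_id: str) -> list[ReactionInstance]:
        return [r for r in self.transfer_reactions if r.base_id == met_id]

    def tpm_of(self, instance_id_: str) -> int | None:
        m = re.search(r"_tpm(\d+)(?:_tpm\d+)?$", instance_id_)
        return int(m.group(1)) if m else None


# ---------------------------------------------------------------------------
# Assembly operations
# ---------------------------------------------------------------------------

def replicate(base: BaseGSM, config: TPMConfig) -> DielModel:
    """Duplicate the base model into K TPMs ("_tpmX" / "[tpmX]" naming)."""
    base.validate()
    config.validate_against(base)
    K = config.n_tpm
    model = DielModel(base=base, config=config, tpm_count=K)
    for k in range(1, K + 1):
        for met in base.metabolites:
            mid = metabolite_instance_id(met.id, k)
            model.metabolites[mid] = MetaboliteInstance(
                id=mid, base_id=met.id, tpm=k, compartment=met.compartment
            )
    exchange_set = set(base.exchange_ids)
    for k in range(1, K + 1):
        for rxn in base.reactions:
            rid = instance_id(rxn.id, k)
            model.reactions[rid] = ReactionInstance(
                id=rid,
                base_id=rxn.id,
                tpm=k,
                stoichiometry={
                    metabolite_instance_id(m, k): c
                    for m, c in rxn.stoichiometry.items()
                },
                lower_bound=rxn.lower_bound,
                upper_bound=rxn.upper_bound,
                kind="core",
                gpr=rxn.gpr,
                subsystem=rxn.subsystem,
                exchange=rxn.id in exchange_set,
                base_lower=rxn.lower_bound,
                base_upper=rxn.upper_bound,
            )
    return model


def _boundaries(tpm_count: int, wrap_around: bool) -> list[tuple[int, int]]:
    pairs = [(k, k + 1) for k in range(1, tpm_count)]
    if wrap_around:
        pairs.append((tpm_count, 1))
    return pairs


def transfer_eligible(model: DielModel, met_id: str) -> bool:
    met = model.base.metabolite(met_id)
    return (
        met.compartment in model.config.transfer_compartments
        and met.id not in model.config.non_transfer_metabolites
    )


def add_transfers(model: DielModel, config: TPMConfig | None = None) -> DielModel:
    """Create one irreversible transfer per eligible metabolite per boundary."""
    config = config or model.config
    if model.transfers_added:
        raise ConfigurationError("transfer reactions already added")
    eligible = [m for m in model.base.metabolites if transfer_eligible(model, m.id)]
    for met in eligible:
        for k, target in _boundaries(model.tpm_count, config.wrap_around):
            tid = transfer_id(met.id, k, target)
            model.reactions[tid] = ReactionInstance(
                id=tid,
                base_id=met.id,
                tpm=k,
                stoichiometry={
                    metabolite_instance_id(met.id, k): -1.0,
                    metabolite_instance_id(met.id, target): +1.0,
                },
                lower_bound=0.0,
                upper_bound=config.transfer_ub,
                kind="transfer",
                target_tpm=target,
            )
    model.transfers_added = True
    return model


def apply_phase_bounds(model: DielModel, config: TPMConfig | None = None) -> DielModel:
    """Open CO2/photon uptake only during light; set ATP maintenance everywhere."""
    config = config or model.config
    for k in range(1, model.tpm_count + 1):
        light = k <= config.n_light
        for rid, ub in ((config.co2_uptake_id, config.co2_uptake_ub),
                        (config.photon_uptake_id, config.photon_uptake_ub)):
            inst = model.instance(rid, k)
            inst.upper_bound = ub if light else 0.0
            inst.lower_bound = min(inst.lower_bound, inst.upper_bound)
        maint = model.instance(config.atp_maintenance_id, k)
        maint.lower_bound = config.atp_maintenance_lb
        if maint.upper_bound < maint.lower_bound:
            raise ConfigurationError(
                f"ATP maintenance upper bound {maint.upper_bound} below the "
                f"demanded {config.atp_maintenance_lb}"
            )
    model.phase_bounds_applied = True
    return model


def place_biomass(model: DielModel, config: TPMConfig | None = None) -> DielModel:
    """Keep one active biomass drain; bound all other copies to zero.

    The inactive copies are retained (bounded, not deleted) so strain
    comparisons keep aligned reaction-instance universes.
    """
    config = config or model.config
    if not (1 <= config.biomass_tpm <= model.tpm_count):
        raise ConfigurationError(
            f"biomass_tpm={config.biomass_tpm} outside 1..{model.tpm_count}"
        )
    for k in range(1, model.tpm_count + 1):
        inst = model.instance(model.base.biomass_reaction_id, k)
        if k == config.biomass_tpm:
            model.biomass_instance_id = inst.id
        else:
            inst.lower_bound = 0.0
            inst.upper_bound = 0.0
    return model


def add_pigment_coupling(model: DielModel, config: TPMConfig | None = None) -> DielModel:
    """Cap each photosynthesis instance by average pigment availability.

    For TPM k:  v_photo,k <= 1/2 * (sum of pigment synthesis - degradation
    in TPM k) * M_C, summed over the configured pigment species. By the
    pigment mass balance the synthesis/degradation difference equals the
    difference between the pigment transfer flux leaving the TPM
    (t_k->k+1) and the one entering it (t_k-1->k) in every TPM where the
    biomass drain is inactive, so this is the transfer-difference form of
    the same constraint. It is written on the synthesis side because the
    transfer-difference form is degenerate on a closed TPM cycle: the
    differences telescope to zero around the loop while each row forces its
    own difference to be nonnegative, pinning every photosynthesis flux at
    zero; and in the biomass TPM the drain makes the transfer difference
    negative, an outright infeasibility for irreversible photosynthesis
    reactions.
    """
    config = config or model.config
    if not config.pigment_metabolite_ids or not config.photosynthesis_reaction_ids:
        return model
    if not model.transfers_added:
        raise ConfigurationError("add_transfers must run before pigment coupling")
    for pid in sorted(config.pigment_metabolite_ids):
        if not model.transfers_of(pid):
            raise ConfigurationError(
                f"pigment metabolite {pid!r} has no transfer reactions "
                "(not transfer-eligible?)"
            )
    biomass_base = model.base.biomass_reaction_id
    for k in range(1, model.tpm_count + 1):
        terms: dict[str, float] = {}
        for pid in sorted(config.pigment_metabolite_ids):
            met_inst = metabolite_instance_id(pid, k)
            for inst in model.reactions.values():
                if inst.kind != "core" or inst.tpm != k:
                    continue
                if inst.base_id == biomass_base:
                    continue  # the drain is not pigment turnover
                coef = inst.stoichiometry.get(met_inst)
                if coef:
                    terms[inst.id] = terms.get(inst.id, 0.0) + coef
        for rid in sorted(config.photosynthesis_reaction_ids):
            model.coupling_rows.append(
                CouplingRow(
                    photo_instance_id=instance_id(rid, k),
                    tpm=k,
                    synthesis_terms=dict(terms),
                    m_c=config.m_c,
                )
            )
    return model


def assemble(base: BaseGSM, config: TPMConfig) -> DielModel:
    """Run the full assembly pipeline in order."""
    model = replicate(base, config)
    add_transfers(model)
    apply_phase_bounds(model)
    place_biomass(model)
    add_pigment_coupling(model)
    return model


def to_base_gsm(model: DielModel) -> BaseGSM:
    """Flatten a diel model into a BaseGSM (e.g. for SBML export)."""
    from .model import Metabolite, Reaction

    mets = [
        Metabolite(id=m.id, name="", compartment=m.compartment)
        for m in model.metabolites.values()
    ]
    rxns = [
        Reaction(
            id=r.id,
            stoichiometry=dict(r.stoichiometry),
            lower_bound=r.lower_bound,
            upper_bound=r.upper_bound,
            gpr=r.gpr,
            subsystem=r.subsystem or ("transfer" if r.kind == "transfer" else ""),
        )
        for r in model.reactions.values()
    ]
    biomass = model.biomass_instance_id or instance_id(
        model.base.biomass_reaction_id, model.config.biomass_tpm
    )
    return BaseGSM(
        metabolites=mets,
        reactions=rxns,
        biomass_reaction_id=biomass,
        exchange_ids=[r.id for r in model.reactions.values() if r.exchange],
    )
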