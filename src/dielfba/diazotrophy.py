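"""Nitrogen fixation extension and wild-type vs diazotroph comparison.

Nitrogenase is irreversibly inhibited by oxygen, so an engineered diazotroph
must keep fixation and intracellular oxygen apart in time. Fixation
reactions (the ATP-hydrolyzing reduced-ferredoxin:dinitrogen oxidoreductase
plus the N2 exchange and diffusion transport chain) are replicated into
every TPM like core reactions; a mixed-integer switch then forbids fixation
in any TPM whose oxygen transfer to the next TPM carries flux — i.e. any TPM
that has not consumed its oxygen within the period:

    LB_fix,k  * y_n2,k <= v_fix,k  <= UB_fix,k  * y_n2,k
    LB_o2t,k  * y_o2,k <= v_o2t,k  <= UB_o2t,k  * y_o2,k
    y_n2,k + y_o2,k <= 1

Big-M values are each governed reaction's own bounds (tight relaxation).
Strain comparison classifies reactions by whether their FVA envelopes
overlap between wild type and diazotroph.
"""

from __future__ import annotations

from dataclasses import dataclass

from .assemble import (
    DielModel,
    MetaboliteInstance,
    ReactionInstance,
    SwitchConstraint,
    instance_id,
    metabolite_instance_id,
    transfer_id,
    transfer_eligible,
    _boundaries,
)
from .model import ConfigurationError, Metabolite, Reaction
from .optimize import TAU, FluxRange, FluxSolution, maximize_biomass


@dataclass
class ComparisonRecord:
    """Per-reaction-instance classification between two strains' envelopes.

    ``classification`` is the direction token (upregulated / downregulated /
    unchanged); ``labels`` additionally carries ``switched`` and the
    essentiality flags, since one reaction can satisfy several definitions
    at once.
    """

    reaction_instance: str
    wt_range: tuple[float, float]
    mut_range: tuple[float, float]
    classification: str
    labels: frozenset[str]


def add_nitrogen_fixation(
    model: DielModel, nif_reactions: list[Reaction]
) -> DielModel:
    """Replicate fixation + transport reactions into every TPM.

    The list must contain the nitrogen exchange and an unbroken transport
    chain carrying the nitrogen species from the extracellular compartment
    into the cytosol where the fixation reaction consumes it; a broken chain
    is a configuration error. New transferable metabolites get transfer
    reactions on every TPM boundary.
    """
    mets_by_id = {m.id: m for r in nif_reactions for m in _new_metabolites(model, r)}
    exchanges = [r for r in nif_reactions if len(r.stoichiometry) == 1]
    if not exchanges:
        raise ConfigurationError(
            "nitrogen-fixation set has no exchange reaction; N2 cannot enter"
        )
    _check_transport_chain(model, nif_reactions, exchanges)

    # register new metabolites on the base model and per TPM
    for met in mets_by_id.values():
        model.base.metabolites.append(met)
        model.base._met_index[met.id] = met
        for k in range(1, model.tpm_count + 1):
            mid = metabolite_instance_id(met.id, k)
            model.metabolites[mid] = MetaboliteInstance(
                id=mid, base_id=met.id, tpm=k, compartment=met.compartment
            )

    for rxn in nif_reactions:
        if model.base.has_reaction(rxn.id):
            raise ConfigurationError(f"reaction {rxn.id!r} already in model")
        model.base.reactions.append(rxn)
        model.base._rxn_index[rxn.id] = rxn
        is_exchange = len(rxn.stoichiometry) == 1
        if is_exchange:
            model.base.exchange_ids.append(rxn.id)
        for k in range(1, model.tpm_count + 1):
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
                exchange=is_exchange,
                base_lower=rxn.lower_bound,
                base_upper=rxn.upper_bound,
            )

    if model.transfers_added:
        for met in mets_by_id.values():
            if not transfer_eligible(model, met.id):
                continue
            for k, target in _boundaries(model.tpm_count, model.config.wrap_around):
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
                    upper_bound=model.config.transfer_ub,
                    kind="transfer",
                    target_tpm=target,
                )
    return model


def _new_metabolites(model: DielModel, rxn: Reaction) -> list[Metabolite]:
    """Metabolites referenced by a nif reaction but absent from the base.

    Compartment is inferred from an ``_e`` / ``_p`` / ``_c`` id suffix,
    defaulting to cytosol.
    """
    out = []
    for mid in rxn.stoichiometry:
        if model.base.has_metabolite(mid):
            continue
        compartment = "c"
        for suffix, token in (("_e", "e"), ("_p", "p"), ("_c", "c")):
            if mid.endswith(suffix):
                compartment = token
                break
        out.append(Metabolite(id=mid, compartment=compartment))
    return out


def _check_transport_chain(model, nif_reactions, exchanges) -> None:
    """BFS from the exchanged species through the nif set to the cytosol."""
    def compartment(mid: str) -> str:
        if model.base.has_metabolite(mid):
            return model.base.metabolite(mid).compartment
        for suffix, token in (("_e", "e"), ("_p", "p"), ("_c", "c")):
            if mid.endswith(suffix):
                return token
        return "c"

    reachable = {next(iter(ex.stoichiometry)) for ex in exchanges}
    frontier = set(reachable)
    while frontier:
        nxt = set()
        for rxn in nif_reactions:
            touched = set(rxn.stoichiometry)
            if touched & reachable:
                nxt |= touched - reachable
        frontier = nxt
        reachable |= nxt
    if not any(compartment(mid) == "c" for mid in reachable):
        raise ConfigurationError(
            "nitrogen transport chain does not reach the cytosol "
            "(missing transport step?)"
        )


def add_oxygen_exclusion(
    model: DielModel,
    o2_metabolite_id: str,
    fixation_reaction_id: str,
) -> DielModel:
    """Attach per-TPM fixation/oxygen-carry-over exclusion switches.

    The gated oxygen reaction is the transfer k -> k+1 (intracellular
    carry-over), not the extracellular oxygen exchange. TPMs without an
    oxygen transfer (acyclic last TPM) carry no switch.
    """
    if not model.transfers_added:
        raise ConfigurationError("add_transfers must run before oxygen exclusion")
    if not model.transfers_of(o2_metabolite_id):
        raise ConfigurationError(
            f"oxygen metabolite {o2_metabolite_id!r} has no transfer reactions"
        )
    for k in range(1, model.tpm_count + 1):
        o2t = model.transfer(o2_metabolite_id, k)
        if o2t is None:
            continue
        fix_id = instance_id(fixation_reaction_id, k)
        if fix_id not in model.reactions:
            raise ConfigurationError(
                f"fixation instance {fix_id!r} missing; run "
                "add_nitrogen_fixation first"
            )
        fix = model.reactions[fix_id]
        model.switches.append(
            SwitchConstraint(
                tpm=k,
                fixation_instance_id=fix_id,
                o2_transfer_id=o2t.id,
                fixation_bounds=(fix.lower_bound, fix.upper_bound),
                o2_bounds=(o2t.lower_bound, o2t.upper_bound),
            )
        )
    return model


def solve_diazotroph(model: DielModel) -> FluxSolution:
    """Maximize biomass as a MILP, then freeze the incumbent binaries.

    After this call the switches carry their optimal on/off pattern, so the
    transfer-minimizing stage and FVA run as plain LPs over the fixed
    fixation schedule (a free-binary FVA is available by clearing
    ``switch.fixed``).
    """
    if not model.switches:
        raise ConfigurationError("no mutual-exclusion switches present")
    solution = maximize_biomass(model)
    if not solution.optimal:
        return solution
    for sw in model.switches:
        y_n2 = solution.binaries.get(f"y_n2_tpm{sw.tpm}")
        y_o2 = solution.binaries.get(f"y_o2_tpm{sw.tpm}")
        if y_n2 is not None and y_o2 is not None:
            sw.fixed = (y_n2, y_o2)
    return solution


def compare_ranges(
    wt: FluxRange | dict, mut: FluxRange | dict, tau: float = TAU
) -> list[ComparisonRecord]:
    """Classify every reaction instance by envelope overlap between strains.

    Non-overlap: upregulated iff mut_min > wt_max + tau, downregulated iff
    mut_max < wt_min - tau; otherwise unchanged. ``switched`` flags ranges
    excluding zero with opposite signs; essentiality means a strictly
    positive or strictly negative envelope.
    """
    missing_wt = sorted(set(mut) - set(wt))
    missing_mut = sorted(set(wt) - set(mut))
    if missing_wt or missing_mut:
        raise ConfigurationError(
            f"range universes differ; only in mutant: {missing_wt}, "
            f"only in wild type: {missing_mut}"
        )

    def essential(rng: tuple[float, float]) -> bool:
        lo, hi = rng
        return lo > tau or hi < -tau

    def sign(rng: tuple[float, float]) -> int:
        lo, hi = rng
        if lo > tau:
            return 1
        if hi < -tau:
            return -1
        return 0

    records = []
    for rid in sorted(wt):
        w, m = wt[rid], mut[rid]
        if m[0] > w[1] + tau:
            classification = "upregulated"
        elif m[1] < w[0] - tau:
            classification = "downregulated"
        else:
            classification = "unchanged"
        labels = {classification}
        if sign(w) != 0 and sign(m) == -sign(w):
            labels.add("switched")
        if essential(w) and essential(m):
            labels.add("essential_both")
        elif essential(m):
            labels.add("essential_mut_only")
        records.append(
            ComparisonRecord(
                reaction_instance=rid,
                wt_range=tuple(w),
                mut_range=tuple(m),
                classification=classification,
                labels=frozenset(labels),
            )
        )
    return records


def unique_base_count(records: list[ComparisonRecord], label: str) -> int:
    """Deduplicate flagged instances by base reaction id across TPMs."""
    bases = set()
    for rec in records:
        if label in rec.labels:
            bases.add(rec.reaction_instance.rsplit("_tpm", 1)[0])
    return len(bases)
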