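"""Self-contained toy phototroph models and synthetic diel expression.

The toy network is a minimal, carbon-consistent cartoon of oxygenic
phototrophic metabolism: photon and CO2 exchanges, a pigment-gated light
reaction generating ATP/NADPH and evolving O2, carbon fixation to a hexose,
a glycogen-like storage polymer, aerobic respiration, an ATP maintenance
drain, and a biomass sink consuming hexose, pigment, nitrogen and ATP. All
stoichiometric coefficients are integers so oracle LPs are exact to solver
tolerance. The glycogen analogue is deliberately the only metabolite able to
carry energy across TPM boundaries (ATP, NADPH, hexose and reduced
ferredoxin are declared non-transferable), which makes the light->dark
storage transfer a forced, assertable behavior.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .assemble import TPMConfig
from .expression import ExpressionSeries
from .model import BaseGSM, ConfigurationError, Metabolite, Reaction

#: carbon content per toy metabolite, used by the elemental audit
TOY_CARBON = {
    "co2": 1, "hexose": 6, "glycogen": 6, "chl": 1,
    "photon": 0, "o2": 0, "atp": 0, "nadph": 0, "nh3": 0, "fdxrd": 0,
    "n2_e": 0, "n2_p": 0, "n2_c": 0,
}

#: metabolites never carried across TPM boundaries in the toy configuration
TOY_NON_TRANSFER = frozenset({"photon", "atp", "nadph", "hexose", "fdxrd"})


@dataclass
class ToySpec:
    n_tpm: int = 4
    n_light: int = 2
    include_storage: bool = True
    include_pigment: bool = True
    include_nif: bool = False
    seed: int = 0
    bound_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.include_storage and not (1 <= self.n_light < self.n_tpm):
            raise ConfigurationError(
                "storage behavior needs at least one dark TPM (n_light < n_tpm)"
            )


def make_toy_gsm(spec: ToySpec | None = None) -> BaseGSM:
    """Build the toy base model described in the module docstring."""
    spec = spec or ToySpec()
    cap = 10_000.0 * spec.bound_scale

    mets = [
        Metabolite("photon", "photon", "c"),
        Metabolite("co2", "carbon dioxide", "c"),
        Metabolite("o2", "oxygen", "c"),
        Metabolite("atp", "ATP", "c"),
        Metabolite("nadph", "NADPH", "c"),
        Metabolite("hexose", "hexose pool", "c"),
        Metabolite("chl", "chlorophyll pool", "c"),
        Metabolite("nh3", "ammonium", "c"),
    ]
    rxns = [
        Reaction("EX_photon", {"photon": 1.0}, 0.0, cap,
                 subsystem="exchange"),
        # positive = uptake; export of respired CO2 stays open in the dark
        Reaction("EX_co2", {"co2": 1.0}, -cap, cap, subsystem="exchange"),
        # positive = evolution/export, negative = uptake for dark respiration
        Reaction("EX_o2", {"o2": -1.0}, -cap, cap, subsystem="exchange"),
        Reaction("EX_nh3", {"nh3": 1.0}, 0.0, cap, subsystem="exchange"),
        # enzymatic capacities are modest (not the generic cap) so that
        # transcript-derived scaling can actually become limiting
        Reaction(
            "LIGHT_RXN",
            {"photon": -4.0, "atp": 2.0, "nadph": 2.0, "o2": 1.0},
            0.0, 20.0 * spec.bound_scale,
            gpr="gpsA and gpsB", subsystem="photosynthesis",
        ),
        # cyclic electron flow: photon-driven ATP with no NADPH and no O2,
        # balancing the ATP/NADPH demand ratio of carbon fixation
        Reaction(
            "CEF",
            {"photon": -2.0, "atp": 2.0},
            0.0, 30.0 * spec.bound_scale,
            gpr="gpsA", subsystem="photosynthesis",
        ),
        Reaction(
            "PIG_SYNTH", {"co2": -1.0, "atp": -1.0, "chl": 1.0},
            0.0, 5.0 * spec.bound_scale,
            gpr="gchl1", subsystem="pigment biosynthesis",
        ),
        Reaction(
            "CBB",
            {"co2": -6.0, "atp": -18.0, "nadph": -12.0, "hexose": 1.0},
            0.0, 3.0 * spec.bound_scale,
            gpr="gcbb1 and gcbb2", subsystem="carbon fixation",
        ),
        Reaction(
            "RESP",
            {"hexose": -1.0, "o2": -6.0, "co2": 6.0, "atp": 30.0},
            0.0, 2.0 * spec.bound_scale,
            gpr="gresp1 or gresp2", subsystem="respiration",
        ),
        Reaction("ATPM", {"atp": -1.0}, 0.0, cap, subsystem="maintenance"),
        Reaction(
            "BIOMASS",
            {"hexose": -1.0, "chl": -1.0, "nh3": -2.0, "atp": -10.0},
            0.0, cap, subsystem="biomass",
        ),
    ]
    if spec.include_storage:
        rxns += [
            Reaction(
                "GLG_SYNTH", {"hexose": -1.0, "atp": -1.0, "glycogen": 1.0},
                0.0, 5.0 * spec.bound_scale, gpr="gglgA", subsystem="storage",
            ),
            Reaction(
                "GLG_DEG", {"glycogen": -1.0, "hexose": 1.0},
                0.0, 5.0 * spec.bound_scale, gpr="gglgP", subsystem="storage",
            ),
        ]
        mets.append(Metabolite("glycogen", "glycogen unit", "c"))
    if spec.include_nif:
        mets.append(Metabolite("fdxrd", "reduced ferredoxin", "c"))
        rxns.append(
            Reaction(
                "FDX_RED", {"nadph": -1.0, "fdxrd": 1.0},
                0.0, cap, gpr="gfnr1", subsystem="electron transport",
            )
        )

    model = BaseGSM(
        metabolites=mets,
        reactions=rxns,
        biomass_reaction_id="BIOMASS",
        exchange_ids=[r.id for r in rxns if len(r.stoichiometry) == 1
                      and r.id != "ATPM" and r.id != "BIOMASS"],
        sink_ids=set(),
    )
    model.validate()
    return model


def make_toy_config(spec: ToySpec | None = None, **overrides) -> TPMConfig:
    """The toy study conditions.

    Photon cap and maintenance demand keep the organism-scale values (60 and
    10 mmol gDW^-1 hr^-1); the CO2 uptake cap is 5.0 because the toy
    network's respiration yield cannot cover the maintenance demand of the
    dark TPMs at the organism-scale cap. M_C and the transfer cap keep their
    reference values (1000 and 10,000).
    """
    spec = spec or ToySpec()
    non_transfer = TOY_NON_TRANSFER if spec.include_nif else TOY_NON_TRANSFER - {"fdxrd"}
    kwargs = dict(
        co2_uptake_id="EX_co2",
        photon_uptake_id="EX_photon",
        atp_maintenance_id="ATPM",
        n_tpm=spec.n_tpm,
        n_light=spec.n_light,
        hours_per_tpm=24.0 / spec.n_tpm,
        co2_uptake_ub=5.0,
        photon_uptake_ub=60.0,
        atp_maintenance_lb=10.0,
        m_c=1000.0,
        transfer_ub=10_000.0,
        transfer_compartments=frozenset({"c"}),
        non_transfer_metabolites=non_transfer,
        pigment_metabolite_ids=frozenset({"chl"}) if spec.include_pigment else frozenset(),
        photosynthesis_reaction_ids=(
            frozenset({"LIGHT_RXN", "CEF"}) if spec.include_pigment else frozenset()
        ),
        biomass_tpm=spec.n_tpm,
        wrap_around=True,
    )
    kwargs.update(overrides)
    return TPMConfig(**kwargs)


def carbon_audit(model: BaseGSM, boundary_ids: set[str] | None = None) -> list[str]:
    """Return ids of non-boundary reactions that do not conserve carbon."""
    boundary = boundary_ids or (
        set(model.exchange_ids) | {model.biomass_reaction_id, "ATPM"}
    )
    offenders = []
    for rxn in model.reactions:
        if rxn.id in boundary:
            continue
        net = sum(
            TOY_CARBON.get(met, 0) * coef for met, coef in rxn.stoichiometry.items()
        )
        if abs(net) > 1e-9:
            offenders.append(rxn.id)
    return offenders


# ---------------------------------------------------------------------------
# Synthetic expression
# ---------------------------------------------------------------------------

@dataclass
class ExpressionPattern:
    """Diel expression shapes per gene.

    ``shapes`` maps gene -> token (diel-peak-light | diel-peak-dark |
    constant | noisy); genes not listed take ``default_shape``. Diel peaks
    are a raised cosine over the cycle discretized to TPM midpoints, with
    ``baseline`` additive floor and ``amplitude`` peak height.
    """

    shapes: dict[str, str] = field(default_factory=dict)
    default_shape: str = "constant"
    amplitude: float = 1.0
    baseline: float = 0.2
    seed: int = 0
    n_light: int | None = None


def make_expression(
    genes: set[str] | list[str],
    spec: ExpressionPattern | None = None,
    n_tpm: int = 12,
) -> ExpressionSeries:
    """Generate reproducible synthetic diel expression for the given genes."""
    spec = spec or ExpressionPattern()
    n_light = spec.n_light if spec.n_light is not None else n_tpm // 2
    rng = np.random.default_rng(spec.seed)
    values: dict[tuple[str, int], float] = {}
    for gene in sorted(genes):
        shape = spec.shapes.get(gene, spec.default_shape)
        for k in range(1, n_tpm + 1):
            phase = (k - 0.5) / n_tpm  # TPM midpoint as a cycle fraction
            if shape == "diel-peak-light":
                center = 0.5 * n_light / n_tpm
                v = spec.baseline + spec.amplitude * 0.5 * (
                    1 + math.cos(2 * math.pi * (phase - center))
                )
            elif shape == "diel-peak-dark":
                center = (n_light + 0.5 * (n_tpm - n_light)) / n_tpm
                v = spec.baseline + spec.amplitude * 0.5 * (
                    1 + math.cos(2 * math.pi * (phase - center))
                )
            elif shape == "constant":
                v = spec.baseline + spec.amplitude
            elif shape == "noisy":
                v = spec.baseline + spec.amplitude * float(rng.random())
            else:
                raise ConfigurationError(f"unknown expression shape {shape!r}")
            values[(gene, k)] = max(0.0, float(v))
    return ExpressionSeries(values=values, n_tpm=n_tpm)


def toy_expression(
    base: BaseGSM, n_tpm: int, seed: int = 0, amplitude: float = 1.0
) -> ExpressionSeries:
    """A plausible diel program for the toy gene set: photosynthesis, pigment
    and fixation genes peak in light; storage mobilization and respiration
    peak in dark; everything else constant."""
    shapes = {
        "gpsA": "diel-peak-light", "gpsB": "diel-peak-light",
        "gfnr1": "diel-peak-light",
        "gchl1": "diel-peak-light",
        "gcbb1": "diel-peak-light", "gcbb2": "diel-peak-light",
        "gresp1": "diel-peak-dark", "gresp2": "diel-peak-dark",
        "gglgP": "diel-peak-dark", "gglgA": "diel-peak-light",
    }
    genes = set(base.gene_ids)
    return make_expression(
        genes,
        ExpressionPattern(shapes=shapes, amplitude=amplitude, baseline=0.2,
                          seed=seed),
        n_tpm=n_tpm,
    )


# ---------------------------------------------------------------------------
# Nitrogen-fixation reaction set
# ---------------------------------------------------------------------------

def make_nif_set(cap: float = 10_000.0) -> list[Reaction]:
    """Fixation plus the three-step nitrogen entry chain.

    The fixation reaction spends 16 ATP and 8 reduced-ferredoxin equivalents
    per N2 and yields two ammonium; transport runs extracellular ->
    periplasm -> cytosol, with an environmental N2 exchange.
    """
    return [
        Reaction("EX_n2", {"n2_e": 1.0}, 0.0, cap, subsystem="exchange"),
        Reaction("N2T_EP", {"n2_e": -1.0, "n2_p": 1.0}, -cap, cap,
                 subsystem="transport"),
        Reaction("N2T_PC", {"n2_p": -1.0, "n2_c": 1.0}, -cap, cap,
                 subsystem="transport"),
        Reaction(
            "N2_FIX",
            {"n2_c": -1.0, "atp": -16.0, "fdxrd": -8.0, "nh3": 2.0},
            0.0, cap,
            gpr="gnifH and gnifD and gnifK",
            subsystem="nitrogen fixation",
        ),
    ]
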