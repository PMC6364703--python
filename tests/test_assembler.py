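"""TPM replication, transfers, phase bounds, biomass placement, coupling."""

import pytest

from dielfba import fixtures as fx
from dielfba.assemble import (
    add_pigment_coupling,
    add_transfers,
    assemble,
    replicate,
)
from dielfba.model import ConfigurationError
from dielfba.optimize import maximize_biomass

from lp_oracle import oracle_solve


def test_replicate_multiplies_instances(toy_base, toy_config):
    model = replicate(toy_base, toy_config)
    K = toy_config.n_tpm
    assert len(model.reactions) == K * len(toy_base.reactions)
    assert len(model.metabolites) == K * len(toy_base.metabolites)
    # exact naming conventions
    assert "CBB_tpm3" in model.reactions
    assert "co2[tpm2]" in model.metabolites


def test_replicate_rejects_unresolvable_config(toy_base, toy_spec):
    config = fx.make_toy_config(
        toy_spec, pigment_metabolite_ids=frozenset({"not_a_met"})
    )
    with pytest.raises(ConfigurationError, match="not_a_met"):
        replicate(toy_base, config)


def test_transfer_eligibility_rules(toy_model, toy_base, toy_config):
    transfer_mets = {t.base_id for t in toy_model.transfer_reactions}
    # photons and the declared energy carriers are never transferred
    assert "photon" not in transfer_mets
    assert "atp" not in transfer_mets
    # cytosolic inventory metabolites are
    assert {"glycogen", "chl", "co2", "o2"} <= transfer_mets
    K = toy_config.n_tpm
    for t in toy_model.transfer_reactions:
        assert t.lower_bound == 0.0
        assert t.upper_bound == toy_config.transfer_ub
        assert t.target_tpm == t.tpm % K + 1  # forward edges only, wrap closes


def test_compartment_rule_blocks_extracellular_transfer(toy_spec):
    base = fx.make_toy_gsm(fx.ToySpec(include_nif=True))
    from dielfba.diazotrophy import add_nitrogen_fixation

    config = fx.make_toy_config(fx.ToySpec(include_nif=True))
    model = assemble(base, config)
    add_nitrogen_fixation(model, fx.make_nif_set())
    transfer_mets = {t.base_id for t in model.transfer_reactions}
    assert "n2_c" in transfer_mets          # cytosolic species transfers
    assert "n2_e" not in transfer_mets      # extracellular does not
    assert "n2_p" not in transfer_mets      # periplasmic does not


def test_add_transfers_twice_is_an_error(toy_base, toy_config):
    model = replicate(toy_base, toy_config)
    add_transfers(model)
    with pytest.raises(ConfigurationError, match="already"):
        add_transfers(model)


def test_phase_bounds(toy_model, toy_config):
    K, L = toy_config.n_tpm, toy_config.n_light
    for k in range(1, K + 1):
        co2 = toy_model.instance("EX_co2", k)
        photon = toy_model.instance("EX_photon", k)
        maint = toy_model.instance("ATPM", k)
        if k <= L:
            assert co2.upper_bound == toy_config.co2_uptake_ub
            assert photon.upper_bound == toy_config.photon_uptake_ub
        else:
            assert co2.upper_bound == 0.0
            assert photon.upper_bound == 0.0
        assert maint.lower_bound == toy_config.atp_maintenance_lb


def test_dark_uptakes_carry_zero_flux(toy_cascade, toy_model, toy_config):
    fluxes = toy_cascade.pfba.fluxes
    for k in range(toy_config.n_light + 1, toy_config.n_tpm + 1):
        assert fluxes[f"EX_photon_tpm{k}"] == pytest.approx(0.0, abs=1e-9)
        assert fluxes[f"EX_co2_tpm{k}"] <= 1e-9  # export may still run


def test_biomass_placement(toy_base, toy_spec):
    config = fx.make_toy_config(toy_spec, biomass_tpm=2)
    model = assemble(toy_base, config)
    assert model.biomass_instance_id == "BIOMASS_tpm2"
    for k in (1, 3, 4):
        inst = model.instance("BIOMASS", k)
        assert inst.lower_bound == inst.upper_bound == 0.0
    # instances are retained (bounded, not deleted) for aligned comparisons
    assert "BIOMASS_tpm1" in model.reactions


def test_biomass_tpm_out_of_range(toy_base, toy_spec):
    config = fx.make_toy_config(toy_spec, biomass_tpm=13)
    with pytest.raises(ConfigurationError, match="biomass_tpm"):
        assemble(toy_base, config)


def test_alternative_biomass_placement_is_solvable(toy_base, toy_spec):
    config = fx.make_toy_config(toy_spec, biomass_tpm=toy_spec.n_light)
    model = assemble(toy_base, config)
    assert maximize_biomass(model).optimal


def test_transfer_graph_is_a_single_forward_cycle(toy_model, toy_config):
    K = toy_config.n_tpm
    for met in {t.base_id for t in toy_model.transfer_reactions}:
        edges = {
            (t.tpm, t.target_tpm)
            for t in toy_model.transfer_reactions
            if t.base_id == met
        }
        assert edges == {(k, k % K + 1) for k in range(1, K + 1)}


def test_acyclic_mode_drops_the_wrap_edge(toy_base, toy_spec):
    config = fx.make_toy_config(toy_spec, wrap_around=False)
    model = assemble(toy_base, config)
    K = toy_spec.n_tpm
    assert all(t.tpm != K for t in model.transfer_reactions)


def test_pigment_coupling_requires_transfers(toy_base, toy_config):
    model = replicate(toy_base, toy_config)
    with pytest.raises(ConfigurationError, match="add_transfers"):
        add_pigment_coupling(model)


def test_pigment_coupling_requires_transferable_pigment(toy_base, toy_spec):
    config = fx.make_toy_config(
        toy_spec,
        non_transfer_metabolites=fx.TOY_NON_TRANSFER - {"fdxrd"} | {"chl"},
    )
    model = replicate(toy_base, config)
    add_transfers(model)
    with pytest.raises(ConfigurationError, match="chl"):
        add_pigment_coupling(model)


def test_coupling_zero_net_synthesis_shuts_photosynthesis(toy_base, toy_spec):
    """With pigment synthesis bounded to zero the cap is 0 in every TPM and
    the diel model cannot grow (it cannot even meet maintenance by light)."""
    base = fx.make_toy_gsm(toy_spec)
    base.reaction("PIG_SYNTH").upper_bound = 0.0
    model = assemble(base, fx.make_toy_config(toy_spec))
    solution = maximize_biomass(model)
    if solution.optimal:  # maintenance may still be met by stored carbon
        for k in range(1, toy_spec.n_tpm + 1):
            assert solution.fluxes[f"LIGHT_RXN_tpm{k}"] == pytest.approx(0, abs=1e-9)
            assert solution.fluxes[f"CEF_tpm{k}"] == pytest.approx(0, abs=1e-9)
    else:
        assert solution.status == "infeasible"


def test_coupling_bound_arithmetic(toy_base, toy_spec):
    """Transfer difference of 0.002 with M_C=1000 caps photosynthesis at 1.0.

    The pigment transfer out of a drain-free TPM exceeds the transfer in by
    exactly the net synthesis, so pinning synthesis pins the cap: maximizing
    photosynthesis in that TPM must return 1/2 * 0.002 * 1000 = 1.0.
    """
    base = fx.make_toy_gsm(toy_spec)
    model = assemble(base, fx.make_toy_config(toy_spec))
    pig = model.instance("PIG_SYNTH", 1)
    pig.lower_bound = pig.upper_bound = 0.002
    # free the photon budget so only the coupling can bind
    model.instance("EX_photon", 1).upper_bound = 10_000.0
    model.instance("ATPM", 1).lower_bound = 0.0
    status, value, fluxes = oracle_solve(model, "LIGHT_RXN_tpm1", "max")
    assert status == "optimal"
    assert value == pytest.approx(0.5 * 0.002 * 1000.0, rel=1e-9)
    # and the transfer-difference form of the cap holds at that optimum
    t_out = fluxes["TF_chl_tpm1_tpm2"]
    t_in = fluxes[model.transfer("chl", toy_spec.n_tpm).id]
    assert t_out - t_in == pytest.approx(0.002, abs=1e-9)


def test_k1_identity_limit():
    """A single-TPM acyclic diel model equals plain FBA on the base model."""
    import numpy as np
    from scipy.optimize import linprog

    spec = fx.ToySpec(n_tpm=1, n_light=1, include_storage=False,
                      include_pigment=False)
    base = fx.make_toy_gsm(spec)
    config = fx.make_toy_config(spec, wrap_around=False)
    model = assemble(base, config)
    assert len(model.transfer_reactions) == 0
    diel_optimum = maximize_biomass(model).objective_value

    # reference: a dense LP over the base model with the light-phase bounds
    rids = [r.id for r in base.reactions]
    mets = [m.id for m in base.metabolites]
    bounds = []
    for r in base.reactions:
        lb, ub = r.lower_bound, r.upper_bound
        if r.id == "EX_co2":
            ub = config.co2_uptake_ub
        elif r.id == "EX_photon":
            ub = config.photon_uptake_ub
        elif r.id == "ATPM":
            lb = config.atp_maintenance_lb
        bounds.append((lb, ub))
    a_eq = np.zeros((len(mets), len(rids)))
    for j, r in enumerate(base.reactions):
        for met, coef in r.stoichiometry.items():
            a_eq[mets.index(met), j] = coef
    c = np.zeros(len(rids))
    c[rids.index("BIOMASS")] = -1.0
    res = linprog(c, A_eq=a_eq, b_eq=np.zeros(len(mets)), bounds=bounds,
                  method="highs")
    assert res.success
    assert diel_optimum == pytest.approx(-res.fun, rel=1e-6)
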