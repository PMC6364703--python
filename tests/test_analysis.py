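"""Active bounds, flux control coefficients, MMCA, categories, profiles."""

import copy

import numpy as np
import pytest
from scipy import stats

from dielfba.analysis import (
    aggregate_by_category,
    correlation_matrix,
    find_active_bounds,
    flux_control_coefficients,
    mmca,
    normalize_profile,
    transfer_profiles,
)
from dielfba.expression import RatioTable, apply_eflux
from dielfba.optimize import fva, maximize_biomass, minimize_transfers


def _scaled_cascade(toy_model, table):
    apply_eflux(toy_model, table)
    biomass = maximize_biomass(toy_model)
    assert biomass.optimal
    budget, pfba = minimize_transfers(toy_model, biomass.objective_value)
    ranges = fva(toy_model, biomass.objective_value, budget.f,
                 targets=sorted(toy_model.unscaled_upper))
    return biomass, pfba, ranges


# ---------------------------------------------------------------------------
# Active bounds
# ---------------------------------------------------------------------------

def test_binding_scaled_bound_is_flagged(toy_model):
    """Scaling the photosystem below its optimal flux makes the bound active."""
    flux_at_optimum = 15.0  # photon cap 60 / 4 photons per reaction turn
    table = RatioTable(a={("LIGHT_RXN", 1): 0.5})  # cap 10 < 15: binding
    biomass, pfba, ranges = _scaled_cascade(toy_model, table)
    result = find_active_bounds(toy_model, pfba, ranges)
    flagged = {r.reaction_instance for r in result.records}
    assert "LIGHT_RXN_tpm1" in flagged
    record = next(r for r in result.records if r.reaction_instance == "LIGHT_RXN_tpm1")
    assert record.scaled_upper < flux_at_optimum
    assert record.unscaled_upper > record.scaled_upper


def test_unscaled_bounds_are_never_flagged(toy_model):
    table = RatioTable(a={("LIGHT_RXN", 1): 1.0, ("CBB", 1): 1.0})
    biomass, pfba, ranges = _scaled_cascade(toy_model, table)
    result = find_active_bounds(toy_model, pfba, ranges)
    assert result.records == []


def test_slack_scaled_bound_is_not_flagged(toy_model):
    # RESP in a light TPM runs far below 90% of its capacity
    table = RatioTable(a={("RESP", 1): 0.9})
    biomass, pfba, ranges = _scaled_cascade(toy_model, table)
    flagged = {r.reaction_instance for r in find_active_bounds(
        toy_model, pfba, ranges).records}
    assert "RESP_tpm1" not in flagged


def test_unique_count_deduplicates_across_tpms(toy_model):
    # carbon fixation capped well below demand in both light TPMs: both
    # instances saturate, one unique reaction
    table = RatioTable(a={("CBB", 1): 0.2, ("CBB", 2): 0.2})
    biomass, pfba, ranges = _scaled_cascade(toy_model, table)
    result = find_active_bounds(toy_model, pfba, ranges)
    assert {r.reaction_instance for r in result.records} == {
        "CBB_tpm1", "CBB_tpm2"
    }
    assert result.unique_count == 1


# ---------------------------------------------------------------------------
# Flux control coefficients
# ---------------------------------------------------------------------------

def test_fcc_is_zero_for_slack_bounds(toy_model):
    table = RatioTable(a={("RESP", 1): 0.9})  # scaled but nowhere near binding
    apply_eflux(toy_model, table)
    records = flux_control_coefficients(toy_model)
    assert len(records) == 1
    assert records[0].coefficient == 0.0


def test_fcc_matches_direct_perturbation_and_is_near_one_when_controlling(
    toy_model,
):
    """A photosystem bound capped below the photon-limited flux controls
    growth: the recorded coefficient equals the directly measured relative
    biomass response, and is ~1 (proportional control; the small excess over
    1 reflects the fixed maintenance offset in the growth-vs-bound line)."""
    table = RatioTable(a={("LIGHT_RXN", k): 0.5 for k in (1, 2)})
    apply_eflux(toy_model, table)
    # cyclic electron flow off, so the capped reaction is the only light
    # ATP source and its bound is guaranteed to control growth
    for k in (1, 2):
        toy_model.instance("CEF", k).upper_bound = 0.0
    delta = 0.01
    v0 = maximize_biomass(toy_model).objective_value
    inst = toy_model.instance("LIGHT_RXN", 1)
    old = inst.upper_bound
    inst.upper_bound = old * (1 - delta)
    v1 = maximize_biomass(toy_model).objective_value
    inst.upper_bound = old
    expected = ((v1 - v0) / v0) / (-delta)

    records = flux_control_coefficients(toy_model, delta=delta)
    by_tpm = {r.tpm: r.coefficient for r in records if r.reaction_id == "LIGHT_RXN"}
    assert by_tpm[1] == pytest.approx(expected, rel=1e-6)
    assert by_tpm[1] == pytest.approx(1.0, rel=0.05)
    assert by_tpm[2] == pytest.approx(by_tpm[1], rel=1e-6)  # symmetric TPMs


def test_fcc_perturbs_one_bound_at_a_time(toy_model):
    table = RatioTable(a={("LIGHT_RXN", 1): 0.5, ("RESP", 3): 0.9})
    apply_eflux(toy_model, table)
    before = {
        rid: (toy_model.reactions[rid].lower_bound,
              toy_model.reactions[rid].upper_bound)
        for rid in toy_model.unscaled_upper
    }
    flux_control_coefficients(toy_model)
    after = {
        rid: (toy_model.reactions[rid].lower_bound,
              toy_model.reactions[rid].upper_bound)
        for rid in toy_model.unscaled_upper
    }
    assert before == after  # bounds restored after perturbation


# ---------------------------------------------------------------------------
# MMCA
# ---------------------------------------------------------------------------

def test_spearman_on_monotone_pairs():
    records = mmca({"a": [1, 2, 3], "b": [1, 4, 9], "c": [3, 2, 1]})
    by_pair = {(r.metabolite_a, r.metabolite_b): r for r in records}
    assert by_pair[("a", "b")].r_s == pytest.approx(1.0)
    assert by_pair[("a", "c")].r_s == pytest.approx(-1.0)
    assert by_pair[("b", "c")].r_s == pytest.approx(-1.0)


def test_spearman_with_ties_matches_the_rank_formula():
    """Mid-rank computation via the raw product-moment formula on ranks."""
    u_raw = [1.0, 2.0, 2.0, 4.0]
    v_raw = [1.0, 3.0, 2.0, 4.0]
    records = mmca({"u": u_raw, "v": v_raw})
    r_impl = records[0].r_s

    def midranks(xs):
        order = sorted(range(len(xs)), key=lambda i: xs[i])
        ranks = [0.0] * len(xs)
        i = 0
        while i < len(xs):
            j = i
            while j + 1 < len(xs) and xs[order[j + 1]] == xs[order[i]]:
                j += 1
            mid = (i + j) / 2 + 1
            for t in range(i, j + 1):
                ranks[order[t]] = mid
            i = j + 1
        return ranks

    u = midranks(u_raw)
    v = midranks(v_raw)
    n = len(u)
    num = n * sum(a * b for a, b in zip(u, v)) - sum(u) * sum(v)
    den_u = n * sum(a * a for a in u) - sum(u) ** 2
    den_v = n * sum(b * b for b in v) - sum(v) ** 2
    r_oracle = num / (den_u * den_v) ** 0.5
    assert r_impl == pytest.approx(r_oracle, rel=1e-12)


def test_spearman_invariant_under_monotone_transform():
    rng = np.random.default_rng(3)
    x = rng.random(6) + 0.1
    y = rng.random(6) + 0.1
    base = mmca({"x": x, "y": y})[0].r_s
    transformed = mmca({"x": np.exp(3 * x), "y": y ** 3})[0].r_s
    assert transformed == pytest.approx(base, rel=1e-12)


def test_exact_small_n_p_value_agrees_with_enumeration_extremes():
    # a perfectly monotone pair of 4 untied profiles: p = 2/4! (both signs)
    records = mmca({"a": [1, 2, 3, 4], "b": [2, 4, 6, 8]})
    assert records[0].p_value == pytest.approx(2 / 24)
    assert not records[0].significant  # 1/12 > 0.05


def test_significance_flag_respects_alpha():
    x = list(range(1, 8))
    y = [v + 0.01 * (-1) ** v for v in x]  # near-perfectly monotone, n=7
    records = mmca({"x": x, "y": y}, alpha=0.05)
    assert records[0].significant  # 2/5040 < 0.05
    strict = mmca({"x": x, "y": y}, alpha=1e-5)
    assert not strict[0].significant


def test_mmca_needs_three_tpms_and_drops_zero_profiles():
    with pytest.raises(ValueError, match="at least 3"):
        mmca({"a": [1, 2], "b": [2, 1]})
    records = mmca({"a": [1, 2, 3], "z": [0, 0, 0], "b": [3, 1, 2]})
    mets = {r.metabolite_a for r in records} | {r.metabolite_b for r in records}
    assert "z" not in mets


def test_bh_correction_never_adds_significant_pairs():
    rng = np.random.default_rng(12)
    profiles = {m: rng.random(7) for m in "abcdef"}
    plain = mmca(profiles)
    corrected = mmca(profiles, correction="bh")
    sig_plain = {(r.metabolite_a, r.metabolite_b) for r in plain if r.significant}
    sig_bh = {(r.metabolite_a, r.metabolite_b) for r in corrected if r.significant}
    assert sig_bh <= sig_plain
    with pytest.raises(ValueError, match="correction"):
        mmca(profiles, correction="bonferroni")


def test_correlation_matrix_is_symmetric_with_unit_diagonal():
    rng = np.random.default_rng(8)
    profiles = {m: rng.random(5) for m in "abcd"}
    mat = correlation_matrix(mmca(profiles))
    assert np.allclose(mat, mat.T)
    assert np.allclose(np.diag(mat), 1.0)
    assert np.all(np.abs(mat) <= 1 + 1e-12)


# ---------------------------------------------------------------------------
# Categories and normalized profiles
# ---------------------------------------------------------------------------

def test_category_aggregation_sums_members(toy_model, toy_cascade):
    annotation = {"glycogen": "storage", "chl": "pigments", "co2": "gases",
                  "o2": "gases", "nh3": "nitrogen"}
    profiles_max = transfer_profiles(toy_model, toy_cascade.ranges, "max")
    cats = aggregate_by_category(toy_model, toy_cascade.ranges, annotation)
    by_name = {c.category: c for c in cats}
    gases = by_name["gases"]
    assert gases.max_profile == pytest.approx(
        profiles_max["co2"] + profiles_max["o2"]
    )
    # partition conservation: category sums reproduce the total profile
    total = sum(c.max_profile for c in cats)
    assert total == pytest.approx(sum(profiles_max.values()))


def test_unannotated_metabolites_fall_into_unclassified(toy_model, toy_cascade):
    with pytest.warns(RuntimeWarning, match="unclassified"):
        cats = aggregate_by_category(toy_model, toy_cascade.ranges,
                                     {"glycogen": "storage"})
    names = {c.category for c in cats}
    assert "unclassified" in names


def test_category_totals_are_order_invariant(toy_model, toy_cascade):
    ann = {"glycogen": "storage", "chl": "pigments", "co2": "gases",
           "o2": "gases", "nh3": "nitrogen"}
    a = aggregate_by_category(toy_model, toy_cascade.ranges, ann)
    b = aggregate_by_category(toy_model, dict(reversed(list(
        toy_cascade.ranges.items()))), ann)
    for ca, cb in zip(a, b):
        assert ca.category == cb.category
        assert ca.max_profile == pytest.approx(cb.max_profile)


@pytest.mark.parametrize(
    "series, expected",
    [
        ([2, 4, 8, 6], [0.25, 0.5, 1.0, 0.75]),
        ([5, 5, 5], [1.0, 1.0, 1.0]),
    ],
)
def test_normalize_profile(series, expected):
    out = normalize_profile(series)
    assert out == pytest.approx(expected)
    assert out.max() == 1.0


def test_normalize_profile_rejects_all_zero():
    with pytest.raises(ValueError, match="positive"):
        normalize_profile([0.0, 0.0])
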