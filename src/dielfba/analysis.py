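"""Post-solution analyses.

* active-bound detection: which transcript-scaled bounds actually limit
  growth at the optimum;
* flux control coefficients: normalized sensitivity of biomass to a 1%
  perturbation of each transcript-derived bound (transcripts standing in
  for enzyme levels);
* metabolite-metabolite correlation analysis (MMCA): pairwise Spearman rank
  correlation of per-TPM transfer-flux profiles, the FVA maximum transfer
  flux serving as a concentration proxy;
* category aggregation and peak-normalized accumulation profiles.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations, permutations

import numpy as np
from scipy import stats

from .assemble import DielModel
from .expression import RatioTable
from .optimize import TAU, FluxRange, FluxSolution

#: exact permutation p-values are computed up to this profile length
EXACT_PERMUTATION_N = 7


# ---------------------------------------------------------------------------
# Active bounds
# ---------------------------------------------------------------------------

@dataclass
class ActiveBound:
    reaction_instance: str
    tpm: int
    scaled_upper: float
    unscaled_upper: float
    flux: float | None


@dataclass
class ActiveBoundsResult:
    records: list[ActiveBound]
    unique_base_ids: set[str]

    @property
    def unique_count(self) -> int:
        return len(self.unique_base_ids)


def find_active_bounds(
    model: DielModel,
    solution: FluxSolution | None,
    ranges: FluxRange | dict,
    tau: float = TAU,
) -> ActiveBoundsResult:
    """Flag instances whose scaled upper bound is attained by the FVA max.

    An instance is flagged iff its FVA maximum equals the transcript-scaled
    upper bound within tau * max(1, |bound|) and the bound is strictly below
    the unscaled base bound. Unscaled instances are never flagged. The
    deduplicated base-reaction count accompanies the instance list.
    """
    records = []
    bases: set[str] = set()
    for rid, unscaled in model.unscaled_upper.items():
        inst = model.reactions[rid]
        if inst.upper_bound >= unscaled - tau:
            continue  # bound not constricted
        if rid not in ranges:
            continue
        _, vmax = ranges[rid]
        if abs(vmax - inst.upper_bound) <= tau * max(1.0, abs(inst.upper_bound)):
            records.append(
                ActiveBound(
                    reaction_instance=rid,
                    tpm=inst.tpm,
                    scaled_upper=inst.upper_bound,
                    unscaled_upper=unscaled,
                    flux=solution.fluxes.get(rid) if solution else None,
                )
            )
            bases.add(inst.base_id)
    return ActiveBoundsResult(records=records, unique_base_ids=bases)


# ---------------------------------------------------------------------------
# Flux control coefficients
# ---------------------------------------------------------------------------

@dataclass
class FCCRecord:
    reaction_id: str
    tpm: int
    coefficient: float | None  # None = perturbed problem infeasible
    status: str = "ok"


def flux_control_coefficients(
    model: DielModel,
    ratios: RatioTable | None = None,
    delta: float = 0.01,
    direction: int = -1,
    tau: float = TAU,
) -> list[FCCRecord]:
    """Perturb each transcript-scaled bound by 1% and record the biomass
    response, as C = (dv_biomass / dx) * (x / v_biomass).

    The default tightens the bound (direction=-1): tightening a binding
    constraint is guaranteed to produce a measurable response, whereas
    loosening a bound that the optimum already saturates may not. Exchange,
    transfer and biomass instances carry no transcript bound and are not
    perturbed. Coefficients within tau of zero are reported as exactly 0;
    infeasible perturbations are marked undefined, never zero.
    """
    del ratios  # the applied table is already baked into the instance bounds
    from optlang.glpk_interface import Objective

    from .optimize import _status, build_problem

    if model.biomass_instance_id is None:
        raise RuntimeError("no biomass instance placed")
    problem, variables, _ = build_problem(model, with_binaries=False)
    problem.objective = Objective(
        variables[model.biomass_instance_id], direction="max"
    )
    problem.optimize()
    if _status(problem) != "optimal":
        raise RuntimeError("baseline model is not solvable")
    v0 = float(problem.objective.value)
    rel_dx = direction * delta

    records = []
    for rid in sorted(model.unscaled_upper):
        inst = model.reactions[rid]
        if inst.upper_bound >= model.unscaled_upper[rid] - tau:
            continue  # not transcript-constrained in this TPM
        var = variables[rid]
        old_ub, old_lb = var.ub, var.lb
        new_ub = inst.upper_bound * (1.0 + rel_dx)
        var.lb = min(old_lb, new_ub)
        var.ub = new_ub
        problem.optimize()
        status = _status(problem)
        v1 = float(problem.objective.value) if status == "optimal" else None
        var.ub, var.lb = old_ub, old_lb
        if v1 is None:
            records.append(
                FCCRecord(inst.base_id, inst.tpm, None, status="undefined")
            )
            continue
        if v0 <= tau:
            coefficient = 0.0
        else:
            coefficient = ((v1 - v0) / v0) / rel_dx
        if abs(coefficient) <= tau:
            coefficient = 0.0
        records.append(FCCRecord(inst.base_id, inst.tpm, coefficient))
    return records


# ---------------------------------------------------------------------------
# MMCA
# ---------------------------------------------------------------------------

@dataclass
class CorrelationRecord:
    metabolite_a: str
    metabolite_b: str
    r_s: float
    p_value: float
    significant: bool


def _exact_spearman_p(u: np.ndarray, v: np.ndarray, r_obs: float) -> float:
    """Two-sided permutation p-value over all orderings of one rank vector."""
    n = len(u)
    count = 0
    total = 0
    u_centered = u - u.mean()
    denom_u = float(np.sqrt((u_centered ** 2).sum()))
    for perm in permutations(v):
        p = np.asarray(perm)
        p_centered = p - p.mean()
        denom = denom_u * float(np.sqrt((p_centered ** 2).sum()))
        r = float(u_centered @ p_centered) / denom if denom > 0 else 0.0
        if abs(r) >= abs(r_obs) - 1e-12:
            count += 1
        total += 1
    return count / total


def mmca(
    profiles: dict[str, "np.ndarray | list[float]"],
    alpha: float = 0.05,
    correction: str | None = None,
) -> list[CorrelationRecord]:
    """Pairwise Spearman correlation of per-TPM transfer-flux profiles.

    Profiles are peak-normalized per metabolite (all-zero profiles are
    excluded up front). Two-sided p-values come from an exact permutation
    enumeration for short profiles (n <= 7) and the large-sample
    approximation otherwise; no multiple-testing correction is applied by
    default (``correction="bh"`` switches the significance call to
    Benjamini-Hochberg at level alpha). Records with p >= alpha are
    retained but flagged insignificant.
    """
    arrays = {m: np.asarray(p, dtype=float) for m, p in profiles.items()}
    lengths = {len(a) for a in arrays.values()}
    if len(lengths) > 1:
        raise ValueError(f"profiles have unequal lengths: {sorted(lengths)}")
    n = lengths.pop() if lengths else 0
    if n < 3:
        raise ValueError(
            f"rank correlation needs at least 3 TPMs, got {n}"
        )
    kept = {}
    for met, arr in sorted(arrays.items()):
        peak = np.abs(arr).max()
        if peak <= 0:
            continue
        kept[met] = arr / peak

    records = []
    for a, b in combinations(sorted(kept), 2):
        ua, vb = kept[a], kept[b]
        if np.ptp(ua) == 0 or np.ptp(vb) == 0:
            records.append(CorrelationRecord(a, b, float("nan"), 1.0, False))
            continue
        r_s, p_approx = stats.spearmanr(ua, vb)
        r_s = float(r_s)
        if n <= EXACT_PERMUTATION_N:
            ranks_u = stats.rankdata(ua)
            ranks_v = stats.rankdata(vb)
            p = _exact_spearman_p(ranks_u, ranks_v, r_s)
        else:
            p = float(p_approx)
        records.append(CorrelationRecord(a, b, r_s, p, p < alpha))
    if correction == "bh":
        tested = [r for r in records if not math.isnan(r.r_s)]
        m = len(tested) or 1
        ranked = sorted(tested, key=lambda r: r.p_value)
        threshold = 0.0
        for i, rec in enumerate(ranked, start=1):
            if rec.p_value <= i * alpha / m:
                threshold = rec.p_value
        for rec in records:
            rec.significant = (not math.isnan(rec.r_s)
                               and rec.p_value <= threshold)
    elif correction is not None:
        raise ValueError(f"unknown correction {correction!r}")
    return records


def correlation_matrix(records: list[CorrelationRecord]) -> "np.ndarray":
    """Square symmetric r_s matrix (unit diagonal) in sorted-metabolite order."""
    mets = sorted({r.metabolite_a for r in records} | {r.metabolite_b for r in records})
    index = {m: i for i, m in enumerate(mets)}
    mat = np.eye(len(mets))
    for rec in records:
        i, j = index[rec.metabolite_a], index[rec.metabolite_b]
        mat[i, j] = mat[j, i] = rec.r_s
    return mat


# ---------------------------------------------------------------------------
# Transfer profiles, categories, normalization
# ---------------------------------------------------------------------------

def transfer_profiles(
    model: DielModel, ranges: FluxRange | dict, which: str = "max"
) -> dict[str, np.ndarray]:
    """Per-metabolite transfer-flux profile over source TPMs 1..K.

    ``which`` selects the FVA envelope side ("min" | "max"). Boundaries
    without a range entry contribute 0.
    """
    side = {"min": 0, "max": 1}[which]
    profiles: dict[str, np.ndarray] = {}
    for inst in model.transfer_reactions:
        profiles.setdefault(inst.base_id, np.zeros(model.tpm_count))
        if inst.id in ranges:
            profiles[inst.base_id][inst.tpm - 1] = ranges[inst.id][side]
    return profiles


@dataclass
class CategoryProfile:
    category: str
    min_profile: np.ndarray
    max_profile: np.ndarray


def aggregate_by_category(
    model: DielModel,
    ranges: FluxRange | dict,
    annotation: dict[str, str],
) -> list[CategoryProfile]:
    """Sum member metabolites' transfer min/max per category and TPM.

    Metabolites without an annotation fall into "unclassified" (warned).
    Summation order never affects the totals.
    """
    mins = transfer_profiles(model, ranges, "min")
    maxs = transfer_profiles(model, ranges, "max")
    unannotated = sorted(set(mins) - set(annotation))
    if unannotated:
        warnings.warn(
            f"metabolites without category annotation -> 'unclassified': "
            f"{unannotated}",
            RuntimeWarning,
            stacklevel=2,
        )
    categories = sorted(set(annotation.values()) | ({"unclassified"} if unannotated else set()))
    out = []
    for cat in categories:
        members = [m for m in mins if annotation.get(m, "unclassified") == cat]
        lo = np.sum([mins[m] for m in members], axis=0) if members else np.zeros(model.tpm_count)
        hi = np.sum([maxs[m] for m in members], axis=0) if members else np.zeros(model.tpm_count)
        out.append(CategoryProfile(category=cat, min_profile=lo, max_profile=hi))
    return out


def normalize_profile(series) -> np.ndarray:
    """Divide a per-TPM series by its maximum (peak value maps to 1.0)."""
    arr = np.asarray(series, dtype=float)
    peak = arr.max()
    if not math.isfinite(peak) or peak <= 0:
        raise ValueError("cannot normalize a profile with no positive value")
    return arr / peak
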