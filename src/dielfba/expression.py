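"""Transcript-derived flux bounds (the E-flux scheme) and noise robustness.

Per gene, the expression value at each TPM is divided by that gene's maximum
over all TPMs, giving a ratio in [0, 1] with no nonlinear (e.g. sigmoid)
transform. Per reaction, the GPR rule folds gene ratios with max over
isozymes (OR) and min over complex subunits (AND). The reaction's unscaled
upper bound — taken from the unsegmented base model so every TPM starts with
equal metabolic capacity — is multiplied by the ratio:

    v_jk^LB <= v_jk <= v_jk^UB * a_jk

Lower bounds of reversible reactions are left unscaled, exactly as the
constraint is written; ``scale_reversible_lb`` switches on symmetric
magnitude scaling (classic E-flux) for sensitivity analysis. Transfer
reactions, exchanges, and the biomass drain carry no transcript and are
never scaled.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .assemble import DielModel
from .gpr import evaluate_gpr
from .model import ConfigurationError
from .optimize import TAU, maximize_biomass, minimize_transfers


@dataclass
class ExpressionSeries:
    """Per-gene, per-TPM nonnegative expression values.

    Every included gene must have a value at every TPM (1..n_tpm); genes
    with partial coverage are rejected rather than imputed.
    """

    values: dict[tuple[str, int], float]
    n_tpm: int
    genes: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.genes:
            self.genes = {g for g, _ in self.values}
        incomplete = sorted(
            g for g in self.genes
            if any((g, k) not in self.values for k in range(1, self.n_tpm + 1))
        )
        if incomplete:
            raise ConfigurationError(
                f"genes missing values at some TPMs: {incomplete}"
            )
        negative = sorted({g for (g, _), v in self.values.items() if v < 0})
        if negative:
            raise ConfigurationError(f"negative expression values for: {negative}")

    def series(self, gene: str) -> np.ndarray:
        return np.array([self.values[(gene, k)] for k in range(1, self.n_tpm + 1)])

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ExpressionSeries":
        """Build from a table with a ``gene`` column and one column per TPM
        (``tpm1`` .. ``tpmK``, or plain integers)."""
        frame = frame.set_index("gene") if "gene" in frame.columns else frame
        cols = []
        for c in frame.columns:
            token = str(c)
            k = int(token[3:]) if token.startswith("tpm") else int(token)
            cols.append((k, c))
        cols.sort()
        values = {
            (str(g), k): float(frame.at[g, c])
            for g in frame.index
            for k, c in cols
        }
        return cls(values=values, n_tpm=len(cols))

    @classmethod
    def from_tsv(cls, path) -> "ExpressionSeries":
        return cls.from_frame(pd.read_csv(path, sep="\t"))


@dataclass
class RatioTable:
    """Per-reaction, per-TPM scaling factors a_jk in [0, 1] (default 1)."""

    a: dict[tuple[str, int], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = {k: v for k, v in self.a.items() if not (0.0 <= v <= 1.0)}
        if bad:
            raise ConfigurationError(f"ratios outside [0, 1]: {bad}")

    def get(self, reaction_id: str, tpm: int) -> float:
        return self.a.get((reaction_id, tpm), 1.0)


def compute_gene_ratios(expr: ExpressionSeries) -> dict[tuple[str, int], float]:
    """Normalize each gene's series by its maximum over TPMs.

    All-zero series are uninformative: they map to ratio 1 everywhere, with
    a warning, rather than shutting the reaction down.
    """
    ratios: dict[tuple[str, int], float] = {}
    flat = []
    for gene in sorted(expr.genes):
        series = expr.series(gene)
        peak = series.max()
        if peak <= 0:
            flat.append(gene)
            for k in range(1, expr.n_tpm + 1):
                ratios[(gene, k)] = 1.0
            continue
        for k in range(1, expr.n_tpm + 1):
            ratios[(gene, k)] = float(series[k - 1] / peak)
    if flat:
        warnings.warn(
            f"genes with all-zero expression treated as unconstrained: {flat}",
            RuntimeWarning,
            stacklevel=2,
        )
    return ratios


def reaction_ratios(
    model: DielModel, gene_ratios: dict[tuple[str, int], float]
) -> RatioTable:
    """Fold gene ratios through each reaction's GPR, per TPM.

    Genes absent from the table evaluate to 1; reactions with no GPR are
    omitted (implicit ratio 1).
    """
    table: dict[tuple[str, int], float] = {}
    for rxn in model.base.reactions:
        if not rxn.gpr.strip():
            continue
        for k in range(1, model.tpm_count + 1):
            per_gene = {
                g: gene_ratios[(g, k)]
                for g in rxn.genes()
                if (g, k) in gene_ratios
            }
            if not per_gene:
                continue
            table[(rxn.id, k)] = evaluate_gpr(rxn.gpr, per_gene)
    return RatioTable(a=table)


def apply_eflux(
    model: DielModel, ratios: RatioTable, scale_reversible_lb: bool = False
) -> DielModel:
    """Scale core-instance upper bounds by a_jk in place.

    The reference bound is the unsegmented base-model bound, so repeated
    application is idempotent for the same table. Transfers, exchanges, and
    the biomass drain are never touched. Pre-scaling bounds are recorded in
    ``model.unscaled_upper`` for active-bound detection.
    """
    biomass_id = model.base.biomass_reaction_id
    for inst in model.core_reactions:
        if inst.exchange or inst.base_id == biomass_id:
            continue
        a = ratios.get(inst.base_id, inst.tpm)
        if (inst.base_id, inst.tpm) not in ratios.a:
            continue
        model.unscaled_upper[inst.id] = inst.base_upper
        inst.upper_bound = inst.base_upper * a
        if scale_reversible_lb and inst.base_lower < 0:
            inst.lower_bound = inst.base_lower * a
        inst.lower_bound = min(inst.lower_bound, inst.upper_bound)
    return model


@dataclass
class NoiseResult:
    mean_deviation_pct: float
    per_replicate_pct: list[float]
    n_excluded: int
    n_infeasible: int


def noise_robustness(
    model: DielModel,
    expr: ExpressionSeries,
    n_reps: int,
    seed: int,
    tau: float = TAU,
) -> NoiseResult:
    """Gaussian perturbation of the normalized expression ratios.

    Per gene, the noise standard deviation equals the standard deviation of
    that gene's time-normalized series; perturbed ratios are clamped to
    [0, 1], the E-flux table rebuilt, and the biomass/pFBA cascade re-solved.
    The statistic is the mean over transferable metabolites and TPM
    boundaries of |perturbed - baseline| / max(|baseline|, tau) * 100,
    averaged over replicates. Boundary fluxes whose baseline magnitude is
    below tau are excluded (counted in ``n_excluded``); infeasible replicates
    are excluded and counted.

    ``model`` must be the assembled, unscaled diel model; it is never
    mutated (replicas are deep-copied).
    """
    rng = np.random.default_rng(seed)
    base_ratios = compute_gene_ratios(expr)
    sigma = {
        gene: float(np.std([base_ratios[(gene, k)]
                            for k in range(1, expr.n_tpm + 1)]))
        for gene in expr.genes
    }

    def solve_with(gene_ratios) -> FluxVector:
        replica = copy.deepcopy(model)
        apply_eflux(replica, reaction_ratios(replica, gene_ratios))
        biomass = maximize_biomass(replica)
        if not biomass.optimal:
            return None
        _, pfba = minimize_transfers(replica, biomass.objective_value)
        if not pfba.optimal:
            return None
        return {
            r.id: pfba.fluxes[r.id] for r in replica.transfer_reactions
        }

    baseline = solve_with(base_ratios)
    if baseline is None:
        raise ConfigurationError("baseline diel model is not solvable")
    included = [rid for rid, v in baseline.items() if abs(v) >= tau]
    n_excluded = len(baseline) - len(included)

    per_rep: list[float] = []
    n_infeasible = 0
    for _ in range(n_reps):
        perturbed = {}
        for gene in sorted(expr.genes):
            noise = rng.normal(0.0, sigma[gene], size=expr.n_tpm)
            for k in range(1, expr.n_tpm + 1):
                value = base_ratios[(gene, k)] + noise[k - 1]
                perturbed[(gene, k)] = float(min(1.0, max(0.0, value)))
        fluxes = solve_with(perturbed)
        if fluxes is None:
            n_infeasible += 1
            continue
        deviations = [
            abs(fluxes[rid] - baseline[rid]) / max(abs(baseline[rid]), tau) * 100.0
            for rid in included
        ]
        per_rep.append(float(np.mean(deviations)) if deviations else 0.0)
    mean_pct = float(np.mean(per_rep)) if per_rep else float("nan")
    return NoiseResult(
        mean_deviation_pct=mean_pct,
        per_replicate_pct=per_rep,
        n_excluded=n_excluded,
        n_infeasible=n_infeasible,
    )


FluxVector = dict[str, float] | None
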