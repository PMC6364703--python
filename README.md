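# dielfba

Multi-period flux balance analysis for organisms with a diel (light/dark)
lifestyle. Conventional FBA describes a single pseudo-steady state and so
averages away everything a cyanobacterium actually does over a day:
fix carbon and build storage in the light, then respire those reserves to
survive the dark. `dielfba` turns any base genome-scale metabolic model into
a cyclic sequence of K *time-point models* (TPMs), each a steady-state copy
of the network covering one slice of the 24-hour cycle, linked by
irreversible transfer pseudo-reactions that carry each metabolite's surplus
from TPM k to TPM k+1 (and from K back to 1, closing the cycle). A
metabolite may only be consumed in a TPM if it was produced there or carried
in from an earlier one, so the solution inventories metabolite accumulation
and remobilization over the whole cycle while remaining a single LP.

## The model

With stoichiometric coefficients S_ijk for metabolite i, reaction j, TPM k,
the core program is

```
max  v_biomass,K'                      (biomass drained in one TPM, K'=12)
s.t. sum_j S_ijk v_jk = 0              for all i, k   (per-TPM steady state)
     v_jk^LB <= v_jk <= v_jk^UB
     0 <= v_jk <= 10000                for transfer reactions
     v_CO2,k <= 1.1,  v_photon,k <= 60       for light TPMs only
     v_ATPM,k >= 10                          for every TPM
     v_photo,k <= 1/2 (net pigment synthesis in k) * M_C,   M_C = 1000
```

The last row gates every photosynthetic reaction on chlorophyll made during
the TPM (through the pigment mass balance this equals the difference between
the pigment transfer leaving and entering the TPM wherever the biomass drain
is inactive), so photosynthetic capacity must be paid for in pigment
synthesis. After the biomass maximum is found, a modified parsimonious FBA
re-solves with biomass pinned, minimizing the *sum of all transfer fluxes* f
— this suppresses thermodynamically infeasible cycling around the closed TPM
loop — and flux variability analysis then brackets every transfer flux
subject to the pinned biomass and the cap `sum of transfers <= f`.

On top of the cascade the package implements:

* **E-flux transcript constraints** — per gene, expression at each TPM is
  normalized by that gene's maximum over the cycle; GPR rules fold gene
  ratios with max over isozymes (OR) and min over complex subunits (AND);
  each reaction's upper bound becomes `UB_j * a_jk`.
* **A diazotrophy MILP** — nitrogen-fixation reactions are replicated into
  every TPM and per-TPM binaries enforce that nitrogenase (irreversibly
  poisoned by oxygen) never runs in a TPM whose oxygen transfer to the next
  TPM carries flux: `y_N2,k + y_O2,k <= 1` with big-M rows taken from each
  reaction's own bounds. Wild-type and diazotroph FVA envelopes are then
  classified per reaction (upregulated / downregulated / unchanged /
  switched / essential).
* **Downstream analyses** — detection of transcript bounds that actively
  limit growth; flux control coefficients
  `C = (dv_biomass/dx) * (x/v_biomass)` from a 1% bound perturbation;
  metabolite–metabolite correlation analysis (Spearman, two-sided, p < 0.05)
  on peak-normalized maximum transfer-flux profiles; category aggregation
  and peak-normalized accumulation curves.

A self-contained toy phototroph (photon/CO2 exchanges, pigment-gated
photosystem plus cyclic electron flow, carbon fixation, a glycogen-like
storage polymer, respiration, ATP maintenance, biomass) and a synthetic diel
transcriptome generator make every stage testable offline.

## Worked example

```python
from dielfba import fixtures as fx
from dielfba.assemble import assemble
from dielfba.expression import apply_eflux, compute_gene_ratios, reaction_ratios
from dielfba.optimize import maximize_biomass, minimize_transfers

spec = fx.ToySpec(n_tpm=12, n_light=6)          # 12 x 2 h, first 6 lit
base = fx.make_toy_gsm(spec)
model = assemble(base, fx.make_toy_config(spec))

expr = fx.toy_expression(base, spec.n_tpm, seed=1)
apply_eflux(model, reaction_ratios(model, compute_gene_ratios(expr)))

biomass = maximize_biomass(model)
budget, pfba = minimize_transfers(model, biomass.objective_value)
print(f"biomass optimum: {biomass.objective_value:.4f}")
print(f"transfer budget f: {budget.f:.4f}")
glycogen = [pfba.fluxes[model.transfer("glycogen", k).id] for k in range(1, 13)]
print("glycogen transfer k->k+1:", " ".join(f"{v:.2f}" for v in glycogen))
```

prints

```
biomass optimum: 2.3792
transfer budget f: 45.5183
glycogen transfer k->k+1: 1.09 1.92 2.76 3.59 4.42 5.25 4.92 4.58 4.25 3.89 3.51 0.00
```

The biomass optimum is the growth drain in TPM 12 under transcript-scaled
bounds (32% below the unconstrained optimum of 3.5 for this expression
program). The glycogen transfer profile is the storage inventory carried
across each TPM boundary: it climbs through the six light TPMs, peaks at the
light→dark boundary (5.25 after TPM 6), and is drawn down monotonically
through the dark as it fuels the 10 mmol gDW⁻¹ hr⁻¹ ATP maintenance demand —
the accumulate-then-drain signature of a storage polymer.

The same pipeline is scriptable from the shell (`dielfba fixtures`,
`dielfba build`, `dielfba solve`, `dielfba analyze` with a YAML config); run
`dielfba --help`.

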