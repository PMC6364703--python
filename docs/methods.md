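# Methods

## The diel multi-period model

A 24-hour light/dark cycle is discretized into K time-point models (TPMs),
each a full copy of the base stoichiometric network operating at pseudo
steady state for its interval (default K=12, 2 h per TPM, the first 6 lit).
Reaction copies are suffixed `_tpmX` and metabolite copies `[tpmX]`.
Coupling between periods is purely material: for every metabolite in a
transferable compartment (cytosol and carboxysome by default) an
irreversible transfer pseudo-reaction moves its surplus from TPM k to TPM
k+1, with a wrap edge K→1 closing the cycle so the solution is periodic.
Transfer fluxes are bounded in [0, 10 000] mmol gDW⁻¹ hr⁻¹; the forward-only
direction encodes that a metabolite can be consumed only after it has been
produced. Photons and protons are excluded from transfer by configuration:
carrying a transmembrane proton gradient across a two-hour boundary would be
an untenable energy store, so dark metabolism must run on real storage
compounds.

Phase structure enters through three bound families: CO2 uptake (≤ 1.1) and
photon uptake (≤ 60) are open only in light TPMs and forced to zero in the
dark; a basal ATP maintenance demand (≥ 10) applies to every TPM. All three
defaults are the organism-scale values for the reference cyanobacterial
instance; units are mmol gDW⁻¹ hr⁻¹ throughout. A single biomass drain is
active in one TPM (the last dark TPM by default; any TPM can be configured),
and the inactive biomass copies are bounded to zero rather than deleted so
that two strains always share an aligned reaction-instance universe.

## Pigment–photosynthesis coupling

Photosynthetic flux in a TPM is capped by the chlorophyll available during
that TPM. Approximating pigment growth within a TPM as linear, the average
pigment made in TPM k is half the net synthesis over the period, giving

    v_photo,k ≤ ½ · M_C · (pigment synthesis − degradation in TPM k)

for every configured photosynthesis reaction, with M_C = 1000 a constant
large enough not to constrain flux when pigment is present. Multiple pigment
species contribute their summed net synthesis. Through the pigment mass
balance, synthesis − degradation equals the difference between the pigment
transfer leaving the TPM and the one entering it wherever the biomass drain
is inactive, so this is equivalent to a cap written on transfer differences
in all such TPMs.

The constraint is deliberately written on the synthesis side rather than on
transfer differences. On a closed TPM cycle the transfer-difference form is
degenerate: every row forces its own difference to be nonnegative (the
photosynthesis fluxes it caps are nonnegative), the differences telescope to
exactly zero around the loop, and the only solutions pin photosynthesis to
zero. In the biomass TPM the pigment drain additionally makes the transfer
difference strictly negative, which is infeasible outright for irreversible
photosynthesis reactions. The synthesis-side form has neither defect,
reduces to the transfer-difference form wherever that form is
well-posed, and keeps the intended biology: photosynthetic capacity in each
TPM must be paid for with same-TPM pigment synthesis, an extra demand on the
pigment pathway beyond its role as a biomass precursor.

## The optimization cascade

1. **Biomass maximization** — a single LP (MILP when diazotrophy switches
   are present) maximizing the flux of the active biomass instance.
2. **Transfer-minimizing parsimonious FBA** — biomass is pinned at its
   optimum with an equality row and the sum of all transfer fluxes is
   minimized, yielding the transfer budget f. Because the TPM graph is a
   closed cycle, unpenalized transfers could carry arbitrary
   thermodynamically infeasible loop flux; minimizing the transfer sum
   removes it. If the equality is numerically infeasible the stage retries
   once with a relative slack of 1e−6 and warns.
3. **Flux variability analysis** — per target reaction (all transfer
   reactions by default), minimize and maximize its flux subject to the
   pinned biomass and `sum of transfers ≤ f` (an inequality, as the budget
   is a cap, not a quota). Results are order-independent; per-target solver
   failures are recorded without aborting the remaining targets.

LPs and MILPs are built with optlang on GLPK. Statuses are propagated
verbatim — an infeasible stage never reports silent zeros. The zero-flux
tolerance τ = 1e−6 mmol gDW⁻¹ hr⁻¹ is used by every downstream
classification. A separate audit (`check_unbounded_loops`) runs FVA on the
*base* model with all exchanges closed and flags any reaction that can still
carry flux — the standard pre-flight check that the input network is free of
unbounded thermodynamically infeasible cycles.

## Transcript-derived bounds (E-flux)

Per gene, the expression value at each TPM is divided by that gene's maximum
over all TPMs — a linear ratio in [0, 1], with no sigmoid or other
nonlinear transform. Genes whose series is all zero are treated as
uninformative (ratio 1, warned) rather than shutting their reactions. Per
reaction and TPM, the GPR boolean rule is folded over gene ratios: OR nodes
(isozymes) take the maximum child, AND nodes (complex subunits) the minimum;
genes absent from the table evaluate to 1. The reaction's upper bound
becomes `UB_j · a_jk`, where UB_j is the *base-model* bound, so every TPM
has equal capacity before the data enter. Lower bounds of reversible
reactions are not scaled, exactly as the constraint is written; a
`scale_reversible_lb` switch enables symmetric magnitude scaling for
sensitivity analysis. Transfer reactions, exchanges, and the biomass drain
carry no transcript and are never scaled.

GPR parsing accepts case-insensitive `and`/`or` with parentheses and
arbitrary whitespace-delimited gene tokens; a hand-written recursive-descent
parser reports malformed input with the failing position. (COBRApy's parser
was not used here because it requires gene ids to be valid Python
identifiers.)

**Noise robustness.** The link between transcript and protein is noisy, so
the pipeline can replay itself under perturbed ratios: per gene, Gaussian
noise with standard deviation equal to the standard deviation of that gene's
time-normalized series is added to the normalized ratios (the constraint
consumes ratios, so noise is applied in ratio space), clamped to [0, 1];
the cascade is re-solved and the transfer fluxes compared to baseline. The
statistic is the mean over transferable metabolites and TPM boundaries of
|perturbed − baseline| / max(|baseline|, τ) × 100, averaged over seeded
replicates; boundary fluxes with baseline below τ are excluded (counted),
and infeasible replicates are dropped (counted). On the toy instance this
deviation is large (∼75–100% depending on seed): the toy has essentially one
route per function, so a perturbed bound propagates directly into the
transfer program, whereas a genome-scale network's pathway redundancy
buffers most perturbations. The number is a property of the fixture, not of
the method.

## Diazotrophy

Nitrogen fixation is added as a reaction set — the ATP-hydrolyzing reduced-
ferredoxin:dinitrogen oxidoreductase (16 ATP and 8 reduced-ferredoxin
equivalents per N2) plus the N2 exchange and the extracellular→periplasm→
cytosol diffusion chain — replicated into every TPM; the chain is verified
to reach the cytosol before anything is added. Nitrogenase is irreversibly
inhibited by oxygen, so fixation in TPM k is allowed only if the cell has
consumed its oxygen within the period, i.e. the oxygen transfer k→k+1 is
off. Per TPM, binaries y_N2 and y_O2 gate the fixation instance and the
oxygen transfer through big-M rows built from each reaction's own bounds
(no global M), and y_N2 + y_O2 ≤ 1 enforces exclusion. Only the inter-TPM
oxygen transfer is gated — the extracellular oxygen exchange is not, as the
exclusion concerns intracellular oxygen carried into the fixation window.

After the MILP is solved the incumbent binary pattern is frozen into the
switches, so the pFBA stage and FVA run as plain LPs over a fixed fixation
schedule (clearing `switch.fixed` re-enables free binaries for sensitivity
checks at MILP cost). Strain comparison classifies each shared reaction
instance from the two FVA envelopes: upregulated iff mut_min > wt_max + τ,
downregulated iff mut_max < wt_min − τ, otherwise unchanged; `switched`
flags envelopes excluding zero with opposite signs, and essentiality means a
strictly positive or strictly negative envelope. One record can legitimately
carry several labels (e.g. downregulated + switched + essential in both), so
records expose a primary direction token plus a label set. Unique-reaction
counts deduplicate instances by base reaction id across TPMs.

## Downstream analyses

**Active bounds.** An instance is flagged when its FVA maximum equals its
transcript-scaled upper bound within τ·max(1, |bound|) *and* the scaled
bound sits strictly below the unscaled base bound — i.e. the data, not the
network, limit growth there. Reported as instances plus the deduplicated
unique-reaction count.

**Flux control coefficients.** For each transcript-constrained instance the
scaled bound x (the transcript standing in for the enzyme level) is
perturbed by 1% and biomass re-maximized:
C = (Δv_biomass/Δx)·(x/v_biomass). The default perturbation *tightens* the
bound, since tightening a binding constraint always produces a measurable
response while loosening a saturated one may not; the direction is
configurable. Coefficients within τ of zero are reported as exactly 0;
infeasible perturbations are marked undefined, never zero. Exchange,
transfer and biomass instances carry no transcript bound and are excluded.
Because growth is affine (not linear) in a controlling bound when fixed
demands such as ATP maintenance are present, a fully controlling bound
yields C slightly above 1.

**MMCA.** Each metabolite's per-TPM maximum transfer flux (from FVA) is
peak-normalized and used as a concentration proxy; all-zero profiles are
dropped. Pairwise Spearman rank correlations use mid-ranks for ties.
Two-sided p-values come from exact permutation enumeration for profiles of
length ≤ 7 and from the large-sample approximation above that (the exact
table at n=9 would cost 362 880 permutations per metabolite pair for no
practical gain at this scale). Significance is flagged at α = 0.05 with no
multiple-testing correction by default, matching the analysis convention of
the reference instance; `correction="bh"` switches the significance call to
Benjamini–Hochberg at the same level. Correlation needs at least 3 TPMs.

**Categories and profiles.** Per user-supplied annotation, member
metabolites' FVA minima and maxima are summed per category and TPM
(unannotated metabolites fall into `unclassified`, warned); accumulation
profiles are normalized by their cycle maximum, so the peak maps to 1.0.

## The toy fixture

The generator emulates a minimal oxygenic phototroph with integer
stoichiometry so oracle LPs are exact: photon/CO2/O2/ammonium exchanges, a
pigment-gated photosystem (4 photons → 2 ATP + 2 NADPH + O2), cyclic
electron flow (2 photons → 2 ATP, no O2 — without it the light phase is
ATP-starved relative to the 18 ATP : 12 NADPH demand of fixation, as in real
thylakoids), pigment synthesis, carbon fixation to a hexose, a glycogen-like
polymer (synthesis costs 1 ATP, phosphorolytic mobilization is free),
aerobic respiration (30 ATP per hexose), an ATP maintenance drain, and a
biomass sink consuming hexose + pigment + 2 ammonium + 10 ATP. Enzymatic
capacities are modest constants (photosystem 20, fixation 3, respiration 2,
storage 5, pigment 5) rather than the generic 10 000 cap, so transcript
scaling can genuinely become limiting. ATP, NADPH, hexose and reduced
ferredoxin are declared non-transferable, making the glycogen analogue the
only storage route — dark maintenance then *forces* a positive storage
transfer across the light→dark boundary, which the tests assert. The toy
CO2 uptake cap is 5.0 rather than the organism-scale 1.1: the toy's
respiration yield cannot cover the 10 mmol gDW⁻¹ hr⁻¹ dark maintenance at
the organism-scale cap. Synthetic expression uses raised-cosine diel shapes
discretized at TPM midpoints (light-peaking for photosynthesis, fixation and
pigment genes; dark-peaking for respiration and storage mobilization), with
constant and seeded-noise shapes available.

What the toy does *not* emulate: pathway redundancy and isozyme multiplicity
(hence its high noise sensitivity), realistic biomass composition, membrane
energetics, photoinhibition, and any organism-scale parameter fitting.
Passing tests demonstrate the correctness of the machinery — replication,
transfer topology, coupling, cascade optimality against independent dense-
matrix LPs, MILP optimality against exhaustive enumeration, and the
statistics against hand computations — not quantitative agreement with any
real organism.

## Problem sizes and numerical choices

The test suite runs the cascade on K=4–6 fixtures (≤ 30 base reactions;
five-fixture oracle sweep, 81-pattern MILP enumeration at K=4) and the
acceptance script uses K=12 for the diel study with 10 noise replicates —
sizes at which GLPK and HiGHS agree to well below the 1e−6 relative
tolerance asserted. Ties in FVA alternate optima are immaterial because only
envelope endpoints are compared. Degenerate inputs are rejected early:
models with duplicate ids, unresolved stoichiometry, inverted bounds,
exchanges touching more than one metabolite, expression tables with partial
gene coverage, ratios outside [0, 1], and biomass placement outside 1..K all
raise configuration errors naming the offender.
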