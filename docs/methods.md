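# Methods

## The mass-balance model

`limnoweb` models a lake ecosystem as functional groups exchanging biomass
at steady state.  For every living group *i*,

    B_i (P/B)_i EE_i = Σ_j B_j (Q/B)_j DC_ji + EX_i

production used inside the system (left) equals predation plus exports
(right).  `EX` is fishery landings plus (optional) net migration and biomass
accumulation, both zero by default.  The diet matrix `DC` is
column-stochastic over each consumer's in-system prey; an import row is
carried but zero in the bundled model.

**Solver.**  The equation is linear in every unknown.  Unknown biomasses
(groups whose EE is specified instead) are collected into one linear system
— the unknown appears in its own production term and wherever it acts as a
predator — and solved exactly with `numpy.linalg.solve`; unknown EEs then
follow by substitution.  The result is independent of group order, and
cannibalism needs no special casing.  A structurally singular system (e.g. a
cannibal whose production demand exactly cancels its self-predation) raises
an error naming the groups involved.  EE outside [0, 1] does not abort: the
model is returned flagged `unbalanced` so the re-balancing routine can act.

**Derived statistics** per consumer, with `GS` the unassimilated fraction
of consumption: assimilation `A = Q(1−GS)`, respiration `R = A − P`, net
efficiency `P/A`, flow to detritus `FD = GS·Q + (1−EE)·P` (producers
contribute `(1−EE)·P`).  Negative respiration (P > A) flags the group as
thermodynamically inconsistent.  The detritus pool has no production of its
own; its EE is consumption-by-detritivores / total inflow, and its
omnivory index is the inflow-weighted variance of contributor trophic
levels — conventions that mirror the standard ecosystem-summary output.

**Key defaults.**  `GS = 0.2` for every consumer (the conventional value
for fish and aquatic invertebrates; it reproduces the published respiration
and detritus flows of the bundled model exactly).  Detritus biomass defaults
to the value supplied by the user; the empirical standing-stock relation
(`log10 D = 0.954 log10 PP + 0.863 log10 E − 2.41`, euphotic depth
`E = 2.5 × Secchi depth`) is available as an estimator but is not used to
overwrite an explicit input.

## The bundled Kaptai Lake model

Fifteen groups (ten fish, Whisker Shrimp, Insects/larvae, Zooplankton,
Phytoplankton, Detritus) with published biomass, P/B, Q/B, diets and 2024
landings; landings in whole-lake tonnes are converted with the 583 km²
water surface.  Snakehead biomass is unknown with EE fixed at 0.95.  Two
reconstruction choices are documented in the fixture source:

- the published diet proportions are rounded to 3–4 digits and four columns
  sum to 0.999–1.0023; exact stochasticity is restored by absorbing each
  column's residual into its largest entry, leaving all other printed
  proportions untouched;
- the Whisker Shrimp landing is absent from the published landings table
  and is back-derived from the balance identity with the published shrimp
  B, P/B and EE (0.982), giving 0.21143 t/km²/yr, frozen in the fixture.

The published flows-into-detritus total (1550.573 t/km²/yr in the summary
table) is internally consistent with Σ FD and is the value this package
reproduces; the alternative in-text figure of 2385.1 is not.

## Trophic structure

Fractional trophic levels solve `TL_i = 1 + Σ_j DC_ji TL_j` with producers
and detritus pinned at 1 (exact linear solve).  The omnivory index is the
diet-weighted variance of prey TLs about `TL_i − 1`.

**Lindeman spine.**  Groups are split across integer levels by the
flow-fraction recursion: non-consumers are 100% level 1; a consumer's
level-(k+1) share is the diet-weighted mean of its prey's level-k shares.
Consumption, predation losses, catches, respiration and detritus flows are
apportioned by those shares; the flow from level k to k+1 is the predation
on level-k parts.  **Cannibalism is netted out first** (self-predation
removed from both consumption and predation, columns renormalised): a
self-loop would otherwise smear a group across ever-higher levels and
roughly double the apparent level-2→3 transfer in the bundled model.  With
this convention the spine closes exactly (per-level inflow = outflows) and
reproduces the published inter-level flows.  Producer- and detritus-origin
pathways are tracked by running the same recursion from origin-specific
level-1 masses, which partitions every level's throughput, transfers and
exports by origin.  Transfer efficiency at level k is
`(flow to k+1 + catches at k) / inflow at k`; the headline "mean TE" is the
geometric mean over levels II–IV (configurable).

## Whole-system indices

- TST = consumption + exports + respiration + flows into detritus (the
  detritus surplus — inflow not re-consumed — leaves as an export).
- TNPP = Σ producer `B·P/B`; NSP = TNPP − respiration; on a web without
  imports NSP equals total exports.
- MTLc is the landings-weighted mean trophic level; gross efficiency is
  catch/TNPP; Shannon diversity uses natural logs on living-biomass shares.
- Connectance counts realized diet links over `N_living²` by default
  (`N(N−1)` selectable).  The system omnivory index is the
  log-consumption-weighted mean of consumer OIs; this documented convention
  yields 0.083 on the bundled model versus the published 0.166, whose exact
  weighting is not stated — SOI is reported but not treated as a
  reproduction target.
- Finn's cycling: with `G` the flow matrix column-normalised by compartment
  inflow and `L = (I − G)⁻¹`, the cycled share of compartment j's
  throughput is `(L_jj − 1)/L_jj`; FCI is cycled throughput as % of TST,
  and FMPL = TST / (exports + respiration).
- Ascendancy/overhead follow the information-theoretic decomposition
  `A = Σ T_ij log2(T_ij T·· / T_i· T·_j)`, `C = −Σ T_ij log2(T_ij/T··)`,
  `O = C − A`, on the compartment matrix extended with import, export and
  dissipation nodes.  Primary production is *not* routed through the import
  node — producers are source compartments — which is the convention that
  matches the published ascendancy of the bundled model (32.09% of
  capacity).  Percentages are base- and scale-invariant.
- A pedigree scaffold aggregates user-supplied per-parameter data-quality
  scores; no scores are bundled, so no pedigree value is reproduced.

## Impacts and overlap

Net impact of group i on j combines benefit as food (`DC_ij`) and harm as a
predator (share of j's predation-plus-catch mortality taken by i); the MTI
matrix is `(I − q)⁻¹ − I`, i.e. the sum over all direct and indirect impact
paths whenever that series converges (the inverse is used regardless).  The
fishing fleet enters as a consumer whose diet is the landings composition
and as a mortality agent via catch shares.  Total impact
`ε_i = sqrt(Σ_{j≠i} m_ij²)` excludes the fleet column; relative total
impact is `ε/max ε` over functional groups; keystoneness is
`log10(ε_i (1 − p_i))` with `p_i` the living-biomass share (a rank-based
penalty variant is selectable; the biomass-share variant is the default
because it reproduces the published keystone ranking).

Pianka overlap is the normalised inner product of two groups' diet columns
(prey overlap) or of their predation-mortality compositions (predator
overlap, defined here as each group's vector of predator shares of its
total predation, since the source analyses do not state a formula).  The
0.2 display threshold used in published overlap plots is a reporting filter
only.

## Automated re-balancing

When any EE exceeds 1, the worst offender (highest EE, ties by index) is
treated first: the predator link carrying the largest predation flow on it
is reduced by `step_fraction` (default 10%) of its diet proportion, and the
removed share is redistributed over the predator's other prey with weights
`(DC_max − DC_mean)` computed across each prey's current predators (prey
with flat predator profiles fall back to the predator's own diet
proportions).  Columns remain exactly stochastic and predator consumption
is untouched.  The procedure is one interpretation of the published
redistribution rule, whose ensemble ("max"/"mean" over what) is not fully
defined; the reading and the step size are configurable, every edit is
audited, and no claim of equivalence with any particular software's
internal routine is made.  Non-convergence within `max_iter` returns the
best model with a flag rather than raising.

## Synthetic webs

The generator emulates the bundled model's shape: 1+ producers, a detritus
pool, consumers in trophic layers with sparse Dirichlet-sampled diets
biased to lower layers, P/Q in [0.05, 0.3], biomass and Q/B declining up
the layers.  EEs are set by construction: predation is computed forward and
per-group landings (fishing pressure, the free variable) are chosen so
every living EE lands in the requested interval; consumer biomasses are
shrunk when predation alone exceeds the EE ceiling.  `has_detritus=False`
keeps the pool as an inert sink (no detritivory), making cannibalism-free
webs exactly acyclic.  All draws come from one seeded generator; the seed
is recorded in the ground-truth ledger.

What the generator does *not* emulate: imports, multi-fleet fisheries,
migration/accumulation terms, realistic taxonomic structure, or parameter
uncertainty.  Passing the recovery and oracle tests therefore demonstrates
the correctness of the algebra and the algorithms, not the realism of any
particular lake parameterisation.

## Numerical choices and limitations

- Diet columns are validated to sum to 1 within 1e-6 on load; balance
  residuals are checked at 1e-9 relative; spine closure at 1e-6 relative.
- The level decomposition is truncated when the remaining mass per level
  falls below 1e-12 (row sums then hold to better than 1e-9).
- The MTI path-sum equivalence is asserted only below spectral radius 1;
  realistic webs (including the bundled one, ρ ≈ 1.25) can exceed it while
  `(I − q)` remains invertible.
- Solved values differ from published ones in the third decimal in places
  (e.g. Snakehead biomass 0.072 vs 0.073) because the published inputs are
  rounded to 3–4 digits; all reproduction tests pass at tolerances
  consistent with that input precision.
- Dynamic (time- or space-resolved) simulation is out of scope, as are
  GIS outputs and the published historical-landings trend analyses.
- Problem sizes used in tests and the acceptance script: the 15-group
  bundled model and synthetic webs of 4–13 groups, 100 webs for the
  parameter-recovery property; the whole suite runs in a few seconds.
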