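# Methods

## Model

A metabolic network at steady state satisfies mass balance
`S (v_f - v_r) + S_e v_e = 0`, where `S` (M metabolites × N internal
reactions) and `S_e` (M × K exchange reactions) split the stoichiometry at
the system boundary, and every internal net flux is represented as the
difference of non-negative forward and reverse components,
`v = v_f - v_r` (mmol g⁻¹ h⁻¹). A reaction is classified as exchange when
its stoichiometry is one-sided (pure source or sink); a biomass
pseudo-reaction fixed to a measured growth rate can be forced into the
exchange partition via `load_sbml(..., boundary_ids=...)`.

The solver maximises the expression-weighted flux entropy

```
H_g(v) = - v_fᵀ (log v_f - log g) - v_rᵀ (log v_r - log g)
```

subject to mass balance and, for every reaction `i` in the irreversible
set `I` (model lower bound ≥ 0), the net-flux inequality
`v_f,i - v_r,i ≥ 0`. Maximising `H_g` is equivalent to minimising the
Kullback–Leibler divergence between the flux distribution and the
expression-derived reference distribution `g`: the result is the least
biased fluxome consistent with the measured exchanges, the stoichiometry
and the directionality priors. Exchange fluxes are decision variables
bounded by model/configuration intervals and carry no objective term;
measured exchanges are equalities.

Three modes are exposed:

* `teraflux` — full split of every internal reaction plus the
  irreversibility inequalities (the default);
* `all_reversible` — full split, inequalities dropped: the classical
  all-reversible variational formulation, used as a control (on the toy
  loop network it reverses the nominally irreversible leg);
* `pheflux` — irreversible reactions keep a single non-negative variable
  and only reversible reactions are split. Because the single log term
  forces interior (strictly positive) flux, this mode can recirculate flux
  through infeasible loops, which is exactly the pathology the full-split
  formulation removes.

## Duals as thermodynamic quantities

At the optimum, stationarity gives `v_f = (g/e) exp(θ)` and
`v_r = (g/e) exp(-θ)` with `θ = Sᵀλ + α`, where `λ` are the mass-balance
multipliers and `α ≥ 0` the irreversibility multipliers. Two consequences
are load-bearing and asserted in the test suite:

* **Product invariant.** `v_f · v_r = (g/e)²` for every split reaction at
  any interior optimum, including blocked ones.
* **Chemical potentials.** `μ = -2RT λ*` and `ΔG = Sᵀμ`; equivalently
  `ΔG = RT ln(v_r/v_f) + 2RT α`. Both routes must agree at a converged
  optimum (the package checks them against each other at 10⁻⁴ kJ mol⁻¹).

A note on the sign of `α`. The package reports `α ≥ 0` as the *unspent
driving force* dual: it is zero for all reversible reactions and all
flux-carrying irreversible reactions, and positive exactly on irreversible
reactions blocked at zero net flux. For such a blocked reaction
`v_f = v_r`, so the log-ratio vanishes and `ΔG = +2RT α ≥ 0`: the reverse
direction is thermodynamically favourable but kinetically forbidden, and
`2RTα` measures the magnitude of that unexploited driving force. This is
forced by the KKT conditions — a reaction blocked by a *binding*
irreversibility constraint necessarily has its driving force pointing
against the allowed direction (otherwise the constraint would be slack and
the reaction active). Writing the relation with the multiplier on the
other side (`RT ln(v_r/v_f) = ΔG + 2RTα`) is equivalent with `α` of the
opposite sign; the API pins the non-negative convention because it matches
the "unspent driving force" reading and gives clean complementary
slackness (`α · v = 0`).

For active reactions (`|v| > 10⁻⁶ mmol g⁻¹ h⁻¹`, the configurable
`active_flux_threshold`), `sign(v)·ΔG < 0` always holds — the flux–force
relation. This is what excludes thermodynamically infeasible cycles: a
sign-aligned circulation `y` in the null space of `S` would satisfy
`Σ y_j ΔG_j = (S y)ᵀ μ = 0` while every term is strictly negative, a
contradiction. The cycle-witness oracle (`find_infeasible_cycle`) makes the
converse check operational: it solves a small LP for a circulation
supported on active reactions, sign-aligned with their fluxes and
normalised to `‖y‖₁ = 1`, and returns the witness or `None`.

## Numerical scheme

The strictly convex program is solved in two stages:

1. **Interior-point stage.** SciPy's `trust-constr` on the split variables
   with analytic gradient and (diagonal) Hessian, bounds
   `v_f, v_r ≥ flux_floor` (default 10⁻¹⁰ — far below the active
   threshold, so a floored flux never masquerades as an active one), the
   mass balance as a linear equality and the irreversibility rows as
   linear inequalities. The start point splits a mass-balanced LP point
   around the symmetric core `v_f = v_r = g`, so the initial iterate is
   equality-feasible; an alternative purely symmetric start is exposed as
   `initialization="symmetric"` and is used to verify solution uniqueness.
2. **Newton polish.** The reduced KKT system in `(λ, interior exchange
   fluxes, active-constraint multipliers)` — with the primal eliminated
   through the explicit map `v(θ)` — is square; a damped Newton iteration
   (step capped at `|Δθ|∞ ≤ 2`) drives the residuals to ~10⁻¹² and yields
   the duals with a backend-independent sign convention. An active-set
   outer loop adds violated irreversibility constraints and drops
   constraints with negative multipliers (at most six passes). If the
   polish cannot converge, the trust-constr primal is kept and duals fall
   back to a stationarity least-squares estimate, recorded in
   `diagnostics["polish"]`; if the backend itself also failed, the solve
   raises instead of returning silently.

Reactions whose forward or reverse component sits at the floor (possible
when a floor-weighted reaction is forced to carry flux) are excluded from
the stationarity rows and flagged; their ratio-route ΔG is reported as NaN
rather than a wrong number. Degenerate inputs are kept: a reaction with
`g` at the floor still enters the objective (removal would change the
duals). The solver itself uses no random numbers; `λ` is computed by
minimum-norm least squares when the stoichiometry has dependent rows
(conserved moieties), which fixes the gauge freedom of the potentials.

Matrices are dense; the intended scale is toy-to-medium networks
(hundreds of reactions). Genome-scale use would want sparse factorisation
in both stages.

## Expression weights

`g` is one positive weight per internal reaction, obtained by evaluating
the reaction's GPR rule on a normalised expression table (TPM/FPKM/
quantile units; upstream normalisation is out of scope): AND → minimum
(a complex limited by its scarcest subunit), OR → sum (isozymes add
capacity). Missing genes and empty rules fall back to a floor, by default
`10⁻⁶ ×` the median nonzero rule-backed weight, keeping `log g` finite
without letting unmeasured reactions matter. Weights are normalised to sum
to 1 by default; because total flux is not fixed, the scale of `g` shifts
the optimum, so the choice is explicit (`normalize=`) and recorded on the
`ReactionWeights` object. Expression weighs forward and reverse fluxes
symmetrically; asymmetric weighting is deliberately not attempted. The
simulated-expression mode `g = max(|v|, floor)` bypasses GPR evaluation
and is the convention used throughout the cycle-elimination tests.

## Thermodynamic variability analysis

For one condition, the TVA linear program has decision variables
`Δ_rG′°_j` (standard transformed reaction energies) and `ln c_i`
(log metabolite concentrations), coupled by
`ΔG_j = Δ_rG′°_j + RT Σ_i S_ij ln c_i` with:

* `Δ_rG′°_j ∈ γ_j ± 2.58 σ_j` — a 99% confidence box around the supplied
  component-contribution means (`γ`, `σ` are consumed from a TSV and are
  properties of that table, e.g. pH 7.0, I = 0.15 M; they are not
  recomputed here);
* `ln c_i ∈ [ln 10⁻⁶, ln 10⁻¹]` — physiological concentrations 1 μM to
  100 mM (mol L⁻¹), individually overridable; water and protons carry no
  concentration variable (standard transformed-energy convention,
  configurable exclusion list);
* `sign(v_j) ΔG_j ≤ -ε` for every active reaction, with
  `ε = 10⁻³ kJ mol⁻¹` the minimum driving force.

All direction constraints share one variable set, so the condition is
either globally feasible or globally infeasible; per-reaction
`[ΔG_min, ΔG_max]` come from a min and a max LP each (SciPy HiGHS).
Enlarging the concentration box can only widen the intervals (asserted as
a property test). The consistency score is the fraction of active internal
reactions whose solver-inferred ΔG lies inside its TVA interval, with a
caller-supplied exclusion list (e.g. extracellular transports, which mix
compartment potentials).

`RT` defaults to 2.4789 kJ mol⁻¹ (298.15 K) and is configurable through
the temperature everywhere it appears.

## Synthetic data

The fixtures module generates every tested input:

* `fig1` — the worked two-metabolite loop (uptake fixed at 10; the
  irreversible return leg must end at exactly zero net flux);
* `infeasible_pair` — two antiparallel reactions with no cosubstrate; the
  internal null space contains the circulation (1, 1);
* `feasible_coupled_loop` — a two-leg cycle whose forward leg consumes a
  cofactor supplied and drained across the boundary; the aligned
  circulation is *not* internally balanced, so the cycle is
  thermodynamically legitimate and must keep its flux;
* `random_loopy` — a seeded reversible chain with random shortcut
  reactions and a planted three-reaction off-chain cycle, guaranteeing at
  least one null-space circulation per network.

Fluxomes are drawn by a null-space hit-and-run chain over
`{S v + S_e v_e = 0, bounds}` (burn-in 1000, thinning 10, both
configurable; pinned exchanges are folded into the equality system so the
walk stays interior). Default conditions mirror the unconstrained-sampling
regime the method is meant to repair: wide internal bounds
±30 000 mmol g⁻¹ h⁻¹ with substrate uptake capped at 10 mmol g⁻¹ h⁻¹.
Simulated expression sets `g = |v|` from a sampled fluxome, and the
sampled uptake value is pinned as the measured exchange for the
subsequent solve.

What these fixtures emulate — and what they do not: they reproduce the
*structural* phenomena (circulations inflated by sampling, their
elimination by the solver, preservation of cofactor-coupled cycles,
dual-route thermodynamic agreement) on networks of a dozen reactions. They
do not emulate genome-scale degeneracy, realistic GPR complexity,
measurement noise in expression data, or compartmentalisation; passing
tests therefore demonstrate correctness of the method, not its published
predictive accuracy on organisms, which requires external genome-scale
models and transcriptome/fluxome datasets. One consequence worth noting:
the relative *entropy* of sampled versus solved fluxomes is
geometry-dependent at this scale (in small dense networks, wide-bound
samples spread mass over most reactions), so the desk-scale suite asserts
the robust magnitude signature (sampled cycle fluxes orders of magnitude
above the solver's, which never approaches the sampling bounds) rather
than an entropy ordering.

## Evaluation metrics

Fluxome entropy is the Shannon entropy (bits) of `p_j = |v_j| / Σ|v_k|`
over internal net fluxes — exchanges excluded, net not split fluxes; any
cross-study comparison of absolute bit values depends on this definition,
which is why it is stated here. `compare()` reports MSE, Pearson r, and
Pearson r after an elementwise arcsinh transform (compressing the
power-law flux range so dominant reactions cannot mask the rest), each
with a seeded bootstrap CI over reaction pairs (n = 1000 resamples,
percentile intervals). Reaction mapping between predicted and reference
fluxomes is an explicit user-supplied table (id, id, sign); no fuzzy name
matching. A Welch t-test helper compares entropy sets; no multiple-testing
correction is applied (single planned comparisons).

## Known limitations

* Dense linear algebra throughout; genome-scale models will work but not
  at the published speed envelope.
* The hit-and-run sampler is a simple fixture-grade chain, not a
  production sampler; its mixing on high-dimensional polytopes is slow.
* Pheflux mode returns primal fluxes and diagnostics only; its duals do
  not carry the thermodynamic interpretation (the mode exists as the
  published comparison point, and lacks the structure that grants it).
* TVA treats one compartment; membrane potential and pH gradients for
  transporters are out of scope, which is why transport reactions are
  conventionally excluded from consistency scoring.
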