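# Methods

`fedscreen` implements an adaptive model-calibration loop for parallel
fed-batch screening of E. coli clones in mini-bioreactors, together with a
virtual plant that emulates the robotic facility so the whole loop runs —
and can be tested — entirely in silico.

## The growth model

Five ODE states describe one culture: biomass `X`, glucose `S`, acetate
`A`, dissolved oxygen tension `DOT` (% air saturation) and polymeric
glucose equivalents `P` (enzymatic glucose release; zero in the main
culture). The broth volume `V` changes only at discrete pipetting events
and does not enter the concentration dynamics.

Specific rates (g g⁻¹ h⁻¹):

    qS   = qSmax · S/(S+Ks) · DOT/(DOT+Ko)        total glucose uptake
    qSof = pAmax · qS/(qS+Kap)                    overflow branch
    qSox = qS − qSof                              oxidative branch
    qAc  = qAmax · A/(A+Kaq) · Ksq/(Ksq+S)        acetate re-consumption
    µ    = (qSox−qm)⁺·Yem + qSof·Yofm + qAc·Yam
    qO   = (qSox−qm)⁺·Yosresp + qAc·Yaresp

and the balances

    dX/dt   = µX
    dS/dt   = −qS·X + kP·P
    dA/dt   = (Yaof·qSof − qAc)·X
    dDOT/dt = kLa·(DOT* − DOT) − qO·X·H,   H = DOT*/cO2sat
    dP/dt   = −kP·P

Thirteen parameters are clone-specific and estimable (`qAmax, Kaq, Ksq,
Yam, Yaresp, Yem, qSmax, Ks, Ko, Yosresp, pAmax, Yaof, Yofm`); five are
fixed by the operating setup (`qm = 0.04 g g⁻¹ h⁻¹`, `Kap`, `kLa`,
`DOT* = 100 %`, `kP = 0`). `Ko` is carried in % DOT: fitted values of
order 10 are only physical on that scale. The `(x)⁺` clamp on the
oxidative term prevents negative growth at vanishing substrate;
maintenance-starvation dynamics are out of scope.

Two fixed constants deserve comment because the model's qualitative
behavior hinges on them:

* **Kap = 2.0 g g⁻¹ h⁻¹.** The overflow branch `qSof = pAmax·qS/(qS+Kap)`
  exceeds *total* uptake whenever `pAmax > qS + Kap`. With fitted `pAmax`
  up to ≈1.6, any `Kap < 1.6` makes the model overflow-dominated at the
  low uptake rates of glucose-limited feeding — acetate would accumulate
  throughout the fed-batch, contradicting the observed behavior of these
  cultivations. `Kap ≥ max pAmax` keeps the branch sub-total everywhere.
* **kLa = 1000 h⁻¹.** The robot's maximum feed (22 µL of 400 g/L glucose
  every 5 min into ≈11 mL) demands ≈0.64 g O₂ L⁻¹ h⁻¹ when fully
  oxidized. The facility's design premise — glucose limitation maintained
  up to the feed cap — requires the reactor's oxygen transfer to cover
  that demand; 1000 h⁻¹ is in the documented range of 10-mL
  mini-bioreactors at 3000 rpm and is the smallest round value that
  satisfies it. Late in a run, cultures still approach the oxygen-transfer
  ceiling (X ≈ 13–20 g/L), which throttles uptake through the
  `DOT/(DOT+Ko)` factor; this is physical and the adaptive loop responds
  by shrinking subsequent feeds.

`cO2sat = 0.0067 g/L` is the oxygen solubility at 37 °C used to convert
the oxygen uptake rate to %-DOT units.

### Integration

`simulate()` integrates with LSODA (via `scipy.integrate.odeint`, one call
per inter-event segment, the right-hand side compiled with numba). Because
`V` never enters the concentration dynamics, only *additions* (feed
pulses) interrupt the integrator; sample draws update the precomputed
volume step-function only. Defaults `rtol = 1e-6`,
`atol = (1e-8, 1e-8, 1e-8, 1e-6, 1e-8)` (DOT lives on a 0–100 scale).
Halving the tolerances moves reported states by < 1e-4 relative (tested);
against a tight BDF reference the error is below 1e-4 relative. Output
times that coincide with an event report the post-event state.

## Virtual plant

The generator emulates the facility's measurement process, not just its
model: online DOT every 20 s (1440 points per 8-h run), 23 at-line
biomass samples on a 20-min rhythm from 0.4 h, 20 glucose and 20 acetate
samples sharing that rhythm from 1.4 h (1503 records per reactor in
total); at-line results arrive late — biomass after 0.25–1.35 h, glucose
and acetate after 0.66–2 h, linear in the reactor's column index; each
draw removes 150 µL. Biomass is reported through the full OD600 path
(DCW → 1-cm-corrected OD (×2.62) → dilution into the linear range
(20–100×) → DCW = OD·dilution·2.62·0.33), which is exactly invertible and
exercises the conversion code. Noise is multiplicative Gaussian with
relative σ 0.15 for biomass/glucose/acetate and 0.05 for DOT, clipped at
zero, drawn positionally per record so that extending a run never rewrites
history.

Clone libraries scale the 13 estimable parameters of a base set by
`(1+η)`, `η ~ N(0, spread²)` clipped to bounds, with clone 0 unperturbed.
The default spread of 0.1 mirrors the modest phenotype differences of a
knockout screen (fitted qSmax across clones spans ≈15%). The nominal
inoculation state is X = 1.3 g/L in 10 mL of 5 g/L glucose medium, chosen
once so the initial-guess model predicts the batch end near 1.9 h and the
feed start near 2.3 h, i.e. a fed-batch phase of ≈5.5–6 h within an 8-h
run — the regime this screening protocol operates in. A protocol pulse at
1 h tops glucose back up to 5 g/L (sized from the controller's prior
prediction).

What the generator does *not* emulate: pH dynamics and base dosing,
evaporation, plate-batched analytics (each at-line result arrives
individually after its column delay), sensor drift, and biological
deviations from the model family (the plant *is* the model). Passing
tests therefore demonstrate internal consistency of the loop and correct
propagation of information, not robustness to model misspecification.

## Estimation

The objective pools all variables and replicates,
`Φ = Σᵢ (1/Nᵢ) Σⱼ wᵢⱼ²(yᵢⱼ − yᵢⱼᵐ)²`, with three weighting modes:

* `strict` — wᵢⱼ = 1: the textbook form; DOT (0–100) dominates.
* `variable` — wᵢⱼ = 1/mean|yᵢᵐ|: per-variable scales make DOT and g/L
  concentrations commensurable (the estimation functions' default).
* `relative` — wᵢⱼ = 1/(σᵢ·max(|yᵢⱼᵐ|, floor)): per-point weights matching
  the multiplicative assay-noise model; the maximum-likelihood choice and
  the campaign loop's default. Under `variable` weighting the few
  high-glucose batch points carry ~50× the weight of the fed-batch points
  relative to their noise, and the optimizer can push Φ *below* the noise
  floor by bending the model through them.

Fitting is bounded trust-region least squares (`scipy.optimize
.least_squares`, TRF) over the selected subset only; non-subset
parameters keep their incoming values. The finite-difference step is
1e-4 relative — far above the integrator's noise floor; with the default
step the Jacobian in shallow directions is numerical garbage and the fit
stalls (a 6% yield error on noise-free data; with the explicit step,
noise-free recovery is exact to 1e-8). Results flag any parameter on a
bound. Default bounds are expert physiological windows (e.g. `Yem` in
[0.3, 0.75], `qSmax` in [0.4, 2.5]; see `parameters.EXPERT_BOUNDS`) —
ten-fold boxes around the initial guess admit wildly non-physiological
compensating optima along the model's sloppy directions.

## Identifiability

Sensitivities are central finite differences of the simulated outputs at
the measurement points (relative step 1e-4, end points pulled inside
bounds so a parameter sitting on a bound still gets its one-sided
column), scaled by θ and by the per-variable mean absolute measurement.
Subset selection is greedy orthogonalized forward selection: repeatedly
take the column with the largest residual norm after projection on the
span of the selected ones (ties broken by parameter name, making the
result invariant to column order), and stop when the collinearity index
(1/σ_min of the column-normalized selected submatrix) of the would-be
prefix exceeds the threshold, or when the residual norm falls below 1e-8
of the largest initial column norm.

The default threshold is 25. This was calibrated on synthetic campaigns:
at 10 the selection strands the yield family (the estimate inherits the
prior's error for them); much beyond ~50 it admits the model's sloppy
overflow-split direction (below) and the fit wanders. At 25 most of the
13 parameters enter on a full campaign while the marginal ones (`Ko`,
`Ksq`, `Yofm`, `Yosresp`) drop in and out across cycles as information
accumulates — the qualitative selection pattern these screens report.
Near the threshold, adding rows can legitimately shrink the selected set
by one (the index itself moves); the monotone-information property holds
away from the margin.

### A structural identifiability limit

The family (`Yem`, `Yofm`, `pAmax`, `Yaof`) is nearly degenerate: growth
and oxygen data constrain `Yem·qSox + Yofm·qSof`, and the overflow
fraction `pAmax/(qS+Kap)` varies by only ~15–20% between the batch and
fed-batch regimes, so the split is poorly resolved at 15% biomass noise.
Fitting `Yem` alone (all else at truth) recovers it to <1%; jointly with
its partners, errors of 5–20% occur, and acetate turnover (production
instantly re-consumed, invisible at A ≈ 0) adds a second compensating
path through `Yam`. The expert bounds contain the excursions but cannot
remove the flat direction. This is a property of the model family and
the stated assay noise, not of the optimizer, and it is why a screening
campaign discriminates clones primarily by `qSmax` and µmax.

## Feed design

The batch ends when predicted glucose and acetate both fall below
0.02 g/L, but no later than 45 min after glucose depletion; prediction is
feed-free forward simulation on a 0.25-min grid from the current
calibrated state, with committed sampling events included. The
exponential profile `V(t) = V₀ + (F₀/µset)(e^{µset·t} − 1)` is
discretized into 5-min pulses (each pulse carries its interval's profile
volume, so cumulative volume telescopes to the closed form exactly;
`expm1` keeps the µset → 0 limit stable); the first pulse that would
exceed 22 µL switches the schedule to a constant 22-µL feed. Pulses below
the 1-µL pipetting minimum are emitted as zero-volume entries.

`F₀ = µset·X₀·V₀/(YXS·Si)` with µset = 0.5·µmax of the current model and
X₀, V₀ from the event-aware simulation at feed start. The design yield
`YXS` defaults to the *effective* yield µset/qS*(µset) obtained by
inverting the growth law — the oxidative yield `Yem` alone ignores
overflow and maintenance losses and oversizes F₀ by ≈30%, compounding
exponentially. On recalibration mid-feed, executed pulses are immutable;
the future profile is re-anchored at the next scheduled pulse with F₀
recomputed from the current predicted biomass, which continues
`F = µset·X·V/(YXS·Si)` self-consistently.

## The calibration loop

Per clone, one model is fitted to the pooled biological triplicate and
one shared schedule is committed to all replicates. A cycle runs at each
new at-line availability, with at most one cycle per 0.75 h (the at-line
delays make results trickle in; the gap reproduces the ≈9–10 cycles per
8-h run such campaigns report and bounds compute). Each cycle: pool all
records with availability ≤ now → select the subset at the current
parameters → re-fit (warm-started, iteration-capped) → predict batch end
→ redesign the feed. The first cycle triggers at the second biomass
availability and back-extrapolates the biomass belief to inoculation at
the current µmax. Cycles that fail (no batch end in sight, solver
failure) fall back to the previous schedule and are flagged; a clone
whose cycles never succeed gets open-loop initial-guess feeding — the
plant never stalls.

## Monte Carlo uncertainty

Parametric bootstrap: re-perturb the measurement set with the assay noise
model, re-fit the subset from the point estimate, keep the lowest-Φ
draws; report per-parameter mean, σ_θ, %σ_θ and pairwise correlations,
and predictive quantile bands by simulating every kept draw. Defaults
n_draws = 550 / n_keep = 500 (over-drawing tolerates non-convergent
draws); the bundled tests and the acceptance script run reduced ensembles
(n = 60–100, iteration-capped refits) to stay within a desk-scale compute
envelope — ensemble sizes are recorded next to each reported number.
Because draws are local refits around the point estimate, %σ_θ measures
the curvature of the objective there; it understates uncertainty along
the long sloppy valley described above.

## Problem sizes used by the bundled checks

Unit tests run single cultures or small campaigns (2 clones × 3
replicates, 4–5 h). The acceptance script runs, per seed: one full
24-pulse-train reactor for accounting; 20 random-parameter batch-end
comparisons against fixed-step RK4 (dt = 1e-3 h); 100 subset-selection
oracle trials; 20 single-clone triplicate closed-loop campaigns (8 h,
≈10 cycles each) for recovery; two paired campaigns plus a fixed-setpoint
comparison for adaptive feeding; and reduced Monte Carlo ensembles
(60 and 30 draws) on one full campaign dataset.
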