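# Methods

`mguq` implements a surrogate-assisted uncertainty-quantification workflow
for computational models of magnesium-implant biodegradation: three forward
simulators, a design-of-experiments layer (one-shot and adaptive), three
surrogate families (Kriging, polynomial chaos expansion, PC-Kriging),
and forward-UQ tasks (Sobol sensitivity analysis, uncertainty propagation,
surrogate-based calibration). This note records the models, the numerical
choices, and the places where the design was genuinely open.

## Degradation models

### Model 1 — quasi-1D interface recession (pure Mg in SBF)

The Mg2+ release rate at the metal/electrolyte interface is gated by a
logistic switch that represents the breakdown of the native MgO film:

    release(t) = eps * k_deg / (1 + exp(-(t - t_init))),    t in days.

The interface recedes with normal velocity v = (M_Mg/rho_Mg) * |release|,
and the mean degradation depth (MDD, um) is the integral of v with
MDD(0) = 0, capped at the Mg-domain length `r_initial` (0.2 mm). The
alternative convention MDD(0) = r_initial (decreasing) is algebraically
equivalent; the increasing convention is used because measured degradation
depths start at zero. The integral is evaluated with the trapezoidal rule
on `n_t` steps (default 800; halving the step moves MDD(28 d) by < 0.5%).
If the domain is consumed before the horizon the run is truncated with a
`RuntimeWarning` and the MDD capped.

Parameters: `k_deg` (mol m^-2 s^-1, stored signed as tabulated, magnitude
used as the dissolution flux), `t_init` (days), porosity `eps`. The
porosity of the degradation layer is not a published constant; the default
is 0.05, chosen so that the model at its calibrated optimum
(k_deg = -2.4321e-5, t_init = 1.932 d) yields MDD(28 d) ≈ 38 um — the
order of magnitude reported for pure Mg in SBF — and so that no value in
the tested k_deg range consumes the 0.2 mm domain within 28 days. (With
eps = 0.5 the domain is consumed in under a week at the optimum, which is
inconsistent with the calibration setting the optimum comes from.)

### Model 2 — precipitation in the degradation layer

Six dissolved species (Mg2+, OH-, H+, HCO3-, Ca2+, HPO4^2-) diffuse on a
1-D domain composed of the porous degradation layer (DL, default 20 um)
and the electrolyte (0.2 mm). Inside the DL every species uses the porous
-medium diffusivity 1.4e-16 m^2/s; in the electrolyte, species-specific
infinite-dilution coefficients. Transport is integrated with implicit
(backward-Euler) finite volumes and zero-flux boundaries, so the scheme is
conservative and positivity-preserving. An optional electro-migration term
closes the electric field with a zero-net-current condition; it is off by
default because no boundary conditions for the potential are published.

Mg2+ and 2 OH- per Mg enter the first cell with the model-1 release flux;
the metal reservoir is book-kept in mol/m^2 and one mole of H2 is credited
per mole of Mg dissolved (anodic/cathodic stoichiometry). Six precipitates
(brucite, magnesite, nesquehonite, portlandite, calcite, hydroxyapatite;
hydroxyapatite stoichiometry assumed 5 Ca2+ + 3 HPO4^2- + 4 OH- ->
Ca5(PO4)3OH + 3 H2O) form only inside the DL with the bilinear rate law

    d c_p / dt = eps * k_l * (K_eq,l - c_i c_j),

with k_l signed exactly as tabulated. Each reaction step solves the
backward-Euler equation for the reaction extent per cell — a scalar
quadratic with an analytic root — and clamps the extent so that neither
the dissolved species nor the precipitate goes negative. This is
unconditionally stable, which matters because the tabulated rate constants
span ~35 orders of magnitude; in the stiff limit the step projects the
species product onto K_eq (verified against a stiff ODE reference).

Elemental wt% of the DL is computed from the precipitate fields and the
formula-unit compositions: wt_i = rho_i / sum(rho) * 100 over
(C, Ca, P, H, O, Mg). Dissolved species are not counted towards the layer
composition. Equilibrium constants and the SBF composition are not
published constants of the model; the shipped defaults (documented in
`precipitation.default_species` / `default_reactions`) are plausible
synthetic values, all config-overridable; conservation and oracle tests
are composition-independent.

Total elemental Mg (metal + dissolved + precipitate-bound) closes to
~1e-11 relative over 28 days on the default grid.

### Model 3 — diffusion-limited volume loss of a simplified implant

The screw is reduced to an axisymmetric cylinder (radius 1 mm, length
4 mm) centred in a cylindrical bath whose volume matches the experimental
3 x 3 x 5 mm bath (radius 1.7 mm, chosen additionally so the implant
surface falls exactly on grid faces — this removes the first-order
staircase error and restores clean grid convergence). The implant starts
at the alloy Mg concentration (7.13e-5 / 7.07e-5 mol/mm^3 for Mg-5Gd /
Mg-10Gd), the bath at zero, and one diffusivity D_Mg governs transport.
Backward-Euler finite volumes on the (r, z) grid (default 34 x 40 cells,
112 steps; halving all steps moves VL(56 d) by < 1%). Boundary options:
`closed` (zero-flux walls; mass-conserving; the default) or `sink`
(renewed medium, c = 0 at the walls). Volume loss is

    VL(t) = 100 * (1 - N_implant(t) / N_implant(0)),

with the implant moles integrated over the original implant region, and
DR(t) = (V(0) - V(t)) / (A(0) t) in mm/yr (the t = 0 point is excluded).
A 1-D slab reduction with a perfect sink verifies the early-time Fickian
closed form VL = (2/L) sqrt(D t / pi) * 100 to better than 2%.

D_Mg units: the tabulated testing range (1e-12 to 1e-4) and optima
(e.g. 6.05e-9 for Mg-5Gd) are interpreted in mm^2/s. In m^2/s on this
mm-scale geometry every value in the range equilibrates the bath within
minutes, VL(56 d) is constant over the whole range, and calibration of
D_Mg would be ill-posed; in mm^2/s the optimum yields VL(56 d) ≈ 22% for
Mg-5Gd, inside the experimentally reported range, and the response varies
smoothly across the interval. Config objects are SI internally
(1 mm^2/s = 1e-6 m^2/s); the case bindings and synthetic datasets carry
the tabulated numbers.

## Parameter spaces

All uncertain parameters are uniform. Ranges printed as powers of ten
spanning many decades (rate constants: 5-21 decades; D_Mg: 8) are treated
as log-magnitude intervals: `ParameterSpace` supports a per-parameter
`"log"` scale under which the uniform distribution lives on the decade
scale, and the sign of the interval is the sign of the tabulated optimum.
The rationale is identifiability: every tabulated optimum sits at a linear
position of ~1e-4 to 1e-6 of its interval, so a linearly-uniform design of
any realistic size contains no information about it, while on the decade
scale the optima are comfortably interior. Surrogates, the CMM learning
function, calibration refinement, and Sobol indices all operate in the
scale-aware unit hypercube, so "sensitivity to D_Mg" means sensitivity to
its order of magnitude — the natural reading for a rate constant.
`t_init` stays linear.

## Design of experiments

One-shot samplers: plain Monte Carlo, Latin hypercube (one point per
marginal stratum), Sobol and Halton sequences (scrambled only when a seed
is supplied, so unseeded designs are the canonical sequences). The
conventional minimum one-shot size is 10 d + 2.

Adaptive sampling starts from a Latin hypercube of five points per
parameter (the often-cited alternative of ten per parameter is available
via `n_initial`), then repeats: fit surrogate -> compute the
normalised leave-one-out error eps_LOO -> stop if eps_LOO < theta
(default 1e-4) -> otherwise add the constrained-min-max (CMM) candidate
and refit. The CMM rule maximises the minimum unit-scaled Euclidean
distance to the existing design over a fresh 100 d-point LHS pool,
restricted to the upper quartile of predictive variance when the
surrogate provides one (Kriging, PC-Kriging); ties break to the lowest
pool index. Additional stops: the evaluation budget, and a no-improvement
rule (no relative eps_LOO improvement of at least 1% over 10 consecutive
enrichments). Model evaluation failures reject the point, are logged on
the run state, and the loop continues.

## Surrogates

**PCE.** Orthonormal Legendre basis on [-1, 1]^d (inputs mapped through
the scale-aware unit cube), hyperbolic q-norm truncation ||alpha||_q <= p
(default q = 0.75), coefficients by least squares with a ridge fallback
when the design matrix conditioning exceeds 1e10. The degree is selected
from a candidate range (default 1-10, capped so the basis stays smaller
than the training set) by the closed-form leave-one-out error
mean((r_i/(1-h_ii))^2)/Var(Y).

**Kriging.** Universal Kriging with Matérn 5/2 correlation, anisotropic
lengthscales in unit coordinates, trend = constant by default. Profiled
maximum likelihood over log-lengthscales, L-BFGS-B with five seeded
starts, bounds [1e-2, 5]. The upper lengthscale bound doubles as a
conditioning guard: beyond it the correlation matrix approaches rank one
and the nugget-regularised solve loses the interpolation property. With
the default nugget 1e-10 (escalated to 1e-8/1e-6 on Cholesky failure) the
model reproduces training data to ~1e-8 of the response range; the nugget
is the documented deviation from exact interpolation. Leave-one-out
residuals use the closed form for universal Kriging via the bordered
matrix [[R, F], [F', 0]] (Dubrule's identities), verified against explicit
refits to 1e-12.

**PC-Kriging.** Sequential: the eps_LOO-optimal PCE basis is selected
first (restricted so the trend leaves at least two degrees of freedom),
then Kriging is fitted with that basis as its trend. Because maximum
likelihood optimises the likelihood rather than cross-validation, the
fitted lengthscales can occasionally cross-validate worse than the trend
alone; the constructor therefore also evaluates the short-lengthscale
limit (where universal-Kriging LOO coincides exactly with the trend's OLS
LOO) and keeps the better of the two, so PCK never cross-validates worse
than its own PCE trend.

Time-resolved QoIs are handled as one independent scalar surrogate per
output time point (`TimeGridSurrogate`); the model-2 QoI is the 5-element
wt% vector (Mg, O, P, C, Ca) at day 28 with one surrogate per element.
k-fold cross-validation defaults to k = N (true leave-one-out).

## UQ tasks

**Sobol indices.** For PCE (and the trend of a PCK) the first-order and
total indices follow analytically from the orthonormal coefficients
(S_i from the univariate terms in i, S_T,i from every term involving i,
normalised by the non-constant coefficient energy); a constant expansion
raises. For black-box surrogates a Saltelli pick-freeze estimator is used
(Janon first-order, Jansen total, two independent input matrices plus d
hybrids), with bootstrap (200 resamples) standard errors; small negative
estimates are reported as-is. The schematic printed total-index formula is
replaced by the standard total-effect definition.

**Propagation.** LHS sample of the space pushed through the model;
mean, variance, quantiles; aborts if more than 10% of evaluations return
non-finite values.

**Calibration.** Minimises the range-normalised RMSE (NRMSE) between
predictions and observations — multi-QoI objectives average per-QoI NRMSE
with equal weights (no weighting is published) — via a seeded LHS screen
(default 1000 points) followed by Nelder-Mead refinement in the
scale-aware unit cube, clipped to bounds; the returned optimum is never
worse than the best screened point. Any object with `predict` /
`predict_at` can be calibrated, so the same machinery runs against a
surrogate (fast path) or the simulator itself (reference path).

## Synthetic calibration data

`synthetic_data` stands in for the unpublished experimental curves:
weekly MDD over 28 days, day-28 elemental wt%, and VL at days 7-56 (plus
42/56), generated by the simulators at known true parameters with
multiplicative Gaussian noise (default relative SD 5%, configurable to
additive). wt% rows are renormalised to sum to 100 after noising; VL is
clipped to [0, 100]. Every dataset records seed and ground truth, so
calibration closes the loop exactly in the noiseless limit. What passing
recovery tests show is that the estimation machinery is unbiased and
precise under the assumed noise model; they cannot show robustness to
structural model error, correlated measurement error, or imaging
artefacts, which real uCT/EDX data contain.

## Reproducibility

Every stochastic component takes a seed; the workflow driver derives all
stage seeds from one master seed via spawned `SeedSequence` substreams,
and repeated runs produce byte-identical CSV/JSON artifacts apart from
recorded wall times. Run manifests decompose wall time into black-box
evaluation, surrogate training and parameter-estimation phases
(communication and idle time are zero in-process).

## Known limitations

* Model 1 prescribes the release rate; there is no transport-limitation
  feedback, so MDD is exactly linear in |k_deg| at fixed t_init. Over the
  5-decade k_deg interval the response then spans ~5 orders of magnitude,
  which a stationary-kernel Kriging surrogate resolves only slowly
  (normalised eps_LOO plateaus near 1e-3-1e-2 for design sizes below
  ~100). Adaptive terminal design sizes on this response are therefore
  substantially larger than they would be for transport-coupled models,
  whose effective response ranges are narrower.
* Model 2's wt% QoIs are supply-limited compositions with sigmoidal
  switches per rate constant; in 8 dimensions the cross-validated error
  of all three surrogate families plateaus near 5e-2 within an
  80-evaluation budget.
* The precipitation model does not move the metal interface (no ALE-type
  domain deformation) and confines the DL to a fixed region.
* Desk-scale grid resolutions are deliberate defaults chosen to keep a
  full adaptive study in the minutes range; the convergence tests pin
  their discretisation error (< 0.5% MDD, < 1% VL per halving).
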