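# Methods

## Model

Transport across the vesicle membrane is modelled as a symmetric
carrier cycle: a transporter X with a single substrate site, equal
dissociation constant K on both membrane faces, equal forward/backward
translocation rates for the loaded complex, and an unloaded-carrier
mobility h relative to the loaded one. Tracer A and unlabelled substrate B
are kinetically identical (only the label differs). Under these assumptions
the net tracer influx is the rational flux law implemented in
`carrier_model.tracer_influx`, and the unlabelled flux is the same law with
the A/B labels exchanged. The parameter h carries all the mechanism: h = 0
is strictly obligatory 1:1 exchange (the unloaded carrier cannot return
empty, and the internal total A+B is exactly conserved); h > 0 permits net
transport, relaxing to diffusive equilibrium with the bath; h = 1 makes the
apparent initial-rate parameters equal the intrinsic ones regardless of the
internal pool, because binding of internal substrate then does not change
the carrier's return rate.

Assumptions inherited from this construction, all deliberate
simplifications:

* one transporter species, one substrate site;
* symmetric translocation and binding (no side-specific rates);
* no membrane potential (the transporters of interest are not electrogenic);
* constant vesicle volume, single volume per mg protein;
* constant external (bath) concentrations — the extravesicular volume is
  treated as infinite. The `constant_bath` flag exists so the assumption is
  explicit at call sites; finite-bath dynamics are not implemented.

## Units and parameters

Internal units are fixed: concentrations in µmol l⁻¹, time in minutes,
V in µmol l⁻¹ min⁻¹ (flux divided by vesicle volume). Files use seconds,
the experimental convention; conversion happens only in `interface_io`.
The protein-normalized ↔ concentration bridge is the vesicle volume factor,
default 1.6 µl per mg protein, derivable from an equilibrium uptake
measurement (`volume_factor_from_equilibrium`).

Parameters that matter and their defaults:

| parameter | meaning | default / bounds | rationale |
|---|---|---|---|
| h | unloaded-carrier mobility | fitted in [1e-3, 10], or fixed (incl. 0) | spans antiport→uniport; log-space fitting keeps it positive, h = 0 reachable only as an explicit constraint |
| V | maximal rate | fitted in [1, 1e4] µmol l⁻¹ min⁻¹ | generous decade bracket around physiological vesicle rates |
| K | dissociation constant | fixed, or derived from a fixed Kapp at each candidate (h, B_in0) | K is not separately identifiable from tracer time courses; deriving it from the measured saturation keeps fits internally consistent |
| B_in0 | initial internal unlabelled pool | assumption, scanned 0–1000 µmol l⁻¹ | unobservable; the sensitivity scan quantifies its leverage |

## Inversion of apparent parameters

The zero-trans initial rate reduces exactly to
`Vapp·A0/(Tot0 + Kapp)`; both apparent parameters share the denominator
`2·B_in0 + K(h+1)`. This reading of the algebra is enforced by tests: the
reduction is property-tested against the full flux law, and
`invert_apparent ∘ apparent_params` is the identity to 1e-8 over the
(h, B_in0) grid. The inversion solves

    2h·K² + (h+1)(B_in0 − Kapp)·K − 2·B_in0·Kapp = 0

(linear for h = 0; for h > 0 the constant term is non-positive so exactly
one positive root exists, taken in a cancellation-stable form for small h),
then V from the Vapp relation. For h = 0 a positive root requires
B_in0 > Kapp — an obligatory exchanger cannot exhibit an apparent Kapp at or
above its internal pool — and the configuration (h = 0, B_in0 = 0) is
rejected everywhere as "no uptake possible".

Inverting the integer-rounded measured pair (Kapp = 87, Vapp = 131)
reproduces each published intrinsic-parameter cell to within one integer
unit (asserted in the unit tests); exact integer agreement for every cell
would require the unrounded fitted pair, which is not available. The
degenerate flux case (h = 0 with all four concentrations zero) is defined
as zero flux, the physically forced value of the 0/0 limit.

## Integration

Time courses integrate the coupled (A_in, B_in) system with adaptive
Runge–Kutta 4(5) (`scipy.integrate.solve_ivp`, RK45), rtol 1e-8,
atol 1e-10. The tolerances are chosen so the h = 0 conservation law holds
to < 1e-6 µmol l⁻¹ over any tested horizon and the solution matches an
independent fixed-step Euler oracle (step 1e-5 min) to 1e-4. Negative
excursions beyond 1e-7 µmol l⁻¹ raise rather than clamp, so integrator
artifacts surface instead of being silently absorbed. In the fitting
objective all external conditions are stacked into one ODE system and
integrated together — identical mathematics, one adaptive-stepping pass.

Equilibrium read-outs use a doubling-horizon loop
(`simulate_to_equilibrium`) that stops when the internal tracer changes by
less than a relative tolerance (default 1e-4) over the last half of the
horizon. Overshoot detection evaluates the dense interpolant on ≥ 500
points independent of the reporting grid, requires the trajectory to have
settled (< threshold change over the last 10 % of the horizon), and flags a
peak exceeding the terminal value by more than a 1 % relative threshold —
a default chosen because experimental variability makes smaller excursions
unresolvable in practice.

## Fitting

The initial-rate fit minimises unweighted SSE of the apparent
Michaelis–Menten law against per-condition mean rates (per-replicate
fitting available, non-default, matching how such experiments are
reported). The time-course fit minimises the relative normalized SSE,
Σ((model − mean)/mean)², which balances conditions whose absolute uptake
differs by an order of magnitude. Points with zero experimental mean are
excluded — the normalization is undefined there — which in particular drops
the t = 0 point, where uptake is identically zero and carries no
information. The 15 s initial-uptake read is converted to a rate by simple
division (uptake is linear over that window by design); model-consistent
averaging over the window is a straightforward alternative but the default
keeps the conversion transparent.

Both fits use Nelder–Mead simplex minimisation in log-parameter space
(positivity by construction), with 8 starts (default) drawn from a seeded
Latin hypercube over the bounds above; the best restart wins. Nelder–Mead
tolerances: xatol 1e-7 in log space (~1e-5 relative parameter precision),
fatol 1e-12. Non-finite objectives (failed inversions, integrator failures)
are treated as +inf within a run; a fit where every restart fails raises,
carrying the best candidate.

`profile_objective` re-runs the *full* multi-start fit at every grid point
of a 1- or 2-axis scan over {B_in0, K, h}; `sensitivity.run_scan` divides
each point's objective by the baseline fit's objective, so the baseline
point has relative error exactly 1. Failed points are masked, never
interpolated; 2-D maps can additionally mask relative errors above a cutoff
(default in the CLI examples: 2.5), retaining the values behind the mask.

## Synthetic data

The generator emulates the two vesicle assay designs: 7.5 µmol l⁻¹ external
tracer throughout; 23 unlabelled levels for the saturation design
(tracer-alone plus 22 log-spaced levels, 0.2 µmol l⁻¹ – 20 mmol l⁻¹ — the
upper bound is configurable since assay buffers differ), read at 15 s,
n = 4; and the time-course design at (0, 5, 10, 15, 20, 60, 120, 300,
600) s for external unlabelled levels (0, 250, 1000) µmol l⁻¹, n = 3.
Noise is multiplicative log-normal, mean one, nominal CV 10 % — a generic
model for scintillation-counting variability, which is reported only as
mean ± SD in practice; replicate draws are independent with no
placenta-level random effect. The t = 0 observation is exactly zero.

What passing the closed-loop tests shows: the estimator recovers the
generating parameters under the stated designs and noise when its
assumptions (mechanism, internal pool, noise shape) match the generator.
What it does not show: robustness to vesicle size heterogeneity,
time-varying vesicle volume, orientation mixtures, nonspecific binding or
filtration losses — none of which the generator emulates.

## Problem sizes

The test suite uses the experimental designs at their native sizes: the
parameter-recovery check runs 100 noisy synthetic replicates of the
three-condition time course (CV 10 %, n = 3) with V free and the mechanism
fixed at truth; model discrimination and the h-profile use a single seeded
dataset with 3–4 restarts per fit. The acceptance script's equilibrium
simulation integrates to a horizon where the solution changes by < 0.01 %
(doubling-horizon loop, 201 grid points).

## Known limitations

* Asymmetric translocation or binding (side-specific rates/affinities) is
  not modelled; asymmetry would change transient predictions but not the
  passive equilibrium levels.
* The (h, V) pair is weakly identified from zero-internal-pool time
  courses — the data constrain the combined cycle velocity, producing the
  documented V–h trade-off; h is best treated as a scan axis, not an
  estimate.
* The relative-error objective cannot use conditions whose mean is zero
  everywhere (e.g. an obligatory exchanger with an empty pool); such series
  are rejected with an explicit error.
* Bootstrap or profile-based uncertainty for the time-course fit is not
  built in; the sensitivity scan is the intended instrument for assessing
  how conclusions depend on the fixed assumptions.
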