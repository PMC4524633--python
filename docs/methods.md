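# Methods

This note records the model, the numerical choices, and the design
decisions behind `ceraflux`, together with what the synthetic-data tests
do and do not demonstrate.

## The GMA model of the ceramide subsystem

The network has 15 dependent pools — X1–X5 dihydroceramides (DHC), X6–X10
phytoceramides (PHC), X11–X15 fatty acyl CoAs, each block spanning the
chain classes C14/C16, C18, C18:1, C24/C24:1, C26/C26:1 in that order —
and 53 fluxes.  Flux rates follow the Generalized Mass Action form with
every kinetic order fixed at 1 and the enzyme activity entering linearly:
`v_j = a_j · ∏(substrate pools) · ∏(boundary drivers)`.  The estimated
`a_j` is therefore the product of a rate constant and an enzyme activity
(analogous to a V<sub>max</sub>), and only fold changes of it are
interpretable; absolute magnitudes are not claimed.

Per chain class k the DHC column holds ceramide synthase (DHS + CoA_k →
DHC_k), IPCase (IPC → DHC_k), dihydroceramidase (DHC_k → DHS, leaving the
subsystem), DHC hydroxylase (DHC_k → PHC_k) and IPC synthase (DHC_k →
IPC); the PHC column mirrors it without the hydroxylase.  Ceramide
synthase consumes the matching acyl-CoA pool as a stoichiometric
co-substrate, so its inferred activity trend is really the combined trend
of synthase activity and acyl-CoA availability — the two cannot be
disentangled from these data, and we do not try.

DHS, PHS, a single lumped complex-sphingolipid pool (IPC, MIPC and
M(IP)₂C together, since all three can source ceramide), and the
fatty-acid input are boundary drivers: time-dependent inputs, not state
variables.  Defaults hold them at their baseline value; any driver can be
given a (time, value) table in the topology config.

**Elongation wiring.**  The published pathway diagram fixes the enzyme
classes of the center column (remodelase V46, elongases V47, V48, V50–V53,
desaturase V49) but not the pool-level wiring among the five lumped CoA
classes.  The bundled default uses a connected single-step wiring —
V46: source → X11; V47: X11 → X12; V48: X12 → X14 (lumped C18→C24
elongation); V49: X12 → X13 (desaturation); V51: X13 → X14 (lumped
unsaturated elongation); V50: X14 → X15; V52/V53: drains of X14/X15 for
acyl-CoA consumption outside the subsystem.  This is a package design
choice, made so that every CoA pool has supply and demand; it is
config-overridable.

## Baseline and units

Pool concentrations are carried in the units the data arrive in; the
bundled synthetic baseline spans ~3 orders of magnitude across species
(C26 PHC by far the most abundant), mimicking the large spread in
prevalence of ceramide variants.  The baseline (t = 0, pre-stress) flux
vector is defined as the unique solution of

    min ‖v − 1‖²   s.t.   S·v = 0,  (group totals),  v ≥ 0,

i.e. the balanced nonnegative flux vector closest to unit fluxes — the
canonical reference in fold-of-baseline units.  (A pure minimum-norm
choice would collapse to v = 0 whenever no boundary totals anchor the
scale.)  This quadratic program is solved exactly by a primal active-set
method (`_qp.py`); a soft-penalty least-squares formulation proved too
inaccurate near active bounds, and the generator and the estimator must
agree on this vector to machine precision.  Three fluxes (V30, V34, V52)
carry exactly zero baseline flux in the default network — the nonnegative
balance pins them — and consequently have no defined fold change; they
are reported as missing.

## Preprocessing

Duplicate series are fit with one cubic smoothing spline per pool
(`scipy.interpolate.make_smoothing_spline`), the penalty chosen by
generalized cross-validation unless overridden.  Replicates are pooled:
the penalized fit over all observations equals the weighted fit of the
per-time means with weight = replicate count, which is how it is
computed.  Slopes are represented as the discrete difference
X(t) − X(t−1) on the per-minute grid — this is the quantity the flux
estimator constrains — while the spline's analytic derivative is exposed
for diagnostics only.  Negative spline excursions are floored at
1e-9 × baseline with a warning, since concentrations are positive and
small undershoot is a smoothing artifact.

## Dynamic flux estimation

With 53 fluxes and only 15 pools the per-minute system is strongly
underdetermined; each minute t = 1..30 is solved as a bound-constrained
weighted least-squares problem

    J(v) = w_s‖S·v − ΔX(t)‖² + w_b‖G·v − g(t)‖² + w_m‖v − v_prev‖²,
    0 ≤ v ≤ ub,

with defaults w_s = w_b = 1, w_m = 0.1 (no weights are prescribed by the
problem, so they are config-exposed), ub = 100 × baseline flux (floored
at 1), and g(t) the boundary-table group totals interpolated per minute.
The unmeasured acyl-CoA pools get slope target 0: no time series exist
for them and they are assumed quasi-stationary.  The smoothness anchor
`v_prev` is the previous minute's ensemble mean; for t = 1 it is the
baseline flux profile derived from the boundary table at t = 0.

Each restart clips its U(0.01, 100) init into the bounds and runs
L-BFGS-B followed by a projected-Newton polish on the free variable set.
Because the objective is a convex quadratic and w_m > 0 makes it
strictly convex, the minimizer is unique: the restart ensemble measures
optimizer and bound-activity variability rather than solution-set
diameter, and its aggregates (mean, median, p20/p80 — both mean and
median are first-class) are correspondingly tight.  A restart counts as
converged when its projected gradient norm falls below 1e-8; only
converged restarts enter the aggregates.

The full-scale setting of 1,000 restarts per minute remains desk-feasible
(~15 minutes), but all recovery properties already hold at the 100
restarts the validation suite uses, so that is the default problem size
in `validation.py` and `scripts/acceptance.py`.

**Noise robustness** compares per-flux mean time courses between a clean
and a multiplicatively perturbed run using the *uncentered* correlation
(cosine similarity): on the steady reference scenario the clean courses
are constant, which makes centered Pearson correlation undefined (0/0);
the uncentered form still returns 1 for identical courses.

## Activity inference

Proxies a_j(t) = v_j(t) / (substrate × driver product at t) invert the
GMA form exactly (proxy × substrates reproduces the input flux to
machine precision).  Concentrations of the unmeasured CoA pools are
reconstructed by integrating the estimated fluxes,
X(t) = X(t−1) + (S·v̄(t)), consistent with the slope convention.  Proxies
are smoothed into nonnegative spline functions f_j(t); fluxes with fewer
than 4 valid minutes are excluded with a warning.

**Windowed shooting refinement.**  The 30 minutes are split into ten
3-minute windows (window length config-exposed; 5- or 10-minute windows
give visibly worse fits).  Each window is an independent initial-value
problem whose initial state comes from the splined data — never from the
previous window's simulated endpoint — with unmeasured pools taken from a
reference simulation under the unrefined f.  Activities inside window w
are C_{j,w}·f_j(t); the coefficients minimize the SSE between simulated
and splined concentrations at the window's minutes, each measured pool
divided by its baseline so the most abundant species (C26 PHC) does not
dominate.  Coefficient search runs from `n_inits` random starts drawn
U(0.1, 10) within bounds [0.01, 100]; all solutions are retained as an
ensemble and the reported coefficient set is the lowest-cost member.
Reported fold-change trends keep the discontinuities at window
boundaries — they are a signature of the optimization method, not noise.

Two refinement granularities exist: one coefficient per flux per window
(default) and one per enzyme class per window.  A window has only
3 minutes × 10 measured pools = 30 residuals, so 53 per-flux coefficients
are never fully identifiable; worse, two first-order drains of the same
pool into different boundary sinks (e.g. dihydroceramidase and IPC
synthase acting on the same DHC pool) have *identical* signatures on the
measured data within a window, so even per-class coefficients share flat
directions when the reference f does not already separate the classes
(the boundary-group constraints of the flux-estimation stage are what
separates them in the full pipeline).  Two measures address this: a mild
ridge √λ·(C − 1) with λ = 1e-3 appended to the residuals — the search is
explicitly for slight adjustments of f, so pulling unidentifiable
directions to the no-change value is the right prior — and the per-class
mode (9 coefficients per window) for validation runs where
identifiability matters.

**Window integrator.**  Every flux has at most one internal substrate,
so the window ODE is linear in the state, x' = M(t)x + b(t) with M
Metzler.  Windows are integrated with a fixed-step midpoint
matrix-exponential scheme on the augmented matrix [[M, b], [0, 0]]
(second-order Magnus, step = activity-table spacing, default 0.01 min).
This is unconditionally stable — essential because the coefficient
search probes multipliers up to 100×, where any explicit stepper crosses
its stability limit and turns the objective into noise — preserves
positivity exactly, and is smooth in the coefficients.  Its accuracy
against the adaptive reference integrator is ~1e-4 relative at the
default step, which bounds the residual bias on recovered coefficients
(the self-consistency check measures ≤ ~5e-4).

The general-purpose simulator (`simulate`) is scipy's LSODA at
rtol 1e-8 / atol 1e-10, with sub-tolerance negative excursions clipped
to 0 under a logged warning.

## The synthetic-data generator

The generator defines the study conditions: 10 measured DHC/PHC pools
(acyl CoAs unobserved), sample times {0, 5, …, 30} minutes, 2 replicates,
steady-state start, and i.i.d. multiplicative noise U(1/1.5, 1.5) per
replicate/time/pool (a lognormal option exists for sensitivity studies).
The noise magnitude is borrowed from the perturbation level used in the
robustness analysis, as no replicate-noise estimate for the real data is
available.  Activity scenarios are parametric shapes — flat, spike–decay,
delayed peak, undershoot–recover, step change — with presets named after
the qualitative biology they emulate (immediate synthase spike, delayed
IPC-utilization peak, very-long-chain undershoot); all magnitudes are
synthetic.  The step shape is baseline up to and including its step time
and stepped strictly after it, so a step "at minute 9" aligns with a
3-minute window boundary.

What passing tests show: the estimator chain recovers known fluxes and
activities under the stated sampling, noise and identifiability
conditions.  What they do not show: performance under HPLC-MS artifacts
(detection limits, batch effects, heteroscedastic noise), model
misspecification (kinetic orders ≠ 1, missing reactions), or errors in
the boundary-flux table imported from the prior model — real-data runs
inherit whatever bias that table carries.  When external data are
supplied without CoA baseline information, unit CoA baselines are
assumed.

## Validation studies and problem sizes

`validation.py` implements the desk-scale studies (also run by
`scripts/acceptance.py`): structural counts; steady-state exactness
(objective < 1e-10 from 100 restarts); noise-free flux recovery (≥ 90% of
fluxes within 5% of truth at every minute, with an absolute floor of
1e-6 for the structurally-zero fluxes); the SSE-range property of the
ensemble mean at every minute; noise robustness (median uncentered
correlation ≥ 0.8); shooting self-consistency (all window coefficients
within 1e-3 of 1 when the data are generated under f itself); and
step-change recovery.  For the step study, the 5-minute sampling grid
cannot localize a step more sharply than its bracketing samples, so the
windows from minute 7 onward count as affected (20% tolerance on the
recovered windowed activity of the stepped class) and the first two as
unaffected (10%); coefficients of all untouched classes must stay within
10% of 1 in every window.  These studies use 100 estimation restarts,
30 restarts for the step pipeline and 3 shooting inits — sizes at which
every property is already stable.

## Known limitations

- Ensemble spread at 100–1,000 restarts reflects optimizer variability
  of a strictly convex problem, not posterior uncertainty; it should not
  be read as a confidence band on the fluxes.
- Activity trends for ceramide synthase confound enzyme activity with
  acyl-CoA availability (by construction).
- Sharp activity transients (< the 5-minute sampling interval) are
  recovered with damped magnitude; shapes, not magnitudes, are the
  reliable output.
- The per-flux shooting mode relies on the ridge prior for its flat
  directions; conclusions about *individual* fluxes within a degenerate
  drain pair should come from the flux-estimation stage (which sees the
  boundary totals), not from window coefficients.
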