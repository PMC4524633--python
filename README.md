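# ceraflux

Inference of time-varying enzyme activities in the yeast ceramide
subsystem from sparse metabolite time series.

When *Saccharomyces cerevisiae* is shifted to heat-stress temperature, the
concentrations of its ceramide species — dihydroceramides (DHC) and
phytoceramides (PHC) with fatty-acyl chains from C14/C16 up to C26/C26:1 —
change within minutes, driven by fast modulation of the activities of
ceramide synthase, the ceramidases, IPC synthase, IPCase (Isc1), and DHC
hydroxylase.  Those activity changes cannot be measured directly.
`ceraflux` reconstructs them computationally from duplicate concentration
measurements taken every 5 minutes over a 30-minute stress experiment,
for researchers studying sphingolipid-mediated stress signalling or, more
generally, dynamic flux estimation from metabolomic time series.

## Method

The ceramide subsystem is modelled as a Generalized Mass Action (GMA)
network with 15 dependent pools (X1–X5 DHC, X6–X10 PHC, X11–X15 fatty
acyl CoA, each spanning the five chain classes) and 53 fluxes.  Every
flux follows the power-law form

    v_j(t) = a_j(t) · ∏ X_i(t) · ∏ D_k(t)

with all kinetic orders fixed at 1; `a_j` is the product of a rate
constant and the enzyme activity (a V<sub>max</sub>-like quantity) and
`D_k` are boundary drivers (DHS, PHS, the lumped IPC/MIPC/M(IP)₂C pool).
The inference proceeds in three stages:

1. **Preprocessing** — duplicate series are pooled into cubic smoothing
   splines (penalty by generalized cross-validation) and resampled per
   minute; discrete differences X(t) − X(t−1) serve as slope targets.
2. **Dynamic flux estimation** — for every minute t the 53 fluxes are
   estimated by minimizing

       J(v) = w_s‖S·v − ΔX(t)‖² + w_b‖G·v − g(t)‖² + w_m‖v − v(t−1)‖²,
       0 ≤ v ≤ v_max,

   where S is the stoichiometric matrix, G sums grouped fluxes whose
   totals g(t) are known from a prior whole-pathway model (the boundary
   constraint table), and the last term enforces smooth flux changes.
   Each minute is solved from many random restarts (inits from
   U(0.01, 100)); the solution ensemble is summarized by means, medians
   and 20th/80th percentiles.
3. **Activity inference** — dividing each estimated flux by its
   mass-action substrate/driver product yields per-minute activity
   proxies, smoothed into functions f_j(t).  A multiple-shooting-style
   refinement then splits the 30 minutes into 3-minute windows, each an
   independent initial-value problem starting from the splined data, and
   fits window coefficients C (activities C_{j,w}·f_j(t), C ≡ 1 leaves
   the model unchanged) against the concentrations from random starts.

Because no public raw dataset exists, the package ships a first-class
synthetic-data generator that emulates the experiment: steady-state
start, parametric activity scenarios (spike–decay, delayed peak,
undershoot–recover, step), 10 measured pools × 7 time points × 2
replicates, multiplicative U(1/1.5, 1.5) replicate noise, and the
boundary-flux table a real analysis would import from the prior model.

## Worked example

```python
import numpy as np, ceraflux as cf

model = cf.build_ceramide_network()               # 15 pools, 53 fluxes
scenario = cf.make_scenario(model, "heat_stress_demo")
dataset = cf.generate_dataset(model, scenario, noise_low_high=(1.0, 1.0),
                              seed=42)
ensemble, per_minute, fits = cf.estimate_from_observations(
    model, dataset.observations, dataset.boundary_table,
    n_restart=50, seed=42)

agg = ensemble.aggregates
v1 = agg[agg["flux_id"] == 1].sort_values("time_min")
est, truth = v1["mean"].to_numpy(), dataset.true_fluxes[1:, 0]
print("V1 mean flux  t=1: %.3f  t=5: %.3f  t=15: %.3f" % (est[0], est[4], est[14]))
print("V1 true flux  t=1: %.3f  t=5: %.3f  t=15: %.3f" % (truth[0], truth[4], truth[14]))
print("correlation with truth: %.3f" % np.corrcoef(est, truth)[0, 1])
```

prints

```
V1 mean flux  t=1: 0.736  t=5: 0.677  t=15: 0.534
V1 true flux  t=1: 0.979  t=5: 0.771  t=15: 0.433
correlation with truth: 0.949
```

V1 is the ceramide-synthase flux making C14/C16 DHC.  The estimated mean
course tracks the shape of the true flux (correlation 0.95) while the
sharp activation spike at ~2 minutes is damped — an expected consequence
of the 5-minute sampling grid and the smoothness constraint, and the
reason trends rather than magnitudes are the interpretable output.

The same pipeline runs from the shell:

```bash
ceraflux run-all --out demo_run --n-restart 100 --seed 0
ceraflux plot demo_run
```

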