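"""Ground-truth scenarios and simulated heat-stress datasets.

Generates everything the downstream estimators consume, with known truth:
time-varying enzyme-activity scenarios (fold change of the pre-stress
baseline), simulated per-minute trajectories of all 15 pools, duplicate
"observed" samples of the 10 measured ceramide pools every 5 minutes over
0-30 min with multiplicative replicate noise, and the boundary-flux
constraint table (per-minute group totals) that stands in for the fluxes
exported from the prior whole-pathway model.

All magnitudes are synthetic.  The scenario shapes emulate the qualitative
activity trends seen in heat-stressed yeast (immediate spike-and-decay of
the synthases, delayed mid-course peak of IPC utilization, an undershoot
with late recovery for very-long-chain synthesis), not measured values.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .model_core import (
    StoichiometricModel,
    evaluate_fluxes,
    simulate,
    solve_baseline_steady_state,
)

MEASURED_POOLS = tuple(range(1, 11))  # DHC and PHC; acyl CoAs are unobserved
SAMPLE_TIMES = (0.0, 5.0, 10.0, 15.0, 20.0, 25.0, 30.0)
MINUTES = np.arange(31.0)

SHAPES = ("flat", "spike_decay", "delayed_peak", "undershoot_recover", "step_change")


def _bump(t, t_peak, decay):
    """Unit-height bump: 0 at t=0, 1 at t=t_peak, exponential tail ~decay."""
    t = np.asarray(t, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (t / t_peak) ** (t_peak / decay) * np.exp((t_peak - t) / decay)
    return np.where(t <= 0, 0.0, out)


def _shape_fold(shape: str, params: dict, t):
    t = np.asarray(t, dtype=float)
    if shape == "flat":
        return np.ones_like(t)
    if shape in ("spike_decay", "delayed_peak"):
        peak = params["peak_fold"]
        tp = params["peak_time"]
        tau = params.get("decay", tp)
        return 1.0 + (peak - 1.0) * _bump(t, tp, tau)
    if shape == "undershoot_recover":
        peak = params["peak_fold"]
        tp = params["peak_time"]
        tau = params.get("decay", tp)
        depth = params.get("undershoot_depth", 0.7)
        t_u = params.get("undershoot_time", 4.0 * tp)
        f = 1.0 + (peak - 1.0) * _bump(t, tp, tau) - depth * _bump(t, t_u, 8.0)
        return np.maximum(f, 0.0)
    if shape == "step_change":
        # baseline up to and including t_step, stepped strictly after it
        fold = params["fold"]
        t_step = params["t_step"]
        return np.where(t <= t_step, 1.0, fold)
    raise ValueError(f"unknown shape {shape!r}")


_DEFAULTS = {
    "flat": {},
    "spike_decay": {"peak_fold": 4.0, "peak_time": 2.0},
    "delayed_peak": {"peak_fold": 3.0, "peak_time": 10.0, "decay": 6.0},
    "undershoot_recover": {"peak_fold": 5.0, "peak_time": 1.5},
    "step_change": {"fold": 2.0, "t_step": 9.0},
}


@dataclass
class ActivityScenario:
    """Per-flux parametric activity trajectories, as fold of baseline.

    Every trajectory starts at fold 1 at t=0 and stays nonnegative on
    [0, 30] minutes.
    """

    shapes: dict[int, str]
    params: dict[int, dict]
    seed: int = 0
    name: str = "custom"

    def fold(self, t) -> np.ndarray:
        """Fold-change matrix; shape (len(t), n_fluxes) or (n_fluxes,)."""
        t = np.asarray(t, dtype=float)
        scalar = t.ndim == 0
        tt = np.atleast_1d(t)
        n = len(self.shapes)
        out = np.empty((tt.size, n))
        for j in range(n):
            out[:, j] = _shape_fold(self.shapes[j + 1], self.params[j + 1], tt)
        return out[0] if scalar else out

    def activity_fn(self, baseline_activities: np.ndarray):
        a0 = np.asarray(baseline_activities, dtype=float)
        return lambda t: a0 * self.fold(float(t))

    def to_manifest(self) -> dict:
        return {
            "name": self.name,
            "seed": self.seed,
            "fluxes": {
                str(j): {"shape": self.shapes[j], "params": self.params[j]}
                for j in sorted(self.shapes)
            },
        }


#: Named presets; magnitudes are synthetic stand-ins, shapes qualitative.
SCENARIO_PRESETS: dict[str, dict] = {
    "flat": {},
    "heat_stress_demo": {
        "ceramide_synthase": ("spike_decay", {"peak_fold": 4.0, "peak_time": 2.0}),
        "dihydroceramidase": ("spike_decay", {"peak_fold": 5.0, "peak_time": 3.0, "decay": 4.0}),
        "phytoceramidase": ("delayed_peak", {"peak_fold": 2.5, "peak_time": 5.0, "decay": 5.0}),
        "IPCase": ("delayed_peak", {"peak_fold": 3.0, "peak_time": 10.0, "decay": 6.0}),
        "IPC_synthase": ("spike_decay", {"peak_fold": 2.0, "peak_time": 2.0, "decay": 5.0}),
        "DHC_hydroxylase": ("spike_decay", {"peak_fold": 3.0, "peak_time": 2.0}),
    },
    "synthase_C26_spike": {
        "ceramide_synthase": ("undershoot_recover", {"peak_fold": 5.0, "peak_time": 1.5}),
    },
    "ipcase_midpeak": {
        "IPCase": ("delayed_peak", {"peak_fold": 3.0, "peak_time": 10.0, "decay": 6.0}),
    },
    "dihydroceramidase_step": {
        "dihydroceramidase": ("step_change", {"fold": 2.0, "t_step": 9.0}),
    },
}


def make_scenario(
    model: StoichiometricModel,
    spec: dict | str | None = None,
    seed: int = 0,
    jitter: float = 0.0,
) -> ActivityScenario:
    """Build an :class:`ActivityScenario` from per-enzyme-class assignments.

    ``spec`` maps enzyme class (or flux id) to ``(shape, params)``; a preset
    name or None (flat) is also accepted.  ``jitter`` multiplies each
    flux's peak parameter by an independent U(1-jitter, 1+jitter) factor,
    so two calls with the same seed produce identical trajectories.
    """
    name = "custom"
    if spec is None:
        spec, name = {}, "flat"
    elif isinstance(spec, str):
        name = spec
        spec = SCENARIO_PRESETS[spec]

    shapes: dict[int, str] = {}
    params: dict[int, dict] = {}
    for f in model.fluxes:
        entry = spec.get(f.id, spec.get(f.enzyme_class, ("flat", {})))
        shape, p = entry
        if shape not in SHAPES:
            raise ValueError(f"unknown shape {shape!r} for flux V{f.id}")
        shapes[f.id] = shape
        params[f.id] = dict(_DEFAULTS[shape], **p)

    rng = np.random.default_rng(seed)
    for j in sorted(shapes):
        p = params[j]
        if jitter > 0 and shapes[j] != "flat":
            key = "peak_fold" if "peak_fold" in p else "fold"
            p[key] = p[key] * rng.uniform(1 - jitter, 1 + jitter)
        peak = p.get("peak_fold", p.get("fold", 1.0))
        if not 0.1 <= peak <= 20.0:
            raise ValueError(f"flux V{j}: peak fold {peak} outside [0.1, 20]")
        tpk = p.get("peak_time", p.get("t_step", 0.0))
        if not 0.0 <= tpk <= 30.0:
            raise ValueError(f"flux V{j}: peak time {tpk} outside [0, 30]")
    return ActivityScenario(shapes=shapes, params=params, seed=seed, name=name)


def default_baseline(model: StoichiometricModel) -> np.ndarray:
    """Baseline pool concentrations (arbitrary units) spanning ~3 orders of
    magnitude across species, mimicking the large spread in prevalence of
    ceramide variants (C26 PHC by far the most abundant)."""
    dhc = [0.5, 0.2, 0.1, 1.0, 5.0]
    phc = [1.0, 0.5, 0.2, 2.0, 50.0]
    coa = [0.8, 0.6, 0.3, 0.4, 0.2]
    base = np.array(dhc + phc + coa)
    if model.n_pools != base.size:
        raise ValueError("default baseline only defined for the 15-pool network")
    return base


@dataclass
class SyntheticDataset:
    """Simulated heat-stress dataset with full ground truth attached."""

    observations: pd.DataFrame  # time_min, replicate, pool, value
    truth: pd.DataFrame         # per-minute, tidy: time_min, pool, value
    truth_states: np.ndarray    # (31, n_pools)
    true_fluxes: np.ndarray     # (31, n_fluxes)
    true_activities: np.ndarray  # (31, n_fluxes), absolute units
    boundary_table: pd.DataFrame  # time_min, group, value
    baseline: np.ndarray
    baseline_activities: np.ndarray
    baseline_fluxes: np.ndarray
    noise_factors: np.ndarray
    scenario: ActivityScenario
    seed: int
    noise_bounds: tuple[float, float] = (1.0, 1.0)
    model: StoichiometricModel | None = field(default=None, repr=False)

    def write(self, outdir) -> dict:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name, df in [
            ("observations", self.observations),
            ("truth_concentrations", self.truth),
            ("boundary_table", self.boundary_table),
        ]:
            p = outdir / f"{name}.csv"
            df.to_csv(p, index=False)
            paths[name] = str(p)
        flux_df = pd.DataFrame(
            self.true_fluxes, columns=[f"V{j + 1}" for j in range(self.true_fluxes.shape[1])]
        )
        flux_df.insert(0, "time_min", MINUTES.astype(int))
        p = outdir / "truth_fluxes.csv"
        flux_df.to_csv(p, index=False)
        paths["truth_fluxes"] = str(p)
        manifest = {
            "seed": self.seed,
            "noise_bounds": list(self.noise_bounds),
            "scenario": self.scenario.to_manifest(),
        }
        mp = outdir / "scenario_manifest.json"
        mp.write_text(json.dumps(manifest, indent=2))
        paths["manifest"] = str(mp)
        return paths


def generate_dataset(
    model: StoichiometricModel,
    scenario: ActivityScenario,
    x0: np.ndarray | None = None,
    noise_low_high: tuple[float, float] = (1 / 1.5, 1.5),
    seed: int = 0,
    n_replicates: int = 2,
    sample_times=SAMPLE_TIMES,
    noise_model: str = "uniform",
) -> SyntheticDataset:
    """Simulate the scenario from its steady-state start and sample it.

    Observed values are the simulated truth at the sample times multiplied
    by i.i.d. factors from U(a, b) (default U(1/1.5, 1.5), matching a
    typical duplicate-measurement spread), independently per replicate,
    time and pool.  Only the 10 DHC/PHC pools are observed.
    """
    a, b = noise_low_high
    if not 0 < a <= 1 <= b:
        raise ValueError("noise bounds must satisfy 0 < a <= 1 <= b")
    if x0 is None:
        x0 = default_baseline(model)
    x0 = np.asarray(x0, dtype=float)

    a0 = solve_baseline_steady_state(model, x0)
    act_fn = scenario.activity_fn(a0)
    states = simulate(model, act_fn, x0, MINUTES)

    n_f = model.n_fluxes
    fluxes = np.empty((MINUTES.size, n_f))
    acts = np.empty((MINUTES.size, n_f))
    for i, t in enumerate(MINUTES):
        acts[i] = act_fn(t)
        fluxes[i] = evaluate_fluxes(model, states[i], acts[i], t)

    rng = np.random.default_rng(seed)
    sample_times = np.asarray(sample_times, dtype=float)
    idx = sample_times.astype(int)
    n_obs = (len(sample_times), n_replicates, len(MEASURED_POOLS))
    if noise_model == "uniform":
        factors = rng.uniform(a, b, size=n_obs)
    elif noise_model == "lognormal":
        sigma = np.log(b) / 2 if b > 1 else 0.0
        factors = rng.lognormal(0.0, sigma, size=n_obs)
    else:
        raise ValueError(f"unknown noise model {noise_model!r}")

    rows = []
    for i, t in enumerate(sample_times):
        for r in range(n_replicates):
            for k, pool in enumerate(MEASURED_POOLS):
                rows.append((t, r + 1, pool, states[idx[i], pool - 1] * factors[i, r, k]))
    obs = pd.DataFrame(rows, columns=["time_min", "replicate", "pool", "value"])

    truth = pd.DataFrame(
        [(int(t), p + 1, states[i, p]) for i, t in enumerate(MINUTES) for p in range(model.n_pools)],
        columns=["time_min", "pool", "value"],
    )

    ds = SyntheticDataset(
        observations=obs,
        truth=truth,
        truth_states=states,
        true_fluxes=fluxes,
        true_activities=acts,
        boundary_table=pd.DataFrame(),
        baseline=x0,
        baseline_activities=a0,
        baseline_fluxes=fluxes[0].copy(),
        noise_factors=factors,
        scenario=scenario,
        seed=seed,
        noise_bounds=(a, b),
        model=model,
    )
    ds.boundary_table = export_boundary_table(ds)
    return ds


def export_boundary_table(
    dataset: SyntheticDataset,
    groups: dict[str, list[int]] | None = None,
) -> pd.DataFrame:
    """Per-minute summed true flux of each constrained group.

    These totals are exactly what the flux estimator is allowed to know
    about the prior whole-pathway model.  Fluxes covered by no group (and
    not declared unconstrained in the topology) trigger a coverage warning.
    """
    model = dataset.model
    if groups is None:
        groups = model.groups
    covered = {fid for members in groups.values() for fid in members}
    exempt = set(model.unconstrained_fluxes)
    missing = sorted(set(range(1, model.n_fluxes + 1)) - covered - exempt)
    if missing:
        warnings.warn(
            "fluxes not covered by any boundary group: "
            + ", ".join(f"V{j}" for j in missing),
            stacklevel=2,
        )
    rows = []
    for i, t in enumerate(MINUTES):
        for name, members in groups.items():
            total = sum(dataset.true_fluxes[i, fid - 1] for fid in members)
            rows.append((int(t), name, total))
    return pd.DataFrame(rows, columns=["time_min", "group", "value"])
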