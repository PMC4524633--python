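"""From estimated fluxes to time-varying enzyme activities.

Because enzyme activities enter every GMA flux linearly and substrates
with power 1, dividing an estimated flux by its mass-action substrate and
driver product yields a Vmax-like activity proxy,

    a_j(t) = v_j(t) / (prod substrate pools * prod boundary drivers).

Proxies are smoothed with splines into continuous activity functions
f_j(t), which are then refined against the concentration data by a
multiple-shooting-style windowed search: the 30-minute experiment is split
into 3-minute windows, each window is its own initial-value problem
starting from the splined concentrations at its left edge (never from the
previous window's simulated endpoint), the activities inside window w are
replaced by C_{j,w} * f_j(t), and the coefficients C are fit to minimize
the concentration SSE inside the window from many random starts.  With
all coefficients equal to 1 the ODEs are unchanged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import make_smoothing_spline
from scipy.optimize import least_squares

from .model_core import StoichiometricModel, evaluate_fluxes
from .synthetic_data import MEASURED_POOLS

WINDOW_LEN = 3.0
MINUTES = np.arange(31.0)


# ---------------------------------------------------------------------------
# activity proxies
# ---------------------------------------------------------------------------

@dataclass
class ActivityProfile:
    """Per-minute Vmax-like proxy of one flux, absolute and fold-of-baseline."""

    flux_id: int
    times: np.ndarray
    proxy: np.ndarray          # absolute units; NaN where a substrate was 0
    fold: np.ndarray           # proxy / proxy at t=0
    missing: np.ndarray        # bool mask of flagged minutes


def reconstruct_unmeasured(
    model: StoichiometricModel,
    x0: np.ndarray,
    flux_course: np.ndarray,
    floor: float = 1e-9,
) -> np.ndarray:
    """Per-minute estimates of all pools, integrating S.v for the
    unmeasured acyl-CoA pools.

    ``flux_course`` is (31, n_fluxes) including the baseline row; the
    discrete update X(t) = X(t-1) + (S v(t)) matches the slope convention
    of the flux estimator.  Measured pools are left untouched (callers
    overwrite them with splined values).
    """
    states = np.tile(np.asarray(x0, dtype=float), (flux_course.shape[0], 1))
    for t in range(1, flux_course.shape[0]):
        states[t] = states[t - 1] + model.S @ flux_course[t]
    return np.maximum(states, floor)


def compute_activity_proxies(
    flux_course: np.ndarray,
    concentrations: np.ndarray,
    model: StoichiometricModel,
    times: np.ndarray = MINUTES,
) -> dict[int, ActivityProfile]:
    """Divide each flux course by its substrate/driver product.

    ``flux_course`` and ``concentrations`` are (n_t, n_fluxes) and
    (n_t, n_pools) on the same time grid (t=0 row = baseline).  Minutes
    where a substrate concentration is zero are flagged and set missing.
    """
    n_t = flux_course.shape[0]
    profiles: dict[int, ActivityProfile] = {}
    denom = np.empty((n_t, model.n_fluxes))
    for i, t in enumerate(times):
        denom[i] = evaluate_fluxes(model, concentrations[i], np.ones(model.n_fluxes), t)
    for j, fx in enumerate(model.fluxes):
        with np.errstate(divide="ignore", invalid="ignore"):
            proxy = np.where(denom[:, j] > 0, flux_course[:, j] / denom[:, j], np.nan)
        missing = ~np.isfinite(proxy)
        if missing.any():
            warnings.warn(
                f"flux V{fx.id}: zero substrate at minutes "
                f"{times[missing].astype(int).tolist()}; proxy set missing",
                stacklevel=2,
            )
        a0 = proxy[0]
        fold = proxy / a0 if np.isfinite(a0) and a0 > 0 else np.full(n_t, np.nan)
        profiles[fx.id] = ActivityProfile(
            flux_id=fx.id, times=times, proxy=proxy, fold=fold, missing=missing
        )
    return profiles


def smooth_activities(
    profiles: dict[int, ActivityProfile],
    smoothing: float | None = None,
) -> dict[int, object]:
    """Smoothing-spline fits f_j(t) >= 0 of the activity proxies.

    Negative spline excursions are floored at 0.  Fluxes with fewer than 4
    valid minutes are excluded with a warning.
    """
    out = {}
    for fid, prof in profiles.items():
        ok = ~prof.missing
        if ok.sum() < 4:
            warnings.warn(f"flux V{fid}: fewer than 4 valid minutes; excluded",
                          stacklevel=2)
            continue
        sp = make_smoothing_spline(prof.times[ok], prof.proxy[ok], lam=smoothing)
        out[fid] = (lambda t, sp=sp: np.maximum(np.asarray(sp(t), dtype=float), 0.0))
    return out


# ---------------------------------------------------------------------------
# multiple-shooting windowed refinement
# ---------------------------------------------------------------------------

@dataclass
class WindowCoefficients:
    """Refined per-window activity multipliers C (C=1 leaves the model
    unchanged).  ``coefficients`` holds the best solution per window,
    expanded to per-flux; ``ensemble`` keeps all random-start solutions."""

    window_starts: np.ndarray            # (n_windows,)
    window_len: float
    coefficients: np.ndarray             # (n_windows, n_fluxes)
    ensemble: np.ndarray                 # (n_windows, n_inits, n_fluxes)
    sse: np.ndarray                      # (n_windows, n_inits) data-fit SSE
    best: np.ndarray                     # (n_windows,) index of best init
    mode: str = "per_flux"
    failed_windows: list[int] = field(default_factory=list)


class _FastSim:
    """Window simulator with pre-tabulated activity*driver products.

    For networks where every flux has at most one internal substrate (true
    for the ceramide network) the GMA ODE is linear in the state,
    x' = M(t) x + b(t), with a Metzler matrix M.  Each fixed step advances
    the state with the matrix exponential of the augmented system
    [[M, b], [0, 0]] evaluated at the step midpoint (second-order Magnus).
    This is unconditionally stable no matter how large the coefficient
    multipliers get during the window search, preserves positivity
    exactly, and is smooth in the multipliers — an explicit stepper
    becomes unstable (hence noisy for the optimizer) once a probed
    coefficient pushes a pool's turnover past its stability limit.
    """

    def __init__(self, model: StoichiometricModel, act_table: np.ndarray,
                 t_table: np.ndarray):
        model._build_index()
        if model._sub_idx is None or model._sub_idx.size != model.n_fluxes:
            raise ValueError("fast simulator requires <=1 substrate/driver per flux")
        self.model = model
        self.sub_idx = model._sub_idx
        self.S = model.S
        self.n = model.n_pools
        self.t0 = t_table[0]
        self.dt = t_table[1] - t_table[0]
        self.nt = t_table.size
        # effective per-flux multiplier: activity * driver product
        drv = np.ones((model.n_fluxes, self.nt))
        for j, f in enumerate(model.fluxes):
            for name in f.boundary_inputs:
                drv[j] *= np.asarray(model.boundary_drivers[name](t_table), dtype=float)
        self.eff = act_table * drv  # (n_fluxes, nt)
        # indicator mapping flux -> substrate column (last = constant input)
        E = np.zeros((model.n_fluxes, self.n + 1))
        E[np.arange(model.n_fluxes), self.sub_idx] = 1.0
        self.E = E

    def _eff_at(self, t: float) -> np.ndarray:
        u = (t - self.t0) / self.dt
        i = min(max(int(u), 0), self.nt - 2)
        frac = u - i
        return self.eff[:, i] * (1 - frac) + self.eff[:, i + 1] * frac

    def rates(self, t: float, x: np.ndarray, mult: np.ndarray | float = 1.0):
        x_ext = np.append(np.maximum(x, 0.0), 1.0)
        return mult * self._eff_at(t) * x_ext[self.sub_idx]

    def simulate(self, x0, t_span, t_eval, mult=1.0):
        from scipy.linalg import expm

        t_start, t_end = float(t_span[0]), float(t_span[1])
        h = self.dt
        n_steps = int(round((t_end - t_start) / h))
        x_aug = np.append(np.asarray(x0, dtype=float), 1.0)
        t_eval = np.asarray(t_eval, dtype=float)
        out = np.empty((t_eval.size, self.n))
        k_out = 0
        eps = 1e-9
        if k_out < t_eval.size and abs(t_start - t_eval[k_out]) < eps:
            out[k_out] = x_aug[:-1]
            k_out += 1
        t = t_start
        A = np.zeros((self.n + 1, self.n + 1))
        for _ in range(n_steps):
            w = self._eff_at(t + h / 2) * mult
            A[: self.n] = (self.S * w) @ self.E
            x_aug = expm(A * h) @ x_aug
            t += h
            if k_out < t_eval.size and t >= t_eval[k_out] - eps:
                out[k_out] = x_aug[:-1]
                k_out += 1
        if not np.all(np.isfinite(x_aug)):
            raise RuntimeError(f"window simulation diverged near t={t:.2f}")
        if k_out != t_eval.size:
            raise RuntimeError("evaluation grid not aligned with step size")
        return out


def _class_map(model: StoichiometricModel) -> tuple[list[str], np.ndarray]:
    classes = sorted({f.enzyme_class for f in model.fluxes})
    idx = np.array([classes.index(f.enzyme_class) for f in model.fluxes])
    return classes, idx


def shooting_refine(
    model: StoichiometricModel,
    f_set: dict[int, object],
    splined_concentrations: np.ndarray,
    unmeasured_states: np.ndarray | None = None,
    window_len: float = WINDOW_LEN,
    n_inits: int = 5,
    init_dist: tuple[float, float] = (0.1, 10.0),
    coef_bounds: tuple[float, float] = (0.01, 100.0),
    seed: int = 0,
    mode: str = "per_flux",
    ridge: float = 1e-3,
    fine_dt: float = 0.01,
    measured_pools=MEASURED_POOLS,
) -> WindowCoefficients:
    """Refine the smoothed activities window by window.

    ``splined_concentrations`` is (31, n_pools): splined data for the
    measured pools; rows for unmeasured pools are taken from
    ``unmeasured_states`` if given, otherwise from a reference simulation
    of the model under the unrefined activities f (each window is an
    independent IVP and needs full initial state).

    Per window, coefficients (per flux, or per enzyme class with
    ``mode='per_class'``) minimize the baseline-scaled SSE between the
    simulated and splined measured concentrations at the minutes inside
    the window, from ``n_inits`` random starts drawn U(0.1, 10), subject
    to bounds; a mild ridge toward C=1 expresses that only slight
    adjustments of f are sought.  Windows whose simulations fail are
    flagged and keep C=1.
    """
    rng = np.random.default_rng(seed)
    n_f = model.n_fluxes
    fids = sorted(f_set)
    if len(fids) != n_f:
        raise ValueError("f_set must cover all fluxes")

    fine = np.arange(0.0, 30.0 + 1e-9, fine_dt)
    act_table = np.vstack([f_set[j + 1](fine) for j in range(n_f)])
    sim = _FastSim(model, act_table, fine)

    meas = np.array(measured_pools) - 1
    unmeas = np.array([i for i in range(model.n_pools) if i not in set(meas)])
    conc = np.asarray(splined_concentrations, dtype=float).copy()
    if unmeas.size:
        if unmeasured_states is None:
            x0 = conc[0].copy()
            ref = sim.simulate(x0, (0.0, 30.0), MINUTES)
            conc[:, unmeas] = ref[:, unmeas]
        else:
            conc[:, unmeas] = np.asarray(unmeasured_states, dtype=float)[:, unmeas]

    baseline_scale = np.maximum(conc[0, meas], 1e-12)

    if mode == "per_class":
        classes, cidx = _class_map(model)
        n_par = len(classes)
        expand = lambda c: c[cidx]
    elif mode == "per_flux":
        n_par = n_f
        expand = lambda c: c
    else:
        raise ValueError(f"unknown mode {mode!r}")

    starts = np.arange(0.0, 30.0, window_len)
    n_w = starts.size
    coefficients = np.ones((n_w, n_f))
    ensemble = np.ones((n_w, n_inits, n_f))
    sse = np.full((n_w, n_inits), np.nan)
    cost = np.full((n_w, n_inits), np.nan)  # data SSE + ridge penalty
    best = np.zeros(n_w, dtype=int)
    failed = []

    for w, s in enumerate(starts):
        t_eval = np.arange(s + 1.0, s + window_len + 1e-9, 1.0)
        x_init = conc[int(round(s))].copy()
        target = conc[t_eval.astype(int)][:, meas]

        def residuals(c):
            mult = expand(c)
            traj = sim.simulate(x_init, (s, t_eval[-1]), t_eval, mult=mult)
            res = ((traj[:, meas] - target) / baseline_scale).ravel()
            return np.concatenate([res, np.sqrt(ridge) * (c - 1.0)])

        inits = rng.uniform(init_dist[0], init_dist[1], size=(n_inits, n_par))
        win_ok = False
        for r in range(n_inits):
            try:
                fit = least_squares(
                    residuals, np.clip(inits[r], *coef_bounds),
                    bounds=coef_bounds, method="trf",
                    xtol=1e-12, ftol=1e-14, gtol=1e-12,
                )
                data_res = fit.fun[: target.size]
                ensemble[w, r] = expand(fit.x)
                sse[w, r] = float(np.sum(data_res**2))
                cost[w, r] = float(2.0 * fit.cost)
                win_ok = True
            except RuntimeError:
                ensemble[w, r] = np.nan
        if not win_ok:
            failed.append(w)
            continue
        best[w] = int(np.nanargmin(cost[w]))
        coefficients[w] = ensemble[w, best[w]]

    return WindowCoefficients(
        window_starts=starts,
        window_len=window_len,
        coefficients=coefficients,
        ensemble=ensemble,
        sse=sse,
        best=best,
        mode=mode,
        failed_windows=failed,
    )


def window_of(t: float, window_len: float = WINDOW_LEN, n_windows: int = 10) -> int:
    """Window index owning minute t (minute 3 belongs to window 0-3)."""
    if t <= 0:
        return 0
    return min(int(np.ceil(t / window_len)) - 1, n_windows - 1)


def refined_activity_course(
    coeffs: WindowCoefficients,
    f_set: dict[int, object],
    times: np.ndarray = MINUTES,
    member: int | None = None,
) -> np.ndarray:
    """(n_t, n_fluxes) refined activities C_{j,w(t)} * f_j(t); ``member``
    selects one ensemble solution (default: the per-window best)."""
    n_f = len(f_set)
    times = np.asarray(times, dtype=float)
    F = np.vstack([
        np.broadcast_to(np.asarray(f_set[j + 1](times), dtype=float),
                        times.shape)
        for j in range(n_f)
    ])  # (n_f, n_t)
    n_w = coeffs.window_starts.size
    widx = np.array([window_of(t, coeffs.window_len, n_w) for t in times])
    C = coeffs.coefficients if member is None else coeffs.ensemble[:, member]
    return C[widx] * F.T


def assemble_activity_report(
    coeffs: WindowCoefficients,
    f_set: dict[int, object],
    model: StoichiometricModel,
    times: np.ndarray = MINUTES,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Final per-flux fold-change activity trends.

    Returns (summary, individuals): the summary holds the ensemble-averaged
    fold change per flux and minute with enzyme/chain class labels; the
    individuals table holds each random-start solution.  Every trend is
    normalized to 1 at t=0; window-boundary discontinuities are preserved.
    """
    n_inits = coeffs.ensemble.shape[1]
    members = []
    for m in range(n_inits):
        course = refined_activity_course(coeffs, f_set, times, member=m)
        members.append(course)
    members = np.array(members)  # (n_inits, n_t, n_f)
    with np.errstate(divide="ignore", invalid="ignore"):
        fold_members = members / members[:, :1, :]
    with warnings.catch_warnings():
        # fluxes with zero baseline activity have no fold scale at all
        warnings.filterwarnings("ignore", "Mean of empty slice")
        fold_mean = np.nanmean(fold_members, axis=0)

    rows, irows = [], []
    for j, fx in enumerate(model.fluxes):
        ec = fx.enzyme_class
        cc = model.chain_class_of(fx.id) or ""
        for i, t in enumerate(times):
            rows.append((int(t), fx.id, ec, cc, fold_mean[i, j]))
            for m in range(n_inits):
                irows.append((int(t), fx.id, m, fold_members[m, i, j]))
    summary = pd.DataFrame(
        rows, columns=["time_min", "flux_id", "enzyme_class", "chain_class",
                       "fold_change_mean"],
    )
    individuals = pd.DataFrame(
        irows, columns=["time_min", "flux_id", "member", "fold_change"])
    return summary, individuals
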