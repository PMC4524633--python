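"""End-to-end orchestration: generate -> preprocess -> fluxes -> activities.

Every stage writes tidy CSV/JSON outputs into the run directory and the
run manifest records config, seeds and per-file checksums, so a run is
fully reproducible from its manifest.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .model_core import build_ceramide_network, load_topology
from .synthetic_data import make_scenario, generate_dataset, MEASURED_POOLS
from .preprocessing import preprocess_dataset
from .flux_estimation import (
    DEFAULT_WEIGHTS, build_problems, ensemble_estimate, sse_range_check,
)
from .activity_inference import (
    compute_activity_proxies, smooth_activities, shooting_refine,
    assemble_activity_report, reconstruct_unmeasured, MINUTES,
)


class PipelineError(RuntimeError):
    """A stage failed; partial outputs are preserved in the run directory."""


@dataclass
class RunConfig:
    out_dir: str = "ceraflux_run"
    topology_path: str | None = None        # None = bundled default network
    data_path: str | None = None            # observations CSV; None = generate
    boundary_path: str | None = None        # boundary table CSV; None = generate
    scenario: str = "heat_stress_demo"      # preset used when generating
    noise_low: float = 1 / 1.5
    noise_high: float = 1.5
    seed: int = 0
    n_restart: int = 100
    init_low: float = 0.01
    init_high: float = 100.0
    weights: tuple[float, float, float] = DEFAULT_WEIGHTS
    smoothing: float | None = None
    window_len: float = 3.0
    n_inits: int = 5
    coef_mode: str = "per_class"
    fine_dt: float = 0.01  # activity-table step of the window simulator


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full inference pipeline; returns the manifest dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": asdict(config),
        "stages": {},
        "files": {},
    }
    stage = "setup"
    try:
        topo = load_topology(config.topology_path) if config.topology_path else None
        model = build_ceramide_network(topo)

        # -- generate ---------------------------------------------------
        stage = "generate"
        t0 = time.perf_counter()
        if config.data_path is None:
            scenario = make_scenario(model, config.scenario, seed=config.seed)
            ds = generate_dataset(
                model, scenario,
                noise_low_high=(config.noise_low, config.noise_high),
                seed=config.seed,
            )
            paths = ds.write(out / "data")
            obs = ds.observations
            boundary = ds.boundary_table
            coa0 = ds.baseline[10:]
            manifest["files"].update(paths)
        else:
            obs = pd.read_csv(config.data_path)
            if config.boundary_path is None:
                raise PipelineError("missing input: boundary table "
                                    "(boundary_path) is required with data_path")
            boundary = pd.read_csv(config.boundary_path)
            coa0 = np.ones(5)
        manifest["stages"]["generate"] = round(time.perf_counter() - t0, 3)

        # -- preprocess -------------------------------------------------
        stage = "preprocess"
        t0 = time.perf_counter()
        per_minute, fits = preprocess_dataset(obs, smoothing=config.smoothing)
        per_minute.to_csv(out / "per_minute.csv", index=False)
        manifest["stages"]["preprocess"] = round(time.perf_counter() - t0, 3)

        # -- flux estimation --------------------------------------------
        stage = "estimate_fluxes"
        t0 = time.perf_counter()
        problems, v_base = build_problems(
            model, per_minute, boundary, weights=config.weights)
        ens = ensemble_estimate(
            problems, n_restart=config.n_restart,
            init_low_high=(config.init_low, config.init_high),
            seed=config.seed, v_baseline=v_base,
        )
        ens.aggregates.to_csv(out / "flux_aggregates.csv", index=False)
        ens_dir = out / "ensemble"
        ens_dir.mkdir(exist_ok=True)
        cols = [f"V{j + 1}" for j in range(model.n_fluxes)]
        for i, t in enumerate(ens.times):
            pd.DataFrame(ens.solutions[i], columns=cols).to_csv(
                ens_dir / f"minute_{int(t):02d}.csv", index=False)
        slopes = np.zeros((len(problems), model.n_pools))
        for i, p in enumerate(problems):
            slopes[i] = p.slopes
        sse_report = sse_range_check(ens, slopes, model)
        sse_report.to_csv(out / "sse_range_report.csv", index=False)
        manifest["stages"]["estimate_fluxes"] = round(time.perf_counter() - t0, 3)

        # -- activity inference -----------------------------------------
        stage = "infer_activities"
        t0 = time.perf_counter()
        course = ens.course("mean", include_baseline=True)
        conc = np.empty((31, model.n_pools))
        for pool, grp in per_minute.groupby("pool"):
            conc[:, pool - 1] = grp.sort_values("time_min")["value"].to_numpy()
        x0_full = conc[0].copy()
        x0_full[10:] = coa0
        recon = reconstruct_unmeasured(model, x0_full, course)
        conc[:, 10:] = recon[:, 10:]
        profiles = compute_activity_proxies(course, conc, model)
        f_set = smooth_activities(profiles, smoothing=config.smoothing)
        coeffs = shooting_refine(
            model, f_set, conc,
            window_len=config.window_len, n_inits=config.n_inits,
            seed=config.seed, mode=config.coef_mode,
            fine_dt=config.fine_dt,
        )
        summary, individuals = assemble_activity_report(coeffs, f_set, model)
        summary["fold_change_individuals_ref"] = "activity_individuals.csv"
        summary.to_csv(out / "activity_report.csv", index=False)
        individuals.to_csv(out / "activity_individuals.csv", index=False)
        coef_manifest = {
            "seed": config.seed,
            "mode": coeffs.mode,
            "window_len": coeffs.window_len,
            "window_starts": coeffs.window_starts.tolist(),
            "failed_windows": coeffs.failed_windows,
            "coefficients": coeffs.coefficients.tolist(),
        }
        (out / "window_coefficients.json").write_text(
            json.dumps(coef_manifest, indent=2))
        manifest["stages"]["infer_activities"] = round(time.perf_counter() - t0, 3)

    except PipelineError:
        raise
    except Exception as exc:  # halt with stage name, keep partial outputs
        raise PipelineError(f"stage '{stage}' failed: {exc}") from exc

    for p in sorted(out.rglob("*.csv")):
        manifest["files"][str(p.relative_to(out))] = _checksum(p)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
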