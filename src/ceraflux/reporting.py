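"""Figure generation for a finished pipeline run."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

#: Enzyme classes acting directly on the ceramide pools.
CERAMIDE_CLASSES = (
    "ceramide_synthase",
    "dihydroceramidase",
    "phytoceramidase",
    "IPC_synthase",
    "IPCase",
)


def plot_activity_panels(summary: pd.DataFrame, outdir) -> list[str]:
    """One panel per ceramide-facing enzyme class: averaged fold-change
    activity trends of all member fluxes."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for ec in CERAMIDE_CLASSES:
        sub = summary[summary["enzyme_class"] == ec]
        if sub.empty:
            continue
        fig, ax = plt.subplots(figsize=(6, 4))
        for fid, grp in sub.groupby("flux_id"):
            cc = grp["chain_class"].iloc[0]
            ax.plot(grp["time_min"], grp["fold_change_mean"], label=f"V{fid} {cc}")
        ax.axhline(1.0, color="k", lw=0.5, ls=":")
        ax.set_xlabel("time (min)")
        ax.set_ylabel("activity fold change")
        ax.set_title(ec.replace("_", " "))
        ax.legend(fontsize=7)
        p = outdir / f"activity_{ec}.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        paths.append(str(p))
    return paths


def plot_flux_bands(aggregates: pd.DataFrame, flux_ids, outdir) -> str:
    """Ensemble band plot (mean, median, p20-p80) for selected fluxes."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    flux_ids = list(flux_ids)
    fig, axes = plt.subplots(
        1, len(flux_ids), figsize=(3 * len(flux_ids), 3), squeeze=False)
    for ax, fid in zip(axes[0], flux_ids):
        sub = aggregates[aggregates["flux_id"] == fid].sort_values("time_min")
        ax.fill_between(sub["time_min"], sub["p20"], sub["p80"],
                        alpha=0.3, label="p20-p80")
        ax.plot(sub["time_min"], sub["mean"], label="mean")
        ax.plot(sub["time_min"], sub["median"], "k*", ms=3, label="median")
        ax.set_title(f"V{fid}")
        ax.set_xlabel("time (min)")
    axes[0, 0].set_ylabel("flux")
    axes[0, 0].legend(fontsize=7)
    fig.tight_layout()
    p = Path(outdir) / "flux_bands.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    return str(p)


def plot_concentration_overlay(
    per_minute: pd.DataFrame,
    activity_report_dir,
    outdir,
    window_len: float = 3.0,
) -> str:
    """Splined data per measured pool with window boundaries marked."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pools = sorted(per_minute["pool"].unique())
    fig, axes = plt.subplots(2, 5, figsize=(15, 5), squeeze=False)
    for ax, pool in zip(axes.ravel(), pools):
        sub = per_minute[per_minute["pool"] == pool]
        ax.plot(sub["time_min"], sub["value"], "ro-", ms=2, lw=0.8)
        for b in range(0, 31, int(window_len)):
            ax.axvline(b, color="gray", lw=0.4, alpha=0.5)
        ax.set_title(f"pool {pool}", fontsize=8)
    fig.tight_layout()
    p = outdir / "concentration_overlay.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    return str(p)


def plot_reports(run_dir) -> list[str]:
    """Generate all figures for a pipeline run directory."""
    run_dir = Path(run_dir)
    figdir = run_dir / "figures"
    paths = []
    summary = pd.read_csv(run_dir / "activity_report.csv")
    paths += plot_activity_panels(summary, figdir)
    agg = pd.read_csv(run_dir / "flux_aggregates.csv")
    paths.append(plot_flux_bands(agg, [1, 6, 11, 16, 21], figdir))
    pm = pd.read_csv(run_dir / "per_minute.csv")
    paths.append(plot_concentration_overlay(pm, run_dir, figdir))
    return paths
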