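"""Figure rendering for a completed pipeline run directory.

Reads only the run's CSV/JSON outputs and produces: egg-laying rate and
effect-size-vs-age curves for the fitted parameter classes, histograms of
the fitted k_o and S_0, LOD curves with their permutation thresholds,
genotype-partition plots, and a sign-epistasis-zone diagram.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from . import io as slio
from .model import EggLayingParams, egg_rate

__all__ = ["ReportError", "render_report", "REQUIRED_FILES"]

REQUIRED_FILES = (
    "map.csv",
    "genotypes.csv",
    "phenotypes.csv",
    "params.csv",
)


class ReportError(RuntimeError):
    """A stage output required by the report is missing."""


def _rate_curves(params: pd.DataFrame, out: Path) -> None:
    t = np.linspace(0.0, 120.0, 400)
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 3.2))
    classes = params.drop_duplicates(subset=["k_o", "s_0"])
    for _, row in classes.head(8).iterrows():
        p = EggLayingParams(k_o=row["k_o"], k_f=row["k_f"], s_0=row["s_0"])
        ax1.plot(t[1:], egg_rate(p, t[1:]), lw=1)
    ax1.set_xlabel("hours post-L4")
    ax1.set_ylabel("egg-laying rate (eggs/animal/h)")
    ax1.set_title("fitted classes")
    ax2.hist(params["k_o"].dropna(), bins=20, alpha=0.6, label="k_o")
    ax2.set_xlabel("fitted k_o")
    ax2.set_ylabel("strains")
    ax2b = ax2.twiny()
    ax2b.hist(params["s_0"].dropna(), bins=20, alpha=0.4, color="C1", label="S_0")
    ax2b.set_xlabel("fitted S_0")
    fig.tight_layout()
    fig.savefig(out / "fitted_parameters.png", dpi=120)
    plt.close(fig)


def _lod_curves(run_dir: Path, out: Path) -> None:
    scans = sorted(run_dir.glob("scan_*.csv"))
    if not scans:
        return
    fig, axes = plt.subplots(len(scans), 1, figsize=(8, 2.4 * len(scans)),
                             squeeze=False)
    for ax, scan_path in zip(axes[:, 0], scans):
        df = pd.read_csv(scan_path)
        xs = np.arange(len(df))
        for col in [c for c in df.columns if c.startswith("lod_")]:
            ax.plot(xs, df[col], lw=0.9, label=col)
        thr_path = run_dir / scan_path.name.replace("scan_", "thresholds_").replace(
            ".csv", ".json"
        )
        if thr_path.exists():
            for name, rec in slio.read_json(thr_path).items():
                ax.axhline(rec["threshold"], ls="--", lw=0.8, color="grey")
        for _, grp in df.groupby("chrom", sort=False):
            ax.axvline(grp.index[-1] + 0.5, color="k", lw=0.4, alpha=0.3)
        ax.set_ylabel("LOD")
        ax.set_title(scan_path.stem)
        ax.legend(fontsize=6, ncol=4)
    axes[-1, 0].set_xlabel("marker index (chromosomes in map order)")
    fig.tight_layout()
    fig.savefig(out / "lod_curves.png", dpi=120)
    plt.close(fig)


def _partition_plot(run_dir: Path, out: Path) -> None:
    path = run_dir / "partition.csv"
    if not path.exists():
        return
    df = pd.read_csv(path)
    gcols = [c for c in df.columns if c.startswith("g_")]
    if len(gcols) < 2:
        return
    fig, ax = plt.subplots(figsize=(6, 3.2))
    for (gfocal,), grp in df.groupby(gcols[:1]):
        for gmod, sub in grp.groupby(gcols[1]):
            sub = sub.sort_values("timepoint")
            ax.errorbar(
                sub["timepoint"],
                sub["mean"],
                yerr=sub["sem"],
                marker="o",
                ls="-" if gmod == 0 else "--",
                label=f"{gcols[0]}={gfocal}, {gcols[1]}={gmod}",
            )
    ax.set_xlabel("assay window midpoint (h post-L4)")
    ax.set_ylabel("mean rate (eggs/animal/h)")
    ax.legend(fontsize=6)
    fig.tight_layout()
    fig.savefig(out / "partition.png", dpi=120)
    plt.close(fig)


def _zone_plot(run_dir: Path, out: Path) -> None:
    path = run_dir / "zone.csv"
    if not path.exists():
        return
    z = pd.read_csv(path).iloc[0]
    t = np.linspace(0.5, 120.0, 400)
    fig, ax = plt.subplots(figsize=(6, 3.2))
    for name, ko, style in (
        ("base", z["ko_base"], "-"),
        ("mod", z["ko_mod"], "--"),
        ("focal", z["ko_focal"], "-"),
        ("focal+mod", z["ko_focal_mod"], "--"),
    ):
        p = EggLayingParams(k_o=ko, k_f=z["k_f"], s_0=z["s_0"])
        ax.plot(t, egg_rate(p, t), style, label=f"{name} (k_o={ko:g})")
    if z["t_close"] > z["t_open"]:
        ax.axvspan(z["t_open"], z["t_close"], color="0.85", label="sign-epistasis zone")
    ax.set_xlabel("hours post-L4")
    ax.set_ylabel("egg-laying rate")
    ax.legend(fontsize=6)
    fig.tight_layout()
    fig.savefig(out / "sign_epistasis_zone.png", dpi=120)
    plt.close(fig)


def render_report(run_dir) -> list[str]:
    """Render all figures for a run directory; returns the files written.

    Raises ReportError listing the absent stage outputs if the run is
    incomplete.
    """
    run_dir = Path(run_dir)
    missing = [f for f in REQUIRED_FILES if not (run_dir / f).exists()]
    if missing:
        raise ReportError(f"missing stage outputs: {missing}")
    out = run_dir / "report"
    out.mkdir(exist_ok=True)
    params = slio.read_params_csv(run_dir / "params.csv")
    _rate_curves(params, out)
    _lod_curves(run_dir, out)
    _partition_plot(run_dir, out)
    _zone_plot(run_dir, out)
    return sorted(p.name for p in out.iterdir())
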