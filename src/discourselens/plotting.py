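"""Basic figure rendering from exported pipeline tables.

Plots are generated only from the TSV exports, never from in-memory
state, so the tables are the complete interface.  Styling is minimal:
these are data-level renderings of the four figure families (rank +
ambient timeline, word shift bars, rank-rank histogram, contagiogram),
not publication graphics.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def plot_timeline(out_dir: Path, save: Path | None = None) -> Path:
    """Inverted-log rank series plus smoothed ambient happiness."""
    out_dir = Path(out_dir)
    rank = pd.read_csv(out_dir / "rank_series.tsv", sep="\t", parse_dates=["date"])
    amb = pd.read_csv(out_dir / "ambient.tsv", sep="\t", parse_dates=["date"])
    fig, (ax1, ax2) = plt.subplots(2, 1, figsize=(10, 6), sharex=True)
    ax1.plot(rank["date"], rank["rank"], ".", ms=2, alpha=0.5)
    ax1.plot(rank["date"], rank["smoothed"], "-", lw=1, color="black")
    ax1.set_yscale("log")
    ax1.invert_yaxis()
    ax1.set_ylabel("rank (inverted)")
    med = rank["rank"].median()
    if np.isfinite(med):
        ax1.axhline(med, color="red", lw=0.8)
    ax2.plot(amb["date"], amb["h_avg"], ".", ms=2, alpha=0.4)
    ax2.plot(amb["date"], amb["smoothed"], "-", lw=1, color="black")
    ax2.set_ylabel("ambient happiness")
    if len(amb):
        ax2.axhline(amb["h_avg"].median(), color="red", lw=0.8)
    fig.tight_layout()
    save = save or out_dir / "timeline.png"
    fig.savefig(save, dpi=120)
    plt.close(fig)
    return save


def plot_shift(shift_path, save: Path | None = None) -> Path:
    """Horizontal bar chart of the top word-shift contributions."""
    shift_path = Path(shift_path)
    df = pd.read_csv(shift_path, sep="\t", skiprows=1)
    top = df[df["top"]].iloc[::-1]
    colors = ["#d8a200" if h else "#3b6fb6" for h in (top["class"].str.startswith("+"))]
    fig, ax = plt.subplots(figsize=(6, 6))
    ax.barh(top["word"], top["contribution"], color=colors)
    ax.axvline(0, color="black", lw=0.8)
    ax.set_xlabel("contribution to Δ ambient happiness")
    fig.tight_layout()
    save = save or shift_path.with_suffix(".png")
    fig.savefig(save, dpi=120)
    plt.close(fig)
    return save


def plot_rank_rank_histogram(hist_path, save: Path | None = None) -> Path:
    """Log-rank vs log-rank cell counts with exclusive bands."""
    hist_path = Path(hist_path)
    cells = pd.read_csv(hist_path, sep="\t")
    fig, ax = plt.subplots(figsize=(6, 6))
    main = cells[cells["band"] == "main"]
    sc = ax.scatter(
        main["cell_x"], main["cell_y"], c=np.log10(main["count"] + 1),
        s=60, marker="s", cmap="viridis",
    )
    for band, marker in (("only_1", "<"), ("only_2", "v")):
        b = cells[cells["band"] == band]
        if len(b):
            ax.scatter(b["cell_x"], b["cell_y"], c="tomato", marker=marker, s=40)
    fig.colorbar(sc, ax=ax, label="log10(types + 1)")
    ax.set_xlabel("log10 rank cell (system 1)")
    ax.set_ylabel("log10 rank cell (system 2)")
    fig.tight_layout()
    save = save or hist_path.with_suffix(".png")
    fig.savefig(save, dpi=120)
    plt.close(fig)
    return save


def plot_contagiogram(out_dir: Path, save: Path | None = None) -> Path:
    """Three-panel contagiogram: monthly balance, weekday heatmap, ranks."""
    out_dir = Path(out_dir)
    cdir = out_dir / "contagiogram"
    balance = pd.read_csv(cdir / "balance.tsv", sep="\t")
    heat = pd.read_csv(cdir / "heatmap.tsv", sep="\t")
    panel = pd.read_csv(cdir / "rankpanel.tsv", sep="\t", parse_dates=["date"])
    fig, (ax1, ax2, ax3) = plt.subplots(
        3, 1, figsize=(10, 8), gridspec_kw={"height_ratios": [2, 1, 2]}
    )
    months = pd.PeriodIndex(balance["month"], freq="M").to_timestamp()
    ax1.stackplot(
        months, balance["f_ot"].fillna(0), balance["f_rt"].fillna(0),
        labels=["organic", "retweet"], colors=["#3b6fb6", "#e8862e"], alpha=0.8,
    )
    ax1.axhline(0.5, color="black", lw=0.6, ls="--")
    ax1.set_ylabel("share")
    ax1.legend(loc="upper left", fontsize=8)

    grid = heat.pivot_table(index="weekday", columns="month", values="R")
    im = ax2.imshow(
        np.log10(grid.to_numpy(dtype=float)), aspect="auto", cmap="RdGy_r",
        vmin=-1, vmax=1, interpolation="nearest",
    )
    ax2.set_ylabel("weekday")
    fig.colorbar(im, ax=ax2, label="log10 R")

    ax3.plot(panel["date"], panel["rank"], ".", ms=2, alpha=0.4)
    ax3.plot(panel["date"], panel["smoothed"], "-", color="black", lw=1)
    ax3.fill_between(
        panel["date"], panel["week_min"], panel["week_max"],
        color="gray", alpha=0.3,
    )
    ax3.set_yscale("log")
    ax3.invert_yaxis()
    ax3.set_ylabel("rank (inverted)")
    fig.tight_layout()
    save = save or out_dir / "contagiogram.png"
    fig.savefig(save, dpi=120)
    plt.close(fig)
    return save


def render_all(out_dir) -> list[Path]:
    """Render every figure whose source tables exist in ``out_dir``."""
    out_dir = Path(out_dir)
    made = []
    if (out_dir / "rank_series.tsv").exists():
        made.append(plot_timeline(out_dir))
    for shift in sorted((out_dir / "shifts").glob("shift_*.tsv")):
        made.append(plot_shift(shift))
    for hist in sorted(out_dir.glob("divergence_*_histogram.tsv")):
        made.append(plot_rank_rank_histogram(hist))
    if (out_dir / "contagiogram" / "balance.tsv").exists():
        made.append(plot_contagiogram(out_dir))
    return made
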