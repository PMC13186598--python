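"""Figure-style renderings of experiment CSVs (headless, Agg backend).

Plots are conveniences for eyeballing results; the CSVs written by the
experiments are the contract surface.  Each function takes the CSV a CLI
run produced and writes a PNG next to it.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import pandas as pd

__all__ = ["plot_sweep", "plot_shared_error", "plot_loose_additivity", "plot_iso_a"]


def _read(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise OSError(f"result file not found: {path}")
    try:
        df = pd.read_csv(path, comment="#")
    except Exception as err:  # malformed CSV
        raise OSError(f"could not parse result file {path}: {err}") from err
    if df.empty:
        raise OSError(f"result file {path} contains no rows")
    return df


def plot_sweep(csv_path: str | Path, out_png: str | Path) -> Path:
    """Two panels: mean slope vs rho (with analytic overlay and benchmark
    line) and benchmark rejection rate vs rho."""
    df = _read(csv_path)
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 3.6))
    ax1.plot(df["rho"], df["expected_slope"], color="tab:orange", label="expected")
    ax1.errorbar(
        df["rho"], df["mean_slope"], yerr=2 * df["mc_se_slope"],
        fmt="o", ms=3, color="tab:blue", label="simulated mean",
    )
    ax1.axhline(df["benchmark"].iloc[0], ls="--", color="k", lw=1, label="benchmark")
    ax1.set_xlabel(r"$\rho$")
    ax1.set_ylabel("slope")
    ax1.legend(fontsize=8)
    ax2.plot(df["rho"], 100 * df["rejection_rate"], "o-", ms=3, color="tab:red")
    ax2.axhline(100 * df["alpha"].iloc[0], ls=":", color="k", lw=1)
    ax2.set_xlabel(r"$\rho$")
    ax2.set_ylabel("benchmark rejection rate (%)")
    ax2.set_ylim(0, 100)
    fig.suptitle(f"{df['design'].iloc[0]} sweep (n={df['n'].iloc[0]})", fontsize=10)
    fig.tight_layout()
    out = Path(out_png)
    fig.savefig(out, dpi=150)
    plt.close(fig)
    return out


def plot_shared_error(
    csv_path: str | Path, out_png: str | Path,
    population_slopes: dict[str, float] | None = None,
) -> Path:
    """Three bootstrap-slope histograms with population-slope markers."""
    df = _read(csv_path)
    cols = ["slope_i_on_e", "slope_e_on_a", "slope_i_on_a"]
    titles = [r"$I \sim E$", r"$E \sim A$", r"$I \sim A$"]
    fig, axes = plt.subplots(1, 3, figsize=(10.5, 3.2))
    for ax, col, title in zip(axes, cols, titles):
        ax.hist(df[col], bins=60, color="tab:blue", alpha=0.75)
        if population_slopes and col in population_slopes:
            ax.axvline(population_slopes[col], color="tab:orange", lw=2)
        ax.set_title(title, fontsize=10)
        ax.set_xlabel("slope")
    axes[0].axvline(-1.0, ls="--", color="k", lw=1)
    fig.tight_layout()
    out = Path(out_png)
    fig.savefig(out, dpi=150)
    plt.close(fig)
    return out


def plot_loose_additivity(csv_path: str | Path, out_png: str | Path) -> Path:
    """Boxplot-style slope distributions vs noise with predicted overlay."""
    df = _read(csv_path)
    levels = sorted(df["noise_sd_deg"].unique())
    groups = [df.loc[df["noise_sd_deg"] == s, "slope"].to_numpy() for s in levels]
    pred = [df.loc[df["noise_sd_deg"] == s, "predicted_slope"].iloc[0] for s in levels]
    fig, ax = plt.subplots(figsize=(6.5, 4))
    ax.boxplot(groups, positions=levels, widths=0.3, showfliers=False)
    ax.plot(levels, pred, color="tab:orange", lw=2, label="predicted attenuation")
    ax.axhline(1.0, ls="--", color="k", lw=1)
    ax.set_xlabel("measurement-noise SD (deg)")
    ax.set_ylabel(r"slope of $A$ on $(I_{obs}+E_{obs})$")
    ax.legend(fontsize=8)
    fig.tight_layout()
    out = Path(out_png)
    fig.savefig(out, dpi=150)
    plt.close(fig)
    return out


def plot_iso_a(csv_paths: dict[str, str | Path], out_png: str | Path) -> Path:
    """Scatter of I vs E for the three iso-A demo scenarios."""
    fig, axes = plt.subplots(1, len(csv_paths), figsize=(3.2 * len(csv_paths), 3.2))
    for ax, (name, path) in zip(
        ([axes] if len(csv_paths) == 1 else axes), sorted(csv_paths.items())
    ):
        df = _read(path)
        ax.plot(df["explicit_deg"], df["implicit_deg"], "o")
        ax.set_title(f"scenario {name}", fontsize=10)
        ax.set_xlabel("explicit (deg)")
        ax.set_ylabel("implicit (deg)")
    fig.tight_layout()
    out = Path(out_png)
    fig.savefig(out, dpi=150)
    plt.close(fig)
    return out
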