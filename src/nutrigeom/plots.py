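"""Figure rendering: response-surface heatmaps and the two-curve forecast."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .surfaces import SurfaceFit

__all__ = ["plot_surface", "plot_forecast"]


def plot_surface(fit: SurfaceFit, path: str | Path, cmap: str = "RdYlBu_r") -> None:
    """Heatmap of a fitted intake surface with isolines, masked to the hull.

    Color runs blue (minimal fitted intake) to red (maximal) within the
    panel, unless the fit carries a shared scale from a grouped fit.
    """
    grid = fit.grid
    nx = grid["x"].nunique()
    nz = grid["z"].nunique()
    X = grid["x"].to_numpy().reshape(nz, nx)
    Z = grid["z"].to_numpy().reshape(nz, nx)
    F = grid["fitted"].to_numpy().reshape(nz, nx)
    vmin, vmax = fit.scale if fit.scale else (np.nanmin(F), np.nanmax(F))

    fig, ax = plt.subplots(figsize=(5, 4))
    pcm = ax.pcolormesh(X, Z, F, cmap=cmap, vmin=vmin, vmax=vmax, shading="auto")
    with np.errstate(invalid="ignore"):
        ax.contour(X, Z, F, colors="k", linewidths=0.5)
    fig.colorbar(pcm, ax=ax, label=f"fitted {fit.response} intake")
    title = f"{fit.response} intake"
    if fit.group:
        title += f" — {fit.group}"
    ax.set(xlabel="protein (kJ/g)", ylabel="nonprotein (kJ/g)", title=title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_forecast(tables: dict[str, pd.DataFrame], path: str | Path) -> None:
    """Energy intake vs dietary protein proportion for each substitution mode."""
    colors = {"isocaloric": "tab:blue", "fat_for_protein": "tab:red"}
    fig, ax = plt.subplots(figsize=(5, 4))
    for mode, table in tables.items():
        ax.plot(
            table["p"],
            table["energy_kj_per_day"],
            color=colors.get(mode, "k"),
            label=mode.replace("_", " "),
        )
    ax.set(
        xlabel="proportion of protein in diet (by mass)",
        ylabel="predicted energy intake (kJ/day)",
    )
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
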