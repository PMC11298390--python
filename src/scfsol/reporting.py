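"""Figures for the study: distributions, parity plots, response surfaces.

Every figure is written as PNG + SVG together with a CSV "twin" holding
exactly the numbers drawn, so plots are auditable and re-runs overwrite
deterministically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy import stats

from .datasets import SolubilityDataset

__all__ = ["PlotBundle", "distribution_plots", "parity_plot", "surface_plots"]


@dataclass
class PlotBundle:
    """Figure files plus the CSVs of the values each figure draws."""

    figures: list = field(default_factory=list)
    tables: list = field(default_factory=list)

    def add_figure(self, fig, stem: Path) -> None:
        for ext in ("png", "svg"):
            out = stem.with_suffix(f".{ext}")
            fig.savefig(out, bbox_inches="tight", dpi=150)
            self.figures.append(out)
        plt.close(fig)

    def add_table(self, frame: pd.DataFrame, path: Path) -> None:
        frame.to_csv(path, index=False)
        self.tables.append(path)


def _kde_curve(values: np.ndarray, n_grid: int = 200) -> pd.DataFrame:
    """Gaussian KDE (Scott bandwidth) on a padded grid; degenerate columns
    (a single distinct value) fall back to a point-mass spike."""
    values = np.asarray(values, float)
    lo, hi = values.min(), values.max()
    if lo == hi:
        grid = np.linspace(lo - 1.0, hi + 1.0, n_grid)
        dens = np.where(np.isclose(grid, lo, atol=2.0 / n_grid), 1.0, 0.0)
        return pd.DataFrame({"grid": grid, "density": dens})
    pad = 0.25 * (hi - lo)
    grid = np.linspace(lo - pad, hi + pad, n_grid)
    dens = stats.gaussian_kde(values, bw_method="scott")(grid)
    return pd.DataFrame({"grid": grid, "density": dens})


def distribution_plots(ds: SolubilityDataset, out_dir: str | Path) -> PlotBundle:
    """KDE and violin-with-box plots of T, P and solubility."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    bundle = PlotBundle()

    columns = ["temperature_K", "pressure_bar", "solubility"]
    fig, axes = plt.subplots(1, 3, figsize=(12, 3.2))
    for ax, col in zip(axes, columns):
        values = ds.frame[col].to_numpy(float)
        curve = _kde_curve(values)
        ax.fill_between(curve["grid"], curve["density"], alpha=0.4)
        ax.plot(curve["grid"], curve["density"])
        ax.set_xlabel(col)
        ax.set_ylabel("density")
        bundle.add_table(curve, out_dir / f"kde_{col}.csv")
    fig.suptitle(f"Distributions — {ds.name}")
    bundle.add_figure(fig, out_dir / "distributions_kde")

    fig, axes = plt.subplots(1, 3, figsize=(12, 3.2))
    for ax, col in zip(axes, columns):
        values = ds.frame[col].to_numpy(float)
        ax.violinplot(values, showmedians=True)
        ax.boxplot(values, widths=0.1)
        ax.set_title(col)
    bundle.add_table(ds.frame[columns], out_dir / "violin_values.csv")
    bundle.add_figure(fig, out_dir / "distributions_violin")
    return bundle


def parity_plot(
    observed,
    predicted,
    family: str,
    out_dir: str | Path,
    is_test: np.ndarray | None = None,
) -> PlotBundle:
    """Predicted-vs-actual scatter with the identity line, train/test marked."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    observed = np.asarray(observed, float)
    predicted = np.asarray(predicted, float)
    if observed.shape != predicted.shape:
        raise ValueError("observed and predicted must have equal length")
    if is_test is None:
        is_test = np.zeros(observed.shape, bool)

    bundle = PlotBundle()
    frame = pd.DataFrame(
        {"observed": observed, "predicted": predicted, "subset": np.where(is_test, "test", "train")}
    )
    fig, ax = plt.subplots(figsize=(4.2, 4.2))
    for subset, marker in (("train", "o"), ("test", "s")):
        sel = frame["subset"] == subset
        if sel.any():
            ax.scatter(frame.loc[sel, "observed"], frame.loc[sel, "predicted"],
                       marker=marker, label=subset, alpha=0.8)
    lims = [min(observed.min(), predicted.min()), max(observed.max(), predicted.max())]
    ax.plot(lims, lims, "k--", lw=1)
    ax.set_xlabel("actual solubility")
    ax.set_ylabel("predicted solubility")
    ax.set_title(f"Parity — {family}")
    ax.legend()
    bundle.add_table(frame, out_dir / f"parity_{family}.csv")
    bundle.add_figure(fig, out_dir / f"parity_{family}")
    return bundle


def surface_plots(
    predict,
    T_grid: np.ndarray,
    P_grid: np.ndarray,
    out_dir: str | Path,
    family: str = "model",
) -> PlotBundle:
    """3-D surface + contour of predictions, plus per-level trend curves.

    ``predict`` maps an (n, 2) raw (T, P) matrix to predicted solubility.
    The CSV twin has one row per (T, P) grid node.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    T_grid = np.asarray(T_grid, float)
    P_grid = np.asarray(P_grid, float)
    TT, PP = np.meshgrid(T_grid, P_grid, indexing="ij")
    Z = predict(np.column_stack([TT.ravel(), PP.ravel()])).reshape(TT.shape)

    bundle = PlotBundle()
    bundle.add_table(
        pd.DataFrame({"temperature_K": TT.ravel(), "pressure_bar": PP.ravel(),
                      "predicted_solubility": Z.ravel()}),
        out_dir / f"surface_{family}.csv",
    )

    fig = plt.figure(figsize=(10, 4))
    ax3d = fig.add_subplot(1, 2, 1, projection="3d")
    ax3d.plot_surface(TT, PP, Z, cmap="viridis")
    ax3d.set_xlabel("T (K)")
    ax3d.set_ylabel("P (bar)")
    ax3d.set_zlabel("solubility")
    axc = fig.add_subplot(1, 2, 2)
    cs = axc.contourf(TT, PP, Z, levels=20, cmap="viridis")
    fig.colorbar(cs, ax=axc)
    axc.set_xlabel("T (K)")
    axc.set_ylabel("P (bar)")
    fig.suptitle(f"Predicted solubility surface — {family}")
    bundle.add_figure(fig, out_dir / f"surface_{family}")

    fig, (ax_t, ax_p) = plt.subplots(1, 2, figsize=(9, 3.4))
    for j in np.linspace(0, len(P_grid) - 1, min(5, len(P_grid))).astype(int):
        ax_t.plot(T_grid, Z[:, j], label=f"P={P_grid[j]:.0f} bar")
    ax_t.set_xlabel("T (K)"); ax_t.set_ylabel("solubility"); ax_t.legend(fontsize=7)
    for i in np.linspace(0, len(T_grid) - 1, min(5, len(T_grid))).astype(int):
        ax_p.plot(P_grid, Z[i, :], label=f"T={T_grid[i]:.1f} K")
    ax_p.set_xlabel("P (bar)"); ax_p.set_ylabel("solubility"); ax_p.legend(fontsize=7)
    bundle.add_figure(fig, out_dir / f"trends_{family}")
    return bundle
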