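"""Plot exports: screen bar charts, dose-response curves, scan heatmaps."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

__all__ = ["screen_bar_plot", "dose_curve_plot", "positional_heatmap"]


def screen_bar_plot(records_frame, path, *, threshold: float = 0.5) -> None:
    """Bar chart of per-peptide area values with hits highlighted."""
    df = records_frame
    fig, ax = plt.subplots(figsize=(max(6, 0.05 * len(df)), 3.2))
    colors = ["darkred" if b else "lightgray" for b in df["is_binder"]]
    ax.bar(np.arange(len(df)), df["area"], yerr=df["area_sd"].fillna(0.0),
           color=colors, linewidth=0)
    ax.axhline(threshold, color="k", ls="--", lw=0.8)
    ax.set_xlabel("peptide")
    ax.set_ylabel("area")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def dose_curve_plot(series, fit, path, *, assay=None) -> None:
    """Measured F_norm points and, when available, the fitted curve."""
    fig, ax = plt.subplots(figsize=(4.2, 3.2))
    c, y = series.concentrations, series.fnorm
    excluded = {p["index"] for p in fit.excluded_points}
    keep = np.array([i not in excluded for i in range(c.size)])
    ax.semilogx(c[keep] * 1e6, y[keep], "o", color="tab:blue", label="data")
    if (~keep).any():
        ax.semilogx(c[~keep] * 1e6, y[~keep], "o", color="red", label="excluded")
    if fit.verdict == "ok" and fit.model == "competitive_exact" and assay is not None:
        from .binding import displacement_curve, solve_binary

        grid = np.geomspace(c.min(), c.max(), 100)
        fb = displacement_curve(assay, grid, fit.ki)
        fb0 = solve_binary(assay).tracer_bound_fraction
        amp = (fit.top - fit.bottom) / fb0
        ax.semilogx(grid * 1e6, fit.bottom + amp * fb, "-", color="k",
                    label=f"fit: Ki={fit.ki * 1e6:.3g} uM, S/N={fit.s_n:.1f}")
    ax.set_xlabel("competitor (uM)")
    ax.set_ylabel("F_norm (per-mille)")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def positional_heatmap(matrix, path) -> None:
    """WT-normalized positional-scan heatmap (positions x residues)."""
    grid = matrix.grid
    fig, ax = plt.subplots(figsize=(0.4 * grid.shape[1] + 2, 0.4 * grid.shape[0] + 1.5))
    im = ax.imshow(grid.to_numpy(), aspect="auto", cmap="viridis")
    ax.set_xticks(range(grid.shape[1]), grid.columns)
    ax.set_yticks(range(grid.shape[0]), grid.index)
    ax.set_xlabel("substituting residue")
    ax.set_ylabel("position")
    fig.colorbar(im, ax=ax, label="intensity relative to WT")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
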