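"""Minimal plotting helpers for sweep results (matplotlib, Agg-safe)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402
import pandas as pd  # noqa: E402

__all__ = ["plot_sweep", "plot_grid"]

_LABELS = {
    "fraction_dimeric": "receptors in dimeric form (fraction)",
    "fraction_inside": "receptor molecules inside confined domain (fraction)",
    "n_monomers": "monomer count",
    "n_dimers": "dimer count",
}


def plot_sweep(df: pd.DataFrame, x: str, observable: str = "fraction_dimeric",
               logx: bool = False, out: str | Path | None = None,
               ax=None):
    """Errorbar plot (mean +/- SD) of one observable along a swept axis."""
    sub = df[df["observable"] == observable] if "observable" in df.columns else df
    if sub.empty:
        raise ValueError(f"no rows for observable {observable!r}")
    sub = sub.sort_values(x)
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    ax.errorbar(sub[x], sub["mean"], yerr=sub["sd"].fillna(0.0),
                marker="o", capsize=3, lw=1)
    if logx:
        ax.set_xscale("log", base=2)
    ax.set_xlabel(x)
    ax.set_ylabel(_LABELS.get(observable, observable))
    ax.figure.tight_layout()
    if out is not None:
        ax.figure.savefig(out, dpi=150)
        plt.close(ax.figure)
    return ax


def plot_grid(grid: pd.DataFrame, out: str | Path | None = None, ax=None):
    """Heat map of the k_b x k_d dimer-fraction grid."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(grid.to_numpy(), origin="lower", cmap="coolwarm",
                   aspect="auto",
                   extent=(min(grid.columns), max(grid.columns),
                           min(grid.index), max(grid.index)))
    ax.set_xlabel("k_b (% of default)")
    ax.set_ylabel("k_d (% of default)")
    ax.figure.colorbar(im, ax=ax, label="dimeric fraction")
    ax.figure.tight_layout()
    if out is not None:
        ax.figure.savefig(out, dpi=150)
        plt.close(ax.figure)
    return ax
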