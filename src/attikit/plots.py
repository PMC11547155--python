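"""Static debug/report plots: Bland-Altman and Passing-Bablok."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .stats import BlandAltmanResult, PassingBablokResult

__all__ = ["plot_bland_altman", "plot_passing_bablok"]


def plot_bland_altman(first, second, result: BlandAltmanResult, path: str | Path) -> None:
    x = np.asarray(first, float)
    y = np.asarray(second, float)
    mean = (x + y) / 2.0
    diff = y - x
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(mean, diff, s=18, alpha=0.8)
    ax.axhline(result.bias, color="C0", label=f"bias = {result.bias:.4f}")
    for loa in (result.loa_low, result.loa_high):
        ax.axhline(loa, color="C3", linestyle="--")
    ax.set_xlabel("mean of methods")
    ax.set_ylabel("difference (second - first)")
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_passing_bablok(x, y, result: PassingBablokResult, path: str | Path) -> None:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(x, y, s=18, alpha=0.8)
    xs = np.linspace(x.min(), x.max(), 50)
    ax.plot(xs, result.intercept + result.slope * xs, "C0-",
            label=f"y = {result.intercept:.4f} + {result.slope:.4f} x")
    lo, hi = result.slope_ci
    ilo, ihi = result.intercept_ci
    if np.isfinite([lo, hi, ilo, ihi]).all():
        ax.plot(xs, ihi + lo * xs, "C2--", lw=0.8)
        ax.plot(xs, ilo + hi * xs, "C2--", lw=0.8)
    ax.plot(xs, xs, "k:", lw=0.8, label="identity")
    ax.set_xlabel("reference method")
    ax.set_ylabel("index method")
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
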