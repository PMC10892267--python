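"""Optional matplotlib figures for the three diagnostic plots.

Plotting is never required by any analysis: every figure here renders
values that the corresponding analysis function already computed.
"""
from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .selection_analyses import EncGc3sPoint, PR2Point, RegressionResult, expected_enc


def plot_enc_gc3s(points: Sequence[EncGc3sPoint], path: str | Path) -> None:
    """Observed ENc vs GC3s with the mutation-only expectation curve."""
    fig, ax = plt.subplots(figsize=(5, 4))
    s = np.linspace(0.0, 1.0, 201)
    ax.plot(s, [expected_enc(v) for v in s], "k-", lw=1, label="expected (mutation only)")
    ax.scatter([p.gc3s for p in points], [p.enc_observed for p in points],
               s=12, alpha=0.7, label="genes")
    ax.set_xlabel("GC3s")
    ax.set_ylabel("ENc")
    ax.set_ylim(15, 65)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_pr2(points: Sequence[PR2Point], path: str | Path) -> None:
    """Parity-rule-2 plane with the (0.5, 0.5) equilibrium cross-hairs."""
    fig, ax = plt.subplots(figsize=(4.4, 4.4))
    ax.scatter([p.x for p in points], [p.y for p in points], s=12, alpha=0.7)
    ax.axhline(0.5, color="k", lw=0.8)
    ax.axvline(0.5, color="k", lw=0.8)
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1)
    ax.set_xlabel("G3 / (G3 + C3)")
    ax.set_ylabel("A3 / (A3 + T3)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_neutrality(gc3: Sequence[float], gc12: Sequence[float],
                    fit: RegressionResult, path: str | Path) -> None:
    """GC12 vs GC3 scatter with the fitted regression line."""
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(gc3, gc12, s=12, alpha=0.7)
    xs = np.linspace(min(gc3), max(gc3), 50)
    ax.plot(xs, fit.intercept + fit.slope * xs, "r-", lw=1,
            label=f"slope={fit.slope:.4f}, r={fit.pearson_r:.3f}")
    ax.set_xlabel("GC3")
    ax.set_ylabel("GC12")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
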