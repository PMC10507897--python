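"""Visualizations of the residual-VIMP test.

Kernel densities are used for display only; all decisions are taken on
the empirical distribution.
"""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .resampling import RvimpResult, empirical_quantile  # noqa: E402

__all__ = ["plot_test_density", "plot_vimp_comparison"]


def plot_test_density(result: RvimpResult, path=None, ax=None):
    """Shifted subsample density of VIMP_B(eps_Z) with the observed
    VIMP_A(Z) (solid line), VIMP_B(eps_Z) (dotted line) and the shaded
    upper-alpha tail used for the H0(1) decision."""
    values = np.asarray(result.density_shifted)
    if ax is None:
        fig, ax = plt.subplots(figsize=(7, 4.5))
    else:
        fig = ax.figure

    q_upper = empirical_quantile(values, 1.0 - result.alpha)
    if np.ptp(values) > 0:
        from scipy.stats import gaussian_kde

        kde = gaussian_kde(values)
        lo = min(values.min(), result.vimp_a)
        hi = max(values.max(), result.vimp_a)
        pad = 0.15 * (hi - lo)
        grid = np.linspace(lo - pad, hi + pad, 400)
        dens = kde(grid)
        ax.plot(grid, dens, color="C0", label="d_VIMP_B(eps_Z), shifted")
        tail = grid >= q_upper
        ax.fill_between(grid[tail], dens[tail], color="C0", alpha=0.3,
                        label=f"upper {result.alpha:g} tail")
    else:
        # degenerate density: every subsample VIMP identical
        ax.plot(values, np.zeros_like(values), "|", ms=25, color="C0",
                label="d_VIMP_B(eps_Z) (degenerate)")
    ax.axvline(result.vimp_a, color="k", ls="-", label="VIMP_A(Z)")
    ax.axvline(result.vimp_b_full, color="k", ls=":", label="VIMP_B(eps_Z)")
    ax.set_xlabel("permutation importance")
    ax.set_ylabel("density")
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_vimp_comparison(result: RvimpResult, top_k: int = 10, path=None, ax=None):
    """Paired bars: each feature's VIMP in the original model A and in
    the adjusted model B (where Z is replaced by its residuals), sorted
    by model-A importance."""
    import warnings

    if result.vimps_a is None or result.vimps_b is None:
        raise ValueError("result carries no companion VIMP vectors")
    a = result.vimps_a.to_dict()
    b_raw = result.vimps_b.to_dict()
    b = {
        (result.z_column if k.startswith(result.z_column) else k): v
        for k, v in b_raw.items()
    }
    names = sorted(a, key=a.get, reverse=True)
    if top_k > len(names):
        warnings.warn(f"top_k={top_k} exceeds {len(names)} features; clipping")
        top_k = len(names)
    names = names[:top_k]

    if ax is None:
        fig, ax = plt.subplots(figsize=(7, 4.5))
    else:
        fig = ax.figure
    x = np.arange(len(names))
    width = 0.38
    ax.bar(x - width / 2, [a[k] for k in names], width, label="model A", color="C0")
    ax.bar(x + width / 2, [b[k] for k in names], width, label="model B", color="C1")
    labels = [f"{k} (resid.)" if k == result.z_column else k for k in names]
    ax.set_xticks(x)
    ax.set_xticklabels(labels, rotation=45, ha="right")
    ax.set_ylabel("permutation importance")
    ax.axhline(0, color="k", lw=0.8)
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
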