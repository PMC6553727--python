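"""Bland–Altman agreement plots (solid bias line, dashed 95% LOA lines)."""

from __future__ import annotations

import numpy as np

from .stats import bland_altman


def bland_altman_plot(x, y, label: str, path=None, loa_multiplier: float = 1.96):
    """Plot paired differences x − y against the pairwise means.

    Returns the matplotlib figure; saves to ``path`` when given.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    bias, sd, lo, hi = bland_altman(x, y, loa_multiplier)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter((x + y) / 2.0, x - y, s=18, alpha=0.8, edgecolor="none")
    ax.axhline(bias, color="k", lw=1.5)
    for v in (lo, hi):
        ax.axhline(v, color="k", lw=1.0, ls="--")
    ax.set_xlabel(f"Mean of {label} and CHM (D)")
    ax.set_ylabel(f"{label} − CHM (D)")
    ax.set_title(f"{label} vs CHM  (bias {bias:+.2f} D, LOA {lo:.2f} to {hi:.2f} D)", fontsize=9)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
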