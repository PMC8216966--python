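"""Diagnostic plotting helpers (matplotlib imported lazily)."""

from __future__ import annotations

import numpy as np

__all__ = ["plot_null_cdf", "plot_mst"]


def plot_null_cdf(cdf, observed=None, ax=None):
    """Step plot of a null curve, optionally marking an observed FEE0."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.step(
        cdf.samples,
        np.arange(1, cdf.Q + 1) / cdf.Q,
        where="post",
        label=f"n={cdf.n}, M={cdf.M}, Q={cdf.Q}",
    )
    if observed is not None:
        pos = np.searchsorted(cdf.samples, observed, side="right") / cdf.Q
        ax.axvline(observed, ls="--", color="grey")
        ax.plot([observed], [pos], "o", color="black")
        ax.annotate(f"FEE = {pos:.3f}", (observed, pos),
                    textcoords="offset points", xytext=(6, -10))
    ax.set_xlabel("FEE$_0$")
    ax.set_ylabel("cumulative proportion")
    ax.legend()
    return ax


def plot_mst(points, mst, labels=None, ax=None):
    """Scatter of a 2-D community with its MST branches drawn."""
    import matplotlib.pyplot as plt

    points = np.atleast_2d(np.asarray(points, float))
    if points.shape[1] != 2:
        raise ValueError("plot_mst draws two-dimensional trait spaces only")
    if labels is None:
        labels = [str(i) for i in range(points.shape[0])]
    index = {str(s): i for i, s in enumerate(labels)}
    if ax is None:
        _, ax = plt.subplots()
    for a, b, _length in mst.edges:
        pa, pb = points[index[str(a)]], points[index[str(b)]]
        ax.plot([pa[0], pb[0]], [pa[1], pb[1]], "-", color="tab:blue")
    ax.plot(points[:, 0], points[:, 1], "o", color="black", zorder=3)
    ax.set_xlim(-0.05, 1.05)
    ax.set_ylim(-0.05, 1.05)
    ax.set_aspect("equal")
    return ax
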