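"""Minimal plotting helpers (metagene profiles, eigengene heatmap)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

__all__ = ["plot_metagene_profile", "plot_eigengene_correlation"]


def plot_metagene_profile(profile, ax=None, smooth: bool = True):
    """Line plot of per-quartile methylation over the metagene axis."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    col = "smooth" if smooth and "smooth" in profile else "mean_meth"
    for q, sub in profile.groupby("quartile"):
        ax.plot(sub["x"], sub[col], label=q)
    ax.set_xlabel("relative position")
    ax.set_ylabel("methylation level")
    ax.legend(title="expression quartile", fontsize=8)
    return ax


def plot_eigengene_correlation(ec, ax=None):
    """Heatmap of module-eigengene Pearson correlations."""
    mat = ec.pivot(index="module_a", columns="module_b", values="r")
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(mat.to_numpy(), cmap="RdBu_r", vmin=-1, vmax=1)
    ax.set_xticks(range(mat.shape[1]), mat.columns)
    ax.set_yticks(range(mat.shape[0]), mat.index)
    ax.figure.colorbar(im, ax=ax, label="eigengene r")
    return ax
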