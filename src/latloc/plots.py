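"""Static diagnostic figures: deviation scatters and Z-score profiles."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def deviation_scatter(Z, y, deviations, path) -> None:
    """One panel per latent dimension: outcome vs latent value, coloured by
    the local-minus-global coefficient difference for that dimension."""
    Z = np.atleast_2d(np.asarray(Z, float))
    dev = np.atleast_2d(np.asarray(deviations, float))
    d = Z.shape[1]
    fig, axes = plt.subplots(1, d, figsize=(4 * d, 3.5), squeeze=False)
    vmax = np.max(np.abs(dev)) or 1.0
    for l in range(d):
        ax = axes[0, l]
        sc = ax.scatter(Z[:, l], y, c=dev[:, l], cmap="RdYlBu", s=14,
                        vmin=-vmax, vmax=vmax)
        ax.set_xlabel(f"latent {l + 1}")
        ax.set_ylabel("outcome" if l == 0 else "")
    fig.colorbar(sc, ax=axes.ravel().tolist(), label="beta_local - beta_global")
    fig.savefig(path, dpi=120)
    plt.close(fig)


def zscore_bars(profile, path, labels=None) -> None:
    """Horizontal bar chart of a subgroup's mean standardized predictors."""
    profile = np.asarray(profile, float)
    idx = np.arange(profile.size)
    if labels is None:
        labels = [f"x{j + 1}" for j in idx]
    fig, ax = plt.subplots(figsize=(6, 0.25 * profile.size + 1.5))
    ax.barh(idx, profile, color=np.where(profile >= 0, "steelblue", "indianred"))
    ax.set_yticks(idx, labels=labels, fontsize=7)
    ax.axvline(0.0, color="k", lw=0.8)
    ax.set_xlabel("mean Z-score in subgroup")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
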