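"""Static figure helpers mirroring the standard validation displays.

All functions take an explicit output path and write a PNG; they are
side-effect-only conveniences over the tidy tables the modules return.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

__all__ = [
    "plot_residual_heatmap",
    "plot_information_surface",
    "plot_class_profiles",
    "plot_forest",
]


def plot_residual_heatmap(q3, path) -> None:
    """Item-pair residual-correlation heat map (local-independence screen)."""
    fig, ax = plt.subplots(figsize=(6, 5))
    vals = q3.values.copy()
    np.fill_diagonal(vals, np.nan)
    im = ax.imshow(vals, cmap="RdBu_r", vmin=-0.5, vmax=0.5)
    ax.set_xticks(range(len(q3.item_ids)), q3.item_ids, rotation=90)
    ax.set_yticks(range(len(q3.item_ids)), q3.item_ids)
    fig.colorbar(im, ax=ax, label="Q3 residual correlation")
    ax.set_title("Local independence (|r| >= %.2f flagged)" % q3.threshold)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_information_surface(surface, path, value: str = "information") -> None:
    """Test information (or expected score / SE) over the theta plane."""
    t1 = np.unique(surface["theta1"])
    t2 = np.unique(surface["theta2"])
    grid = surface[value].to_numpy().reshape(len(t1), len(t2))
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.contourf(t2, t1, grid, levels=20, cmap="viridis")
    fig.colorbar(im, ax=ax, label=value)
    ax.set_xlabel("theta 2 (Shift-Persist)")
    ax.set_ylabel("theta 1 (Generic)")
    ax.set_title(f"Test {value.replace('_', ' ')} surface")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_class_profiles(solution, path, indicator_names=None) -> None:
    """Per-class mean indicator profiles from an LPA solution."""
    K, p = solution.means.shape
    names = indicator_names or [f"x{i + 1}" for i in range(p)]
    fig, ax = plt.subplots(figsize=(7, 4))
    for k in range(K):
        ax.plot(range(p), solution.means[k], marker="o",
                label=f"C{k + 1} ({100 * solution.weights[k]:.0f}%)")
    ax.set_xticks(range(p), names, rotation=45)
    ax.set_ylabel("class mean")
    ax.legend()
    ax.set_title(f"{K}-class latent profiles")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_forest(dose_table, path) -> None:
    """Forest-style display of the dose-response odds ratios."""
    frame = dose_table.table
    fig, ax = plt.subplots(figsize=(6, 0.6 * len(frame) + 1))
    ys = np.arange(len(frame))[::-1]
    ax.errorbar(
        frame["or"], ys,
        xerr=[frame["or"] - frame["ci_low"], frame["ci_high"] - frame["or"]],
        fmt="s", color="k", capsize=3,
    )
    ax.axvline(1.0, color="grey", lw=1, ls="--")
    labels = [f"{m}: {c}" for m, c in zip(frame["model"], frame["contrast"])]
    ax.set_yticks(ys, labels)
    ax.set_xlabel("odds ratio of high QoL (95% CI)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
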