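"""Small matplotlib helpers for the experiment reports."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

__all__ = ["plot_pmf_overlay", "plot_heatmap", "plot_mean_bars"]


def plot_pmf_overlay(report, path) -> None:
    """Empirical mRNA pmf with Poisson and zero-spike reference curves."""
    t = report.table
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.bar(t["count"], t["empirical"], color="steelblue", alpha=0.7, label="simulated")
    ax.plot(t["count"], t["poisson"], "r-", label="Poisson fit")
    ax.plot(t["count"], t["pzs"], "c-", label="zero-spike")
    ax.set_xlabel("mRNA copy number")
    ax.set_ylabel("probability")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_heatmap(df, path, cbar_label="") -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(df.to_numpy(), origin="lower", aspect="auto", cmap="viridis")
    ax.set_xticks(range(df.shape[1]), [f"{c:.3g}" for c in df.columns], rotation=45)
    ax.set_yticks(range(df.shape[0]), [f"{i:.3g}" for i in df.index])
    ax.set_xlabel(df.columns.name or "")
    ax.set_ylabel(df.index.name or "")
    fig.colorbar(im, ax=ax, label=cbar_label)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_mean_bars(means, path, column="mrna_mean", isolated_column=None) -> None:
    fig, ax = plt.subplots(figsize=(6, 3.5))
    x = range(len(means))
    ax.bar(x, means[column], width=0.4, color="steelblue", label="linked")
    if isolated_column and isolated_column in means:
        ax.bar([i + 0.4 for i in x], means[isolated_column], width=0.4,
               color="firebrick", label="isolated")
    ax.set_xticks([i + 0.2 for i in x], means.index, rotation=45)
    ax.set_ylabel(column)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
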