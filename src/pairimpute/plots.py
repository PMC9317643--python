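"""Static figures for benchmark results (optional conveniences).

Uses the Agg backend so the pipeline never requires a display.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402
import pandas as pd  # noqa: E402

__all__ = ["plot_metric_boxes", "plot_correlation_scatter"]


def plot_metric_boxes(
    results: pd.DataFrame, metric: str, out: str | Path, profile: str | None = None
) -> Path:
    """Box plots of one metric by missingness level, one panel per approach."""
    df = results if profile is None else results[results["profile"] == profile]
    approaches = sorted(df["approach"].unique())
    methods = sorted(df["method"].unique())
    levels = sorted(df["p"].unique())
    fig, axes = plt.subplots(
        1, len(approaches), figsize=(5.5 * len(approaches), 4), squeeze=False, sharey=True
    )
    for ax, approach in zip(axes[0], approaches):
        sub = df[df["approach"] == approach]
        width = 0.8 / max(len(methods), 1)
        for k, method in enumerate(methods):
            data = [sub[(sub["method"] == method) & (sub["p"] == p)][metric].dropna()
                    for p in levels]
            pos = [i + (k - (len(methods) - 1) / 2) * width for i in range(len(levels))]
            ax.boxplot(data, positions=pos, widths=width * 0.9,
                       label=method, patch_artist=True,
                       boxprops=dict(facecolor=f"C{k}", alpha=0.6))
        ax.set_xticks(range(len(levels)), [f"{p}%" for p in levels])
        ax.set_xlabel("missingness")
        ax.set_title(approach)
    axes[0][0].set_ylabel(metric)
    axes[0][-1].legend(fontsize=8)
    fig.tight_layout()
    out = Path(out)
    out.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(out, dpi=150)
    plt.close(fig)
    return out


def plot_correlation_scatter(
    records: pd.DataFrame, out: str | Path, title: str = ""
) -> Path:
    """Scatter of imputed vs true between-biospecimen correlations."""
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.scatter(records["r_true"], records["r_imputed"], s=8, alpha=0.5)
    ax.plot([-1, 1], [-1, 1], color="grey", lw=1, ls="--")
    ax.set_xlim(-1, 1)
    ax.set_ylim(-1, 1)
    ax.set_xlabel("true correlation")
    ax.set_ylabel("imputed correlation")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    out = Path(out)
    out.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(out, dpi=150)
    plt.close(fig)
    return out
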