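"""Figures: group percent-difference bars and reallocation curves."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def group_difference_plot(diff, path) -> None:
    """Bar plot of percent differences (sDCD vs TD) with bootstrap 95% CIs."""
    t = diff.table
    fig, ax = plt.subplots(figsize=(5, 3.5))
    x = range(len(t))
    ax.bar(x, t["percent"], color="#4878d0")
    yerr = [t["percent"] - t["ci_low_pct"], t["ci_high_pct"] - t["percent"]]
    ax.errorbar(x, t["percent"], yerr=yerr, fmt="none", ecolor="black", capsize=4)
    ax.axhline(0, color="grey", lw=0.8)
    ax.set_xticks(list(x), t["part"].str.upper())
    ax.set_ylabel(f"% difference ({diff.group_b} vs {diff.group_a})")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def reallocation_plot(ism, path) -> None:
    """Predicted outcome change per pairwise reallocation, with 95% CI band."""
    pairs = ism.groupby(["from_part", "to_part"], sort=False)
    n = len(pairs)
    ncols = 3
    nrows = (n + ncols - 1) // ncols
    fig, axes = plt.subplots(nrows, ncols, figsize=(3.2 * ncols, 2.4 * nrows), squeeze=False)
    for ax, ((a, b), g) in zip(axes.flat, pairs):
        ax.plot(g["minutes"], g["delta_outcome"], color="#4878d0")
        ax.fill_between(g["minutes"], g["ci_low"], g["ci_high"], alpha=0.25, color="#4878d0")
        ax.axhline(0, color="grey", lw=0.6)
        ax.set_title(f"{a} → {b}", fontsize=9)
    for ax in axes.flat[n:]:
        ax.axis("off")
    fig.supxlabel("minutes reallocated")
    fig.supylabel("predicted outcome change")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
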