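"""Figures for the evaluation harness (coverage, FDR/power contrasts)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def plot_coverage(report, path) -> None:
    """Strip plot of per-dataset coverage of the exhaustive pair search."""
    covs = report.coverage_per_dataset
    fig, ax = plt.subplots(figsize=(5, 3))
    ax.plot(range(1, len(covs) + 1), covs, "o", ms=4, alpha=0.7)
    ax.axhline(report.mean_coverage, color="C1", lw=1,
               label=f"mean = {report.mean_coverage:.3f}")
    ax.set_xlabel("simulated dataset")
    ax.set_ylabel("coverage of exhaustive pairs")
    ax.set_ylim(-0.02, 1.02)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_fdr_power(contrast, path) -> None:
    """Paired bars: FDR and level-2 power, regular vs conditional."""
    fig, axes = plt.subplots(1, 2, figsize=(6, 3), sharey=True)
    labels = ["regular", "conditional"]
    axes[0].bar(labels, [contrast.fdr_regular, contrast.fdr_conditional],
                color=["C0", "C2"])
    axes[0].set_title("FDR")
    axes[1].bar(labels, [contrast.power2_regular, contrast.power2_conditional],
                color=["C0", "C2"])
    axes[1].set_title("level-2 power")
    for ax in axes:
        ax.set_ylim(0, 1.05)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
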