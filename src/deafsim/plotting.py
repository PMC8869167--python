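"""Line plots of batch summaries (allele frequency and homozygote proportion)."""

from __future__ import annotations

from typing import Sequence, Union

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .batch_stats import BatchSummary

__all__ = ["plot_batch_summaries"]


def plot_batch_summaries(
    summaries: Sequence[BatchSummary],
    path: Union[str, "object"],
) -> None:
    """Two-panel figure: mean allele frequency and homozygote proportion per
    generation, one line per batch, shaded CI bands."""
    fig, axes = plt.subplots(1, 2, figsize=(10, 4), sharex=True)
    for summary in summaries:
        s = summary.summary
        label = summary.scenario or f"seed {summary.root_seed}"
        for ax, stat, title in (
            (axes[0], "allele_freq", "Recessive mutant allele frequency"),
            (axes[1], "prop_hom", "Recessive homozygote proportion"),
        ):
            mean = s[f"{stat}_mean"] * 100
            ci = s[f"{stat}_ci"] * 100
            ax.plot(s["generation"], mean, label=label)
            ax.fill_between(s["generation"], mean - ci, mean + ci, alpha=0.2)
            ax.set_title(title)
            ax.set_xlabel("generation")
            ax.set_ylabel("%")
    axes[0].legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
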