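"""Optional plots of enrichment results (rank scatter with the k·σ line)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .enrichment import EnrichmentResult

__all__ = ["plot_enrichment"]


def plot_enrichment(result: EnrichmentResult, path, highlight: str | None = None) -> None:
    """Δ relative abundance of every minigene in rank order; the dashed line is
    the mean + k·σ hit threshold; ``highlight`` marks one minigene id."""
    ranked = result.ranking
    deltas = result.table.loc[ranked, "delta"].to_numpy()
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(range(1, len(ranked) + 1), deltas, s=8, c="0.4", edgecolors="none")
    ax.axhline(result.threshold, linestyle="--", color="k",
               label=f"mean + {result.k:g}σ")
    if highlight is not None and highlight in result.table.index:
        pos = ranked.index(highlight)
        ax.scatter([pos + 1], [deltas[pos]], s=40, facecolors="none",
                   edgecolors="crimson", label=str(highlight)[:24])
    ax.set_xlabel("minigene rank")
    ax.set_ylabel("Δ relative abundance")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
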