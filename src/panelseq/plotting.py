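"""Optional static figures for cohort summaries.

The canonical outputs of the pipeline are tables; these helpers render the
two standard views (lollipop of per-codon counts, gene x tumour-type
heatmap) for reports.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .cohort import CodonCount


def lollipop_plot(counts: Sequence[CodonCount], gene: str,
                  path: str | Path | None = None):
    """Stem plot of mutation counts per codon for one gene."""
    rows = [c for c in counts if c.gene == gene]
    fig, ax = plt.subplots(figsize=(8, 3))
    if rows:
        codons = [c.codon for c in rows]
        ns = [c.count for c in rows]
        ax.stem(codons, ns)
        ax.set_xlim(0, max(codons) * 1.1)
    ax.set_xlabel(f"{gene} codon")
    ax.set_ylabel("mutations")
    ax.set_title(gene)
    if path is not None:
        fig.savefig(path, dpi=100, bbox_inches="tight")
        plt.close(fig)
    return fig


def gene_tumour_heatmap(matrix: pd.DataFrame, path: str | Path | None = None):
    """Heatmap of the relative mutation-count matrix."""
    fig, ax = plt.subplots(figsize=(0.4 * max(len(matrix.columns), 4) + 2,
                                    0.4 * max(len(matrix.index), 2) + 2))
    im = ax.imshow(matrix.values, aspect="auto", cmap="viridis")
    ax.set_xticks(range(len(matrix.columns)), matrix.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(len(matrix.index)), matrix.index, fontsize=8)
    fig.colorbar(im, ax=ax, label="mutations / sample")
    if path is not None:
        fig.savefig(path, dpi=100, bbox_inches="tight")
        plt.close(fig)
    return fig
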