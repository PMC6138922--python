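"""Optional plotting layer: blob scatter and abundance heatmap.

Tables are the tested surface; these helpers only render them.
Requires matplotlib (the ``plot`` extra).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .quantify import log_abundance


def blob_plot(table: pd.DataFrame, ax=None):
    """GC vs abundance scatter of contigs, coloured by bin membership."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        fig, ax = plt.subplots(figsize=(7, 5))
    else:
        fig = ax.figure
    for i, (name, sub) in enumerate(table.groupby("bin")):
        ax.scatter(
            sub["gc"],
            np.log10(sub["abundance"] + 1.0),
            s=np.sqrt(sub["length"]) / 5.0,
            label=None if name == "UNBINNED" else name,
            color="lightgrey" if name == "UNBINNED" else f"C{i % 10}",
            alpha=0.7,
        )
    ax.set_xlabel("GC content")
    ax.set_ylabel("log10(standardized abundance + 1)")
    return fig


def abundance_heatmap(abundance: pd.DataFrame, pseudocount: float = 1.0, ax=None):
    """Heatmap of log bin abundance across samples."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    mat = log_abundance(abundance, pseudocount)
    if ax is None:
        fig, ax = plt.subplots(figsize=(6, max(3, 0.3 * len(mat))))
    else:
        fig = ax.figure
    im = ax.imshow(mat.to_numpy(), aspect="auto", cmap="viridis")
    ax.set_xticks(range(mat.shape[1]), mat.columns, rotation=90)
    ax.set_yticks(range(mat.shape[0]), mat.index)
    fig.colorbar(im, ax=ax, label="log10(abundance + 1)")
    return fig
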