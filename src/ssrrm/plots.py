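"""Manhattan plots for the per-age GWAS tables."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd


def manhattan(
    table: pd.DataFrame,
    threshold: float | None = None,
    ax=None,
    title: str | None = None,
):
    """Plot -log10(P) against genome position, alternating chromosome colors.

    ``table`` is one per-age GWAS table (columns chrom, pos, neg_log10_p).
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(9, 3))
    offset = 0
    ticks, labels = [], []
    for i, (chrom, grp) in enumerate(table.groupby("chrom", sort=True)):
        x = grp["pos"].to_numpy() + offset
        ax.scatter(
            x,
            grp["neg_log10_p"],
            s=6,
            color="#1f77b4" if i % 2 == 0 else "#ff7f0e",
            rasterized=True,
        )
        ticks.append(x.mean())
        labels.append(str(chrom))
        offset = x.max() + 1
    if threshold is not None:
        ax.axhline(threshold, color="blue", lw=1.0)
    ax.set_xticks(ticks, labels)
    ax.set_xlabel("chromosome")
    ax.set_ylabel(r"$-\log_{10} P$")
    if title:
        ax.set_title(title)
    return ax
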