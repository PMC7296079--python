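"""Minimal Manhattan and PCA scatter helpers."""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["manhattan", "pca_scatter"]


def manhattan(scan: pd.DataFrame, ax=None, thresholds: dict | None = None):
    """Manhattan plot of a scan frame (needs chrom, pos, neglog10p)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(9, 3))
    offset = 0
    ticks, labels = [], []
    for c, sub in scan.groupby("chrom", sort=True):
        x = sub["pos"].to_numpy() + offset
        ax.scatter(x, sub["neglog10p"], s=4, rasterized=True)
        ticks.append(offset + sub["pos"].max() / 2)
        labels.append(str(c))
        offset += sub["pos"].max()
    for name, line in (thresholds or {}).items():
        if line is not None:
            ax.axhline(line, ls="--", lw=0.8, label=name)
    ax.set_xticks(ticks, labels)
    ax.set_xlabel("chromosome")
    ax.set_ylabel(r"$-\log_{10}(p)$")
    if thresholds:
        ax.legend(frameon=False)
    return ax


def pca_scatter(pcs: pd.DataFrame, groups: np.ndarray | None = None, ax=None):
    """PC1 vs PC2 scatter, optionally colored by group labels."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    if groups is None:
        ax.scatter(pcs["PC1"], pcs["PC2"], s=8)
    else:
        for g in pd.unique(groups):
            sel = groups == g
            ax.scatter(pcs.loc[sel, "PC1"], pcs.loc[sel, "PC2"], s=8, label=str(g))
        ax.legend(frameon=False)
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    return ax
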