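"""Convenience Manhattan-style plot for scan results."""

from __future__ import annotations

import pandas as pd

from .gwas import GWASScanResult


def manhattan(scan: GWASScanResult, marker_map: pd.DataFrame,
              lod_threshold: float | None = None, path=None):
    """LOD against cumulative genome position, one colour band per chromosome.

    Returns the matplotlib Axes; saves to ``path`` when given.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pos = marker_map.set_index("marker")[["chrom", "bp"]]
    t = scan.table.join(pos, how="inner").sort_values(["chrom", "bp"])
    offsets, ticks = {}, {}
    cum = 0
    for chrom, grp in t.groupby("chrom", sort=True):
        offsets[chrom] = cum
        ticks[chrom] = cum + grp["bp"].median()
        cum += grp["bp"].max() + 1
    t["x"] = t["bp"] + t["chrom"].map(offsets)

    fig, ax = plt.subplots(figsize=(9, 3))
    for i, (chrom, grp) in enumerate(t.groupby("chrom", sort=True)):
        ax.scatter(grp["x"], grp["lod"], s=4,
                   color="#4477AA" if i % 2 == 0 else "#EE6677", label=None)
    if lod_threshold is not None:
        ax.axhline(lod_threshold, ls="--", color="red", lw=1)
    ax.set_xticks(list(ticks.values()), list(ticks.keys()))
    ax.set_ylabel("LOD")
    ax.set_title(scan.trait)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return ax
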