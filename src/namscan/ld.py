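"""Intrachromosomal linkage disequilibrium and LD-decay distance.

LD between two markers is the squared Pearson correlation of their dosage
vectors across lines (pairwise-complete over non-missing calls), the
natural r^2 for a 0-1-2 dosage matrix.  The decay distance is where a
LOESS smooth of r^2 against physical distance first drops below a
threshold (conventionally 0.2); it motivates the candidate-window size
used in QTL reporting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .simulate import GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass
class LDDecayResult:
    """LOESS-smoothed decay curve and the threshold-crossing distance.

    ``decay_bp`` is None when the smoothed curve never drops below the
    threshold over the fitted range.
    """

    curve: pd.DataFrame  # columns: distance_bp, r2_fit
    decay_bp: float | None
    threshold: float

    @property
    def crossed(self) -> bool:
        return self.decay_bp is not None


def pairwise_r2(geno: GenotypeMatrix, marker_map: pd.DataFrame, chromosome: str,
                max_pairs: int | None = 200_000,
                seed: int = 0) -> pd.DataFrame:
    """All (or a seeded subsample of) intrachromosomal marker-pair r^2.

    Returns columns ``chrom, marker1, marker2, dist_bp, r2``.  Monomorphic
    markers are excluded; missing dosages are handled by pairwise-complete
    correlation.
    """
    sub = marker_map[marker_map["chrom"] == chromosome]
    if sub.empty:
        raise ValueError(f"chromosome {chromosome!r} absent from marker map")
    markers = [m for m in sub["marker"] if m in geno.dosages.columns]
    dos = geno.dosages[markers]
    poly = dos.std(ddof=0) > 0
    dos = dos.loc[:, poly]
    markers = list(dos.columns)
    if len(markers) < 2:
        raise ValueError(
            f"need >= 2 polymorphic markers on chromosome {chromosome!r}"
        )
    pos = sub.set_index("marker")["bp"].reindex(markers).to_numpy()

    m = len(markers)
    iu, ju = np.triu_indices(m, k=1)
    if max_pairs is not None and len(iu) > max_pairs:
        rng = np.random.default_rng(seed)
        keep = rng.choice(len(iu), size=max_pairs, replace=False)
        keep.sort()
        iu, ju = iu[keep], ju[keep]
        corr = None  # computed per pair below
    else:
        corr = dos.corr(method="pearson").to_numpy()

    if corr is not None:
        r = corr[iu, ju]
    else:
        vals = dos.to_numpy()
        r = np.empty(len(iu))
        for k, (i, j) in enumerate(zip(iu, ju)):
            a, b = vals[:, i], vals[:, j]
            ok = ~(np.isnan(a) | np.isnan(b))
            if ok.sum() < 2:
                r[k] = np.nan
                continue
            aa, bb = a[ok], b[ok]
            sa, sb = aa.std(), bb.std()
            r[k] = np.corrcoef(aa, bb)[0, 1] if sa > 0 and sb > 0 else np.nan

    pairs = pd.DataFrame({
        "chrom": chromosome,
        "marker1": np.asarray(markers, dtype=object)[iu],
        "marker2": np.asarray(markers, dtype=object)[ju],
        "dist_bp": np.abs(pos[ju] - pos[iu]).astype(float),
        "r2": r ** 2,
    })
    return pairs.dropna(subset=["r2"]).reset_index(drop=True)


def ld_decay(pairs: pd.DataFrame, threshold: float = 0.2, span: float = 0.3,
             max_distance_bp: float | None = 50_000_000,
             grid_points: int = 500) -> LDDecayResult:
    """LOESS fit of r^2 on physical distance and the threshold crossing.

    The smoother is fitted on pairs within ``max_distance_bp`` (long-range
    pairs carry no decay information and destabilise the local fit).  The
    decay distance is the smallest grid distance whose fitted r^2 falls
    below ``threshold``.
    """
    if not (0 < threshold < 1):
        raise ValueError("threshold must be in (0, 1)")
    df = pairs.dropna(subset=["r2", "dist_bp"])
    if max_distance_bp is not None:
        df = df[df["dist_bp"] <= max_distance_bp]
    if len(df) < 50:
        raise ValueError("need >= 50 pairs to fit the decay curve")
    d = df["dist_bp"].to_numpy(dtype=float)
    if np.ptp(d) == 0:
        raise ValueError("all pairs at a single distance; decay undefined")
    grid = np.linspace(d.min(), d.max(), grid_points)
    fit = lowess(df["r2"].to_numpy(), d, frac=span, xvals=grid)
    curve = pd.DataFrame({"distance_bp": grid, "r2_fit": fit})
    below = np.nonzero(fit < threshold)[0]
    decay = float(grid[below[0]]) if len(below) else None
    if decay is None:
        logger.info("LOESS fit never crossed r2=%.3g over the fitted range", threshold)
    return LDDecayResult(curve=curve, decay_bp=decay, threshold=threshold)


def ld_decay_summary(geno: GenotypeMatrix, marker_map: pd.DataFrame,
                     threshold: float = 0.2, span: float = 0.3,
                     max_pairs: int | None = 200_000,
                     max_distance_bp: float | None = 50_000_000,
                     seed: int = 0) -> dict:
    """Per-chromosome and genome-wide LD-decay distances.

    Genome-wide decay pools the pairs of every chromosome into one fit.
    """
    out: dict = {"threshold": threshold, "per_chromosome": {}}
    all_pairs = []
    for chrom in marker_map["chrom"].unique():
        try:
            pairs = pairwise_r2(geno, marker_map, chrom, max_pairs=max_pairs, seed=seed)
            res = ld_decay(pairs, threshold=threshold, span=span,
                           max_distance_bp=max_distance_bp)
            out["per_chromosome"][str(chrom)] = res.decay_bp
            all_pairs.append(pairs)
        except ValueError as exc:
            logger.warning("LD decay on %s skipped: %s", chrom, exc)
            out["per_chromosome"][str(chrom)] = None
    if all_pairs:
        pooled = pd.concat(all_pairs, ignore_index=True)
        res = ld_decay(pooled, threshold=threshold, span=span,
                       max_distance_bp=max_distance_bp)
        out["genome_wide"] = res.decay_bp
    return out
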