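"""QTL calling, candidate-gene windows and multi-trait co-localisation.

Significant markers (LOD at or above the Bonferroni threshold) are merged
per trait and chromosome into QTLs: within a cluster of significant
markers closer than one window width, the highest-LOD marker is the peak.
QTL identifiers follow the convention ``Q_<marker-suffix>_<chrom>-<n>``
with ordinals assigned per chromosome, across traits, in physical-position
order, so the same peak marker carries the same identifier for every trait
it affects.  Candidate genes are the annotation entries overlapping a
window of total width ``window_bp`` centred on the peak.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gwas import GWASScanResult

logger = logging.getLogger(__name__)

DEFAULT_WINDOW_BP = 1_700_000


@dataclass
class QTL:
    id: str
    peak_marker: str
    chrom: str
    pos_bp: int
    traits: list[str]
    peak_lod: float
    effect: float
    p_value: float
    window: tuple[int, int]

    @property
    def effect_sign(self) -> int:
        return int(np.sign(self.effect))


def _marker_suffix(marker: str) -> str:
    return marker.rsplit("_", 1)[-1]


def call_qtls(scans: dict[str, GWASScanResult], threshold: float,
              marker_map: pd.DataFrame,
              window_bp: int = DEFAULT_WINDOW_BP) -> list[QTL]:
    """Call QTLs from per-trait scan results at a LOD threshold.

    Significant markers on the same chromosome and trait whose windows
    would overlap (peak distance < ``window_bp``) are merged into the
    highest-LOD peak.  Returns one QTL record per (trait, peak).
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    pos = marker_map.set_index("marker")
    half = window_bp // 2

    peak_records = []  # (trait, marker, chrom, bp, lod, effect, p)
    for trait, scan in scans.items():
        sig = scan.table[scan.table["lod"] >= threshold]
        if sig.empty:
            continue
        missing = [m for m in sig.index if m not in pos.index]
        if missing:
            raise ValueError(f"significant markers absent from map: {missing[:5]}")
        sig = sig.join(pos.loc[sig.index, ["chrom", "bp"]])
        for chrom, grp in sig.groupby("chrom", sort=False):
            grp = grp.sort_values("lod", ascending=False)
            taken: list[int] = []
            for marker, row in grp.iterrows():
                if any(abs(row["bp"] - t) < window_bp for t in taken):
                    continue
                taken.append(row["bp"])
                peak_records.append((trait, marker, str(chrom), int(row["bp"]),
                                     float(row["lod"]), float(row["effect"]),
                                     float(row["p"])))

    if not peak_records:
        return []

    # ordinals: unique peak markers per chromosome, position order, across traits
    peaks = pd.DataFrame(peak_records,
                         columns=["trait", "marker", "chrom", "bp", "lod",
                                  "effect", "p"])
    ordinals: dict[str, int] = {}
    for chrom, grp in peaks.groupby("chrom", sort=False):
        uniq = grp.drop_duplicates("marker").sort_values("bp")
        for i, marker in enumerate(uniq["marker"], start=1):
            ordinals[marker] = i

    qtls = []
    for rec in peaks.itertuples(index=False):
        qid = f"Q_{_marker_suffix(rec.marker)}_{rec.chrom}-{ordinals[rec.marker]}"
        qtls.append(QTL(
            id=qid, peak_marker=rec.marker, chrom=rec.chrom, pos_bp=rec.bp,
            traits=[rec.trait], peak_lod=rec.lod, effect=rec.effect,
            p_value=rec.p,
            window=(rec.bp - half, rec.bp + half),
        ))
    qtls.sort(key=lambda q: (q.chrom, q.pos_bp, q.traits[0]))
    return qtls


def genes_in_window(qtl: QTL, annotation: pd.DataFrame) -> pd.DataFrame:
    """Annotation entries overlapping the QTL window.

    ``annotation`` has 1-based inclusive columns ``gene_id, chrom, start,
    end, annotation``.  The window ``[start, end)`` is half-open: a gene
    ending exactly at the window start is excluded, one starting at the
    window end is excluded.
    """
    ws, we = qtl.window
    sub = annotation[annotation["chrom"] == qtl.chrom]
    if sub.empty:
        logger.warning("chromosome %s absent from annotation; no genes for %s",
                       qtl.chrom, qtl.id)
        return annotation.iloc[0:0]
    hit = sub[(sub["end"] > ws) & (sub["start"] < we)]
    return hit.reset_index(drop=True)


def colocalize(qtls: list[QTL], by: str = "marker") -> pd.DataFrame:
    """Group QTL records shared across traits into multi-trait records.

    ``by='marker'`` groups records with the same peak marker;
    ``by='window'`` additionally merges records whose windows overlap on
    the same chromosome.  Returns one row per group with all traits listed.
    """
    if not qtls:
        return pd.DataFrame(columns=["qtl_id", "marker", "chrom", "pos_bp",
                                     "traits", "peak_lod", "min_p"])
    if by not in ("marker", "window"):
        raise ValueError("by must be 'marker' or 'window'")

    groups: list[list[QTL]] = []
    if by == "marker":
        seen: dict[str, list[QTL]] = {}
        for q in qtls:
            seen.setdefault(q.peak_marker, []).append(q)
        groups = list(seen.values())
    else:
        for q in sorted(qtls, key=lambda q: (q.chrom, q.pos_bp)):
            placed = False
            for grp in groups:
                g0 = grp[0]
                if g0.chrom == q.chrom and not (
                        q.window[0] >= max(g.window[1] for g in grp)
                        or q.window[1] <= min(g.window[0] for g in grp)):
                    grp.append(q)
                    placed = True
                    break
            if not placed:
                groups.append([q])

    rows = []
    for grp in groups:
        best = max(grp, key=lambda q: q.peak_lod)
        traits = sorted({t for q in grp for t in q.traits})
        rows.append({
            "qtl_id": best.id, "marker": best.peak_marker, "chrom": best.chrom,
            "pos_bp": best.pos_bp, "traits": "; ".join(traits),
            "peak_lod": best.peak_lod, "min_p": min(q.p_value for q in grp),
        })
    out = pd.DataFrame(rows).sort_values(["chrom", "pos_bp"]).reset_index(drop=True)
    return out


def qtl_report(qtls: list[QTL], annotation: pd.DataFrame | None = None) -> pd.DataFrame:
    """Flat report: one row per QTL x candidate gene (or per QTL if no genes)."""
    rows = []
    for q in qtls:
        genes = genes_in_window(q, annotation) if annotation is not None else None
        base = {
            "traits": "; ".join(q.traits), "marker": q.peak_marker,
            "chrom": q.chrom, "pos_bp": q.pos_bp, "qtl_id": q.id,
            "peak_lod": q.peak_lod, "effect": q.effect, "p_value": q.p_value,
            "window_start": q.window[0], "window_end": q.window[1],
        }
        if genes is None or genes.empty:
            rows.append({**base, "gene_id": "", "gene_annotation": ""})
        else:
            for g in genes.itertuples(index=False):
                rows.append({**base, "gene_id": g.gene_id,
                             "gene_annotation": getattr(g, "annotation", "")})
    return pd.DataFrame(rows)
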