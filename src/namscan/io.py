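"""Readers, writers and marker quality control.

All tabular artefacts are plain TSV.  Files written by the pipeline carry
``#``-prefixed header comments recording the seed and a configuration hash
so runs can be traced and reproduced; readers skip comment lines.

Marker QC mirrors chip-data curation for NAM dosage matrices: a marker is
kept only if it is polymorphic in at least one family, has a missing-call
fraction below 10% and a heterozygous-call fraction below 12.5% (a BC1S3
line is expected to be heterozygous at ~6.25% of loci, so a higher rate
flags genotyping problems).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .config import QCConfig
from .simulate import GenotypeMatrix, PlantedQTL, TruthSet

logger = logging.getLogger(__name__)


def config_hash(obj) -> str:
    """Short stable hash of a configuration object or mapping."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        obj = dataclasses.asdict(obj)
    payload = json.dumps(obj, sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _write_tsv(df: pd.DataFrame, path, comments: dict | None = None,
               index: bool = False) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for key, val in (comments or {}).items():
            fh.write(f"# {key}: {val}\n")
        df.to_csv(fh, sep="\t", index=index)


def _read_tsv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


def write_genotypes(geno: GenotypeMatrix, marker_map: pd.DataFrame,
                    geno_path, map_path, comments: dict | None = None) -> None:
    out = geno.dosages.copy()
    out.insert(0, "family", geno.families)
    out = out.reset_index()
    _write_tsv(out, geno_path, comments)
    _write_tsv(marker_map, map_path, comments)


def read_genotypes(path, map_path) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Read a dosage matrix and its marker map, validating both.

    The matrix TSV has columns ``line, family, <marker ids...>`` with
    entries in {0, 1, 2} or empty/NA for missing.  Every marker column
    must appear in the map.
    """
    df = _read_tsv(path)
    required = {"line", "family"}
    if not required.issubset(df.columns[:2]):
        raise ValueError("malformed genotype header: first columns must be line, family")
    marker_map = read_marker_map(map_path)
    dosages = df.set_index("line").drop(columns=["family"])
    families = df.set_index("line")["family"]

    unknown = [m for m in dosages.columns if m not in set(marker_map["marker"])]
    if unknown:
        raise ValueError(f"markers absent from map: {unknown[:5]}"
                         + ("..." if len(unknown) > 5 else ""))
    vals = dosages.to_numpy(dtype=float)
    ok = np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0))
    if not ok.all():
        r, c = np.argwhere(~ok)[0]
        raise ValueError(
            f"invalid dosage {vals[r, c]!r} at line {dosages.index[r]!r}, "
            f"marker {dosages.columns[c]!r}: entries must be 0, 1, 2 or missing"
        )
    return GenotypeMatrix(dosages.astype(float), families), marker_map


def read_marker_map(path) -> pd.DataFrame:
    mm = _read_tsv(path)
    needed = {"marker", "chrom", "bp"}
    if not needed.issubset(mm.columns):
        raise ValueError(f"marker map must have columns {sorted(needed)}")
    if mm["marker"].duplicated().any():
        raise ValueError("duplicate marker ids in map")
    if (mm["bp"] < 0).any():
        raise ValueError("negative bp positions in map")
    return mm


def write_phenotypes(pheno: pd.DataFrame, path, comments: dict | None = None) -> None:
    _write_tsv(pheno, path, comments)


def read_phenotypes(path) -> pd.DataFrame:
    df = _read_tsv(path)
    needed = {"line", "treatment", "replicate", "trait", "value"}
    if not needed.issubset(df.columns):
        raise ValueError(f"phenotype table must have columns {sorted(needed)}")
    bad = set(df["treatment"].unique()) - {"C", "S"}
    if bad:
        raise ValueError(f"unknown treatment codes: {sorted(bad)}")
    return df


def write_truth(truth: TruthSet, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {
        "grand_means": truth.grand_means,
        "planted_qtls": [dataclasses.asdict(q) for q in truth.planted_qtls],
        "family_effects": truth.family_effects,
    }
    path.write_text(json.dumps(payload, indent=2))


def read_truth(path) -> TruthSet:
    payload = json.loads(Path(path).read_text())
    return TruthSet(
        grand_means=payload["grand_means"],
        planted_qtls=[PlantedQTL(**q) for q in payload.get("planted_qtls", [])],
        family_effects=payload.get("family_effects", {}),
    )


def read_annotation(path) -> pd.DataFrame:
    """Gene annotation as ``gene_id, chrom, start, end, annotation``.

    Accepts either a TSV with those columns or a standard 9-column GFF3
    (gene features only; coordinates 1-based inclusive per the GFF3 spec).
    """
    path = Path(path)
    head = path.read_text().splitlines()
    is_gff = path.suffix.lower() in {".gff", ".gff3"} or (
        head and head[0].startswith("##gff-version"))
    if not is_gff:
        df = _read_tsv(path)
        needed = {"gene_id", "chrom", "start", "end"}
        if not needed.issubset(df.columns):
            raise ValueError(f"annotation TSV must have columns {sorted(needed)}")
        if "annotation" not in df.columns:
            df["annotation"] = ""
        return df[["gene_id", "chrom", "start", "end", "annotation"]]

    rows = []
    for ln in head:
        if not ln or ln.startswith("#"):
            continue
        parts = ln.split("\t")
        if len(parts) != 9:
            raise ValueError("malformed GFF3 line: expected 9 tab-separated columns")
        chrom, _, ftype, start, end, _, _, _, attrs = parts
        if ftype != "gene":
            continue
        attr = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
        rows.append({
            "gene_id": attr.get("ID", ""),
            "chrom": chrom,
            "start": int(start),
            "end": int(end),
            "annotation": attr.get("description", attr.get("Note", "")),
        })
    df = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "annotation"])
    if df["gene_id"].duplicated().any():
        raise ValueError("duplicate gene ids in annotation")
    return df


def qc_filter(geno: GenotypeMatrix, cfg: QCConfig | None = None
              ) -> tuple[GenotypeMatrix, dict]:
    """Drop markers failing the chip-QC rules; return the filtered matrix
    and a per-rule report.

    Rules: polymorphic in >= 1 family; missing fraction < ``max_missing``;
    heterozygous fraction < ``max_het``.  A marker failing several rules is
    counted under each.
    """
    cfg = cfg or QCConfig()
    cfg.validate()
    dos = geno.dosages
    n = len(dos)

    missing_frac = dos.isna().mean()
    het_frac = (dos == 1).sum() / dos.notna().sum().clip(lower=1)

    poly = pd.Series(False, index=dos.columns)
    for _, idx in geno.families.groupby(geno.families).groups.items():
        sub = dos.loc[idx]
        poly |= sub.nunique(dropna=True) > 1
    fail_poly = ~poly if cfg.require_polymorphic else pd.Series(False, index=dos.columns)
    fail_missing = missing_frac >= cfg.max_missing
    fail_het = het_frac >= cfg.max_het

    keep = ~(fail_poly | fail_missing | fail_het)
    report = {
        "n_markers_in": int(dos.shape[1]),
        "n_markers_kept": int(keep.sum()),
        "n_fail_monomorphic": int(fail_poly.sum()),
        "n_fail_missing": int(fail_missing.sum()),
        "n_fail_het": int(fail_het.sum()),
        "n_lines": n,
    }
    if keep.sum() == 0:
        raise ValueError(f"all markers removed by QC: {report}")
    logger.info("QC: kept %d/%d markers (%d monomorphic, %d high-missing, %d high-het)",
                report["n_markers_kept"], report["n_markers_in"],
                report["n_fail_monomorphic"], report["n_fail_missing"],
                report["n_fail_het"])
    return GenotypeMatrix(dos.loc[:, keep], geno.families), report


def write_scan_results(scans, marker_map: pd.DataFrame, path,
                       lod_threshold: float | None = None,
                       comments: dict | None = None) -> pd.DataFrame:
    """Flatten per-trait scan results into one TSV."""
    pos = marker_map.set_index("marker")[["chrom", "bp"]]
    frames = []
    for trait, scan in scans.items():
        t = scan.table.join(pos, how="left")
        t.insert(0, "trait", trait)
        t = t.reset_index().rename(columns={"index": "marker"})
        if lod_threshold is not None:
            t["significant"] = t["lod"] >= lod_threshold
        frames.append(t)
    out = pd.concat(frames, ignore_index=True)
    cols = ["marker", "chrom", "bp", "trait", "p", "lod", "effect", "sp_r2"]
    if lod_threshold is not None:
        cols.append("significant")
    out = out[cols]
    _write_tsv(out, path, comments)
    return out
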