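"""Synthetic NAM genotypes and treatment-structured phenotypes.

The genotype generator realises the BC1S3 pedigree that underlies panels
such as the Halle Exotic Barley NAM population: for every family an F1
(elite x wild donor) is backcrossed once to the elite parent and the
product is selfed for three generations.  Meiosis uses the Haldane map
function (no crossover interference) on the marker cM positions, so the
single-locus genotype law is the exact pedigree Markov chain

    P(dosage 0, 1, 2) = (23/32, 1/16, 7/32),   E[dosage] = 1/2,

with dosage counting wild-donor alleles (0 = elite homozygote,
1 = heterozygote, 2 = wild homozygote).

Phenotypes are drawn from the two-treatment ANOVA model
``Y_ijk = mu_j + G_i + (GT)_ij + R_k(j) + e_ijk`` used generatively: the
genetic value of a line is a family offset plus the sum of planted QTL
effects (treatment-specific, additive in dosage) plus a polygenic normal
deviate; the stress treatment scales the grand mean by a per-trait factor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import (
    TREATMENTS,
    ConfigurationError,
    SimulationConfig,
)

logger = logging.getLogger(__name__)

#: Exact BC1S3 single-locus genotype probabilities for dosages (0, 1, 2).
BC1S3_GENOTYPE_PROBS = (23 / 32, 1 / 16, 7 / 32)


@dataclass
class GenotypeMatrix:
    """Lines x markers wild-allele dosage matrix with family labels.

    ``dosages`` holds floats in {0, 1, 2} with NaN for missing calls;
    ``families`` maps each line id (the dosage index) to its family label.
    """

    dosages: pd.DataFrame
    families: pd.Series

    def __post_init__(self) -> None:
        self.families = self.families.reindex(self.dosages.index)

    @property
    def n_lines(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    @property
    def markers(self) -> pd.Index:
        return self.dosages.columns

    def subset_markers(self, markers) -> "GenotypeMatrix":
        return GenotypeMatrix(self.dosages.loc[:, markers], self.families)


@dataclass
class PlantedQTL:
    marker: str
    trait: str
    effect_control: float
    effect_stress: float


@dataclass
class TruthSet:
    """Ground truth of a simulated scenario, for recovery tests and reports."""

    grand_means: dict[str, float]
    planted_qtls: list[PlantedQTL] = field(default_factory=list)
    #: trait -> {family label -> additive offset}
    family_effects: dict[str, dict[str, float]] = field(default_factory=dict)

    def validate(self, geno: GenotypeMatrix | None = None) -> None:
        for q in self.planted_qtls:
            if not (np.isfinite(q.effect_control) and np.isfinite(q.effect_stress)):
                raise ValueError(f"non-finite effect for planted QTL at {q.marker}")
            if geno is not None and q.marker not in geno.dosages.columns:
                raise ValueError(
                    f"planted QTL marker {q.marker!r} is absent from the genotype matrix"
                )

    @classmethod
    def from_config(cls, cfg: SimulationConfig) -> "TruthSet":
        """Null truth: grand means only, no QTLs, no family effects."""
        return cls(grand_means={t: cfg.trait_means[t] for t in cfg.traits})


def haldane_recomb_fraction(d_cm: np.ndarray) -> np.ndarray:
    """Recombination fraction for a map distance in cM (Haldane, no interference)."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cm, dtype=float) / 100.0))


def _meiosis(hap_a: np.ndarray, hap_b: np.ndarray, rec: np.ndarray,
             rng: np.random.Generator) -> np.ndarray:
    """One gamete per row from individuals with haplotypes ``hap_a``/``hap_b``.

    ``rec`` gives the recombination fraction between adjacent markers
    (length m-1).  The crossover process is Markov along the chromosome.
    """
    n, m = hap_a.shape
    first = (rng.random((n, 1)) < 0.5)
    if m > 1:
        switch = rng.random((n, m - 1)) < rec
        phase = np.logical_xor.accumulate(np.concatenate([first, switch], axis=1), axis=1)
    else:
        phase = first
    return np.where(phase, hap_b, hap_a)


def simulate_nam_genotypes(cfg: SimulationConfig) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Simulate BC1S3 NAM genotypes and the matching marker map.

    Returns the dosage matrix and a marker map with columns
    ``marker, chrom, bp, cm``.  Deterministic given ``cfg.seed``.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    map_rows = []
    per_chrom = []
    for chrom in cfg.chromosomes:
        m = cfg.markers_per_chromosome
        # evenly spaced physical positions; cM proportional to bp
        bp = np.round((np.arange(m) + 0.5) / m * chrom.length_bp).astype(np.int64)
        bp = np.maximum.accumulate(bp)  # guard against rounding ties at tiny lengths
        bp += np.arange(m)  # strictly increasing
        cm = bp / chrom.length_bp * chrom.length_cm
        rec = haldane_recomb_fraction(np.diff(cm))
        ids = [f"SNP_{chrom.name}_{i + 1:05d}" for i in range(m)]
        per_chrom.append((chrom, ids, rec))
        map_rows.append(pd.DataFrame({
            "marker": ids, "chrom": chrom.name, "bp": bp, "cm": cm,
        }))
    marker_map = pd.concat(map_rows, ignore_index=True)

    line_ids, fam_labels = [], []
    for f in range(cfg.n_families):
        fam = f"FAM{f + 1:02d}"
        for l in range(cfg.lines_per_family):
            line_ids.append(f"{fam}_L{l + 1:03d}")
            fam_labels.append(fam)

    blocks = []
    for chrom, ids, rec in per_chrom:
        m = len(ids)
        dos = np.empty((len(line_ids), m), dtype=np.int8)
        row = 0
        for f in range(cfg.n_families):
            n = cfg.lines_per_family
            donor = (rng.random(m) < cfg.donor_allele_freq).astype(np.int8)
            elite = np.zeros((n, m), dtype=np.int8)
            donor_h = np.broadcast_to(donor, (n, m))
            # BC1: (gamete from F1) x elite
            h1 = _meiosis(elite, donor_h, rec, rng)
            h2 = elite
            for _ in range(3):  # S1..S3
                g1 = _meiosis(h1, h2, rec, rng)
                g2 = _meiosis(h1, h2, rec, rng)
                h1, h2 = g1, g2
            dos[row:row + n] = h1 + h2
            row += n
        blocks.append(dos)

    dosages = pd.DataFrame(
        np.concatenate(blocks, axis=1).astype(float),
        index=pd.Index(line_ids, name="line"),
        columns=pd.Index(marker_map["marker"], name="marker"),
    )
    if cfg.missing_rate > 0:
        mask = rng.random(dosages.shape) < cfg.missing_rate
        dosages = dosages.mask(mask)
    families = pd.Series(fam_labels, index=dosages.index, name="family")
    return GenotypeMatrix(dosages, families), marker_map


def plant_qtls(geno: GenotypeMatrix, marker_map: pd.DataFrame, cfg: SimulationConfig,
               n_qtls: int, trait: str = "SL", variance_explained: float = 0.10,
               rng: np.random.Generator | None = None,
               pleiotropic_traits: tuple[str, ...] = ()) -> TruthSet:
    """Build a truth set with ``n_qtls`` markers of equal effect on ``trait``.

    The additive effect is sized so that each QTL explains
    ``variance_explained`` of the total line-mean phenotypic variance of
    the trait within a treatment (the variance of the GWAS response),
    accounting for the variance the planted QTLs themselves add; the
    stress-treatment effect is scaled by the trait's treatment factor so
    effects stay proportional to the trait mean.  QTL markers are spread
    across chromosomes (one per chromosome before wrapping around) to
    keep them unlinked.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 1)
    vc = cfg.variance_spec(trait)
    # within-treatment line-mean phenotypic variance without QTLs
    r = cfg.n_replicates
    var_p = vc.sigma_g2 + vc.sigma_gt2 + vc.sigma_e2 / r
    var_dosage = 0.6875  # exact BC1S3 dosage variance: E[d^2] - 1/4
    if n_qtls * variance_explained >= 1.0:
        raise ValueError("n_qtls * variance_explained must be < 1")
    target_var = variance_explained * var_p / (1.0 - n_qtls * variance_explained)
    effect = float(np.sqrt(target_var / var_dosage))

    chroms = marker_map["chrom"].unique()
    markers = []
    for i in range(n_qtls):
        sub = marker_map[marker_map["chrom"] == chroms[i % len(chroms)]]
        pos = sub.iloc[int(rng.integers(len(sub) // 4, 3 * len(sub) // 4))]
        markers.append(pos["marker"])

    qtls = []
    for mk in markers:
        for t in (trait, *pleiotropic_traits):
            f_t = cfg.treatment_effect.get(t, 1.0)
            scale = cfg.trait_means[t] / cfg.trait_means[trait] if t != trait else 1.0
            qtls.append(PlantedQTL(mk, t, effect * scale, effect * scale * f_t))
    truth = TruthSet(
        grand_means={t: cfg.trait_means[t] for t in cfg.traits},
        planted_qtls=qtls,
    )
    truth.validate(geno)
    return truth


def simulate_phenotypes(geno: GenotypeMatrix, truth: TruthSet,
                        cfg: SimulationConfig) -> pd.DataFrame:
    """Replicate-level phenotypes for both treatments, long format.

    Returns a DataFrame with columns ``line, family, treatment, replicate,
    trait, value``.  Germination (GER) values are integer seed counts in
    [0, seeds_per_replicate] obtained by rounding the latent trait;
    FW/DW pairs are nudged to satisfy FW > DW > 0 so water-content and
    dry-matter ratios are always defined.
    """
    cfg.validate()
    truth.validate(geno)
    rng = np.random.default_rng(cfg.seed + 7)

    lines = geno.dosages.index
    n = len(lines)
    r = cfg.n_replicates
    fam = geno.families

    # per-marker mean imputation for genetic values (missing calls are rare)
    effects_by_trait: dict[str, np.ndarray] = {}
    for q in truth.planted_qtls:
        col = geno.dosages[q.marker]
        d = col.fillna(col.mean()).to_numpy()
        for tre, eff in (("C", q.effect_control), ("S", q.effect_stress)):
            key = f"{q.trait}|{tre}"
            effects_by_trait.setdefault(key, np.zeros(n))
            effects_by_trait[key] += d * eff

    frames = {}
    for trait in cfg.traits:
        mu_c = truth.grand_means[trait]
        factor = cfg.treatment_effect.get(trait, 1.0)
        vc = cfg.variance_spec(trait)
        g = rng.normal(0.0, np.sqrt(vc.sigma_g2), n)
        fam_off = np.zeros(n)
        fe = truth.family_effects.get(trait)
        if fe:
            fam_off = fam.map(fe).fillna(0.0).to_numpy()
        vals = np.empty((n, 2, r))
        for j, tre in enumerate(TREATMENTS):
            mu = mu_c if tre == "C" else mu_c * factor
            gt = rng.normal(0.0, np.sqrt(vc.sigma_gt2), n)
            rep_eff = rng.normal(0.0, np.sqrt(vc.sigma_rep2), r)
            qtl = effects_by_trait.get(f"{trait}|{tre}", 0.0)
            eps = rng.normal(0.0, np.sqrt(vc.sigma_e2), (n, r))
            vals[:, j, :] = (mu + fam_off + g + gt + qtl)[:, None] + rep_eff[None, :] + eps
        frames[trait] = vals

    # enforce FW > DW > 0 where both weights are simulated
    if "FW" in frames and "DW" in frames:
        fw, dw = frames["FW"], frames["DW"]
        fw = np.maximum(fw, 2e-3)
        dw = np.clip(dw, 1e-4, 0.95 * fw)
        frames["FW"], frames["DW"] = fw, dw
    if "GER" in frames:
        frames["GER"] = np.clip(np.round(frames["GER"]), 0, cfg.seeds_per_replicate)

    records = []
    for trait, vals in frames.items():
        for j, tre in enumerate(TREATMENTS):
            for k in range(r):
                records.append(pd.DataFrame({
                    "line": lines,
                    "family": fam.to_numpy(),
                    "treatment": tre,
                    "replicate": k + 1,
                    "trait": trait,
                    "value": vals[:, j, k],
                }))
    pheno = pd.concat(records, ignore_index=True)
    return pheno.sort_values(["trait", "treatment", "replicate", "line"],
                             kind="stable").reset_index(drop=True)
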