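"""Derived seedling traits, tolerance indices, heritability and BLUEs.

Trait conventions follow seedling salinity screens: raw measurements are
coleoptile length (CL), shoot length (SL), longest root length (RL),
seedling fresh and dry weight (FW, DW) and germinated-seed counts (GER).
Derived quantities are

    Ger%    = germinated / total seeds x 100
    WCP     = 100 x (FW - DW) / FW          (water content percentage)
    RSR     = RL / SL                       (root-shoot length ratio)
    DW/FW-R = DW / FW                       (dry-matter fraction)

Every trait gets a per-treatment column (suffix ``_C`` / ``_S``) and a
tolerance index ``_TI`` = stress mean / control mean.

Variance components come from the balanced two-treatment ANOVA model
``Y_ijk = mu + G_i + T_j + (GT)_ij + R_k(T_j) + e_ijk`` with genotype
random and treatment fixed; broad-sense heritability on a line-mean basis
is ``H2 = sg2 / (sg2 + sgt2/y + se2/(y r))`` for y treatments and r
replicates.  BLUEs are generalised-least-squares genotype means within a
treatment, ``beta = (X' V^-1 X)^-1 X' V^-1 y`` with replicate as the only
random term in V.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: raw simulator traits carried through to the trait matrix as-is
RAW_TRAITS = ("CL", "SL", "RL", "FW", "DW")
#: traits computed from the raw ones
DERIVED_TRAITS = ("Ger", "WCP", "RSR", "DW_FW_R")


@dataclass
class VarianceComponents:
    sigma_g2: float
    sigma_gt2: float
    sigma_e2: float
    y: int  # number of treatments
    r: int  # replicates per treatment

    def validate(self) -> None:
        if min(self.sigma_g2, self.sigma_gt2, self.sigma_e2) < 0:
            raise ValueError("variance components must be >= 0")
        if self.y < 1 or self.r < 1:
            raise ValueError("y and r must be >= 1")


def _replicate_means(raw: pd.DataFrame, min_replicates: int = 2) -> pd.DataFrame:
    """Mean over available replicates per (line, treatment, trait).

    Cells with fewer than ``min_replicates`` non-missing replicates are set
    missing.  Wide output: index line, columns (trait, treatment).
    """
    grp = raw.groupby(["line", "treatment", "trait"])["value"]
    means = grp.mean()
    counts = grp.count()
    means[counts < min_replicates] = np.nan
    wide = means.unstack(["trait", "treatment"])
    wide.columns = pd.MultiIndex.from_tuples(wide.columns, names=["trait", "treatment"])
    return wide


def tolerance_index(trait_s, trait_c):
    """TI = stress value / control value; control <= 0 yields missing."""
    s = np.asarray(trait_s, dtype=float)
    c = np.asarray(trait_c, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ti = np.where(c > 0, s / c, np.nan)
    n_bad = int(np.sum((c <= 0) & ~np.isnan(c)))
    if n_bad:
        logger.warning("tolerance index undefined for %d entries with control <= 0", n_bad)
    return ti if ti.ndim else float(ti)


def derive_traits(raw: pd.DataFrame, seeds_per_replicate: int = 16,
                  min_replicates: int = 2) -> pd.DataFrame:
    """Line-level derived traits and tolerance indices.

    ``raw`` is the long-format phenotype table (columns line, treatment,
    replicate, trait, value).  Returns a wide matrix indexed by line with
    columns ``<trait>_C``, ``<trait>_S`` and ``<trait>_TI``.
    """
    dup = raw.duplicated(["line", "treatment", "replicate", "trait"])
    if dup.any():
        raise ValueError("duplicate (line, treatment, replicate, trait) keys in input")
    wide = _replicate_means(raw, min_replicates=min_replicates)

    out = {}
    for trait in RAW_TRAITS:
        if trait in wide.columns.get_level_values(0):
            for tre in ("C", "S"):
                if (trait, tre) in wide.columns:
                    out[f"{trait}_{tre}"] = wide[(trait, tre)]

    for tre in ("C", "S"):
        if ("GER", tre) in wide.columns:
            out[f"Ger_{tre}"] = wide[("GER", tre)] / seeds_per_replicate * 100.0
        fw = out.get(f"FW_{tre}")
        dw = out.get(f"DW_{tre}")
        if fw is not None and dw is not None:
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(fw > 0, dw / fw, np.nan)
            n_zero = int(((fw <= 0) & fw.notna()).sum())
            if n_zero:
                logger.warning("WCP/DW-FW undefined for %d lines with FW <= 0 (%s)",
                               n_zero, tre)
            out[f"WCP_{tre}"] = pd.Series(100.0 * (1.0 - ratio), index=fw.index)
            out[f"DW_FW_R_{tre}"] = pd.Series(ratio, index=fw.index)
        sl = out.get(f"SL_{tre}")
        rl = out.get(f"RL_{tre}")
        if sl is not None and rl is not None:
            with np.errstate(divide="ignore", invalid="ignore"):
                rsr = np.where(sl > 0, rl / sl, np.nan)
            n_zero = int(((sl <= 0) & sl.notna()).sum())
            if n_zero:
                logger.warning("RSR undefined for %d lines with SL <= 0 (%s)", n_zero, tre)
            out[f"RSR_{tre}"] = pd.Series(rsr, index=sl.index)

    traits = sorted({c.rsplit("_", 1)[0] for c in out})
    for trait in traits:
        c, s = out.get(f"{trait}_C"), out.get(f"{trait}_S")
        if c is not None and s is not None:
            out[f"{trait}_TI"] = pd.Series(tolerance_index(s, c), index=c.index)

    cols = [f"{t}_{suf}" for t in traits for suf in ("C", "S", "TI") if f"{t}_{suf}" in out]
    tm = pd.DataFrame(out)[cols]
    tm.index.name = "line"
    return tm


def fit_variance_components(pheno: pd.DataFrame, trait: str) -> VarianceComponents:
    """Expected-mean-squares estimates from the balanced two-way ANOVA.

    Requires a balanced design: every genotype observed in every treatment
    with the same number of replicates.  Negative solutions are truncated
    at zero, as is conventional for method-of-moments components.
    """
    df = pheno[pheno["trait"] == trait].dropna(subset=["value"])
    if df.empty:
        raise ValueError(f"no observations for trait {trait!r}")
    g = df["line"].nunique()
    t = df["treatment"].nunique()
    counts = df.groupby(["line", "treatment"])["value"].count()
    if g < 2 or t < 2:
        raise ValueError("need >= 2 genotypes and 2 treatments")
    full = g * t
    if len(counts) < full:
        have = counts.reset_index().groupby("line")["treatment"].nunique()
        missing = have[have < t].index.tolist()
        raise ValueError(
            f"unbalanced design: genotypes absent from a treatment: {missing[:10]}"
        )
    r = int(counts.iloc[0])
    if r < 2 or counts.nunique() != 1:
        raise ValueError("need a balanced design with >= 2 replicates per cell")

    y = df["value"].to_numpy()
    grand = y.mean()
    m_g = df.groupby("line")["value"].mean()
    m_t = df.groupby("treatment")["value"].mean()
    m_gt = df.groupby(["line", "treatment"])["value"].mean()
    m_rt = df.groupby(["treatment", "replicate"])["value"].mean()

    ss_g = t * r * ((m_g - grand) ** 2).sum()
    ss_t = g * r * ((m_t - grand) ** 2).sum()
    inter = (m_gt - m_g.reindex(m_gt.index.get_level_values(0)).to_numpy()
             - m_t.reindex(m_gt.index.get_level_values(1)).to_numpy() + grand)
    ss_gt = r * (inter ** 2).sum()
    ss_rt = g * ((m_rt - m_t.reindex(m_rt.index.get_level_values(0)).to_numpy()) ** 2).sum()
    ss_tot = ((y - grand) ** 2).sum()
    ss_e = ss_tot - ss_g - ss_t - ss_gt - ss_rt

    ms_g = ss_g / (g - 1)
    ms_gt = ss_gt / ((g - 1) * (t - 1))
    ms_e = ss_e / ((g - 1) * t * (r - 1))

    sigma_e2 = max(ms_e, 0.0)
    sigma_gt2 = max((ms_gt - ms_e) / r, 0.0)
    sigma_g2 = max((ms_g - ms_gt) / (t * r), 0.0)
    vc = VarianceComponents(sigma_g2, sigma_gt2, sigma_e2, y=t, r=r)
    vc.validate()
    return vc


def heritability(vc: VarianceComponents) -> float:
    """Broad-sense heritability on a line-mean basis, clamped to [0, 1]."""
    vc.validate()
    denom = vc.sigma_g2 + vc.sigma_gt2 / vc.y + vc.sigma_e2 / (vc.y * vc.r)
    if denom == 0:
        return float("nan")
    return float(min(max(vc.sigma_g2 / denom, 0.0), 1.0))


def _rep_variance_within_treatment(df: pd.DataFrame) -> tuple[float, float]:
    """EMS estimates of (sigma_rep2, sigma_e2) for genotype(fixed) + rep(random)."""
    g = df["line"].nunique()
    m_r = df.groupby("replicate")["value"].mean()
    m_g = df.groupby("line")["value"].mean()
    grand = df["value"].mean()
    r = len(m_r)
    ss_r = g * ((m_r - grand) ** 2).sum()
    resid = (df["value"]
             - df["line"].map(m_g)
             - df["replicate"].map(m_r) + grand)
    df_e = (g - 1) * (r - 1)
    if df_e <= 0:
        return 0.0, float((resid ** 2).sum())
    ms_e = float((resid ** 2).sum() / df_e)
    ms_r = float(ss_r / (r - 1)) if r > 1 else ms_e
    return max((ms_r - ms_e) / g, 0.0), max(ms_e, 0.0)


def compute_blues(pheno: pd.DataFrame, treatment: str, trait: str) -> pd.DataFrame:
    """Genotype-level adjusted means (BLUEs) within one treatment.

    Model: genotype fixed (cell means), replicate random.  Variance
    components are estimated by expected mean squares and the BLUEs solve
    the GLS normal equations; on balanced data this reduces exactly to the
    per-genotype arithmetic mean.  Returns columns ``line, blue, se``.
    """
    df = pheno[(pheno["trait"] == trait) & (pheno["treatment"] == treatment)]
    df = df.dropna(subset=["value"])
    if df.empty:
        raise ValueError(f"no observations for trait {trait!r} treatment {treatment!r}")
    n_reps = df.groupby("line")["replicate"].count()
    if (n_reps < 2).all():
        raise ValueError("need >= 2 replicates within the treatment")

    lines = pd.Index(sorted(df["line"].unique()), name="line")
    reps = sorted(df["replicate"].unique())
    li = pd.Categorical(df["line"], categories=lines).codes
    ri = pd.Categorical(df["replicate"], categories=reps).codes
    n = len(df)
    ng, nr = len(lines), len(reps)

    counts = np.bincount(li, minlength=ng)
    if (counts == 0).any():
        bad = lines[counts == 0].tolist()
        raise ValueError(f"aliased genotypes with no observations: {bad[:10]}")

    X = np.zeros((n, ng))
    X[np.arange(n), li] = 1.0
    Z = np.zeros((n, nr))
    Z[np.arange(n), ri] = 1.0
    s_rep2, s_e2 = _rep_variance_within_treatment(df)
    if s_e2 <= 0:
        s_e2 = 1e-12

    yv = df["value"].to_numpy()

    def v_inv_apply(M: np.ndarray) -> np.ndarray:
        # Woodbury: V = s_e2 I + s_rep2 Z Z'  (Z has one column per replicate)
        if s_rep2 <= 0:
            return M / s_e2
        core = (s_e2 / s_rep2) * np.eye(nr) + Z.T @ Z
        return (M - Z @ np.linalg.solve(core, Z.T @ M)) / s_e2

    Vi_X = v_inv_apply(X)
    Vi_y = v_inv_apply(yv.reshape(-1, 1)).ravel()
    xtvx = X.T @ Vi_X
    try:
        cov = np.linalg.inv(xtvx)
    except np.linalg.LinAlgError:
        raise ValueError("singular design: genotype effects not estimable")
    beta = cov @ (X.T @ Vi_y)
    se = np.sqrt(np.diag(cov))
    return pd.DataFrame({"line": lines, "blue": beta, "se": se}).reset_index(drop=True)


def blue_table(pheno: pd.DataFrame, traits: list[str] | None = None) -> pd.DataFrame:
    """BLUEs for every (treatment, trait) pair present; long format."""
    traits = traits if traits is not None else sorted(pheno["trait"].unique())
    rows = []
    for trait in traits:
        for tre in sorted(pheno["treatment"].unique()):
            b = compute_blues(pheno, tre, trait)
            b.insert(1, "treatment", tre)
            b.insert(2, "trait", trait)
            rows.append(b)
    return pd.concat(rows, ignore_index=True)


def blues_as_responses(blues: pd.DataFrame) -> pd.DataFrame:
    """Pivot a BLUE table to a wide response matrix with _C/_S columns."""
    wide = blues.pivot(index="line", columns=["trait", "treatment"], values="blue")
    wide.columns = [f"{t}_{tre}" for t, tre in wide.columns]
    return wide


def trait_correlations(traits: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson correlations of trait columns (pairwise-complete)."""
    return traits.corr(method="pearson")
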