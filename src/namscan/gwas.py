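"""Three-step multi-locus association scan with cofactor correction.

The scan treats the lines x markers dosage matrix as the predictor set of
ordinary multiple linear regression (no kinship matrix: in a NAM panel the
shared recurrent parent removes most stratification and the cofactors
absorb the polygenic background):

I.   Stability pre-selection.  Over repeated 80/20 subsamples, forward
     selection is run on the training lines, adding the marker with the
     largest training RSS reduction while the held-out mean squared
     prediction error keeps decreasing.  Markers selected in at least
     ``min_selection_count`` subsamples become cofactor candidates.
II.  Cofactor selection.  Forward selection over the candidates on the
     full data, minimising the Schwarz Bayesian criterion
     SBC = n ln(RSS/n) + k ln(n); stops at the first non-improving step.
III. Conditioned scan.  Every marker is tested in a model holding the
     step-II cofactors in the background; the test of the marker entered
     last is the sequential (type-I) F/t test, its incremental R^2 given
     the cofactors is the squared semi-partial correlation, and its dosage
     coefficient is the allele effect (positive = wild allele raises the
     trait).  A marker that is itself a cofactor, or nearly collinear with
     one, has that cofactor dropped from its own background.

Significance is declared against a Bonferroni LOD threshold
``-log10(alpha / n_tests)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .config import ConfigurationError, ScanConfig
from .simulate import GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass
class GWASScanResult:
    """Per-marker statistics of one conditioned scan."""

    trait: str
    table: pd.DataFrame  # index marker; columns p, lod, effect, sp_r2
    cofactors: list[str]
    n_lines: int
    selection_counts: pd.Series = field(default_factory=lambda: pd.Series(dtype=int))

    def significant(self, lod_threshold: float) -> pd.DataFrame:
        return self.table[self.table["lod"] >= lod_threshold]


def bonferroni_lod(n_tests: int, alpha: float = 0.05) -> float:
    """LOD threshold -log10(alpha / n_tests) for a family-wise error of alpha."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    return float(-np.log10(alpha / n_tests))


def prepare_dosages(geno: GenotypeMatrix) -> pd.DataFrame:
    """Numeric predictor matrix: per-marker mean imputation of missing calls."""
    dos = geno.dosages
    n_missing = int(dos.isna().to_numpy().sum())
    if n_missing:
        frac = n_missing / dos.size
        logger.info("mean-imputing %d missing dosages (%.2f%%)", n_missing, 100 * frac)
        dos = dos.fillna(dos.mean())
    return dos


def _forward_selection_path(X: np.ndarray, y: np.ndarray, max_steps: int):
    """Greedy forward selection by training RSS; yields column indices in order.

    Operates on centred data via Gram-Schmidt residualisation, so each step
    is O(n p).  Yields (index, train_rss_after) tuples.
    """
    n, p = X.shape
    Xr = X - X.mean(axis=0)
    r = y - y.mean()
    norms = (Xr ** 2).sum(axis=0)
    active = norms > 1e-10 * max(norms.max(), 1.0)
    rss = float(r @ r)
    for _ in range(min(max_steps, p)):
        if not active.any():
            return
        scores = np.zeros(p)
        with np.errstate(divide="ignore", invalid="ignore"):
            proj = Xr.T @ r
            scores[active] = proj[active] ** 2 / norms[active]
        j = int(np.argmax(scores))
        if scores[j] <= 1e-12:
            return
        cj = Xr[:, j] / np.sqrt(norms[j])
        rss -= scores[j]
        yield j, rss
        # project the chosen direction out of the residual and the candidates
        r = r - cj * (cj @ r)
        Xr = Xr - np.outer(cj, cj @ Xr)
        norms = (Xr ** 2).sum(axis=0)
        active = norms > 1e-10 * max(norms.max(), 1.0)


def _holdout_mse(X_tr, y_tr, X_va, y_va, cols) -> float:
    A_tr = np.column_stack([np.ones(len(y_tr)), X_tr[:, cols]])
    beta, *_ = np.linalg.lstsq(A_tr, y_tr, rcond=None)
    A_va = np.column_stack([np.ones(len(y_va)), X_va[:, cols]])
    resid = y_va - A_va @ beta
    return float(resid @ resid / len(y_va))


def subsample_preselection(geno: GenotypeMatrix, y: pd.Series,
                           cfg: ScanConfig) -> tuple[list[str], pd.Series]:
    """Step I: stability pre-selection over repeated 80/20 subsamples.

    Returns (candidate markers with selection count >= min_selection_count,
    full selection-count series).  Deterministic given ``cfg.seed``.
    """
    cfg.validate()
    dos = prepare_dosages(geno)
    y = y.reindex(dos.index)
    if y.isna().any():
        raise ValueError("missing responses: drop missing lines before step I")
    n = len(y)
    if n < cfg.min_lines:
        raise ValueError(f"too few lines for subsampling: {n} < {cfg.min_lines}")

    X = dos.to_numpy(dtype=float)
    yv = y.to_numpy(dtype=float)
    markers = dos.columns
    counts = np.zeros(X.shape[1], dtype=int)
    rng = np.random.default_rng(cfg.seed)
    fam_codes = None
    if cfg.stratify_by_family:
        fam_codes = pd.Categorical(geno.families.reindex(dos.index)).codes

    n_train = int(round(cfg.train_fraction * n))
    n_train = min(max(n_train, 2), n - 1)
    for _ in range(cfg.n_subsamples):
        if fam_codes is None:
            perm = rng.permutation(n)
            tr_idx, va_idx = perm[:n_train], perm[n_train:]
        else:
            tr_parts = []
            for f in np.unique(fam_codes):
                idx = np.nonzero(fam_codes == f)[0]
                idx = rng.permutation(idx)
                k = int(round(cfg.train_fraction * len(idx)))
                tr_parts.append(idx[:k])
            tr_idx = np.concatenate(tr_parts)
            mask = np.ones(n, dtype=bool)
            mask[tr_idx] = False
            va_idx = np.nonzero(mask)[0]
            if len(va_idx) == 0:
                continue
        X_tr, y_tr = X[tr_idx], yv[tr_idx]
        X_va, y_va = X[va_idx], yv[va_idx]

        best = _holdout_mse(X_tr, y_tr, X_va, y_va, [])
        chosen: list[int] = []
        for j, _ in _forward_selection_path(X_tr, y_tr, cfg.max_selection_steps):
            trial = chosen + [j]
            mse = _holdout_mse(X_tr, y_tr, X_va, y_va, trial)
            if mse >= best:
                break
            best = mse
            chosen = trial
        counts[chosen] += 1

    series = pd.Series(counts, index=markers, name="selection_count")
    cands = series[series >= cfg.min_selection_count]
    candidates = list(cands.sort_values(ascending=False).index)
    logger.info("step I: %d/%d markers selected >= %d times",
                len(candidates), len(markers), cfg.min_selection_count)
    return candidates, series


def sbc(n: int, rss: float, k: int) -> float:
    """Schwarz Bayesian criterion n ln(RSS/n) + k ln(n); k counts parameters."""
    rss = max(rss, 1e-300)
    return float(n * np.log(rss / n) + k * np.log(n))


def _rss(A: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    beta, _, rank, _ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ beta
    return float(resid @ resid), int(rank)


def sbc_forward_selection(geno: GenotypeMatrix, y: pd.Series,
                          candidates: list[str],
                          max_cofactors: int = 20) -> list[str]:
    """Step II: forward selection over candidates minimising the SBC.

    Adds at each step the candidate whose inclusion lowers the SBC most;
    stops when no addition lowers it.  Candidates whose addition leaves the
    design rank-deficient (e.g. a duplicated column) are skipped.
    """
    if not candidates:
        return []
    dos = prepare_dosages(geno)
    y = y.reindex(dos.index).astype(float)
    if y.isna().any():
        raise ValueError("missing responses: drop missing lines before step II")
    yv = y.to_numpy()
    n = len(yv)
    X = {m: dos[m].to_numpy(dtype=float) for m in candidates}

    selected: list[str] = []
    base = np.ones((n, 1))
    rss0, _ = _rss(base, yv)
    current_sbc = sbc(n, rss0, 1)
    while len(selected) < max_cofactors:
        best_m, best_sbc, best_col = None, current_sbc, None
        k = len(selected) + 2  # intercept + selected + trial marker
        design = np.column_stack([base] + [X[m] for m in selected])
        for m in candidates:
            if m in selected:
                continue
            A = np.column_stack([design, X[m]])
            rss, rank = _rss(A, yv)
            if rank < A.shape[1]:
                logger.info("step II: skipping %s (collinear with current model)", m)
                continue
            s = sbc(n, rss, k)
            if s < best_sbc - 1e-12:
                best_sbc, best_m = s, m
        if best_m is None:
            break
        selected.append(best_m)
        current_sbc = best_sbc
    logger.info("step II: %d cofactors selected (SBC=%.3f)", len(selected), current_sbc)
    return selected


def scan_with_cofactors(geno: GenotypeMatrix, y: pd.Series,
                        cofactors: list[str],
                        collinearity_r: float = 0.99,
                        trait: str = "trait") -> GWASScanResult:
    """Step III: cofactor-conditioned single-marker tests for every marker.

    For each marker m the model ``y ~ 1 + cofactors + m`` is fitted; the
    p-value is the two-sided t test of m entered last, ``sp_r2`` its
    incremental R^2 over the cofactor model relative to the total sum of
    squares, and ``effect`` its dosage coefficient.  Cofactors correlated
    with m at |r| >= ``collinearity_r`` (including m itself) are removed
    from the background of m's own test.
    """
    dos = prepare_dosages(geno)
    y = y.reindex(dos.index).astype(float)
    if y.isna().any():
        raise ValueError("missing responses: drop missing lines before the scan")
    yv = y.to_numpy()
    n = len(yv)
    if np.var(yv) == 0:
        raise ValueError("response has zero variance")
    missing_cof = [c for c in cofactors if c not in dos.columns]
    if missing_cof:
        raise ValueError(f"cofactors absent from genotype matrix: {missing_cof}")

    X = dos.to_numpy(dtype=float)
    markers = dos.columns
    tss = float(((yv - yv.mean()) ** 2).sum())

    # group markers by which cofactors must be excluded from their background
    exclusions: dict[int, frozenset[str]] = {}
    if cofactors:
        C = dos[cofactors].to_numpy(dtype=float)
        Xc = X - X.mean(axis=0)
        Cc = C - C.mean(axis=0)
        xn = np.sqrt((Xc ** 2).sum(axis=0))
        cn = np.sqrt((Cc ** 2).sum(axis=0))
        with np.errstate(divide="ignore", invalid="ignore"):
            corr = (Xc.T @ Cc) / np.outer(xn, cn)
        corr = np.nan_to_num(corr)
        hits = np.abs(corr) >= collinearity_r
        for i in np.nonzero(hits.any(axis=1))[0]:
            exclusions[i] = frozenset(np.asarray(cofactors, dtype=object)[hits[i]])

    groups: dict[frozenset[str], np.ndarray] = {}
    default = frozenset()
    all_idx = np.arange(len(markers))
    excluded_idx = np.fromiter(exclusions.keys(), dtype=int) if exclusions else np.array([], int)
    plain = np.setdiff1d(all_idx, excluded_idx)
    groups[default] = plain
    for i, excl in exclusions.items():
        groups.setdefault(excl, [])
    for i, excl in exclusions.items():
        groups[excl] = np.append(np.asarray(groups[excl], dtype=int), i)

    p = np.ones(len(markers))
    eff = np.zeros(len(markers))
    spr2 = np.zeros(len(markers))
    for excl, idx in groups.items():
        if len(idx) == 0:
            continue
        bg = [c for c in cofactors if c not in excl]
        B = np.column_stack([np.ones(n)] + [dos[c].to_numpy(dtype=float) for c in bg])
        Q, _ = np.linalg.qr(B)
        yr = yv - Q @ (Q.T @ yv)
        Xs = X[:, idx]
        Xr = Xs - Q @ (Q.T @ Xs)
        norms = (Xr ** 2).sum(axis=0)
        rss_bg = float(yr @ yr)
        dof = n - B.shape[1] - 1
        if dof <= 0:
            raise ValueError("not enough lines for the cofactor model")
        with np.errstate(divide="ignore", invalid="ignore"):
            proj = Xr.T @ yr
            ok = norms > 1e-10 * max(norms.max(), 1.0) if len(norms) else norms > 0
            beta = np.where(ok, proj / norms, 0.0)
            gain = np.where(ok, proj ** 2 / norms, 0.0)
            rss_full = np.maximum(rss_bg - gain, 0.0)
            se2 = rss_full / dof / norms
            tstat = np.where(ok & (se2 > 0), beta / np.sqrt(se2), 0.0)
        pvals = 2.0 * stats.t.sf(np.abs(tstat), dof)
        p[idx] = np.clip(pvals, np.finfo(float).tiny, 1.0)
        eff[idx] = beta
        spr2[idx] = gain / tss if tss > 0 else 0.0

    table = pd.DataFrame({
        "p": p,
        "lod": -np.log10(p),
        "effect": eff,
        "sp_r2": np.clip(spr2, 0.0, 1.0),
    }, index=markers)
    return GWASScanResult(trait=trait, table=table, cofactors=list(cofactors), n_lines=n)


def sequential_semipartial_r2(geno: GenotypeMatrix, y: pd.Series,
                              terms: list[str]) -> pd.Series:
    """Sequential (type-I) squared semi-partial correlations of ``terms``.

    Entering the terms in the given order, each value is the incremental
    R^2 of that term over its predecessors; the values sum to the model
    R^2 of the full fit.
    """
    dos = prepare_dosages(geno)
    yv = y.reindex(dos.index).astype(float).to_numpy()
    n = len(yv)
    tss = float(((yv - yv.mean()) ** 2).sum())
    out = {}
    prev_rss = tss
    cols = [np.ones(n)]
    for t in terms:
        cols.append(dos[t].to_numpy(dtype=float))
        rss, _ = _rss(np.column_stack(cols), yv)
        out[t] = (prev_rss - rss) / tss if tss > 0 else 0.0
        prev_rss = rss
    return pd.Series(out)


def run_scan(geno: GenotypeMatrix, y: pd.Series, cfg: ScanConfig,
             trait: str = "trait") -> GWASScanResult:
    """Run steps I-III for a single response vector."""
    candidates, counts = subsample_preselection(geno, y, cfg)
    cofactors = sbc_forward_selection(geno, y, candidates,
                                      max_cofactors=cfg.max_cofactors)
    result = scan_with_cofactors(geno, y, cofactors,
                                 collinearity_r=cfg.collinearity_r, trait=trait)
    result.selection_counts = counts
    return result


def run_gwas(geno: GenotypeMatrix, responses: pd.DataFrame,
             cfg: ScanConfig) -> dict[str, GWASScanResult]:
    """Steps I-III for every trait column of a wide response matrix.

    Traits with more than ``cfg.max_missing_lines`` missing lines or zero
    variance are skipped with a warning.  Each trait uses a seed derived
    from ``cfg.seed`` and the trait name, so results are reproducible and
    independent of trait order.
    """
    cfg.validate()
    if responses.shape[1] < 1:
        raise ValueError("need at least one trait column")
    results: dict[str, GWASScanResult] = {}
    for trait in responses.columns:
        y = responses[trait].reindex(geno.dosages.index)
        frac_missing = y.isna().mean()
        if frac_missing > cfg.max_missing_lines:
            logger.warning("trait %s skipped: %.0f%% missing lines",
                           trait, 100 * frac_missing)
            continue
        y = y.dropna()
        if y.var() == 0 or len(y) < 2:
            logger.warning("trait %s skipped: response has no variance", trait)
            continue
        sub = GenotypeMatrix(geno.dosages.loc[y.index], geno.families.loc[y.index])
        t_seed = (cfg.seed + int.from_bytes(trait.encode(), "little")) % (2 ** 31)
        t_cfg = ScanConfig(**{**cfg.__dict__, "seed": t_seed})
        try:
            results[trait] = run_scan(sub, y, t_cfg, trait=trait)
        except ValueError as exc:
            logger.warning("trait %s skipped: %s", trait, exc)
    return results
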