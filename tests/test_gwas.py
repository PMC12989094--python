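"""Association-scan checks against direct OLS, brute-force SBC and null
simulation oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from namscan import (
    ConfigurationError,
    GenotypeMatrix,
    ScanConfig,
    SimulationConfig,
    PlantedQTL,
    TruthSet,
    bonferroni_lod,
    run_gwas,
    run_scan,
    sbc_forward_selection,
    scan_with_cofactors,
    sequential_semipartial_r2,
    simulate_phenotypes,
    subsample_preselection,
)
from namscan.gwas import sbc, prepare_dosages

from conftest import random_genotypes


class TestBonferroniLod:
    @pytest.mark.parametrize("n_tests, alpha, expected, places", [
        (32995, 0.05, 5.82, 2),   # the 50K-chip genome-wide threshold
        (1, 0.05, 1.301, 3),
        (20, 0.05, 2.602, 3),
    ])
    def test_values(self, n_tests, alpha, expected, places):
        assert round(bonferroni_lod(n_tests, alpha), places) == expected

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            bonferroni_lod(0, 0.05)
        with pytest.raises(ValueError):
            bonferroni_lod(10, 1.5)


def _qtl_response(geno, markers_effects, noise_sd, seed):
    rng = np.random.default_rng(seed)
    y = np.zeros(geno.n_lines)
    for m, a in markers_effects:
        y = y + a * geno.dosages[m].to_numpy()
    y = y + rng.normal(0, noise_sd, geno.n_lines)
    return pd.Series(y, index=geno.dosages.index)


class TestSubsamplePreselection:
    def test_strong_marker_selected_in_nearly_all_subsamples(self):
        """A marker explaining ~25% of variance on an unlinked panel is
        selected in >= 95 of 100 subsamples."""
        geno, _ = random_genotypes(400, 60, seed=0)
        m = geno.dosages.columns[30]
        # var(QTL) = 0.6875; noise var 3x gives ~25% explained
        y = _qtl_response(geno, [(m, 1.0)], np.sqrt(3 * 0.6875), seed=1)
        cands, counts = subsample_preselection(geno, y, ScanConfig(seed=5))
        assert counts[m] >= 95
        assert m in cands

    def test_null_response_keeps_few_candidates(self):
        """On pure noise (200 lines x 200 markers) the retained candidate
        set stays below 5% of markers on average over 20 runs."""
        fracs = []
        for run in range(20):
            geno, _ = random_genotypes(200, 200, seed=100 + run)
            y = pd.Series(np.random.default_rng(run).normal(size=200),
                          index=geno.dosages.index)
            cands, _ = subsample_preselection(geno, y, ScanConfig(seed=run))
            fracs.append(len(cands) / geno.n_markers)
        assert np.mean(fracs) < 0.05

    def test_zero_subsamples_is_a_configuration_error(self):
        with pytest.raises(ConfigurationError):
            ScanConfig(n_subsamples=0).validate()

    def test_too_few_lines_rejected(self):
        geno, _ = random_genotypes(10, 5, seed=1)
        y = pd.Series(np.zeros(10), index=geno.dosages.index)
        with pytest.raises(ValueError, match="too few lines"):
            subsample_preselection(geno, y, ScanConfig(seed=0))

    def test_deterministic_given_seed(self):
        geno, _ = random_genotypes(60, 30, seed=2)
        y = _qtl_response(geno, [(geno.dosages.columns[3], 0.8)], 1.0, seed=3)
        c1, s1 = subsample_preselection(geno, y, ScanConfig(seed=11, n_subsamples=20))
        c2, s2 = subsample_preselection(geno, y, ScanConfig(seed=11, n_subsamples=20))
        assert c1 == c2
        pd.testing.assert_series_equal(s1, s2)


def _brute_force_best_sbc(dos, y, candidates, max_size=3):
    """Minimum SBC over all candidate subsets up to max_size (oracle)."""
    n = len(y)
    best = (sbc(n, float(((y - y.mean()) ** 2).sum()), 1), ())
    for k in range(1, max_size + 1):
        for combo in itertools.combinations(candidates, k):
            A = np.column_stack([np.ones(n)] + [dos[m] for m in combo])
            beta, _, rank, _ = np.linalg.lstsq(A, y, rcond=None)
            if rank < A.shape[1]:
                continue
            rss = float(((y - A @ beta) ** 2).sum())
            s = sbc(n, rss, A.shape[1])
            if s < best[0]:
                best = (s, combo)
    return best


class TestSbcForwardSelection:
    def test_empty_candidates_give_empty_model(self):
        geno, _ = random_genotypes(50, 5, seed=3)
        y = pd.Series(np.ones(50), index=geno.dosages.index)
        assert sbc_forward_selection(geno, y, []) == []

    def test_matches_brute_force_on_separated_signals(self):
        """With near-orthogonal candidates and well-separated effects the
        greedy forward model attains the global best-subset SBC (exhaustive
        enumeration up to size 3)."""
        geno, _ = random_genotypes(200, 10, seed=4)
        cols = geno.dosages.columns
        y = _qtl_response(geno, [(cols[1], 1.2), (cols[4], 0.9), (cols[7], 0.7)],
                          1.0, seed=5)
        chosen = sbc_forward_selection(geno, y, list(cols))
        dos = prepare_dosages(geno)
        yv = y.to_numpy()
        best_sbc, best_set = _brute_force_best_sbc(dos, yv, list(cols))
        n = len(yv)
        A = np.column_stack([np.ones(n)] + [dos[m] for m in chosen])
        rss = float(((yv - A @ np.linalg.lstsq(A, yv, rcond=None)[0]) ** 2).sum())
        assert sbc(n, rss, A.shape[1]) == pytest.approx(best_sbc, abs=1e-9)
        assert set(chosen) == set(best_set)

    def test_each_step_is_the_sbc_argmin_addition(self):
        """Stepwise oracle: every accepted cofactor is the single addition
        with the lowest SBC among the remaining candidates."""
        geno, _ = random_genotypes(120, 8, seed=6)
        cols = list(geno.dosages.columns)
        y = _qtl_response(geno, [(cols[0], 0.9), (cols[3], 0.6)], 1.2, seed=7)
        chosen = sbc_forward_selection(geno, y, cols)
        dos = prepare_dosages(geno)
        yv = y.to_numpy()
        n = len(yv)
        prefix = []
        for pick in chosen:
            scores = {}
            for m in cols:
                if m in prefix:
                    continue
                A = np.column_stack([np.ones(n)] + [dos[c] for c in prefix + [m]])
                rss = float(((yv - A @ np.linalg.lstsq(A, yv, rcond=None)[0]) ** 2).sum())
                scores[m] = sbc(n, rss, A.shape[1])
            assert pick == min(scores, key=scores.get)
            prefix.append(pick)

    def test_duplicated_candidate_enters_once(self):
        geno, _ = random_genotypes(80, 4, seed=8)
        dos = geno.dosages.copy()
        dos["SNP_1H_00099"] = dos.iloc[:, 0]
        geno = GenotypeMatrix(dos, geno.families)
        y = _qtl_response(geno, [(dos.columns[0], 1.5)], 0.8, seed=9)
        chosen = sbc_forward_selection(geno, y, list(dos.columns))
        pair = {str(dos.columns[0]), "SNP_1H_00099"}
        assert len(pair & set(chosen)) == 1


class TestScanWithCofactors:
    def test_empty_cofactors_equal_simple_regression(self):
        """With no cofactors, per-marker p equals the two-sided t test of
        simple linear regression (direct OLS oracle, 1e-10)."""
        geno, _ = random_genotypes(80, 25, seed=10)
        y = _qtl_response(geno, [(geno.dosages.columns[5], 0.7)], 1.0, seed=11)
        res = scan_with_cofactors(geno, y, [])
        for m in geno.dosages.columns:
            lr = stats.linregress(geno.dosages[m], y)
            assert res.table.loc[m, "p"] == pytest.approx(lr.pvalue, abs=1e-10)
            assert res.table.loc[m, "effect"] == pytest.approx(lr.slope, abs=1e-10)

    def test_sequential_semipartials_sum_to_model_r2(self):
        """Sequential R^2 decomposition identity (1e-10)."""
        geno, _ = random_genotypes(100, 10, seed=12)
        cols = list(geno.dosages.columns[:4])
        y = _qtl_response(geno, [(cols[0], 0.5), (cols[2], 0.4)], 1.0, seed=13)
        sp = sequential_semipartial_r2(geno, y, cols)
        dos = prepare_dosages(geno)
        A = np.column_stack([np.ones(len(y))] + [dos[c] for c in cols])
        yv = y.to_numpy()
        rss = float(((yv - A @ np.linalg.lstsq(A, yv, rcond=None)[0]) ** 2).sum())
        tss = float(((yv - yv.mean()) ** 2).sum())
        assert sp.sum() == pytest.approx(1 - rss / tss, abs=1e-10)

    def test_cofactor_tested_without_itself(self):
        """A marker that is a cofactor is tested with that cofactor dropped
        from its own background, recovering its marginal signal."""
        geno, _ = random_genotypes(120, 10, seed=14)
        m = geno.dosages.columns[2]
        other = geno.dosages.columns[7]
        y = _qtl_response(geno, [(m, 1.0), (other, 0.6)], 1.0, seed=15)
        res = scan_with_cofactors(geno, y, [m, other])
        solo = scan_with_cofactors(geno, y, [other])
        assert res.table.loc[m, "p"] == pytest.approx(solo.table.loc[m, "p"],
                                                      abs=1e-10)

    def test_collinear_cofactor_excluded_from_background(self):
        geno, _ = random_genotypes(120, 6, seed=16)
        dos = geno.dosages.copy()
        dup = "SNP_1H_00042"
        dos[dup] = dos.iloc[:, 0]  # |r| = 1 with marker 0
        geno2 = GenotypeMatrix(dos, geno.families)
        y = _qtl_response(geno2, [(dos.columns[0], 1.0)], 1.0, seed=17)
        res = scan_with_cofactors(geno2, y, [dup])
        marg = scan_with_cofactors(geno2, y, [])
        m0 = dos.columns[0]
        assert res.table.loc[m0, "p"] == pytest.approx(marg.table.loc[m0, "p"],
                                                       abs=1e-10)

    def test_zero_variance_response_rejected(self):
        geno, _ = random_genotypes(40, 5, seed=18)
        y = pd.Series(np.full(40, 2.0), index=geno.dosages.index)
        with pytest.raises(ValueError, match="zero variance"):
            scan_with_cofactors(geno, y, [])


class TestRunGwas:
    def _responses(self, geno, seed):
        y1 = _qtl_response(geno, [(geno.dosages.columns[3], 1.0)], 1.0, seed=seed)
        return pd.DataFrame({"SL_C": y1})

    def test_same_seed_identical_results(self):
        geno, _ = random_genotypes(60, 30, seed=19)
        resp = self._responses(geno, 20)
        cfg = ScanConfig(seed=21, n_subsamples=15)
        r1 = run_gwas(geno, resp, cfg)["SL_C"]
        r2 = run_gwas(geno, resp, cfg)["SL_C"]
        pd.testing.assert_frame_equal(r1.table, r2.table)
        assert r1.cofactors == r2.cofactors

    def test_zero_variance_and_high_missing_traits_skipped(self, caplog):
        geno, _ = random_genotypes(60, 20, seed=22)
        resp = self._responses(geno, 23)
        resp["flat"] = 1.0
        resp["holey"] = resp["SL_C"].where(
            np.arange(len(resp)) % 3 != 0, np.nan)  # 33% missing
        out = run_gwas(geno, resp, ScanConfig(seed=24, n_subsamples=10))
        assert "SL_C" in out
        assert "flat" not in out
        assert "holey" not in out

    def test_allele_effect_sign_convention(self):
        """Positive effect = wild allele (dosage 2) raises the trait."""
        geno, _ = random_genotypes(100, 10, seed=25)
        m = geno.dosages.columns[0]
        up = _qtl_response(geno, [(m, 1.0)], 0.5, seed=26)
        down = _qtl_response(geno, [(m, -1.0)], 0.5, seed=27)
        assert scan_with_cofactors(geno, up, []).table.loc[m, "effect"] > 0
        assert scan_with_cofactors(geno, down, []).table.loc[m, "effect"] < 0
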