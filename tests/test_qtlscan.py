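"""Genotype probabilities, Haley-Knott scans, permutations, support
intervals and QTL reporting."""

import numpy as np
import pandas as pd
import pytest

from rilmap import datasets, genmap, qtlscan, simpop
from rilmap.bincall import BinMatrix
from rilmap.genmap import GeneticMap
from rilmap.qtlscan import ProbGrid, ScanResult
from rilmap.simpop import AA, BB, MISSING


def _manual_map(columns, pos_cm, map_function="haldane"):
    """BinMatrix + GeneticMap with explicit genotypes and cM positions."""
    n_bins = len(pos_cm)
    bins = pd.DataFrame(
        {
            "bin_id": [f"bin{k}" for k in range(n_bins)],
            "chrom": "1",
            "start_bp": np.arange(n_bins) * 1_000_000 + 1,
            "end_bp": (np.arange(n_bins) + 1) * 1_000_000,
        }
    )
    geno = np.array(columns, dtype=np.int8)
    bm = BinMatrix(bins=bins, line_ids=[f"L{i}" for i in range(geno.shape[0])],
                   genotypes=geno)
    table = pd.DataFrame(
        {
            "chrom": "1",
            "bin_id": bins["bin_id"],
            "pos_cm": np.asarray(pos_cm, dtype=float),
            "pos_bp": ((bins["start_bp"] + bins["end_bp"]) // 2).astype(int),
            "start_bp": bins["start_bp"],
            "end_bp": bins["end_bp"],
        }
    )
    return bm, GeneticMap(table=table, map_function=map_function)


class TestGenotypeProbabilities:
    def test_typed_marker_probability_one(self):
        bm, gm = _manual_map([[AA, BB]], [0.0, 10.0])
        grid = qtlscan.genotype_probabilities(bm, gm, step_cm=10.0)
        x = grid.x["1"][0]
        assert x[0] == pytest.approx(-1.0)   # AA marker
        assert x[-1] == pytest.approx(1.0)   # BB marker

    def test_missing_flanks_give_half_half(self):
        bm, gm = _manual_map([[MISSING, MISSING]], [0.0, 10.0])
        grid = qtlscan.genotype_probabilities(bm, gm, step_cm=5.0)
        assert np.allclose(grid.x["1"][0], 0.0)

    def test_interior_matches_chain_enumeration(self):
        # midpoint of a 10 cM interval, one line per flank configuration
        d = 5.0
        r = genmap.inverse_map_distance(d, "haldane")
        R = float(genmap.rf_expected_ril(r))
        bm, gm = _manual_map([[AA, AA], [AA, BB]], [0.0, 10.0])
        grid = qtlscan.genotype_probabilities(bm, gm, step_cm=5.0)
        # enumeration over the hidden genotype of the two-interval chain
        pb_same = (R * R) / (R * R + (1 - R) * (1 - R))          # AA--AA flanks
        pb_cross = (R * (1 - R)) / (R * (1 - R) + (1 - R) * R)   # AA--BB flanks
        assert grid.x["1"][0][1] == pytest.approx(2 * pb_same - 1, abs=1e-12)
        assert grid.x["1"][1][1] == pytest.approx(2 * pb_cross - 1, abs=1e-12)
        assert pb_cross == pytest.approx(0.5)

    def test_position_outside_map_rejected(self):
        bm, gm = _manual_map([[AA, BB]], [0.0, 10.0])
        with pytest.raises(ValueError):
            qtlscan.genotype_probabilities(bm, gm, step_cm=0.0)


def _single_position_grid(x_vec):
    n = len(x_vec)
    return ProbGrid(
        pos_cm={"1": np.array([0.0])},
        pos_bp={"1": np.array([500_000.0])},
        x={"1": np.asarray(x_vec, dtype=float)[:, None]},
        line_ids=[f"L{i}" for i in range(n)],
    )


class TestScan:
    def test_lod_closed_form_r2_half(self):
        # y built so that R^2 = 0.5 exactly with n = 20: LOD = 10 log10 2
        rng = np.random.default_rng(1)
        x = rng.choice([-1.0, 1.0], size=20)
        z = rng.normal(size=20)
        xc = x - x.mean()
        z = z - z.mean()
        z -= (z @ xc) / (xc @ xc) * xc      # orthogonal to x
        z *= np.linalg.norm(xc) / np.linalg.norm(z)
        y = xc + z
        res = qtlscan.scan(_single_position_grid(x), y, method="IM")
        assert res.table["lod"].iloc[0] == pytest.approx(10 * np.log10(2), abs=1e-9)

    def test_matches_ols_regression_lod(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(2)
        x = rng.choice([-1.0, 1.0], size=60)
        y = 3.0 * x + rng.normal(scale=2.0, size=60)
        res = qtlscan.scan(_single_position_grid(x), y, method="IM")
        fit = sm.OLS(y, sm.add_constant(x)).fit()
        null = sm.OLS(y, np.ones_like(y)).fit()
        lod = 60 / 2 * np.log10(null.ssr / fit.ssr)
        assert res.table["lod"].iloc[0] == pytest.approx(lod, abs=1e-9)
        assert res.table["add_effect"].iloc[0] == pytest.approx(fit.params[1], abs=1e-9)

    def test_null_phenotype_low_lod(self, small_bin_map):
        bm, gm = small_bin_map["bin_matrix"], small_bin_map["genetic_map"]
        grid = qtlscan.genotype_probabilities(bm, gm)
        y = np.random.default_rng(3).normal(size=len(bm.line_ids))
        res = qtlscan.scan(grid, y, method="IM")
        assert res.max_lod() < 4.0

    def test_perfect_fit_capped_and_flagged(self):
        x = np.array([-1.0, 1.0] * 10)
        res = qtlscan.scan(_single_position_grid(x), x.copy(), method="IM",
                           lod_ceiling=50.0)
        assert res.table["lod"].iloc[0] == 50.0
        assert any("lod_ceiling" in f for f in res.flags)

    def test_affine_phenotype_invariance(self, small_bin_map, single_qtl_phenotype):
        bm, gm = small_bin_map["bin_matrix"], small_bin_map["genetic_map"]
        grid = qtlscan.genotype_probabilities(bm, gm, step_cm=2.0)
        y = qtlscan.phenotype_vector(single_qtl_phenotype["phenotypes"], bm.line_ids)
        a = qtlscan.scan(grid, y, method="IM")
        b = qtlscan.scan(grid, 3.0 * y + 7.0, method="IM")
        assert np.allclose(a.table["lod"], b.table["lod"], atol=1e-8)

    def test_zero_variance_flagged(self):
        x = np.array([-1.0, 1.0] * 10)
        res = qtlscan.scan(_single_position_grid(x), np.full(20, 5.0), method="IM")
        assert "zero_phenotypic_variance" in res.flags
        assert (res.table["lod"] == 0).all()

    def test_too_few_lines_rejected(self):
        x = np.array([1.0, -1.0, 1.0])
        with pytest.raises(ValueError):
            qtlscan.scan(_single_position_grid(x), np.array([1.0, 2.0, 3.0]))


class TestCIM:
    def test_zero_covariates_equals_im(self, small_bin_map, single_qtl_phenotype):
        bm, gm = small_bin_map["bin_matrix"], small_bin_map["genetic_map"]
        grid = qtlscan.genotype_probabilities(bm, gm, step_cm=2.0)
        y = qtlscan.phenotype_vector(single_qtl_phenotype["phenotypes"], bm.line_ids)
        covs = qtlscan.select_cim_covariates(bm, gm, y, max_cov=0)
        assert covs == []
        im = qtlscan.scan(grid, y, method="IM")
        cim = qtlscan.scan(grid, y, covs, method="CIM")
        assert np.allclose(im.table["lod"], cim.table["lod"])

    def test_selects_marker_near_major_qtl(self, small_bin_map, single_qtl_phenotype):
        # single ~40%-variance QTL at 15 Mb: first covariate lands nearby
        bm, gm = small_bin_map["bin_matrix"], small_bin_map["genetic_map"]
        y = qtlscan.phenotype_vector(single_qtl_phenotype["phenotypes"], bm.line_ids)
        covs = qtlscan.select_cim_covariates(bm, gm, y, max_cov=1)
        assert len(covs) == 1
        row = bm.bins.iloc[covs[0].bin_index]
        mid = (row["start_bp"] + row["end_bp"]) / 2
        assert abs(mid - 15_000_000) < 2_000_000

    def test_covariate_excluded_near_test_position(self, small_bin_map,
                                                   single_qtl_phenotype):
        bm, gm = small_bin_map["bin_matrix"], small_bin_map["genetic_map"]
        grid = qtlscan.genotype_probabilities(bm, gm, step_cm=2.0)
        y = qtlscan.phenotype_vector(single_qtl_phenotype["phenotypes"], bm.line_ids)
        covs = qtlscan.select_cim_covariates(bm, gm, y, max_cov=1)
        cim = qtlscan.scan(grid, y, covs, method="CIM", exclusion_window_cm=10.0)
        im = qtlscan.scan(grid, y, method="IM")
        pos = grid.pos_cm["1"]
        near = np.abs(pos - covs[0].pos_cm) <= 10.0
        # within the window the covariate is dropped: model collapses to IM
        assert np.allclose(cim.table["lod"].to_numpy()[near],
                           im.table["lod"].to_numpy()[near], atol=1e-8)
        far = ~near
        assert not np.allclose(cim.table["lod"].to_numpy()[far],
                               im.table["lod"].to_numpy()[far], atol=1e-6)


class TestPermutations:
    def test_same_seed_same_threshold(self, small_bin_map, single_qtl_phenotype):
        bm, gm = small_bin_map["bin_matrix"], small_bin_map["genetic_map"]
        grid = qtlscan.genotype_probabilities(bm, gm, step_cm=2.0)
        y = qtlscan.phenotype_vector(single_qtl_phenotype["phenotypes"], bm.line_ids)
        t1, m1 = qtlscan.permutation_threshold(grid, y, 150, 0.05, seed=9)
        t2, m2 = qtlscan.permutation_threshold(grid, y, 150, 0.05, seed=9)
        assert t1 == t2 and np.array_equal(m1, m2)

    def test_alpha_monotonicity(self, small_bin_map, single_qtl_phenotype):
        bm, gm = small_bin_map["bin_matrix"], small_bin_map["genetic_map"]
        grid = qtlscan.genotype_probabilities(bm, gm, step_cm=2.0)
        y = qtlscan.phenotype_vector(single_qtl_phenotype["phenotypes"], bm.line_ids)
        t05, _ = qtlscan.permutation_threshold(grid, y, 150, 0.05, seed=10)
        t01, _ = qtlscan.permutation_threshold(grid, y, 150, 0.01, seed=10)
        assert t01 >= t05

    def test_rejects_too_few_permutations(self, small_bin_map):
        with pytest.raises(ValueError):
            qtlscan.permutation_threshold(
                ProbGrid(pos_cm={"1": np.array([0.0])},
                         pos_bp={"1": np.array([1.0])},
                         x={"1": np.zeros((12, 1))},
                         line_ids=[f"L{i}" for i in range(12)]),
                np.arange(12.0), n_perm=10,
            )


def _triangular_scan(peak_lod=6.0, slope=0.5, peak_at=50):
    pos = np.arange(0, 101, dtype=float)
    lod = peak_lod - slope * np.abs(pos - peak_at)
    lod = np.maximum(lod, 0.0)
    table = pd.DataFrame(
        {"chrom": "1", "pos_cm": pos, "pos_bp": pos * 1e5, "lod": lod,
         "add_effect": 1.0}
    )
    return ScanResult(table=table)


class TestSupportInterval:
    def test_triangular_peak_interpolation(self):
        res = _triangular_scan()
        si = qtlscan.support_interval(res, "1", 50.0, drop=1.5)
        assert si["cm_lo"] == pytest.approx(47.0)
        assert si["cm_hi"] == pytest.approx(53.0)
        assert si["mb_lo"] == pytest.approx(4.7)
        assert si["mb_hi"] == pytest.approx(5.3)

    def test_peak_at_chromosome_start(self):
        res = _triangular_scan(peak_at=0)
        si = qtlscan.support_interval(res, "1", 0.0, drop=1.5)
        assert si["cm_lo"] == 0.0
        assert si["cm_hi"] == pytest.approx(3.0)

    def test_flat_curve_flagged_whole_chromosome(self):
        table = pd.DataFrame(
            {"chrom": "1", "pos_cm": np.arange(0, 11, dtype=float),
             "pos_bp": np.arange(0, 11) * 1e6, "lod": 4.0, "add_effect": 0.0}
        )
        si = qtlscan.support_interval(ScanResult(table=table), "1", 5.0)
        assert si["flag"] == "flat"
        assert si["cm_lo"] == 0.0 and si["cm_hi"] == 10.0


class TestReport:
    def test_var_explained_reproduces_published_table(self):
        qtls = datasets.reported_ltg_qtls()
        got = qtlscan.var_explained(qtls["lod"].to_numpy(), 144)
        assert np.all(np.abs(got - qtls["var_pct"].to_numpy()) <= 0.1)

    def test_sign_convention_names_positive_parent(self):
        res = _triangular_scan()
        rep = qtlscan.qtl_report(res, threshold=3.0, n_lines=144)
        assert rep["positive_allele"].iloc[0] == "LTH"
        res.table["add_effect"] = -1.0
        rep = qtlscan.qtl_report(res, threshold=3.0, n_lines=144)
        assert rep["positive_allele"].iloc[0] == "SN265"

    def test_below_threshold_empty(self):
        res = _triangular_scan(peak_lod=2.0)
        rep = qtlscan.qtl_report(res, threshold=3.0, n_lines=144)
        assert len(rep) == 0

    def test_distinct_peaks_split_by_dip(self):
        pos = np.arange(0, 101, dtype=float)
        lod = np.maximum(5 - 0.5 * np.abs(pos - 25), 0) + np.maximum(
            6 - 0.5 * np.abs(pos - 75), 0
        )
        table = pd.DataFrame(
            {"chrom": "7", "pos_cm": pos, "pos_bp": pos * 1e5, "lod": lod,
             "add_effect": 2.0}
        )
        rep = qtlscan.qtl_report(ScanResult(table=table), threshold=4.0, n_lines=144)
        assert list(rep["name"]) == ["qLTG7a", "qLTG7b"]
        assert rep["peak_cm"].tolist() == [25.0, 75.0]

    def test_single_qtl_recovered_with_interval(self, small_bin_map,
                                                single_qtl_phenotype):
        bm, gm = small_bin_map["bin_matrix"], small_bin_map["genetic_map"]
        grid = qtlscan.genotype_probabilities(bm, gm)
        y = qtlscan.phenotype_vector(single_qtl_phenotype["phenotypes"], bm.line_ids)
        res = qtlscan.scan(grid, y, method="IM")
        rep = qtlscan.qtl_report(res, threshold=3.0, n_lines=len(bm.line_ids))
        assert len(rep) >= 1
        top = rep.sort_values("lod", ascending=False).iloc[0]
        assert top["ci_mb_lo"] <= 15.0 <= top["ci_mb_hi"]
        assert top["positive_allele"] == "LTH"
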