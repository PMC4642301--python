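import numpy as np
import pandas as pd
import pytest
from scipy import stats

import rohsurv as rs
from rohsurv.burden_inbreeding import _ols_term_p
from rohsurv.simulate import SimulationConfig, simulate_cohort

from conftest import make_dataset


def burden_frame(n_roh, group, population=None):
    n = len(n_roh)
    return pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(n)],
            "population": population if population is not None else ["p"] * n,
            "group": group,
            "n_roh": n_roh,
            "total_kb": np.asarray(n_roh, float) * 1500.0,
            "mean_kb": np.where(np.asarray(n_roh) > 0, 1500.0, 0.0),
        }
    )


class TestBurdenGroupTests:
    def test_matches_hand_pooled_variance_t(self):
        x = np.array([3.0, 5, 4, 6])      # STS
        y = np.array([1.0, 2, 2, 3, 2])   # LTS
        b = burden_frame(np.r_[x, y], ["STS"] * 4 + ["LTS"] * 5)
        res = rs.burden_group_tests(b, stratify_by_population=False)
        row = res[res["metric"] == "n_roh"].iloc[0]
        nx, ny = len(x), len(y)
        sp2 = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
        t = (x.mean() - y.mean()) / np.sqrt(sp2 * (1 / nx + 1 / ny))
        p = 2 * stats.t.sf(abs(t), nx + ny - 2)
        assert row["t"] == pytest.approx(t, abs=1e-10)
        assert row["p"] == pytest.approx(p, abs=1e-10)
        assert row["mean_STS"] == pytest.approx(x.mean())
        assert row["mean_LTS"] == pytest.approx(y.mean())

    def test_population_strata_reported(self):
        rng = np.random.default_rng(0)
        n_roh = rng.poisson(10, size=40)
        b = burden_frame(
            n_roh, ["STS", "LTS"] * 20, population=["A"] * 20 + ["B"] * 20
        )
        res = rs.burden_group_tests(b)
        assert set(res["stratum"]) == {"all", "A", "B"}
        assert len(res) == 9  # 3 strata x 3 metrics

    def test_single_group_stratum_skipped(self):
        b = burden_frame([1, 2, 3, 4, 5, 6],
                         ["STS", "STS", "STS", "STS", "LTS", "LTS"],
                         population=["A", "A", "A", "A", "B", "B"])
        res = rs.burden_group_tests(b)
        assert set(res["stratum"]) == {"all"}


class TestGlmBurden:
    def make_confounded(self, beta_group, seed=0, n=200):
        """Population drives burden and is correlated with group."""
        rng = np.random.default_rng(seed)
        pop = np.array(["A"] * (n // 2) + ["B"] * (n // 2))
        # group composition differs by population: A mostly STS, B mostly LTS
        group = np.where(
            rng.random(n) < np.where(pop == "A", 0.8, 0.2), "STS", "LTS"
        )
        pop_effect = np.where(pop == "A", 4.0, 10.0)
        y = pop_effect + beta_group * (group == "LTS") + rng.normal(0, 1.0, n)
        return y, group, pop

    def test_null_group_effect_not_confounded(self):
        y, group, pop = self.make_confounded(0.0, seed=1)
        # unadjusted comparison is badly confounded by population ...
        x = y[group == "STS"]
        z = y[group == "LTS"]
        _, p_naive = stats.ttest_ind(x, z)
        assert p_naive < 1e-6
        # ... while the population-adjusted GLM coefficient is near zero
        res = rs.glm_burden(y, group, pop)
        assert abs(res["coef_group"]) < 3 * res["se_group"]

    def test_recovers_true_group_effect(self):
        est = []
        for seed in range(5):
            y, group, pop = self.make_confounded(1.5, seed=10 + seed)
            est.append(rs.glm_burden(y, group, pop)["coef_group"])
        assert np.mean(est) == pytest.approx(1.5, abs=0.3)

    def test_poisson_family_detects_effect(self):
        rng = np.random.default_rng(4)
        group = np.array(["STS", "LTS"] * 100)
        y = rng.poisson(np.where(group == "LTS", 12, 8))
        res = rs.glm_burden(y, group, ["p"] * 200, family="poisson")
        assert res["p_group"] < 1e-4
        assert res["coef_group"] > 0  # log rate ratio

    def test_gaussian_matches_ols_coefficients(self):
        rng = np.random.default_rng(5)
        y = rng.normal(size=60)
        group = ["STS", "LTS"] * 30
        pop = ["A", "B", "C"] * 20
        res = rs.glm_burden(y, group, pop)
        from rohsurv.burden_inbreeding import _design

        x_cov, g01 = _design(group, pop)
        x = np.column_stack([x_cov, g01])
        beta, *_ = np.linalg.lstsq(x, y, rcond=None)
        assert res["coef_group"] == pytest.approx(beta[-1], abs=1e-10)
        # the GLM Wald p is z-based; check it against the reported coef/se
        z = res["coef_group"] / res["se_group"]
        assert res["p_group"] == pytest.approx(2 * stats.norm.sf(abs(z)), abs=1e-10)


class TestPermutationTest:
    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(7)
        y = rng.normal(size=80)
        group = ["STS", "LTS"] * 40
        pop = ["A"] * 40 + ["B"] * 40
        p1 = rs.permutation_regressor_residuals(y, group, pop, n_perm=300, seed=5)
        p2 = rs.permutation_regressor_residuals(y, group, pop, n_perm=300, seed=5)
        assert p1 == p2

    def test_strong_effect_hits_floor(self):
        rng = np.random.default_rng(8)
        group = np.array(["STS", "LTS"] * 50)
        y = 5.0 * (group == "LTS") + rng.normal(0, 0.1, 100)
        p = rs.permutation_regressor_residuals(y, group, ["p"] * 100,
                                               n_perm=500, seed=1)
        assert p == pytest.approx(1 / 501)

    def test_null_calibrated_on_average(self):
        # a single dataset can show a chance group difference, so calibration
        # is checked as the mean permutation p over independent null datasets
        ps = []
        for dseed in range(20):
            rng = np.random.default_rng(100 + dseed)
            y = rng.normal(size=100)
            ps.append(rs.permutation_regressor_residuals(
                y, ["STS", "LTS"] * 50, ["A"] * 50 + ["B"] * 50,
                n_perm=300, seed=1,
            ))
        assert 0.35 < np.mean(ps) < 0.65

    def test_collinear_group_rejected(self):
        with pytest.raises(ValueError, match="collinear"):
            rs.permutation_regressor_residuals(
                [1.0, 2, 3, 4], ["STS", "STS", "LTS", "LTS"],
                ["A", "A", "B", "B"], n_perm=100
            )

    def test_poisson_path_runs(self):
        rng = np.random.default_rng(10)
        group = np.array(["STS", "LTS"] * 30)
        y = rng.poisson(np.where(group == "LTS", 14, 6))
        p = rs.permutation_regressor_residuals(y, group, ["p"] * 60,
                                               family="poisson",
                                               n_perm=200, seed=3)
        assert p < 0.05


class TestInbreedingCoeffs:
    def test_fully_homozygous_sample_f2_is_one(self):
        rng = np.random.default_rng(1)
        codes = rng.choice([0, 1, 2], size=(12, 50), p=[0.25, 0.5, 0.25])
        codes[0] = rng.choice([0, 2], size=50)
        ds = make_dataset(codes)
        f = rs.inbreeding_coeffs(ds)
        assert f.loc[0, "F_II"] == pytest.approx(1.0, abs=1e-12)

    def test_exact_hwe_population_means_zero(self):
        # each SNP carries exactly HWE genotype counts at p = 0.5
        # (5 hom-ref, 10 het, 5 hom-alt among 20 samples), so the population
        # means of F_I, F_II and F_III are exactly zero
        rng = np.random.default_rng(2)
        cols = [rng.permutation([0] * 5 + [1] * 10 + [2] * 5) for _ in range(200)]
        ds = make_dataset(np.column_stack(cols))
        f = rs.inbreeding_coeffs(ds)
        for col in ("F_I", "F_II", "F_III"):
            assert f[col].mean() == pytest.approx(0.0, abs=1e-12)

    def test_recovers_simulated_inbreeding(self):
        cfg = SimulationConfig(
            pop_sizes={"P": (150, 150)}, m_variants=6000,
            chrom_lengths={"1": 72_000_000}, fst=0.0,
            inbreeding_f=0.05, roh_rate=(0, 0), missing_rate=0.0, seed=13,
        )
        ds, _ = simulate_cohort(cfg)
        f = rs.inbreeding_coeffs(ds)
        for col in ("F_I", "F_II", "F_III"):
            assert f[col].mean() == pytest.approx(0.05, abs=0.015)

    def test_per_chromosome_scopes(self, small_cohort):
        ds, _ = small_cohort
        f = rs.inbreeding_coeffs(ds, per_chromosome=True)
        assert set(f["scope"]) == {"genome", "1", "2"}
        genome = f[f["scope"] == "genome"]
        assert len(genome) == ds.n_samples

    def test_missing_genotypes_excluded(self):
        rng = np.random.default_rng(3)
        codes = rng.choice([0, 1, 2], size=(20, 100), p=[0.25, 0.5, 0.25])
        ds_full = make_dataset(codes.copy())
        freqs = codes.mean(axis=0) / 2.0
        codes_miss = codes.copy()
        codes_miss[5, 40:60] = -1
        ds_miss = make_dataset(codes_miss)
        f = rs.inbreeding_coeffs(ds_miss, allele_freqs=freqs)
        # hand recount for sample 5 over its observed SNPs
        obs = codes[5].astype(float).copy()
        mask = np.ones(100, bool)
        mask[40:60] = False
        h = 2 * freqs * (1 - freqs)
        f2_hand = np.mean(1 - obs[mask] * (2 - obs[mask]) / h[mask])
        assert f.loc[5, "F_II"] == pytest.approx(f2_hand, abs=1e-12)


class TestFRoh:
    def seg(self, rows):
        return pd.DataFrame(rows, columns=["sample_id", "chrom", "start_bp",
                                           "end_bp", "n_snps", "length_kb"])

    def samples(self, ids):
        return pd.DataFrame({"sample_id": ids, "population": "p", "group": "STS"})

    def test_simple_ratio(self):
        seg = self.seg([("a", "1", 1, 2_000_000, 100, 2000.0)])
        f = rs.f_roh(seg, self.samples(["a", "b"]), l_auto=10_000_000)
        f = f.set_index("sample_id")
        assert f.loc["a", "F_ROH"] == pytest.approx(0.2)
        assert f.loc["b", "F_ROH"] == 0.0

    def test_short_segments_excluded(self):
        seg = self.seg([("a", "1", 1, 900_000, 80, 900.0)])
        f = rs.f_roh(seg, self.samples(["a"]), l_auto=10_000_000)
        assert f["F_ROH"].iloc[0] == 0.0

    def test_centromere_overlap_trimmed(self):
        seg = self.seg([("a", "1", 1_000_000, 3_000_000, 150, 2000.0)])
        cent = pd.DataFrame(
            {"chrom": ["1"], "start_bp": [2_000_000], "end_bp": [2_499_999]}
        )
        f = rs.f_roh(seg, self.samples(["a"]), l_auto=10_000_000, centromeres=cent)
        # 2000001 bp minus the 500000 bp centromere overlap
        assert f["F_ROH"].iloc[0] == pytest.approx(1_500_001 / 10_000_000)

    def test_per_chromosome_columns(self):
        seg = self.seg([
            ("a", "1", 1, 1_000_000, 80, 1000.0),
            ("a", "2", 1, 2_000_000, 90, 2000.0),
        ])
        f = rs.f_roh(seg, self.samples(["a"]), l_auto=20_000_000,
                     per_chromosome={"1": 10_000_000, "2": 10_000_000})
        assert f["F_ROH_1"].iloc[0] == pytest.approx(0.1)
        assert f["F_ROH_2"].iloc[0] == pytest.approx(0.2)

    def test_invalid_l_auto(self):
        with pytest.raises(ValueError):
            rs.f_roh(self.seg([]), self.samples(["a"]), l_auto=0)


class TestConsanguinityCorrelations:
    def fixtures(self, n_roh, f2, froh_vals):
        n = len(n_roh)
        ids = [f"s{i}" for i in range(n)]
        burden = pd.DataFrame(
            {"sample_id": ids, "population": "p", "group": "STS",
             "n_roh": n_roh, "total_kb": np.asarray(n_roh, float) * 1000.0,
             "mean_kb": 1000.0}
        )
        inb = pd.DataFrame({"sample_id": ids, "scope": "genome",
                            "F_I": f2, "F_II": f2, "F_III": f2})
        froh = pd.DataFrame({"sample_id": ids, "F_ROH": froh_vals})
        return burden, inb, froh

    def test_proportional_measures_r_one(self):
        n_roh = np.array([1.0, 2, 3, 4, 5])
        r, p = rs.consanguinity_correlations(*self.fixtures(n_roh, n_roh / 100,
                                                            n_roh / 50))
        assert np.allclose(r.to_numpy(dtype=float), 1.0)

    def test_five_sample_hand_oracle(self):
        n_roh = np.array([2.0, 5, 3, 8, 4])
        f2 = np.array([0.01, 0.03, 0.015, 0.05, 0.02])
        froh = np.array([0.002, 0.004, 0.001, 0.006, 0.003])
        r, p = rs.consanguinity_correlations(*self.fixtures(n_roh, f2, froh))
        x, y = n_roh, f2
        r_hand = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
            np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
        )
        t = r_hand * np.sqrt(3 / (1 - r_hand**2))
        p_hand = 2 * stats.t.sf(abs(t), 3)
        assert r.loc["n_roh", "F_II"] == pytest.approx(r_hand, abs=1e-10)
        assert p.loc["n_roh", "F_II"] == pytest.approx(p_hand, abs=1e-10)

    def test_independent_measures_low_r(self):
        rng = np.random.default_rng(6)
        n = 500
        r, p = rs.consanguinity_correlations(
            *self.fixtures(rng.poisson(10, n), rng.normal(0, 0.01, n),
                           rng.uniform(0, 0.01, n))
        )
        assert abs(r.loc["n_roh", "F_II"]) < 0.2
        assert abs(r.loc["F_II", "F_ROH"]) < 0.2

    def test_extreme_outlier_excluded(self):
        n_roh = np.array([3.0, 4, 5, 4, 3, 4, 5, 3, 4, 1000.0])
        f2 = np.linspace(0.01, 0.05, 10)
        r_with, _ = rs.consanguinity_correlations(
            *self.fixtures(n_roh, f2, f2 / 5), outlier_sd=1e9
        )
        r_wo, _ = rs.consanguinity_correlations(
            *self.fixtures(n_roh, f2, f2 / 5), outlier_sd=2.0
        )
        r_all = stats.pearsonr(n_roh, f2).statistic
        r_kept = stats.pearsonr(n_roh[:9], f2[:9]).statistic
        assert r_with.loc["n_roh", "F_II"] == pytest.approx(r_all, abs=1e-10)
        assert r_wo.loc["n_roh", "F_II"] == pytest.approx(r_kept, abs=1e-10)
        assert r_all != pytest.approx(r_kept, abs=0.01)


class TestInbreedingGroupTests:
    def test_regression_p_is_twosided_t(self):
        rng = np.random.default_rng(8)
        ids = [f"s{i}" for i in range(40)]
        groups = ["STS", "LTS"] * 20
        measures = pd.DataFrame(
            {"sample_id": ids, "F_II": rng.normal(0.01, 0.005, 40)}
        )
        samples = pd.DataFrame({"sample_id": ids, "population": "p", "group": groups})
        res = rs.inbreeding_group_tests(measures, samples, columns=("F_II",))
        row = res.iloc[0]
        # the OLS group-indicator p equals the two-sided pooled t p
        p_two = 2 * min(row["p_t"], 1 - row["p_t"])
        assert row["p_glm"] == pytest.approx(p_two, abs=1e-8)

    def test_detects_direction(self):
        rng = np.random.default_rng(9)
        ids = [f"s{i}" for i in range(60)]
        groups = np.array(["STS", "LTS"] * 30)
        vals = np.where(groups == "LTS", 0.03, 0.01) + rng.normal(0, 0.005, 60)
        measures = pd.DataFrame({"sample_id": ids, "F_ROH": vals})
        samples = pd.DataFrame({"sample_id": ids, "population": "p", "group": groups})
        res = rs.inbreeding_group_tests(measures, samples, columns=("F_ROH",))
        assert res.iloc[0]["p_t"] < 1e-6  # H1: STS < LTS holds
        assert res.iloc[0]["coef_glm"] > 0
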