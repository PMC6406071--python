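"""TMM/CPM normalization, trimmed statistics, fold changes, correlations."""

import math
import statistics

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import rgscore as rg
from conftest import make_dataset

# frozen from an independent run of Bioconductor edgeR calcNormFactors
# (method="TMM") on the same matrices
EDGER_FACTORS_TOY = (1.73205080757, 0.57735026919)
EDGER_FACTORS_COMPOSITION = (1.174165114, 0.851668976)


class TestTMM:
    def test_identical_columns_unit_factors(self):
        counts = pd.DataFrame({"A": [10, 20, 30.0], "B": [10, 20, 30.0]})
        f, _ = rg.tmm_normalize(counts)
        assert np.allclose(f, 1.0)

    def test_pure_depth_difference_absorbed(self):
        counts = pd.DataFrame({"A": [10, 20, 30.0], "B": [20, 40, 60.0]})
        f, cpm = rg.tmm_normalize(counts)
        assert np.allclose(f, 1.0)
        assert np.allclose(cpm["A"], cpm["B"])

    def test_toy_matrix_matches_edger(self, toy_counts):
        f, _ = rg.tmm_normalize(toy_counts)
        assert f["A"] == pytest.approx(EDGER_FACTORS_TOY[0], rel=1e-9)
        assert f["B"] == pytest.approx(EDGER_FACTORS_TOY[1], rel=1e-9)

    def test_composition_shift_matches_edger(self):
        rng = np.random.default_rng(0)
        base = rng.integers(500, 5000, size=50).astype(float)
        up = base.copy()
        up[:8] *= 4
        counts = pd.DataFrame({"A": base, "B": up},
                              index=[f"g{i}" for i in range(50)])
        f, cpm = rg.tmm_normalize(counts)
        assert f["A"] == pytest.approx(EDGER_FACTORS_COMPOSITION[0], rel=1e-8)
        assert f["B"] == pytest.approx(EDGER_FACTORS_COMPOSITION[1], rel=1e-8)
        # non-shifted genes end up on identical CPM
        assert np.allclose(cpm.iloc[8:]["A"], cpm.iloc[8:]["B"])

    def test_factors_have_unit_geometric_mean(self, toy_counts):
        f, _ = rg.tmm_normalize(toy_counts)
        assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0, rel=1e-12)

    def test_all_zero_gene_kept_as_zero_cpm(self):
        counts = pd.DataFrame({"A": [0, 10, 30.0], "B": [0, 12, 28.0]})
        f, cpm = rg.tmm_normalize(counts)
        assert (cpm.iloc[0] == 0).all()
        assert np.isfinite(f).all()

    def test_rejects_empty_library(self):
        with pytest.raises(ValueError):
            rg.tmm_normalize(pd.DataFrame({"A": [1.0, 2.0], "B": [0.0, 0.0]}))


def oracle_trim(values, lo, hi):
    """Independent sort-and-slice reference for the trim convention."""
    v = sorted(values)
    n = len(v)
    kept = []
    for i, x in enumerate(v, start=1):
        frac = (i - 0.5) / n
        if frac >= lo / 100 and (frac <= 1.0 if hi == 100 else frac < hi / 100):
            kept.append(x)
    return kept


class TestTrimmedStat:
    def test_one_to_ten_10_90_mean(self):
        assert rg.trimmed_stat(range(1, 11), 10, 90, "mean") == pytest.approx(5.5)

    def test_constant_vector(self):
        assert rg.trimmed_stat([4.2] * 9, 10, 90, "mean") == 4.2
        assert rg.trimmed_stat([4.2] * 9, 10, 90, "stdev") == 0.0

    def test_no_trimming_is_plain_stat(self):
        vals = [3.0, 1.0, 4.0, 1.0, 5.0, 9.0]
        assert rg.trimmed_stat(vals, 0, 100, "mean") == pytest.approx(statistics.mean(vals))
        assert rg.trimmed_stat(vals, 0, 100, "stdev") == pytest.approx(statistics.stdev(vals))

    def test_errors(self):
        with pytest.raises(ValueError):
            rg.trimmed_stat([], 10, 90)
        with pytest.raises(ValueError):
            rg.trimmed_stat([1, 2, 3], 90, 10)
        with pytest.raises(ValueError):
            rg.trimmed_stat([1.0], 0, 100, "stdev")

    @settings(derandomize=True, max_examples=150)
    @given(
        values=st.lists(st.floats(-1e6, 1e6), min_size=2, max_size=1000),
        bounds=st.sampled_from([(10, 90), (0, 10), (90, 100), (0, 100), (25, 75)]),
    )
    def test_matches_sort_and_slice_oracle(self, values, bounds):
        lo, hi = bounds
        kept = oracle_trim(values, lo, hi)
        if not kept:
            return  # fallback convention covered separately
        assert rg.trimmed_stat(values, lo, hi, "mean") == pytest.approx(
            statistics.fmean(kept), rel=1e-9, abs=1e-9)
        if len(kept) >= 2:
            assert rg.trimmed_stat(values, lo, hi, "stdev") == pytest.approx(
                statistics.stdev(kept), rel=1e-9, abs=1e-9)

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(0, 1e3), min_size=10, max_size=200),
           st.floats(1e6, 1e9))
    def test_single_outlier_magnitude_ignored(self, values, outlier):
        """The 10-90 trim depends on an extreme value only through its rank."""
        a = rg.trimmed_stat(values + [outlier], 10, 90, "mean")
        b = rg.trimmed_stat(values + [outlier * 2], 10, 90, "mean")
        assert a == b


class TestFoldChanges:
    def _cpm(self, tumor_rows, normal_rows, genes=("g1",)):
        t_cols = {f"T{i}": [r[i] for r in tumor_rows] for i in range(len(tumor_rows[0]))}
        n_cols = {f"N{i}": [r[i] for r in normal_rows] for i in range(len(normal_rows[0]))}
        return pd.DataFrame({**t_cols, **n_cols}, index=list(genes))

    def test_identical_pools_zero(self):
        cpm = self._cpm([[100.0] * 6], [[100.0] * 6])
        fc = rg.pooled_log2fc(cpm, [f"T{i}" for i in range(6)],
                              [f"N{i}" for i in range(6)])
        assert fc["g1"] == 0.0

    def test_exact_doubling_is_one(self):
        cpm = self._cpm([[200.0, 400, 600, 800]], [[100.0, 200, 300, 400]])
        fc = rg.pooled_log2fc(cpm, [f"T{i}" for i in range(4)],
                              [f"N{i}" for i in range(4)], eps=0.0)
        assert fc["g1"] == pytest.approx(1.0, rel=1e-12)

    def test_pool_swap_flips_sign(self):
        cpm = self._cpm([[220.0, 230, 250]], [[100.0, 105, 111]])
        t, n = [f"T{i}" for i in range(3)], [f"N{i}" for i in range(3)]
        assert rg.pooled_log2fc(cpm, t, n)["g1"] == pytest.approx(
            -rg.pooled_log2fc(cpm, n, t)["g1"])

    def test_zero_pool_without_pseudocount_errors(self):
        cpm = self._cpm([[0.0, 0, 0]], [[10.0, 10, 10]])
        with pytest.raises(ValueError, match="pseudocount"):
            rg.pooled_log2fc(cpm, [f"T{i}" for i in range(3)],
                             [f"N{i}" for i in range(3)], eps=0.0)

    def test_paired_equal_cpm_zero_and_label_reversal(self):
        cpm = pd.DataFrame({"T0": [100.0], "N0": [100.0], "T1": [300.0],
                            "N1": [150.0]}, index=["g1"])
        fc = rg.paired_log2fc(cpm, [("T0", "N0"), ("T1", "N1")], eps=0.0)
        assert fc.iloc[0, 0] == 0.0
        rev = rg.paired_log2fc(cpm, [("N0", "T0"), ("N1", "T1")], eps=0.0)
        assert np.allclose(rev.to_numpy(), -fc.to_numpy())

    def test_missing_pair_sample_named(self):
        cpm = pd.DataFrame({"T0": [1.0], "N0": [1.0]}, index=["g1"])
        with pytest.raises(ValueError, match="NOPE"):
            rg.paired_log2fc(cpm, [("T0", "NOPE")])

    def test_decile_means_of_paired_ratios(self):
        """10 pairs, nine with ratio 1 and one with ratio 8."""
        cols = {}
        for i in range(10):
            cols[f"T{i}"] = [800.0 if i == 9 else 100.0]
            cols[f"N{i}"] = [100.0]
        cpm = pd.DataFrame(cols, index=["g1"])
        fc = rg.paired_log2fc(cpm, [(f"T{i}", f"N{i}") for i in range(10)],
                              eps=0.0).iloc[0].to_numpy()
        assert rg.trimmed_stat(fc, 90, 100, "mean") == pytest.approx(3.0)
        assert rg.trimmed_stat(fc, 10, 90, "mean") == pytest.approx(0.0)


class TestPoolStability:
    def test_constant_pool(self):
        cpm = pd.DataFrame({f"S{i}": [256.0] for i in range(12)}, index=["g1"])
        st_ = rg.pool_stability(cpm)
        assert st_.loc["g1", "relsd"] == 0.0
        assert st_.loc["g1", "outlier_hi"] == 0.0
        assert st_.loc["g1", "outlier_lo"] == 0.0
        assert st_.loc["g1", "inv_log2_cpm"] == pytest.approx(0.125)

    def test_scale_invariance(self):
        rng = np.random.default_rng(5)
        row = rng.uniform(50, 150, 20)
        a = rg.pool_stability(pd.DataFrame([row]), eps=0.0)
        b = rg.pool_stability(pd.DataFrame([row * 37.0]), eps=0.0)
        for col in ("relsd", "outlier_hi", "outlier_lo"):
            assert a.iloc[0][col] == pytest.approx(b.iloc[0][col], rel=1e-9)

    def test_top_decile_outlier(self):
        row = [100.0] * 9 + [800.0]
        st_ = rg.pool_stability(pd.DataFrame([row], index=["g1"]), eps=0.0)
        assert st_.loc["g1", "outlier_hi"] == pytest.approx(3.0)

    def test_low_expression_sentinel(self):
        cpm = pd.DataFrame({f"S{i}": [0.5] for i in range(12)}, index=["g1"])
        st_ = rg.pool_stability(cpm, min_cpm=2.0)
        assert math.isinf(st_.loc["g1", "inv_log2_cpm"])


class TestClinicalCorrelations:
    def test_perfect_monotone_with_stage(self):
        clin = pd.DataFrame(
            {"pathologic_stage": ["Stage I", "Stage II", "Stage III", "Stage IV"]},
            index=[f"P{i}" for i in range(4)],
        )
        for col in ("pathologic_t", "pathologic_n", "pathologic_m",
                    "neoplasm_cancer_status", "treatment_success"):
            clin[col] = ""
        enc = rg.encode_clinical(clin)
        out = rg.clinical_correlations(
            {"tumor_cpm": (np.array([1.0, 2, 3, 4]), list(clin.index))}, enc,
            characteristics=["pathologic_stage"],
        )
        r, p = out[("tumor_cpm", "pathologic_stage")]
        assert r == pytest.approx(1.0)

    def test_too_few_or_constant_is_neutral(self):
        clin = pd.DataFrame(
            {
                "pathologic_t": ["T2", "T2", "T2", "T2"],
                "pathologic_n": ["N0", "N1", "", ""],
            },
            index=[f"P{i}" for i in range(4)],
        )
        for col in ("pathologic_m", "pathologic_stage",
                    "neoplasm_cancer_status", "treatment_success"):
            clin[col] = ""
        enc = rg.encode_clinical(clin)
        out = rg.clinical_correlations(
            {"tumor_cpm": (np.array([1.0, 2, 3, 4]), list(clin.index))}, enc,
            characteristics=["pathologic_t", "pathologic_n", "pathologic_m"],
        )
        assert out[("tumor_cpm", "pathologic_t")] == (0.0, 1.0)  # constant level
        assert out[("tumor_cpm", "pathologic_n")] == (0.0, 1.0)  # n < 3
        assert out[("tumor_cpm", "pathologic_m")] == (0.0, 1.0)  # all missing

    def test_null_correlations_stay_small(self):
        """Independent expression vs shuffled stage: |r_s| < 0.15 in >=95/100."""
        rng = np.random.default_rng(42)
        n = 200
        small = 0
        for _ in range(100):
            x = rng.normal(size=n)
            y = rng.integers(1, 5, size=n).astype(float)
            from scipy.stats import spearmanr
            r = spearmanr(x, y).statistic
            small += abs(r) < 0.15
        assert small >= 95

    def test_encoding_rules(self):
        clin = pd.DataFrame(
            {
                "pathologic_t": ["T2a", "TX", "Tis", ""],
                "pathologic_n": ["N1", "NX", "N0", "N2a"],
                "pathologic_m": ["M0", "MX", "M1", ""],
                "pathologic_stage": ["Stage IIIA", "Stage I", "Stage IV", "Stage IIB"],
                "neoplasm_cancer_status": ["tumor free", "with tumor", "", "WITH TUMOR"],
                "treatment_success": ["complete remission", "progressive disease",
                                      "stable disease", ""],
            },
            index=["a", "b", "c", "d"],
        )
        enc = rg.encode_clinical(clin)
        assert enc["pathologic_t"].tolist()[:1] == [2.0]
        assert np.isnan(enc["pathologic_t"].iloc[1]) and np.isnan(enc["pathologic_t"].iloc[2])
        assert enc["pathologic_stage"].tolist() == [3.0, 1.0, 4.0, 2.0]
        assert enc["neoplasm_cancer_status"].tolist()[:2] == [0.0, 1.0]
        assert enc["neoplasm_cancer_status"].iloc[3] == 1.0
        assert enc["treatment_success"].tolist()[:3] == [0.0, 3.0, 2.0]


class TestExtractFeatures:
    def test_stable_gene_features_near_zero(self):
        rows = {
            "stable": ([1000.0] * 10, [1000.0] * 10),
            "fill1": ([500.0] * 10, [500.0] * 10),
            "fill2": ([2000.0] * 10, [2000.0] * 10),
        }
        ds = make_dataset(rows)
        feats = rg.extract_features(ds)["stable"]
        assert feats.log2fc_p == pytest.approx(0.0, abs=1e-9)
        assert feats.avg_log2fc_l_10_90 == pytest.approx(0.0, abs=1e-9)
        assert feats.relsd_tumor == pytest.approx(0.0, abs=1e-9)
        assert feats.outlier_hi_tumor == pytest.approx(0.0, abs=1e-9)

    def test_two_fold_gene(self):
        rows = {
            "up2x": ([2000.0] * 10, [1000.0] * 10),
            "fill1": ([500.0] * 10, [500.0] * 10),
            "fill2": ([800.0] * 10, [800.0] * 10),
            "fill3": ([1200.0] * 10, [1200.0] * 10),
        }
        ds = make_dataset(rows)
        feats = rg.extract_features(ds)["up2x"]
        assert feats.log2fc_p == pytest.approx(1.0, abs=0.01)
        assert feats.avg_log2fc_l_10_90 == pytest.approx(1.0, abs=0.01)

    def test_x_values_cover_registry(self):
        rows = {f"g{i}": ([100.0 + i] * 10, [100.0 + i] * 10) for i in range(5)}
        ds = make_dataset(rows)
        feats = rg.extract_features(ds)
        registry_labels = {i.instance_label for i in rg.build_component_registry()}
        for f in feats.values():
            assert set(f.x_values()) == registry_labels
            assert len(f.x_values()) == 48

    def test_low_expression_gene_flagged(self):
        rows = {
            "low": ([0.5] * 10, [0.5] * 10),
            "hi1": ([5e6] * 10, [5e6] * 10),
            "hi2": ([3e6] * 10, [3e6] * 10),
        }
        ds = make_dataset(rows)
        feats = rg.extract_features(ds)["low"]
        assert "low_expression" in feats.flags
        assert math.isinf(feats.inv_log2_cpm)


class TestDatasetInvariances:
    def _features_frame(self, ds):
        feats = rg.extract_features(ds)
        return pd.DataFrame({g: f.x_values() for g, f in sorted(feats.items())})

    def test_sample_permutation_invariance(self, small_panel_data):
        _, data = small_panel_data
        ds1 = data.to_expression_dataset()
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(data.samples))
        counts_p = data.counts.iloc[:, perm]
        samples_p = data.samples.iloc[perm]
        ds2 = rg.ExpressionDataset.from_tables(counts_p, samples_p, data.clinical)
        f1, f2 = self._features_frame(ds1), self._features_frame(ds2)
        assert np.allclose(f1.to_numpy(), f2.to_numpy(), rtol=1e-9, atol=1e-9)

    def test_uniform_count_scaling_invariance(self, small_panel_data):
        _, data = small_panel_data
        ds1 = data.to_expression_dataset()
        ds2 = rg.ExpressionDataset.from_tables(
            data.counts * 3, data.samples, data.clinical)
        f1, f2 = self._features_frame(ds1), self._features_frame(ds2)
        assert np.allclose(f1.to_numpy(), f2.to_numpy(), rtol=1e-9, atol=1e-9)
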