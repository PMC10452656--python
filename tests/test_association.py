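import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import epiburden as eb
from epiburden.matrix import M_SCALE, MethylationMatrix

from conftest import bh_brute_force


def scores_from_grid(values: dict, region="TSS1500", direction="hyper"):
    rows = []
    for gene, per_sample in values.items():
        for sample, w in per_sample.items():
            if w:
                rows.append({"sample": sample, "gene": gene, "region": region,
                             "direction": direction, "wsems": w})
    return pd.DataFrame(rows, columns=["sample", "gene", "region", "direction", "wsems"])


def covariates(groups: dict, **extra):
    df = pd.DataFrame({"group": pd.Series(groups)})
    for k, v in extra.items():
        df[k] = pd.Series(v)
    return df


class TestQuantileRegression:
    def test_identical_groups_give_zero_coefficient(self):
        samples = [f"S{i}" for i in range(40)]
        grp = {s: ("positive" if i < 20 else "negative") for i, s in enumerate(samples)}
        vals = {s: 3 for s in samples}
        res = eb.quantile_regression_median(
            scores_from_grid({"G": vals}), covariates(grp), "hyper", "TSS1500", n_boot=50
        )
        assert res.iloc[0]["beta_group"] == pytest.approx(0.0, abs=1e-9)

    def test_recovers_median_shift(self):
        samples = [f"S{i}" for i in range(100)]
        grp = {s: ("positive" if i < 50 else "negative") for i, s in enumerate(samples)}
        vals = {s: (5 if i < 50 else 0) for i, s in enumerate(samples)}
        res = eb.quantile_regression_median(
            scores_from_grid({"G": vals}), covariates(grp), "hyper", "TSS1500", n_boot=50
        )
        assert res.iloc[0]["beta_group"] == pytest.approx(5.0, abs=1e-9)

    def test_sign_convention_swaps_with_labels(self):
        rng = np.random.default_rng(0)
        samples = [f"S{i}" for i in range(60)]
        grp = {s: ("positive" if i % 3 else "negative") for i, s in enumerate(samples)}
        flipped = {s: ("negative" if g == "positive" else "positive") for s, g in grp.items()}
        vals = {s: int(rng.integers(0, 6)) for s in samples}
        scores = scores_from_grid({"G": vals})
        a = eb.quantile_regression_median(scores, covariates(grp), "hyper", "TSS1500", n_boot=20)
        b = eb.quantile_regression_median(scores, covariates(flipped), "hyper", "TSS1500", n_boot=20)
        assert a.iloc[0]["beta_group"] == pytest.approx(-b.iloc[0]["beta_group"], abs=1e-8)

    def test_unknown_samples_rejected(self):
        scores = scores_from_grid({"G": {"S0": 1}})
        with pytest.raises(ValueError, match="missing from the covariate"):
            eb.quantile_regression_median(scores, covariates({"S1": "positive", "S2": "negative"}),
                                          "hyper", "TSS1500")

    def test_single_group_rejected(self):
        scores = scores_from_grid({"G": {"S0": 1, "S1": 2}})
        with pytest.raises(ValueError, match="one group"):
            eb.quantile_regression_median(
                scores, covariates({"S0": "positive", "S1": "positive"}), "hyper", "TSS1500"
            )

    def test_untestable_genes_reported_not_tested(self):
        samples = {f"S{i}": ("positive" if i % 2 else "negative") for i in range(10)}
        scores = scores_from_grid({"G1": {"S1": 2}})
        res = eb.quantile_regression_median(
            scores, covariates(samples), "hyper", "TSS1500", n_boot=20, genes=["G1", "G2"]
        )
        row = res.set_index("gene").loc["G2"]
        assert row["n_nonzero"] == 0 and np.isnan(row["p"])


class TestBHAdjust:
    def test_textbook_example(self):
        np.testing.assert_allclose(eb.bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_degenerate_cases(self):
        assert eb.bh_adjust([0.2]).tolist() == [0.2]
        assert eb.bh_adjust([1.0, 1.0, 1.0]).tolist() == [1.0] * 3

    def test_rejects_invalid(self):
        with pytest.raises(ValueError):
            eb.bh_adjust([0.5, 1.5])

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=40))
    @settings(max_examples=100, deadline=None)
    def test_matches_brute_force(self, p):
        p = np.asarray(p)
        np.testing.assert_allclose(eb.bh_adjust(p), bh_brute_force(p), atol=1e-12)


class TestSummarizeCohort:
    def her2_table(self):
        """HER2 status against receptor group in a 521-sample cohort."""
        groups, factor = [], []
        for grp, und, neg, pos in [("negative", 31, 55, 9), ("positive", 128, 244, 54)]:
            for level, count in [("Undetermined", und), ("HER2-", neg), ("HER2+", pos)]:
                groups += [grp] * count
                factor += [level] * count
        idx = [f"S{i}" for i in range(len(groups))]
        cov = pd.DataFrame({"group": groups}, index=idx)
        return cov, pd.Series(factor, index=idx)

    def test_within_group_percentages(self):
        cov, factor = self.her2_table()
        out = eb.summarize_cohort(cov, factor)
        pct = out["percents"]
        assert round(pct.loc["HER2+", "positive"], 1) == 12.7
        assert round(pct.loc["HER2+", "negative"], 1) == 9.5
        assert round(pct.loc["HER2-", "positive"], 1) == 57.3
        assert round(pct.loc["HER2-", "negative"]) == 58

    def test_independent_table_gives_zero_statistic(self):
        cov = pd.DataFrame({"group": ["positive"] * 20 + ["negative"] * 20},
                           index=[f"S{i}" for i in range(40)])
        factor = pd.Series((["a"] * 10 + ["b"] * 10) * 2, index=cov.index)
        out = eb.summarize_cohort(cov, factor)
        assert out["chi2"] == pytest.approx(0.0, abs=1e-12)
        assert out["p"] == pytest.approx(1.0)

    def test_hand_computed_chi_square(self):
        # counts [[20, 10], [10, 20]]: expected all 15, chi2 = 4 * 25/15
        cov = pd.DataFrame({"group": ["positive"] * 30 + ["negative"] * 30},
                           index=[f"S{i}" for i in range(60)])
        factor = pd.Series(["a"] * 20 + ["b"] * 10 + ["a"] * 10 + ["b"] * 20, index=cov.index)
        out = eb.summarize_cohort(cov, factor, correction=False)
        assert out["chi2"] == pytest.approx(20 / 3)
        assert out["continuity_correction"] is False

    def test_empty_raises(self):
        cov = pd.DataFrame({"group": []}, index=pd.Index([]))
        with pytest.raises(ValueError):
            eb.summarize_cohort(cov, pd.Series(dtype=object))


class TestPCACheck:
    def make_matrix(self, data, samples):
        return MethylationMatrix(
            pd.DataFrame(data, index=[f"p{i}" for i in range(data.shape[0])], columns=samples),
            scale=M_SCALE,
        )

    def test_pc1_recovers_dominant_covariate(self):
        rng = np.random.default_rng(1)
        samples = [f"S{i}" for i in range(50)]
        age = rng.normal(60, 10, 50)
        data = np.outer(np.ones(30), age) + rng.normal(0, 1e-3, (30, 50))
        cov = pd.DataFrame({"group": ["positive"] * 50, "age": age}, index=samples)
        out = eb.pca_covariate_check(self.make_matrix(data, samples), cov, k=2)
        r = out[(out["component"] == "PC1") & (out["covariate"] == "age")]["r"].iloc[0]
        assert abs(r) == pytest.approx(1.0, abs=1e-6)

    def test_independent_covariate_uncorrelated(self):
        rng = np.random.default_rng(2)
        samples = [f"S{i}" for i in range(200)]
        data = rng.normal(size=(50, 200))
        cov = pd.DataFrame({"group": ["positive"] * 200, "age": rng.normal(60, 10, 200)},
                           index=samples)
        out = eb.pca_covariate_check(self.make_matrix(data, samples), cov, k=1)
        assert abs(out["r"].iloc[0]) < 0.2

    def test_probe_centering_invariance(self):
        rng = np.random.default_rng(3)
        samples = [f"S{i}" for i in range(20)]
        data = rng.normal(size=(15, 20))
        cov = pd.DataFrame({"group": ["positive"] * 20, "age": rng.normal(60, 5, 20)}, index=samples)
        a = eb.pca_covariate_check(self.make_matrix(data, samples), cov, k=3)
        b = eb.pca_covariate_check(
            self.make_matrix(data + rng.normal(size=(15, 1)), samples), cov, k=3
        )
        np.testing.assert_allclose(np.abs(a["r"]), np.abs(b["r"]), atol=1e-8)

    def test_k_too_large(self):
        rng = np.random.default_rng(4)
        samples = [f"S{i}" for i in range(5)]
        cov = pd.DataFrame({"group": ["positive"] * 5, "age": np.arange(5.0)}, index=samples)
        with pytest.raises(ValueError, match="k exceeds"):
            eb.pca_covariate_check(self.make_matrix(rng.normal(size=(4, 5)), samples), cov, k=10)
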