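import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

import edi


def hypergeometric_two_sided(a, b, c, d):
    """Independent oracle: enumerate the hypergeometric tail areas."""
    n = a + b + c + d
    r1, c1 = a + b, a + c
    support = np.arange(max(0, r1 + c1 - n), min(r1, c1) + 1)
    pmf = hypergeom.pmf(support, n, r1, c1)
    obs = hypergeom.pmf(a, n, r1, c1)
    return float(pmf[pmf <= obs * (1 + 1e-9)].sum())


class TestDichotomize:
    def test_five_is_high_rest_low(self):
        labels = edi.dichotomize_edi([1, 2, 3, 4, 5])
        assert list(labels) == ["low", "low", "low", "low", "high"]

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            edi.dichotomize_edi([0])

    def test_pure_function(self):
        scores = [5, 3, 5, 1]
        np.testing.assert_array_equal(
            edi.dichotomize_edi(scores), edi.dichotomize_edi(scores)
        )


class TestFisher:
    def test_diagonal_table_enumeration(self):
        # [[10,0],[0,10]]: only the two extreme tables are as improbable
        p = edi.fisher_two_sided([[10, 0], [0, 10]])
        assert p == pytest.approx(2 / 184756, rel=1e-9)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_hypergeometric_oracle_random_tables(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(50):
            a, b, c, d = rng.integers(0, 12, size=4)
            if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
                continue
            assert edi.fisher_two_sided([[a, b], [c, d]]) == pytest.approx(
                hypergeometric_two_sided(a, b, c, d), rel=1e-9
            )

    def test_enrichment_recovers_planted_block(self):
        groups = np.array(["high"] * 80 + ["low"] * 320)
        block = [f"g{i:04d}" for i in range(10)]
        cna = edi.simulate_cna(
            150, 400, groups,
            enriched_block={"genes": block, "direction": "loss", "odds": 20.0},
            seed=0,
        )
        res = edi.fisher_enrichment(cna, groups)
        top = set(
            res[res["direction"] == "loss"].nsmallest(10, "p_adj")["gene"]
        )
        assert len(top & set(block)) >= 8

    def test_zero_variance_gene_flagged_p1(self):
        cna = pd.DataFrame(
            [[0, 0, 0, 0]], index=["flat"], columns=list("abcd")
        )
        res = edi.fisher_enrichment(cna, np.array(["high", "high", "low", "low"]))
        assert (res["p"] == 1.0).all()
        assert res["constant"].all()

    def test_sample_label_mismatch(self):
        cna = pd.DataFrame([[0, 1]], index=["g"], columns=["a", "b"])
        with pytest.raises(ValueError):
            edi.fisher_enrichment(cna, np.array(["high"]))


class TestKMLogrank:
    def test_no_events_flagged(self):
        out = edi.km_logrank(
            [5.0, 6.0, 7.0, 8.0], [0, 0, 0, 0], ["a", "a", "b", "b"]
        )
        assert not out["defined"]
        for curve in out["curves"].values():
            assert (curve.to_numpy() == 1.0).all()

    def test_curves_start_at_one_and_decrease(self, cohort_df):
        out = edi.km_logrank(
            cohort_df["survival_months"], cohort_df["event"], cohort_df["edi_group"]
        )
        for curve in out["curves"].values():
            vals = curve.to_numpy().ravel()
            assert vals[0] == 1.0
            assert (np.diff(vals) <= 1e-12).all()

    def test_time_doubling_doubles_median(self):
        rng = np.random.default_rng(1)
        t = rng.exponential(20, 300)
        e = np.ones(300, int)
        times = np.concatenate([t, 2 * t])
        events = np.concatenate([e, e])
        groups = np.array(["a"] * 300 + ["b"] * 300)
        out = edi.km_logrank(times, events, groups)

        def km_median(curve):
            s = curve.iloc[:, 0]
            return s.index[s <= 0.5][0]

        m_a = km_median(out["curves"]["a"])
        m_b = km_median(out["curves"]["b"])
        assert m_b == pytest.approx(2 * m_a, rel=1e-9)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            edi.km_logrank([1.0, 2.0], [1, 1], ["a", "a"])


class TestCox:
    def test_recovers_true_hazard_ratio(self):
        df = edi.validate_cohort(
            edi.simulate_cohort(edi.CohortSpec(n=1000, hr_edi_high=2.0), seed=5)
        )
        df["edi_high"] = (df["edi_group"] == "high").astype(int)
        fit = edi.cox_fit(df, ["edi_high"])
        assert 1.6 <= fit.loc["edi_high", "HR"] <= 2.5
        assert fit.loc["edi_high", "CI_lower"] < 2.0 < fit.loc["edi_high", "CI_upper"]

    def test_null_covariate_near_one(self):
        df = edi.validate_cohort(
            edi.simulate_cohort(edi.CohortSpec(n=1500, hr_edi_high=1.0), seed=6)
        )
        df["edi_high"] = (df["edi_group"] == "high").astype(int)
        fit = edi.cox_fit(df, ["edi_high"])
        assert fit.loc["edi_high", "HR"] == pytest.approx(1.0, abs=0.25)

    def test_duplicate_covariate_rank_deficient(self, cohort_df):
        df = cohort_df.copy()
        df["edi_high"] = (df["edi_group"] == "high").astype(int)
        df["edi_high2"] = df["edi_high"]
        with pytest.raises(ValueError, match="rank"):
            edi.cox_fit(df, ["edi_high", "edi_high2"])

    def test_multivariate_model(self, cohort_df):
        df = cohort_df.copy()
        df["edi_high"] = (df["edi_group"] == "high").astype(int)
        fit = edi.cox_fit(df, ["edi_high", "node", "size_cat"])
        assert set(fit.index) == {"edi_high", "node", "size_cat"}


class TestCombineEdiTp53:
    @pytest.mark.parametrize(
        "group, tp53, expected",
        [
            ("high", "MUT", "adverse"),
            ("low", "WT", "favorable"),
            ("low", "MUT", "intermediate"),
            ("high", "WT", "intermediate"),
        ],
    )
    def test_label_rules(self, group, tp53, expected):
        df = pd.DataFrame({"edi_group": [group], "tp53": [tp53]})
        out = edi.combine_edi_tp53(df)
        assert out.loc[0, "combined_group"] == expected
        assert out.loc[0, "combined_code"] == {
            "favorable": 0,
            "intermediate": 1,
            "adverse": 2,
        }[expected]

    def test_missing_tp53_excluded_and_counted(self):
        df = pd.DataFrame(
            {"edi_group": ["high", "low"], "tp53": ["MUT", None]}
        )
        out = edi.combine_edi_tp53(df)
        assert len(out) == 1
        assert out.attrs["n_excluded_tp53"] == 1

    def test_ordinal_code_is_prognostic_on_synthetic_cohort(self):
        spec = edi.CohortSpec(n=1200, hr_edi_high=2.0, hr_tp53_mut=1.8)
        df = edi.validate_cohort(edi.simulate_cohort(spec, seed=7))
        out = edi.combine_edi_tp53(df)
        fit = edi.cox_fit(out, ["combined_code"])
        assert fit.loc["combined_code", "HR"] > 1.2
        assert fit.loc["combined_code", "p"] < 0.01


class TestExpressionCorrelation:
    def test_perfectly_tracking_gene(self):
        scores = np.array([1, 2, 3, 4, 5, 3, 2, 4] * 4)
        expr = pd.DataFrame(
            {f"s{i}": [v] for i, v in enumerate(scores)}, index=["tracker"]
        )
        out = edi.expression_correlation(expr, scores)
        assert out.loc["tracker", "r"] == pytest.approx(1.0)

    def test_anticorrelated_gene_attains_minimum_q(self):
        rng = np.random.default_rng(8)
        scores = rng.integers(1, 6, 50)
        expr = edi.simulate_expression(
            500, 50, edi_scores=scores,
            planted={"genes": ["g0007"], "slope": -1.0, "noise_sd": 0.05},
            seed=8,
        )
        out = edi.expression_correlation(expr, scores)
        assert out.loc["g0007", "r"] < -0.95
        assert out.loc["g0007", "q"] == out["q"].min()

    def test_constant_genes_excluded(self):
        scores = np.array([1.0, 2.0, 3.0, 4.0])
        expr = pd.DataFrame(
            [[1.0, 1.0, 1.0, 1.0], [0.1, 0.5, 0.2, 0.9]],
            index=["flat", "ok"],
            columns=list("abcd"),
        )
        out = edi.expression_correlation(expr, scores)
        assert "flat" not in out.index
        assert out.attrs["n_excluded_constant"] == 1

    def test_qvalues_monotone_in_p(self):
        rng = np.random.default_rng(9)
        p = rng.uniform(size=500)
        q = edi.storey_qvalues(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()
        assert ((q > 0) & (q <= 1)).all()


class TestGenomicInstability:
    @pytest.mark.parametrize(
        "calls, expected",
        [([0, 0], 0.0), ([1, -2], 1.0), ([1, 0], 0.5)],
    )
    def test_fractions(self, calls, expected):
        seg = pd.DataFrame({"length": [50.0, 50.0], "call": calls})
        assert edi.genomic_instability(seg) == expected

    def test_negative_length_rejected(self):
        seg = pd.DataFrame({"length": [-1.0], "call": [0]})
        with pytest.raises(ValueError):
            edi.genomic_instability(seg)
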