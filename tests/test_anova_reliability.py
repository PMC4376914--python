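import numpy as np
import pytest
from scipy import stats

from riskimagery import (
    holm_adjust,
    icc_consistency,
    panas_change,
    posthoc_vs_neutral,
    rm_anova,
    subject_level_correlation,
)
from riskimagery.data_model import PANASRecord
from riskimagery.exceptions import (
    DegenerateDataError,
    DesignError,
    DomainViolationError,
    SampleSizeError,
)


class TestRMAnova:
    @pytest.mark.parametrize("seed", range(10))
    def test_two_level_factor_equals_paired_t_squared(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(5, 40)
        data = rng.normal(0, 1, (n, 2)) + rng.normal(0, 1, (n, 1))
        eff = rm_anova(data, [("cond", 2)])["cond"]
        t = stats.ttest_rel(data[:, 0], data[:, 1])
        assert eff.F == pytest.approx(t.statistic**2, rel=1e-10)
        assert eff.p_uncorrected == pytest.approx(t.pvalue, rel=1e-10)
        assert eff.gg_epsilon == 1.0
        assert (eff.df1, eff.df2) == (1, n - 1)

    def test_compound_symmetry_gives_epsilon_near_one(self):
        rng = np.random.default_rng(42)
        n, k = 400, 4
        data = rng.normal(0, 1, (n, k)) + rng.normal(0, 1, (n, 1))
        eff = rm_anova(data, [("f", k)])["f"]
        assert eff.gg_epsilon > 0.95

    def test_matches_pingouin_oneway_gg(self):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(7)
        n, k = 20, 5
        data = rng.normal(0, 1, (n, k)) + rng.normal(0, 1.2, (n, 1))
        data[:, 0] += 0.8
        eff = rm_anova(data, [("cond", k)])["cond"]
        long = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(n), k),
                "cond": np.tile(np.arange(k), n),
                "y": data.ravel(),
            }
        )
        aov = pg.rm_anova(data=long, dv="y", within="cond", subject="subject", correction=True)
        assert eff.F == pytest.approx(float(aov["F"].iloc[0]), rel=1e-6)
        assert eff.gg_epsilon == pytest.approx(float(aov["eps"].iloc[0]), rel=1e-6)
        assert eff.p_gg == pytest.approx(float(aov["p_GG_corr"].iloc[0]), rel=1e-5)
        assert eff.partial_eta_sq == pytest.approx(float(aov["ng2"].iloc[0]), abs=0.2)

    def test_factorial_design_produces_all_effects(self):
        rng = np.random.default_rng(8)
        n = 16
        # 2 x 3 x 5 x 2 within design (hemisphere x electrode x scenario x phase)
        data = rng.normal(0, 1, (n, 60)) + rng.normal(0, 0.5, (n, 1))
        effects = rm_anova(
            data,
            [("hemisphere", 2), ("electrode", 3), ("scenario", 5), ("phase", 2)],
        )
        assert len(effects) == 15  # 4 mains + 6 two-way + 4 three-way + 1 four-way
        ph = effects["phase"]
        assert (ph.df1, ph.df2) == (1, 15)
        for eff in effects.values():
            assert eff.F >= 0
            assert 0 <= eff.partial_eta_sq <= 1
            assert 0 <= eff.p_gg <= 1
            assert eff.gg_epsilon <= 1.0 + 1e-12

    def test_constant_extra_level_reconstruction_dfs(self):
        # ten scenarios compared against an explicit neutral (constant 0)
        # level: df = (10, 590) at 60 subjects
        rng = np.random.default_rng(9)
        wide = rng.normal(0.8, 1, (60, 10))
        data = np.column_stack([wide, np.zeros(60)])
        eff = rm_anova(data, [("scenario", 11)])["scenario"]
        assert (eff.df1, eff.df2) == (10, 590)

    def test_incomplete_design_rejected(self):
        data = np.ones((5, 4))
        data[0, 0] = np.nan
        with pytest.raises(DesignError):
            rm_anova(data, [("f", 4)])


class TestHolm:
    def test_hand_computed_triple(self):
        adj = holm_adjust([0.01, 0.02, 0.03])
        np.testing.assert_allclose(adj, [0.03, 0.04, 0.04])

    def test_single_p_and_all_ones(self):
        assert holm_adjust([0.04])[0] == pytest.approx(0.04)
        np.testing.assert_allclose(holm_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_input_order_preserved(self):
        adj = holm_adjust([0.03, 0.01, 0.02])
        np.testing.assert_allclose(adj, [0.04, 0.03, 0.04])

    def test_family_size_larger_than_supplied(self):
        np.testing.assert_allclose(holm_adjust([0.01, 0.02], m=4), [0.04, 0.06])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_statsmodels_and_dominates_raw(self, seed):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(seed)
        p = rng.uniform(0, 1, 12)
        adj = holm_adjust(p)
        _, adj_sm, _, _ = multipletests(p, method="holm")
        np.testing.assert_allclose(adj, adj_sm, atol=1e-12)
        assert np.all(adj >= p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_invalid_p_rejected(self):
        with pytest.raises(DomainViolationError):
            holm_adjust([0.5, 1.2])


class TestPosthocVsNeutral:
    def test_all_zero_scenario_gives_p_one(self):
        data = np.zeros((10, 3))
        res = posthoc_vs_neutral(data)
        assert np.all(res.p_adjusted == 1.0)
        assert res.degenerate == [0, 1, 2]

    def test_shifted_scenarios_detected(self):
        rng = np.random.default_rng(1)
        data = rng.normal(0.8, 0.5, (60, 10))
        res = posthoc_vs_neutral(data)
        assert np.all(res.p_adjusted < 0.01)

    def test_familywise_error_under_null(self):
        rng = np.random.default_rng(2)
        fw = 0
        n_rep = 500
        for _ in range(n_rep):
            data = rng.normal(0.0, 1.0, (30, 10))
            fw += (posthoc_vs_neutral(data).p_adjusted < 0.05).any()
        assert fw / n_rep <= 0.07  # at most ~alpha family-wise


class TestICC:
    def test_subject_shifted_profiles_give_one(self):
        base = np.linspace(1, 10, 8)
        data = base[None, :] + np.arange(6)[:, None] * 2.0
        assert icc_consistency(data) == pytest.approx(1.0)

    def test_invariant_to_scenario_constants_and_affine_rescale(self):
        # consistency ICC ignores scenario (column) level shifts and any
        # common affine transform of the ratings
        rng = np.random.default_rng(3)
        data = rng.normal(5, 2, (20, 10))
        base = icc_consistency(data)
        col_shifted = data + rng.normal(0, 3, (1, 10))
        assert icc_consistency(col_shifted) == pytest.approx(base, abs=1e-10)
        assert icc_consistency(3.0 * data + 7.0) == pytest.approx(base, abs=1e-10)

    def test_matches_pingouin_icc3k(self):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(4)
        data = rng.normal(5, 2, (15, 6)) + rng.normal(0, 1.5, (15, 1))
        long = pd.DataFrame(
            {
                "targets": np.repeat(np.arange(15), 6),
                "raters": np.tile(np.arange(6), 15),
                "ratings": data.ravel(),
            }
        )
        icc = pg.intraclass_corr(data=long, targets="targets", raters="raters", ratings="ratings")
        ours = icc_consistency(data)
        # pingouin labels the two-way consistency average-measures ICC "ICC(C,k)"
        theirs = float(icc.loc[icc["Type"] == "ICC(C,k)", "ICC"].iloc[0])
        assert ours == pytest.approx(theirs, abs=1e-10)

    def test_pure_noise_near_zero_on_average(self):
        # E[ICC(3,k)] under pure noise is -(k-1)/... slightly negative at
        # finite n (MS ratio bias); with 80 subjects the bias is ~ -0.03
        rng = np.random.default_rng(5)
        vals = [icc_consistency(rng.normal(0, 1, (80, 10))) for _ in range(300)]
        assert abs(np.mean(vals)) < 0.06

    def test_zero_between_subject_variance_flagged(self):
        with pytest.raises((DegenerateDataError, DesignError)):
            icc_consistency(np.tile(np.linspace(1, 5, 4), (6, 1)))


class TestPANASChange:
    def _records(self, d_pa, d_na, n=22, seed=0):
        rng = np.random.default_rng(seed)
        out = []
        for i in range(n):
            pa = float(np.clip(rng.normal(30, 4), 11, 45))
            na = float(np.clip(rng.normal(15, 3), 11, 45))
            out.append(
                PANASRecord(
                    f"s{i}", pa_pre=pa, pa_post=float(np.clip(pa + d_pa[i], 10, 50)),
                    na_pre=na, na_post=float(np.clip(na + d_na[i], 10, 50)),
                )
            )
        return out

    def test_no_change_gives_zero_f(self):
        recs = self._records(np.zeros(10), np.zeros(10), n=10)
        res = panas_change(recs)
        assert res.delta_pa == 0.0 and res.delta_na == 0.0
        assert res.F == 0.0 and res.p == 1.0

    def test_dfs_match_sample_size(self):
        rng = np.random.default_rng(6)
        recs = self._records(rng.normal(-2.5, 4, 22), rng.normal(2.67, 4, 22), seed=6)
        res = panas_change(recs)
        assert (res.df1, res.df2) == (1, 21)
        assert 0 <= res.partial_eta_sq <= 1

    def test_recovers_built_in_shifts(self):
        # 200 replicates at n = 22 with shifts (-3, +3): the mean estimates
        # should land on the truth and the 95% CI should usually cover it
        rng = np.random.default_rng(7)
        d_pa_hat, d_na_hat, cover = [], [], 0
        n_rep = 200
        for _ in range(n_rep):
            recs = self._records(rng.normal(-3, 4, 22), rng.normal(3, 4, 22), seed=rng.integers(2**31))
            res = panas_change(recs)
            d_pa_hat.append(res.delta_pa)
            d_na_hat.append(res.delta_na)
            cover += res.delta_pa_ci[0] <= -3 <= res.delta_pa_ci[1]
        assert np.mean(d_pa_hat) == pytest.approx(-3.0, abs=0.3)
        assert np.mean(d_na_hat) == pytest.approx(3.0, abs=0.3)
        assert cover / n_rep > 0.88

    def test_too_few_subjects(self):
        with pytest.raises(SampleSizeError):
            panas_change(self._records(np.zeros(2), np.zeros(2), n=2))


class TestSubjectLevelCorrelation:
    def test_self_correlation_is_one(self, study1_table):
        res = subject_level_correlation(study1_table, "stai", "stai")
        assert res.r == pytest.approx(1.0)

    def test_known_positive_association(self, study1_table):
        res = subject_level_correlation(study1_table, "stai", "x")
        assert res.r > 0.2
        assert res.n == 60

    def test_independent_variables_average_near_zero(self):
        import pandas as pd

        from riskimagery import TrialSchema, TrialTable

        rng = np.random.default_rng(8)
        rs = []
        for _ in range(300):
            n = 30
            df = pd.DataFrame(
                {
                    "subject_id": np.repeat(np.arange(n), 2),
                    "item_id": np.tile(["a", "b"], n),
                    "x": rng.normal(0, 1, 2 * n),
                    "stress": rng.normal(0, 1, 2 * n),
                }
            )
            table = TrialTable(df=df, schema=TrialSchema.unbounded())
            rs.append(subject_level_correlation(table, "x", "stress").r)
        assert abs(np.mean(rs)) < 0.03

    def test_zero_variance_flagged(self):
        import pandas as pd

        from riskimagery import TrialSchema, TrialTable

        df = pd.DataFrame(
            {
                "subject_id": ["s1", "s2", "s3"],
                "item_id": ["a", "a", "a"],
                "x": [1.0, 1.0, 1.0],
                "stress": [1.0, 2.0, 3.0],
            }
        )
        table = TrialTable(df=df, schema=TrialSchema.unbounded())
        with pytest.raises(DegenerateDataError):
            subject_level_correlation(table, "x", "stress")
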