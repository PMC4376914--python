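import numpy as np
import pandas as pd
import pytest
from scipy import stats

from riskimagery import fit_interaction, gen_study3, jn_regions, simple_slopes
from riskimagery.jn_moderation import ModerationResult
from riskimagery.synthetic_data import Study3Config


def planar_table(seed=0, b=(1.0, 2.0, -1.0, 0.5), n_subj=8, n_item=5, noise=0.0):
    rng = np.random.default_rng(seed)
    subj = np.repeat(np.arange(n_subj), n_item)
    item = np.tile(np.arange(n_item), n_subj)
    x = rng.normal(5, 2, n_subj * n_item)
    w = rng.normal(1.0, 0.3, n_subj * n_item)
    y = b[0] + b[1] * x + b[2] * w + b[3] * x * w + noise * rng.normal(size=len(x))
    return pd.DataFrame(
        {
            "subject_id": [f"s{k}" for k in subj],
            "item_id": [f"i{k}" for k in item],
            "risk_perception": x,
            "x": w,
            "risk_taking": y,
        }
    )


def synthetic_result(b1, b3, vcov3, w_range=(0.9, 1.3), df=76):
    """Build a ModerationResult directly from coefficients and a 3x3
    covariance of (b1, b3) embedded at positions (1, 3) of a 4x4 vcov."""
    V = np.zeros((4, 4))
    V[1, 1], V[1, 3], V[3, 1], V[3, 3] = vcov3[0], vcov3[1], vcov3[1], vcov3[2]
    names = ("(Intercept)", "risk_perception", "iai_mean", "risk_perception:iai_mean")
    coeffs = {
        names[0]: (0.0, 0.1),
        names[1]: (b1, np.sqrt(max(vcov3[0], 1e-12))),
        names[2]: (0.0, 0.1),
        names[3]: (b3, np.sqrt(max(vcov3[2], 1e-12))),
    }
    return ModerationResult(
        names=names,
        coefficients=coeffs,
        vcov=V,
        lrt_interaction={"chi_sq": 0.0, "df": 1, "p": 1.0},
        moderator_range=w_range,
        moderator_mean=float(np.mean(w_range)),
        moderator_sd=(w_range[1] - w_range[0]) / 4,
        n_obs=df + 4,
        resid_df=df,
    )


def random_psd(rng):
    A = rng.normal(0, 1, (2, 2)) * rng.uniform(0.05, 0.5)
    M = A @ A.T + 1e-4 * np.eye(2)
    return (M[0, 0], M[0, 1], M[1, 1])


class TestFitInteraction:
    def test_noiseless_planar_coefficients_exact(self):
        df = planar_table(seed=0)
        res = fit_interaction(df, y="risk_taking", x_focal="risk_perception", moderator="x")
        est = {k: v[0] for k, v in res.coefficients.items()}
        assert est["(Intercept)"] == pytest.approx(1.0, abs=1e-6)
        assert est["risk_perception"] == pytest.approx(2.0, abs=1e-6)
        assert est["x"] == pytest.approx(-1.0, abs=1e-6)
        assert est["risk_perception:x"] == pytest.approx(0.5, abs=1e-6)

    def test_lrt_df_is_one_and_chi_nonnegative(self):
        df = planar_table(seed=1, noise=0.5)
        res = fit_interaction(df, y="risk_taking", x_focal="risk_perception", moderator="x")
        assert res.lrt_interaction["df"] == 1
        assert res.lrt_interaction["chi_sq"] >= 0

    def test_study3_generator_interaction_recovered(self):
        b = gen_study3(Study3Config(), seed=10, include_eeg=False)
        res = fit_interaction(b["trials"], moderator="x")
        est, se = res.coefficients["risk_perception:x"]
        assert abs(est - 3.0) < 4 * se
        assert res.lrt_interaction["p"] < 0.05

    def test_recentring_oracle(self):
        # refitting with the moderator centered at w0 turns the focal main
        # effect into theta(w0)
        df = planar_table(seed=2, noise=0.3)
        res = fit_interaction(df, y="risk_taking", x_focal="risk_perception", moderator="x")
        w0 = 1.1
        df2 = df.copy()
        df2["x"] = df2["x"] - w0
        res2 = fit_interaction(df2, y="risk_taking", x_focal="risk_perception", moderator="x")
        theta = res.b1 + res.b3 * w0
        assert res2.coefficients["risk_perception"][0] == pytest.approx(theta, abs=1e-5)


class TestSimpleSlopes:
    def test_zero_interaction_gives_constant_slope(self):
        res = synthetic_result(b1=-0.4, b3=0.0, vcov3=(0.01, 0.0, 0.0))
        slopes = simple_slopes(res, at=(0.9, 1.1, 1.3))
        vals = [v["slope"] for v in slopes.values()]
        assert vals == pytest.approx([-0.4] * 3)

    def test_slope_is_linear_in_moderator(self):
        res = synthetic_result(b1=-0.5, b3=0.3, vcov3=(0.01, 0.001, 0.02))
        slopes = simple_slopes(res, at=(1.0, 1.2))
        assert slopes[1.0]["slope"] == pytest.approx(-0.5 + 0.3)
        assert slopes[1.2]["slope"] == pytest.approx(-0.5 + 0.3 * 1.2)

    def test_default_pick_a_point_values(self):
        res = synthetic_result(b1=-0.5, b3=0.3, vcov3=(0.01, 0.001, 0.02))
        slopes = simple_slopes(res)
        m, s = res.moderator_mean, res.moderator_sd
        assert set(slopes) == {m - s, m, m + s}

    def test_se_matches_delta_method(self):
        v = (0.02, -0.004, 0.015)
        res = synthetic_result(b1=-0.5, b3=0.3, vcov3=v)
        w = 1.17
        se = simple_slopes(res, at=(w,))[w]["se"]
        assert se == pytest.approx(np.sqrt(v[0] + 2 * w * v[1] + w * w * v[2]), abs=1e-12)


class TestJNRegions:
    def test_zero_interaction_no_boundary_constant_significance(self):
        res = synthetic_result(b1=-0.4, b3=0.0, vcov3=(0.002, 0.0, 0.0))
        jn = jn_regions(res)
        assert jn.boundaries == []
        assert jn.grid["significant"].all() or not jn.grid["significant"].any()

    def test_ci_touches_zero_at_boundary(self):
        rng = np.random.default_rng(0)
        found = 0
        for _ in range(50):
            v = random_psd(rng)
            res = synthetic_result(
                b1=rng.normal(0, 1), b3=rng.normal(0, 2), vcov3=v, w_range=(0.5, 1.5)
            )
            jn = jn_regions(res)
            for w in jn.boundaries:
                theta = res.b1 + res.b3 * w
                se = np.sqrt(v[0] + 2 * w * v[1] + w * w * v[2])
                assert abs(abs(theta) - jn.t_crit * se) < 1e-8
                found += 1
        assert found > 5  # the draw ranges do produce boundaries

    @pytest.mark.parametrize("seed", range(4))
    def test_boundaries_agree_with_grid_scan(self, seed):
        rng = np.random.default_rng(seed)
        step = 1e-4
        for _ in range(25):
            v = random_psd(rng)
            res = synthetic_result(
                b1=rng.normal(0, 0.8), b3=rng.normal(0, 1.5), vcov3=v, w_range=(0.8, 1.4)
            )
            jn = jn_regions(res)
            w = np.arange(0.8, 1.4 + step, step)
            theta = res.b1 + res.b3 * w
            se = np.sqrt(v[0] + 2 * w * v[1] + w * w * v[2])
            sig = np.abs(theta / se) > jn.t_crit
            flips = w[np.flatnonzero(np.diff(sig.astype(int)))]
            assert len(flips) == len(jn.boundaries)
            for f, b in zip(sorted(flips), sorted(jn.boundaries)):
                assert abs(f - b) <= 2 * step

    def test_slopes_and_regions_consistent(self):
        rng = np.random.default_rng(5)
        v = random_psd(rng)
        res = synthetic_result(b1=-0.6, b3=0.55, vcov3=v, w_range=(0.5, 1.6))
        jn = jn_regions(res)
        for w in np.linspace(0.5, 1.6, 23):
            if any(abs(w - b) < 0.02 for b in jn.boundaries):
                continue
            p = simple_slopes(res, at=(float(w),))[float(w)]["p"]
            idx = (np.abs(jn.grid["w"] - w)).idxmin()
            assert (p < jn.alpha) == bool(jn.grid.loc[idx, "significant"])

    def test_z_critical_option(self):
        res = synthetic_result(b1=-0.4, b3=0.3, vcov3=(0.01, 0.0, 0.01))
        jn = jn_regions(res, df_method="z")
        assert jn.t_crit == pytest.approx(stats.norm.ppf(0.975))
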