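"""Moderation of risk perception -> risk taking by imagery intensity.

Two crossed random-intercept mixed models are compared: step 1 regresses
risk taking on risk perception and the moderator (mean parieto-occipital
IAI); step 2 adds their interaction.  A likelihood-ratio test (ML refits,
df = 1) assesses the interaction.  The conditional (simple) slope of the
focal predictor at moderator value w is

    theta(w) = b1 + b3 * w,    SE(w) = sqrt(v11 + 2 w v13 + w^2 v33),

probed both at pick-a-point values (mean and +/- 1 SD) and over the whole
observed moderator range via the Johnson-Neyman procedure, which solves
|theta(w)| = t_crit * SE(w), a quadratic in w, for the boundaries of the
regions of significance.

Neither predictor is mean-centered, so coefficients stay on the raw scale
of the ratings and the IAI.  The critical value uses a Student t with
df = n_obs - (number of fixed effects); a normal approximation (1.96) is
available via ``df_method="z"``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import TrialTable
from .exceptions import ConvergenceError, DesignError
from .mixed import fit_lmm

__all__ = ["ModerationResult", "JNResult", "fit_interaction", "simple_slopes", "jn_regions"]

log = logging.getLogger(__name__)


@dataclass
class ModerationResult:
    """Interaction-model coefficients with covariance and the step LRT."""

    names: tuple[str, ...]  # (intercept, focal, moderator, interaction)
    coefficients: Mapping[str, tuple[float, float]]
    vcov: np.ndarray
    lrt_interaction: dict
    moderator_range: tuple[float, float]
    moderator_mean: float
    moderator_sd: float
    n_obs: int
    resid_df: int
    fits: dict = field(default_factory=dict, repr=False)

    @property
    def b1(self) -> float:
        return self.coefficients[self.names[1]][0]

    @property
    def b3(self) -> float:
        return self.coefficients[self.names[3]][0]

    def slope_variance_terms(self) -> tuple[float, float, float]:
        """(v11, v13, v33) for theta(w) = b1 + b3 w."""
        return (
            float(self.vcov[1, 1]),
            float(self.vcov[1, 3]),
            float(self.vcov[3, 3]),
        )

    def to_dict(self) -> dict:
        return {
            "coefficients": {
                k: {"estimate": v[0], "se": v[1]} for k, v in self.coefficients.items()
            },
            "vcov": np.asarray(self.vcov).tolist(),
            "lrt_interaction": self.lrt_interaction,
            "moderator_range": list(self.moderator_range),
            "moderator_mean": self.moderator_mean,
            "moderator_sd": self.moderator_sd,
            "n_obs": self.n_obs,
            "resid_df": self.resid_df,
        }


def fit_interaction(
    table: TrialTable | pd.DataFrame,
    y: str = "risk_taking",
    x_focal: str = "risk_perception",
    moderator: str = "x",
) -> ModerationResult:
    """Fit the moderated model and test the interaction by LRT.

    Step 1: ``y ~ x_focal + moderator`` (+ crossed random intercepts);
    step 2 adds ``x_focal * moderator``.  Both steps are refit by ML for
    the likelihood-ratio test (df = 1); reported coefficients come from
    the REML fit of step 2.
    """
    cols = [y, x_focal, moderator]
    df = (table.dropna_for(cols) if isinstance(table, TrialTable) else table.dropna(subset=cols)).copy()
    w = df[moderator].to_numpy(float)
    if np.all(w == w[0]):
        raise DesignError(f"moderator {moderator!r} is constant across rows")
    inter = f"{x_focal}:{moderator}"
    df[inter] = df[x_focal] * df[moderator]

    step2 = fit_lmm(df, y, fixed=[x_focal, moderator, inter], objective="REML")
    base_ml = fit_lmm(df, y, fixed=[x_focal, moderator], objective="ML")
    full_ml = fit_lmm(df, y, fixed=[x_focal, moderator, inter], objective="ML")
    if full_ml.log_likelihood < base_ml.log_likelihood:
        # nested models: retry the full fit from the base model's optimum
        full_ml = fit_lmm(
            df, y, fixed=[x_focal, moderator, inter], objective="ML",
            start=base_ml.log_variance_ratios,
        )
    chi_sq = 2.0 * (full_ml.log_likelihood - base_ml.log_likelihood)
    if chi_sq < -0.01:  # beyond profiled-deviance flatness noise
        raise ConvergenceError("interaction model log-likelihood below baseline")
    chi_sq = max(chi_sq, 0.0)
    lrt = {
        "chi_sq": float(chi_sq),
        "df": 1,
        "p": float(stats.chi2.sf(chi_sq, 1)),
        "ll_base": base_ml.log_likelihood,
        "ll_full": full_ml.log_likelihood,
    }
    return ModerationResult(
        names=step2.fe_names,
        coefficients=step2.fixed_effects,
        vcov=np.asarray(step2.vcov_fixed),
        lrt_interaction=lrt,
        moderator_range=(float(w.min()), float(w.max())),
        moderator_mean=float(w.mean()),
        moderator_sd=float(w.std(ddof=1)),
        n_obs=step2.n_obs,
        resid_df=step2.n_obs - len(step2.fe_names),
        fits={"step1_ml": base_ml, "step2_ml": full_ml, "step2_reml": step2},
    )


def _theta_se(result: ModerationResult, w: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    v11, v13, v33 = result.slope_variance_terms()
    theta = result.b1 + result.b3 * w
    se = np.sqrt(v11 + 2 * w * v13 + w * w * v33)
    return theta, se


def simple_slopes(
    result: ModerationResult,
    at: Sequence[float] | None = None,
) -> dict[float, dict]:
    """Conditional slopes theta(w) = b1 + b3 w with t-tests.

    Defaults to the pick-a-point values mean - SD, mean, mean + SD of the
    moderator (SD across analysis rows).  Values outside the observed
    moderator range are allowed but logged as extrapolation.
    """
    if at is None:
        m, s = result.moderator_mean, result.moderator_sd
        at = (m - s, m, m + s)
    w = np.asarray(list(at), dtype=float)
    lo, hi = result.moderator_range
    for wi in w:
        if wi < lo or wi > hi:
            log.warning("moderator value %.4g outside observed range [%.4g, %.4g]", wi, lo, hi)
    theta, se = _theta_se(result, w)
    t = theta / se
    p = 2 * stats.t.sf(np.abs(t), result.resid_df)
    return {
        float(wi): {"slope": float(th), "se": float(s_), "t": float(t_), "p": float(p_)}
        for wi, th, s_, t_, p_ in zip(w, theta, se, t, p)
    }


@dataclass
class JNResult:
    """Johnson-Neyman regions of significance."""

    boundaries: list[float]  # roots inside the observed moderator range
    alpha: float
    t_crit: float
    df_method: str
    grid: pd.DataFrame  # w, theta, lower, upper, significant
    significant_at_min: bool
    significant_at_max: bool

    def to_dict(self) -> dict:
        return {
            "jn_boundaries": self.boundaries,
            "alpha": self.alpha,
            "t_crit": self.t_crit,
            "df_method": self.df_method,
            "significant_at_min": self.significant_at_min,
            "significant_at_max": self.significant_at_max,
        }


def jn_regions(
    result: ModerationResult,
    alpha: float = 0.05,
    df_method: str = "t",
    n_grid: int = 201,
) -> JNResult:
    """Johnson-Neyman boundaries and a dense conditional-effect grid.

    Solves |theta(w) / SE(w)| = t_crit, i.e. the quadratic

        (b3^2 - t^2 v33) w^2 + 2 (b1 b3 - t^2 v13) w + (b1^2 - t^2 v11) = 0,

    and returns the real roots inside the observed moderator range plus a
    grid of theta(w) with pointwise (1 - alpha) confidence bands.  Complex
    roots mean significance never changes over the real line; the
    boundary list is then empty.
    """
    if df_method == "t":
        t_crit = float(stats.t.ppf(1 - alpha / 2, result.resid_df))
    elif df_method == "z":
        t_crit = float(stats.norm.ppf(1 - alpha / 2))
    else:
        raise ValueError(f"unknown df_method {df_method!r}")
    b1, b3 = result.b1, result.b3
    v11, v13, v33 = result.slope_variance_terms()
    t2 = t_crit * t_crit
    qa = b3 * b3 - t2 * v33
    qb = 2 * (b1 * b3 - t2 * v13)
    qc = b1 * b1 - t2 * v11
    lo, hi = result.moderator_range
    roots: list[float] = []
    if qa == 0.0:
        if qb != 0.0:
            roots = [-qc / qb]
    else:
        disc = qb * qb - 4 * qa * qc
        if disc >= 0:
            sq = np.sqrt(disc)
            roots = sorted([(-qb - sq) / (2 * qa), (-qb + sq) / (2 * qa)])
    boundaries = [float(r) for r in roots if lo <= r <= hi]

    wgrid = np.linspace(lo, hi, n_grid)
    theta, se = _theta_se(result, wgrid)
    lower = theta - t_crit * se
    upper = theta + t_crit * se
    grid = pd.DataFrame(
        {
            "w": wgrid,
            "theta": theta,
            "lower": lower,
            "upper": upper,
            "significant": (lower > 0) | (upper < 0),
        }
    )
    th_lo, se_lo = _theta_se(result, np.array([lo]))
    th_hi, se_hi = _theta_se(result, np.array([hi]))
    return JNResult(
        boundaries=boundaries,
        alpha=alpha,
        t_crit=t_crit,
        df_method=df_method,
        grid=grid,
        significant_at_min=bool(abs(th_lo[0]) > t_crit * se_lo[0]),
        significant_at_max=bool(abs(th_hi[0]) > t_crit * se_hi[0]),
    )
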