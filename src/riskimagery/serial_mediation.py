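"""Serial two-mediator path model on crossed random-intercept mixed models.

The causal chain X -> M1 -> M2 -> Y (e.g. negative imagery valence ->
stress -> risk perception -> risk taking) is estimated from three mixed
models, each with crossed subject and item random intercepts:

    (i)   M1 ~ X                      -> a1
    (ii)  M2 ~ X + M1                 -> a2, d21
    (iii) Y  ~ X + M1 + M2 (+ covs)   -> c', b1, b2

Subject-level covariates (trait anxiety, risk propensity) enter only the
Y model.  The three-path indirect effect is the product a1*d21*b2; its 95%
confidence interval is the percentile interval of k Monte-Carlo products
of independent normal draws centered at each path estimate with its SE.
A likelihood-ratio test compares Y ~ X (+ covs) against the full Y model
(both refit by ML, identical random structure, df = 2).

Coefficients are reported from REML fits; the LRT uses ML refits because
REML likelihoods of models with different fixed effects are not
comparable.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import TrialTable
from .exceptions import ConvergenceError, ParameterError
from .mixed import LMMFit, fit_lmm

__all__ = ["MediationResult", "fit_lmm", "LMMFit", "mc_indirect_ci", "serial_mediation", "lrt_mediation"]

log = logging.getLogger(__name__)


def mc_indirect_ci(
    a1: tuple[float, float],
    d21: tuple[float, float],
    b2: tuple[float, float],
    k: int = 100_000,
    seed: int | None = None,
    level: float = 0.95,
    strict: bool = False,
) -> tuple[float, float]:
    """Monte-Carlo percentile CI for the product a1 * d21 * b2.

    Each argument is an (estimate, SE) pair.  ``k`` independent draws are
    taken from Normal(estimate, SE^2) for each path; the interval is the
    (2.5, 97.5) percentile of the k products (linear interpolation between
    order statistics).  Reproducible bit-for-bit given (seed, k).
    """
    for name, (est, se) in (("a1", a1), ("d21", d21), ("b2", b2)):
        if se < 0:
            raise ParameterError(f"negative SE for {name}")
    if k < 1000:
        msg = f"k={k} draws give an imprecise percentile CI; use k >= 1000"
        if strict:
            raise ParameterError(msg)
        warnings.warn(msg)
    rng = np.random.default_rng(seed)
    prod = (
        rng.normal(a1[0], a1[1], k)
        * rng.normal(d21[0], d21[1], k)
        * rng.normal(b2[0], b2[1], k)
    )
    alpha = (1.0 - level) / 2.0
    lo, hi = np.percentile(prod, [100 * alpha, 100 * (1 - alpha)])
    return float(lo), float(hi)


def lrt_mediation(
    table: TrialTable | pd.DataFrame,
    x: str,
    y: str,
    m1: str,
    m2: str,
    covariates_on_y: Sequence[str] = (),
) -> dict:
    """Likelihood-ratio test of the mediators' contribution to the Y model.

    Both models are fit by ML on the same rows (listwise deletion over the
    union of all columns): chi^2 = 2 * (ll_full - ll_base), df = 2.
    """
    cols = [x, m1, m2, y, *covariates_on_y]
    df = table.dropna_for(cols) if isinstance(table, TrialTable) else table.dropna(subset=cols)
    base = fit_lmm(df, y, fixed=[x, *covariates_on_y], objective="ML")
    full = fit_lmm(df, y, fixed=[x, m1, m2, *covariates_on_y], objective="ML")
    if full.log_likelihood < base.log_likelihood:
        # the full model nests the base, so warm-start it from the base
        # model's variance ratios before accepting a negative statistic
        full = fit_lmm(
            df, y, fixed=[x, m1, m2, *covariates_on_y], objective="ML",
            start=base.log_variance_ratios,
        )
    chi_sq = 2.0 * (full.log_likelihood - base.log_likelihood)
    # the profiled deviance is flat near the optimum, so tiny negative
    # differences are optimizer noise; anything larger is a real failure
    if chi_sq < -0.01:
        raise ConvergenceError(
            f"full-model log-likelihood {full.log_likelihood:.6f} below baseline "
            f"{base.log_likelihood:.6f}; optimizer failure"
        )
    chi_sq = max(chi_sq, 0.0)
    return {
        "chi_sq": float(chi_sq),
        "df": 2,
        "p": float(stats.chi2.sf(chi_sq, 2)),
        "ll_base": base.log_likelihood,
        "ll_full": full.log_likelihood,
    }


@dataclass
class MediationResult:
    """Estimates of the serial mediation path model."""

    a1: tuple[float, float]
    a2: tuple[float, float]
    d21: tuple[float, float]
    b1: tuple[float, float]
    b2: tuple[float, float]
    c_prime: tuple[float, float]
    indirect_serial: float
    mc_ci: tuple[float, float]
    mc_samples: int
    seed: int | None
    lrt: dict
    covariates_on_y: tuple[str, ...]
    fits: dict = field(default_factory=dict, repr=False)

    @property
    def significant(self) -> bool:
        """The indirect effect is significant iff the CI excludes zero."""
        return not (self.mc_ci[0] <= 0.0 <= self.mc_ci[1])

    def to_dict(self) -> dict:
        d = {
            name: {"estimate": getattr(self, name)[0], "se": getattr(self, name)[1]}
            for name in ("a1", "a2", "d21", "b1", "b2", "c_prime")
        }
        d.update(
            indirect_serial=self.indirect_serial,
            mc_ci=list(self.mc_ci),
            mc_samples=self.mc_samples,
            seed=self.seed,
            lrt=self.lrt,
            covariates_on_y=list(self.covariates_on_y),
            significant=self.significant,
        )
        return d


def serial_mediation(
    table: TrialTable | pd.DataFrame,
    x: str = "x",
    m1: str = "stress",
    m2: str = "risk_perception",
    y: str = "risk_taking",
    covariates_on_y: Sequence[str] = (),
    k: int = 100_000,
    seed: int | None = None,
) -> MediationResult:
    """Estimate the serial two-mediator model with crossed random intercepts.

    All three models use the same rows (listwise deletion over the union of
    the columns involved) so path coefficients and the LRT refer to one
    sample.
    """
    cols = [x, m1, m2, y, *covariates_on_y]
    df = table.dropna_for(cols) if isinstance(table, TrialTable) else table.dropna(subset=cols)

    fit_m1 = fit_lmm(df, m1, fixed=[x], objective="REML")
    fit_m2 = fit_lmm(df, m2, fixed=[x, m1], objective="REML")
    fit_y = fit_lmm(df, y, fixed=[x, m1, m2, *covariates_on_y], objective="REML")

    a1 = fit_m1.fixed_effects[x]
    a2 = fit_m2.fixed_effects[x]
    d21 = fit_m2.fixed_effects[m1]
    c_prime = fit_y.fixed_effects[x]
    b1 = fit_y.fixed_effects[m1]
    b2 = fit_y.fixed_effects[m2]

    indirect = a1[0] * d21[0] * b2[0]
    ci = mc_indirect_ci(a1, d21, b2, k=k, seed=seed)
    lrt = lrt_mediation(df, x=x, y=y, m1=m1, m2=m2, covariates_on_y=covariates_on_y)

    return MediationResult(
        a1=a1, a2=a2, d21=d21, b1=b1, b2=b2, c_prime=c_prime,
        indirect_serial=float(indirect),
        mc_ci=ci,
        mc_samples=k,
        seed=seed,
        lrt=lrt,
        covariates_on_y=tuple(covariates_on_y),
        fits={"m1": fit_m1, "m2": fit_m2, "y": fit_y},
    )
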