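"""Within-subject classical statistics used throughout the pipeline.

Covers repeated-measures ANOVA for fully-crossed within-subject factorial
designs with the Greenhouse-Geisser sphericity correction, Holm step-down
multiple-comparison adjustment, one-sample post-hocs against a neutral
reference, intraclass correlation reliability, PANAS pre/post change
analysis, and subject-level Pearson correlations.

The RM-ANOVA uses the contrast-variable formulation: for each effect, the
subject x cell matrix is projected onto a Kronecker product of orthonormal
within-factor contrasts (averaging over the factors not in the effect),
and F is computed from the means and covariance of the resulting contrast
scores.  Greenhouse-Geisser epsilon is the standard trace ratio
(tr S)^2 / (m * tr S^2) of the contrast-score covariance S with m contrast
variables; epsilon-corrected p-values deflate both degrees of freedom.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.linalg import helmert

from .data_model import PANASRecord, TrialTable
from .exceptions import (
    DegenerateDataError,
    DesignError,
    DomainViolationError,
    SampleSizeError,
)

__all__ = [
    "RMAnovaEffect",
    "rm_anova",
    "holm_adjust",
    "posthoc_vs_neutral",
    "icc_consistency",
    "panas_change",
    "subject_level_correlation",
]

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Repeated-measures ANOVA with Greenhouse-Geisser correction
# ---------------------------------------------------------------------------


@dataclass
class RMAnovaEffect:
    """One within-subject effect from a repeated-measures ANOVA."""

    F: float
    df1: int
    df2: int
    gg_epsilon: float
    p_gg: float
    p_uncorrected: float
    partial_eta_sq: float

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def _contrast_rows(k: int) -> np.ndarray:
    """Orthonormal contrasts spanning the (k-1)-dim space orthogonal to 1."""
    return helmert(k, full=False)


def rm_anova(
    data: np.ndarray,
    factors: Sequence[tuple[str, int]],
) -> dict[str, RMAnovaEffect]:
    """Repeated-measures ANOVA for a fully-crossed within-subject design.

    Parameters
    ----------
    data
        Subject x cell matrix.  Cells are ordered lexicographically by the
        factor levels, first factor slowest.
    factors
        Sequence of (name, n_levels); the product of level counts must
        equal the number of columns of ``data``.

    Returns
    -------
    dict mapping effect names ("A", "A:B", ...) to :class:`RMAnovaEffect`
    for every main effect and interaction.
    """
    Y = np.asarray(data, dtype=float)
    if Y.ndim != 2:
        raise DesignError("data must be a 2-D subject x cell matrix")
    n, K = Y.shape
    if np.isnan(Y).any():
        raise DesignError("missing cells; within-subject design must be complete")
    levels = [k for _, k in factors]
    if int(np.prod(levels)) != K:
        raise DesignError(
            f"factor levels {levels} imply {int(np.prod(levels))} cells, data has {K}"
        )
    if n < 2:
        raise SampleSizeError("repeated-measures ANOVA needs >=2 subjects")

    out: dict[str, RMAnovaEffect] = {}
    idx_all = range(len(factors))
    for r in range(1, len(factors) + 1):
        for subset in itertools.combinations(idx_all, r):
            mats = []
            for i, (_, k) in enumerate(factors):
                if i in subset:
                    mats.append(_contrast_rows(k))
                else:
                    mats.append(np.full((1, k), 1.0 / k))
            C = mats[0]
            for m_ in mats[1:]:
                C = np.kron(C, m_)
            T = Y @ C.T  # n x m contrast scores
            m = T.shape[1]
            tbar = T.mean(axis=0)
            ss_eff = n * float(tbar @ tbar)
            resid = T - tbar
            ss_err = float((resid * resid).sum())
            df1 = m
            df2 = m * (n - 1)
            # sums of squares at rounding-noise level mean the contrast is
            # degenerate (all cells identical within subject): F = 0
            tiny = 1e-12 * n * m * max(1.0, float((Y * Y).mean()))
            if ss_eff < tiny and ss_err < tiny:
                ss_eff = ss_err = 0.0
            if ss_err <= 0:
                F = np.inf if ss_eff > 0 else 0.0
            else:
                F = (ss_eff / df1) / (ss_err / df2)
            # Greenhouse-Geisser epsilon from the contrast-score covariance
            if m == 1 or n < 2:
                eps = 1.0
            else:
                S = np.cov(T, rowvar=False, ddof=1)
                trS = float(np.trace(S))
                trS2 = float((S * S).sum())  # tr(S @ S) for symmetric S
                eps = 1.0 if trS2 <= 0 else min(1.0, trS * trS / (m * trS2))
            p_unc = float(stats.f.sf(F, df1, df2)) if np.isfinite(F) else 0.0
            p_gg = float(stats.f.sf(F, eps * df1, eps * df2)) if np.isfinite(F) else 0.0
            eta = ss_eff / (ss_eff + ss_err) if (ss_eff + ss_err) > 0 else 0.0
            name = ":".join(factors[i][0] for i in subset)
            out[name] = RMAnovaEffect(
                F=float(F), df1=df1, df2=df2, gg_epsilon=float(eps),
                p_gg=p_gg, p_uncorrected=p_unc, partial_eta_sq=float(eta),
            )
    return out


# ---------------------------------------------------------------------------
# Holm step-down adjustment
# ---------------------------------------------------------------------------


def holm_adjust(p_values: Sequence[float], m: int | None = None) -> np.ndarray:
    """Bonferroni-Holm step-down adjusted p-values, in input order.

    Sort ascending; adjusted p_(i) = max_{j<=i} min(1, (m-j+1) * p_(j)),
    with family size ``m`` defaulting to ``len(p_values)`` (it may be
    larger when some tests of the family are not supplied).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise DomainViolationError("p-values must lie in [0, 1]")
    if m is None:
        m = p.size
    if m < p.size:
        raise DomainViolationError(f"family size m={m} smaller than {p.size} p-values")
    order = np.argsort(p, kind="stable")
    adj_sorted = np.minimum(1.0, (m - np.arange(p.size)) * p[order])
    adj_sorted = np.maximum.accumulate(adj_sorted)
    out = np.empty_like(adj_sorted)
    out[order] = adj_sorted
    return out


# ---------------------------------------------------------------------------
# Post-hoc one-sample tests against a neutral reference
# ---------------------------------------------------------------------------


@dataclass
class PosthocResult:
    """Per-scenario one-sample t-tests against a neutral reference (0),
    two-tailed, Holm-adjusted across scenarios."""

    t: np.ndarray
    p_raw: np.ndarray
    p_adjusted: np.ndarray
    means: np.ndarray
    degenerate: list[int] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "t": self.t.tolist(),
            "p_raw": self.p_raw.tolist(),
            "p_adjusted": self.p_adjusted.tolist(),
            "means": self.means.tolist(),
            "degenerate": self.degenerate,
        }


def posthoc_vs_neutral(valence: np.ndarray, neutral: float = 0.0) -> PosthocResult:
    """One-sample t-test of each scenario's subject means against ``neutral``.

    ``valence`` is a subject x scenario matrix of per-scenario means.
    Scenarios with zero variance are flagged as degenerate: t = 0 / p = 1
    when the mean equals the reference, otherwise p = 0 with a log warning.
    """
    X = np.asarray(valence, dtype=float)
    n, k = X.shape
    if n < 2:
        raise SampleSizeError("post-hoc tests need >=2 subjects")
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    t = np.zeros(k)
    p = np.ones(k)
    degenerate = []
    for j in range(k):
        if sds[j] == 0:
            degenerate.append(j)
            if means[j] != neutral:
                t[j], p[j] = np.inf, 0.0
                log.warning("scenario %d has zero variance with nonzero mean", j)
            continue
        t[j] = (means[j] - neutral) / (sds[j] / np.sqrt(n))
        p[j] = 2 * stats.t.sf(abs(t[j]), n - 1)
    return PosthocResult(
        t=t, p_raw=p, p_adjusted=holm_adjust(p), means=means, degenerate=degenerate
    )


# ---------------------------------------------------------------------------
# Intraclass correlation
# ---------------------------------------------------------------------------


def icc_consistency(ratings: np.ndarray, variant: str = "icc3k") -> float:
    """Intraclass correlation of a complete subject x scenario matrix.

    Default is the two-way mixed, consistency, average-measures coefficient
    ICC(3,k) = (MS_R - MS_E) / MS_R, measuring how consistently a rating
    orders subjects across the scenarios.  ICC(2,1) and ICC(2,k)
    (absolute-agreement, random scenarios) are available via ``variant``.
    """
    X = np.asarray(ratings, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise DesignError("need a complete matrix with >=2 subjects and >=2 scenarios")
    if np.isnan(X).any():
        raise DesignError("ICC requires a complete matrix")
    n, k = X.shape
    grand = X.mean()
    row_means = X.mean(axis=1)
    col_means = X.mean(axis=0)
    ss_rows = k * float(((row_means - grand) ** 2).sum())
    ss_cols = n * float(((col_means - grand) ** 2).sum())
    ss_tot = float(((X - grand) ** 2).sum())
    ss_err = ss_tot - ss_rows - ss_cols
    ms_r = ss_rows / (n - 1)
    ms_c = ss_cols / (k - 1)
    ms_e = ss_err / ((n - 1) * (k - 1))
    if ms_r <= 0:
        raise DegenerateDataError("zero between-subject variance; ICC undefined")
    if variant == "icc3k":
        return (ms_r - ms_e) / ms_r
    if variant == "icc2_1":
        return (ms_r - ms_e) / (ms_r + (k - 1) * ms_e + k * (ms_c - ms_e) / n)
    if variant == "icc2k":
        return (ms_r - ms_e) / (ms_r + (ms_c - ms_e) / n)
    raise ValueError(f"unknown ICC variant {variant!r}")


# ---------------------------------------------------------------------------
# PANAS pre/post change
# ---------------------------------------------------------------------------


@dataclass
class PANASChangeResult:
    """Pre-to-post change in positive and negative affect.

    ``F`` tests the scale x change interaction, i.e. a one-sample F on the
    per-subject difference of change scores (delta NA - delta PA) — the
    contrast asking whether negative affect rose while positive affect
    fell.  This interpretation of the omnibus change test is recorded here
    because pre/post designs admit several equivalent-looking contrasts.
    """

    delta_pa: float
    delta_pa_ci: tuple[float, float]
    delta_na: float
    delta_na_ci: tuple[float, float]
    F: float
    df1: int
    df2: int
    p: float
    partial_eta_sq: float
    n: int
    contrast: str = "scale x change interaction (one-sample F on dNA - dPA)"

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["delta_pa_ci"] = list(self.delta_pa_ci)
        d["delta_na_ci"] = list(self.delta_na_ci)
        return d


def _mean_ci(x: np.ndarray, level: float = 0.95) -> tuple[float, tuple[float, float]]:
    n = x.size
    m = float(x.mean())
    se = float(x.std(ddof=1) / np.sqrt(n))
    tcrit = stats.t.ppf(0.5 + level / 2, n - 1)
    return m, (m - tcrit * se, m + tcrit * se)


def panas_change(records: Sequence[PANASRecord]) -> PANASChangeResult:
    """Mean change in PA and NA with 95% CIs and the scale x change F."""
    n = len(records)
    if n < 3:
        raise SampleSizeError(f"PANAS change analysis needs >=3 subjects, got {n}")
    d_pa = np.array([r.pa_post - r.pa_pre for r in records], dtype=float)
    d_na = np.array([r.na_post - r.na_pre for r in records], dtype=float)
    m_pa, ci_pa = _mean_ci(d_pa)
    m_na, ci_na = _mean_ci(d_na)
    diff = d_na - d_pa
    sd = diff.std(ddof=1)
    if sd == 0:
        F, p = (0.0, 1.0) if diff.mean() == 0 else (np.inf, 0.0)
    else:
        t = diff.mean() / (sd / np.sqrt(n))
        F = t * t
        p = float(stats.f.sf(F, 1, n - 1))
    eta = F / (F + (n - 1)) if np.isfinite(F) else 1.0
    return PANASChangeResult(
        delta_pa=m_pa, delta_pa_ci=ci_pa, delta_na=m_na, delta_na_ci=ci_na,
        F=float(F), df1=1, df2=n - 1, p=p, partial_eta_sq=float(eta), n=n,
    )


# ---------------------------------------------------------------------------
# Subject-level correlations
# ---------------------------------------------------------------------------


@dataclass
class CorrelationResult:
    r: float
    p: float
    n: int
    var_a: str
    var_b: str

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def subject_level_correlation(
    table: TrialTable, var_a: str, var_b: str
) -> CorrelationResult:
    """Pearson correlation between subject-level means of two variables.

    Trial-level variables are first averaged (unweighted) within subject;
    subject-constant covariates are unchanged by the averaging.
    """
    df = table.dropna_for([var_a, var_b])
    grouped = df.groupby("subject_id")
    a = grouped[var_a].mean().to_numpy(float)
    b = grouped[var_b].mean().to_numpy(float)
    if len(a) < 3:
        raise SampleSizeError("correlation needs >=3 subjects after aggregation")
    if a.std(ddof=1) == 0 or b.std(ddof=1) == 0:
        raise DegenerateDataError("zero variance; correlation undefined")
    r, p = stats.pearsonr(a, b)
    return CorrelationResult(r=float(r), p=float(p), n=len(a), var_a=var_a, var_b=var_b)
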