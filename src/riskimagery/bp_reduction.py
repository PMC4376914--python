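"""Cardiovascular stress-reactivity reduction for cuff blood pressure.

Raw cuff readings (systolic/diastolic, mmHg) acquired across a
pre-baseline, a training scenario, five risky-scenario visualizations, and
a post-baseline are reduced to z-scored Mean Arterial Pressure (MAP)
indicators in five steps:

1. every reading is converted to MAP = 2/3 * diastolic + 1/3 * systolic;
2. the first three pre-baseline readings, the training reading, and the
   first post-baseline reading are discarded (habituation to the lab and
   post-stress recovery), leaving 15 of the canonical 20;
3. the 15 retained MAPs are z-scored within subject (sample SD, n-1);
4. the five remaining pre-baseline and five remaining post-baseline
   z-scores are averaged separately;
5. the five visualization z-scores are kept, keyed by risk domain, as the
   psychophysiological stress indicators.

Within-subject z-scoring removes stable individual differences in
absolute blood pressure, so the indicators are comparable across
subjects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .anova_reliability import RMAnovaEffect, rm_anova
from .data_model import BPSeries, CANONICAL_BP_LAYOUT
from .exceptions import (
    DegenerateDataError,
    DomainViolationError,
    LayoutError,
    SampleSizeError,
)

__all__ = ["ReducedBP", "PhaseContrastResult", "map_from_cuff", "reduce_bp_series", "phase_contrast"]

log = logging.getLogger(__name__)


def map_from_cuff(systolic, diastolic):
    """Mean Arterial Pressure from one cuff reading: 2/3*DY + 1/3*SY.

    Accepts scalars or arrays (mmHg).  Requires systolic > diastolic > 0.
    """
    sy = np.asarray(systolic, dtype=float)
    dy = np.asarray(diastolic, dtype=float)
    if np.any(~(sy > dy)) or np.any(~(dy > 0)):
        raise DomainViolationError(
            "require systolic > diastolic > 0 for every reading"
        )
    out = (2.0 / 3.0) * dy + (1.0 / 3.0) * sy
    return float(out) if out.ndim == 0 else out


@dataclass
class ReducedBP:
    """Z-scored MAP stress indicators for one subject.

    ``zscores`` holds all 15 retained within-subject z-scores in
    acquisition order (5 pre-baseline, 5 visualization, 5 post-baseline).
    """

    subject_id: object
    pre_baseline_mean: float
    post_baseline_mean: float
    visualization: Mapping[str, float]
    zscores: np.ndarray = field(repr=False, default=None)

    @property
    def visualization_mean(self) -> float:
        return float(np.mean(list(self.visualization.values())))

    def to_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "pre_baseline_mean": self.pre_baseline_mean,
            "post_baseline_mean": self.post_baseline_mean,
            "visualization": dict(self.visualization),
        }


def _check_layout(series: BPSeries) -> None:
    phases = list(series.readings["phase"])
    expected = (
        ["pre_baseline"] * CANONICAL_BP_LAYOUT["pre_baseline"]
        + ["training"] * CANONICAL_BP_LAYOUT["training"]
        + ["scenario"] * CANONICAL_BP_LAYOUT["scenario"]
        + ["post_baseline"] * CANONICAL_BP_LAYOUT["post_baseline"]
    )
    if phases != expected:
        counts = {ph: phases.count(ph) for ph in CANONICAL_BP_LAYOUT}
        raise LayoutError(
            f"subject {series.subject_id}: non-canonical layout {counts} "
            f"(expected {CANONICAL_BP_LAYOUT}, in acquisition order)"
        )
    doms = list(series.readings.loc[series.readings["phase"] == "scenario", "scenario_domain"])
    if len(set(doms)) != len(doms) or any(d is None or (isinstance(d, float) and np.isnan(d)) for d in doms):
        raise LayoutError(
            f"subject {series.subject_id}: scenario readings must carry 5 distinct risk domains, got {doms}"
        )


def reduce_bp_series(series: BPSeries) -> ReducedBP:
    """Apply the five-step MAP reduction to one canonical 20-reading series."""
    _check_layout(series)
    df = series.readings
    map_all = map_from_cuff(df["systolic"].to_numpy(), df["diastolic"].to_numpy())
    # discard: pre-baseline 1-3 (indices 0..2), training (8), first post-baseline (14)
    keep = np.ones(20, dtype=bool)
    keep[[0, 1, 2, 8, 14]] = False
    retained = map_all[keep]  # 5 pre, 5 visualization, 5 post, acquisition order
    sd = retained.std(ddof=1)
    if sd == 0:
        raise DegenerateDataError(
            f"subject {series.subject_id}: all retained MAPs identical; z-score undefined"
        )
    z = (retained - retained.mean()) / sd
    doms = list(df.loc[df["phase"] == "scenario", "scenario_domain"])
    log.debug("subject %s: retained %d of %d readings", series.subject_id, keep.sum(), len(keep))
    return ReducedBP(
        subject_id=series.subject_id,
        pre_baseline_mean=float(z[:5].mean()),
        post_baseline_mean=float(z[10:].mean()),
        visualization={d: float(v) for d, v in zip(doms, z[5:10])},
        zscores=z,
    )


@dataclass
class PhaseContrastResult:
    """One-way repeated-measures ANOVA over the three phase means
    (pre-baseline, visualization, post-baseline) plus paired follow-ups."""

    anova: RMAnovaEffect
    phase_means: Mapping[str, float]
    pairwise_p: Mapping[str, float]  # uncorrected paired t-tests
    n: int

    def to_dict(self) -> dict:
        return {
            "anova": self.anova.to_dict(),
            "phase_means": dict(self.phase_means),
            "pairwise_p": dict(self.pairwise_p),
            "n": self.n,
        }


def phase_contrast(reduced: Sequence[ReducedBP]) -> PhaseContrastResult:
    """Test whether visualization blood pressure exceeds both baselines.

    Builds the n x 3 matrix of per-subject phase means and runs a one-way
    repeated-measures ANOVA (3 levels), then uncorrected paired t-tests as
    follow-ups.
    """
    n = len(reduced)
    if n < 3:
        raise SampleSizeError(f"phase contrast needs >=3 subjects, got {n}")
    mat = np.array(
        [[r.pre_baseline_mean, r.visualization_mean, r.post_baseline_mean] for r in reduced]
    )
    eff = rm_anova(mat, factors=[("phase", 3)])["phase"]
    labels = ("pre_baseline", "visualization", "post_baseline")
    pairs = {}
    for i, j in ((0, 1), (1, 2), (0, 2)):
        d = mat[:, i] - mat[:, j]
        if d.std(ddof=1) == 0:
            p = 1.0 if d.mean() == 0 else 0.0
        else:
            p = float(stats.ttest_rel(mat[:, i], mat[:, j]).pvalue)
        pairs[f"{labels[i]} vs {labels[j]}"] = p
    return PhaseContrastResult(
        anova=eff,
        phase_means={lab: float(mat[:, k].mean()) for k, lab in enumerate(labels)},
        pairwise_p=pairs,
        n=n,
    )
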