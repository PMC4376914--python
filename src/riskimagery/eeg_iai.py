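"""EEG preprocessing and the Imagery Alpha Index (IAI).

Parieto-occipital alpha power (8-13 Hz) drops when a person engages in
visual mental imagery; the IAI quantifies that attenuation as the ratio of
resting (baseline) alpha power to task alpha power, so higher values mean
stronger imagery-related cortical activation while individual differences
in resting alpha cancel out.

Processing chain per channel:

1. zero-phase band-pass filter, 0.1-35 Hz (linear-phase FIR applied with
   group-delay compensation, so no phase distortion);
2. split each event segment into consecutive non-overlapping 2 s epochs
   (partial trailing windows discarded);
3. reject epochs whose absolute amplitude exceeds 70 uV (artifacts);
4. per kept epoch, a rectangular-window periodogram; alpha power is the
   mean spectral density over the 8-13 Hz bins (inclusive; 2 s epochs give
   0.5 Hz resolution), averaged across kept epochs;
5. IAI = mean alpha power of the two baseline segments / mean alpha power
   of the two scenarios of a risk domain, per subject x electrode x
   domain x phase.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

from .data_model import EEGRecording, IAITable, IMAGERY_CHANNELS, Segment
from .exceptions import (
    CoverageError,
    DegenerateDataError,
    ParameterError,
    SegmentError,
)

__all__ = [
    "EpochSet",
    "AlphaPower",
    "bandpass_filter",
    "epoch_and_reject",
    "alpha_power",
    "compute_iai",
    "aggregate_iai",
    "iai_table_from_recording",
]

log = logging.getLogger(__name__)

ALPHA_BAND = (8.0, 13.0)
EPOCH_SECONDS = 2.0
ARTIFACT_THRESHOLD_UV = 70.0


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------


def bandpass_filter(
    x: np.ndarray,
    sampling_rate: float,
    low: float = 0.1,
    high: float = 35.0,
    numtaps: int | None = None,
) -> np.ndarray:
    """Zero-phase FIR band-pass; output length equals input length.

    The mean is removed first (a finite FIR cannot null DC when the
    high-pass edge is as low as 0.1 Hz), then a linear-phase FIR band-pass
    is applied with group-delay compensation.  The default tap count (4 s
    of filter, odd) keeps the transition band below 1 Hz — far from the
    8-13 Hz alpha band — without smearing segment boundaries excessively.
    Applied along the first axis.
    """
    x = np.asarray(x, dtype=float)
    nyq = sampling_rate / 2.0
    if high >= nyq:
        raise ParameterError(f"high cutoff {high} Hz >= Nyquist {nyq} Hz")
    if not (0 < low < high):
        raise ParameterError(f"need 0 < low < high, got ({low}, {high})")
    if numtaps is None:
        numtaps = int(4 * sampling_rate) + 1
    if numtaps % 2 == 0:
        numtaps += 1
    h = sps.firwin(numtaps, [low, high], pass_zero=False, fs=sampling_rate)
    pad = numtaps // 2

    def _one(col: np.ndarray) -> np.ndarray:
        col = col - col.mean()
        xp = np.pad(col, pad, mode="reflect")
        return sps.fftconvolve(xp, h, mode="same")[pad:-pad]

    if x.ndim == 1:
        return _one(x)
    return np.column_stack([_one(x[:, j]) for j in range(x.shape[1])])


# ---------------------------------------------------------------------------
# Epoching and artifact rejection
# ---------------------------------------------------------------------------


@dataclass
class EpochSet:
    """Fixed-length epochs cut from one segment of one channel."""

    subject_id: object
    electrode: str
    segment_kind: str
    scenario_id: object
    domain: str | None
    epochs: np.ndarray  # (n_epochs, epoch_samples)
    kept_mask: np.ndarray  # bool per epoch

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_kept(self) -> int:
        return int(self.kept_mask.sum())

    @property
    def rejection_fraction(self) -> float:
        return 1.0 - self.n_kept / self.n_epochs


def epoch_and_reject(
    x: np.ndarray,
    sampling_rate: float,
    segment: Segment | None = None,
    threshold: float = ARTIFACT_THRESHOLD_UV,
    epoch_seconds: float = EPOCH_SECONDS,
    criterion: str = "absolute",
    subject_id: object = None,
    electrode: str = "",
) -> EpochSet:
    """Cut a signal (or the segment of it) into 2 s epochs and flag artifacts.

    An epoch is rejected iff its amplitude exceeds ``threshold`` uV under
    the chosen criterion: ``"absolute"`` (any |x| > threshold, the default)
    or ``"peak_to_peak"`` (max - min > threshold).
    """
    x = np.asarray(x, dtype=float)
    if segment is not None:
        x = x[segment.start_sample : segment.end_sample]
    epoch_len = int(round(epoch_seconds * sampling_rate))
    n_epochs = len(x) // epoch_len
    if n_epochs < 1:
        raise SegmentError(
            f"segment of {len(x)} samples shorter than one epoch ({epoch_len} samples)"
        )
    epochs = x[: n_epochs * epoch_len].reshape(n_epochs, epoch_len)
    if criterion == "absolute":
        exceed = np.abs(epochs).max(axis=1) > threshold
    elif criterion == "peak_to_peak":
        exceed = (epochs.max(axis=1) - epochs.min(axis=1)) > threshold
    else:
        raise ParameterError(f"unknown artifact criterion {criterion!r}")
    es = EpochSet(
        subject_id=subject_id,
        electrode=electrode,
        segment_kind=segment.segment_kind if segment else "",
        scenario_id=segment.scenario_id if segment else None,
        domain=segment.domain if segment else None,
        epochs=epochs,
        kept_mask=~exceed,
    )
    if es.rejection_fraction > 0:
        log.debug(
            "%s %s %s: rejected %d/%d epochs",
            subject_id, electrode, es.segment_kind, es.n_epochs - es.n_kept, es.n_epochs,
        )
    return es


# ---------------------------------------------------------------------------
# Alpha power
# ---------------------------------------------------------------------------


@dataclass
class AlphaPower:
    """Mean alpha-band (8-13 Hz) spectral density (uV^2/Hz) over kept epochs."""

    subject_id: object
    electrode: str
    segment_kind: str
    domain: str | None
    power: float
    n_epochs: int
    n_kept: int


def alpha_power(
    epochs: EpochSet,
    sampling_rate: float,
    band: tuple[float, float] = ALPHA_BAND,
) -> AlphaPower:
    """Rectangular-window periodogram alpha power of an epoch set.

    Per epoch, the one-sided periodogram density is averaged over the
    frequency bins inside ``band`` (endpoints inclusive); the epoch values
    are then averaged over kept epochs.
    """
    kept = epochs.epochs[epochs.kept_mask]
    if kept.shape[0] == 0:
        raise DegenerateDataError(
            f"all {epochs.n_epochs} epochs rejected for "
            f"{epochs.subject_id}/{epochs.electrode}/{epochs.segment_kind}"
        )
    freqs, psd = sps.periodogram(kept, fs=sampling_rate, window="boxcar", axis=1)
    sel = (freqs >= band[0]) & (freqs <= band[1])
    power = float(psd[:, sel].mean(axis=1).mean())
    return AlphaPower(
        subject_id=epochs.subject_id,
        electrode=epochs.electrode,
        segment_kind=epochs.segment_kind,
        domain=epochs.domain,
        power=power,
        n_epochs=epochs.n_epochs,
        n_kept=epochs.n_kept,
    )


# ---------------------------------------------------------------------------
# IAI
# ---------------------------------------------------------------------------


def compute_iai(
    baseline_powers: Sequence[float],
    task_powers: Sequence[float],
) -> float:
    """IAI = mean baseline alpha power / mean task alpha power.

    ``baseline_powers`` are the two baseline-segment powers (averaged with
    equal weight regardless of epoch counts); ``task_powers`` are the
    powers of the scenarios belonging to one risk domain and phase.
    """
    b = np.asarray(baseline_powers, dtype=float)
    t = np.asarray(task_powers, dtype=float)
    if b.size == 0 or t.size == 0 or np.any(b <= 0) or np.any(t <= 0):
        raise DegenerateDataError("IAI requires strictly positive baseline and task powers")
    return float(b.mean() / t.mean())


def iai_table_from_recording(
    rec: EEGRecording,
    threshold: float = ARTIFACT_THRESHOLD_UV,
    criterion: str = "absolute",
    filter_kwargs: dict | None = None,
) -> IAITable:
    """Full preprocessing of one recording into IAI rows.

    Filters every channel, epochs every event segment, rejects artifacts,
    computes alpha power, and forms the IAI per electrode x domain x phase
    (listening and visualization, each against the same two baselines).
    Baseline segments contribute their full duration.
    """
    filt = bandpass_filter(rec.signal, rec.sampling_rate, **(filter_kwargs or {}))
    rows = []
    for ci, ch in enumerate(rec.channels):
        x = filt[:, ci]
        base_powers = []
        task: dict[tuple[str, str], list[float]] = {}
        for ev in rec.events:
            es = epoch_and_reject(
                x, rec.sampling_rate, segment=ev, threshold=threshold,
                criterion=criterion, subject_id=rec.subject_id, electrode=ch,
            )
            ap = alpha_power(es, rec.sampling_rate)
            if ev.segment_kind == "baseline":
                base_powers.append(ap.power)
            else:
                task.setdefault((ev.domain, ev.segment_kind), []).append(ap.power)
        for (domain, phase), powers in task.items():
            rows.append(
                {
                    "subject_id": rec.subject_id,
                    "electrode": ch,
                    "domain": domain,
                    "phase": phase,
                    "iai": compute_iai(base_powers, powers),
                }
            )
    return IAITable(pd.DataFrame(rows))


def aggregate_iai(
    table: IAITable,
    electrodes: Iterable[str] = IMAGERY_CHANNELS,
    phase: str = "visualization",
) -> pd.DataFrame:
    """Mean IAI across imagery electrodes, per subject x domain.

    Only the requested phase (visualization by default) enters; a missing
    electrode raises :class:`CoverageError`.
    """
    electrodes = sorted(electrodes)
    df = table.df
    present = set(df["electrode"])
    missing = [e for e in electrodes if e not in present]
    if missing:
        raise CoverageError(f"electrodes {missing} absent from IAI table")
    sub = df[(df["phase"] == phase) & (df["electrode"].isin(electrodes))]
    out = (
        sub.groupby(["subject_id", "domain"], sort=False)["iai"]
        .mean()
        .reset_index()
        .rename(columns={"iai": "iai_mean"})
    )
    return out
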