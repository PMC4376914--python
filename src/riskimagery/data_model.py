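"""Domain types, file readers/writers, and validation for pipeline data.

The pipeline works on four kinds of raw data:

* long-format trial tables (one row per subject x scenario/domain with
  ratings and subject-level covariates),
* ordered cuff blood-pressure series with phase labels,
* PANAS positive/negative affect sums taken before and after the imagery
  task,
* multichannel 200 Hz EEG recordings with an event sidecar marking
  baseline / listening / visualization segments,

plus one derived table (the Imagery Alpha Index per subject, electrode,
domain and phase).  All tabular formats are delimited text; the reader
auto-detects tab/comma/semicolon delimiters and decimal comma vs. point,
because deposited behavioural TXT files frequently use locale-specific
dialects.  Results are serialized to JSON together with a software
fingerprint so a report can always be traced to the code that produced it.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import CoverageError, IntegrityError, SchemaError

__all__ = [
    "DOMAINS",
    "CHANNELS",
    "IMAGERY_CHANNELS",
    "TrialSchema",
    "TrialTable",
    "BPSeries",
    "PANASRecord",
    "Segment",
    "EEGRecording",
    "IAITable",
    "read_trial_table",
    "write_trial_table",
    "read_bp_series",
    "write_bp_series",
    "read_panas",
    "write_panas",
    "read_eeg",
    "write_eeg",
    "read_iai_table",
    "write_iai_table",
    "write_results",
    "read_results",
]

log = logging.getLogger(__name__)

#: The five risk domains used throughout (Weber et al. taxonomy).
DOMAINS = ("financial", "health/safety", "recreational", "ethical", "social")

#: Electrode montage: occipital and parietal imagery sites plus prefrontal
#: control sites, both hemispheres.
CHANNELS = ("Fp1", "Fp2", "P3", "P4", "O1", "O2")

#: Parieto-occipital sites associated with visual mental imagery.
IMAGERY_CHANNELS = ("O1", "O2", "P3", "P4")

#: Blood-pressure phases in acquisition order.
BP_PHASES = ("pre_baseline", "training", "scenario", "post_baseline")

#: EEG segment kinds.
SEGMENT_KINDS = ("baseline", "listening", "visualization")

# ---------------------------------------------------------------------------
# Delimited-text dialect sniffing
# ---------------------------------------------------------------------------

_CANDIDATE_DELIMS = ("\t", ";", ",")


def _sniff_dialect(text: str) -> tuple[str, str]:
    """Guess (delimiter, decimal) from a sample of a delimited text file."""
    header = text.splitlines()[0] if text else ""
    counts = {d: header.count(d) for d in _CANDIDATE_DELIMS}
    delim = max(_CANDIDATE_DELIMS, key=lambda d: counts[d])
    if counts[delim] == 0:
        delim = "\t"
    if delim == ",":
        decimal = "."
    else:
        # decimal commas appear as digit,digit inside fields
        decimal = "," if re.search(r"\d,\d", text) else "."
    return delim, decimal


def _read_delimited(path: str | Path) -> pd.DataFrame:
    text = Path(path).read_text()
    delim, decimal = _sniff_dialect(text)
    return pd.read_csv(path, sep=delim, decimal=decimal)


# ---------------------------------------------------------------------------
# Trial tables
# ---------------------------------------------------------------------------

#: Canonical rating/covariate columns.  ``x`` is the study-specific
#: predictor (recoded thought valence, imagery vividness, or mean IAI).
RATING_COLUMNS = ("x", "stress", "risk_perception", "risk_taking")
COVARIATE_COLUMNS = ("stai", "siri")
OUTCOME_COLUMNS = RATING_COLUMNS


@dataclass(frozen=True)
class TrialSchema:
    """Scale declaration for a trial table.

    ``bounds`` maps a column name to its inclusive (low, high) rating
    bounds, or ``None`` for an unbounded (continuous/latent) column.
    Columns absent from ``bounds`` are not validated numerically.
    """

    bounds: Mapping[str, tuple[float, float] | None]
    required: tuple[str, ...] = ("subject_id", "item_id", "x")

    @classmethod
    def study1(cls) -> "TrialSchema":
        """Recoded thought valence -2..+2; stress/risk perception 1-10;
        risk taking 1-5."""
        return cls(
            bounds={
                "x": (-2, 2),
                "stress": (1, 10),
                "risk_perception": (1, 10),
                "risk_taking": (1, 5),
            }
        )

    @classmethod
    def study2(cls) -> "TrialSchema":
        """Imagery vividness 1-10; all other ratings 1-10."""
        return cls(
            bounds={
                "x": (1, 10),
                "stress": (1, 10),
                "risk_perception": (1, 10),
                "risk_taking": (1, 10),
            }
        )

    @classmethod
    def study3(cls) -> "TrialSchema":
        """Mean IAI (positive ratio) as predictor; risk perception 1-10;
        risk taking 1-5."""
        return cls(
            bounds={
                "x": (0, np.inf),
                "risk_perception": (1, 10),
                "risk_taking": (1, 5),
            }
        )

    @classmethod
    def unbounded(cls) -> "TrialSchema":
        """No numeric bounds — for continuous latent (undiscretized) data."""
        return cls(bounds={})


@dataclass
class TrialTable:
    """Long-format observations: one row per subject x item.

    Invariants checked by :meth:`validate`:

    * ratings fall inside the declared scale bounds,
    * every (subject_id, item_id) pair is unique,
    * subject-level covariates (stai, siri) are constant within subject,
    * no row has every outcome field absent.
    """

    df: pd.DataFrame
    schema: TrialSchema = field(default_factory=TrialSchema.unbounded)

    def __post_init__(self):
        self.validate()

    # -- convenience ------------------------------------------------------
    @property
    def n_rows(self) -> int:
        return len(self.df)

    @property
    def subjects(self) -> list:
        return list(pd.unique(self.df["subject_id"]))

    @property
    def items(self) -> list:
        return list(pd.unique(self.df["item_id"]))

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_items(self) -> int:
        return len(self.items)

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        df = self.df
        for col in self.schema.required:
            if col not in df.columns:
                raise SchemaError(f"missing mandatory column {col!r}")
        dup = df.duplicated(subset=["subject_id", "item_id"])
        if dup.any():
            pairs = df.loc[dup, ["subject_id", "item_id"]].iloc[:3]
            raise IntegrityError(
                "duplicate (subject_id, item_id) pairs, e.g. "
                + ", ".join(f"({r.subject_id}, {r.item_id})" for r in pairs.itertuples())
            )
        for col, bounds in self.schema.bounds.items():
            if bounds is None or col not in df.columns:
                continue
            lo, hi = bounds
            vals = pd.to_numeric(df[col], errors="coerce")
            bad = vals.notna() & ((vals < lo) | (vals > hi))
            if bad.any():
                rows = list(df.index[bad][:5])
                raise IntegrityError(
                    f"column {col!r} outside declared bounds [{lo}, {hi}] "
                    f"at rows {rows}"
                )
        for col in COVARIATE_COLUMNS:
            if col in df.columns:
                nun = df.groupby("subject_id")[col].nunique(dropna=True)
                varying = nun[nun > 1]
                if len(varying):
                    raise IntegrityError(
                        f"covariate {col!r} varies within subjects "
                        f"{list(varying.index[:5])}"
                    )
        outcome_cols = [c for c in OUTCOME_COLUMNS if c in df.columns]
        if outcome_cols and len(df):
            all_absent = df[outcome_cols].isna().all(axis=1)
            if all_absent.any():
                raise IntegrityError(
                    f"rows with every outcome absent: {list(df.index[all_absent][:5])}"
                )

    def dropna_for(self, columns: Sequence[str]) -> pd.DataFrame:
        """Listwise deletion restricted to the columns one model uses."""
        cols = [c for c in columns if c in self.df.columns]
        out = self.df.dropna(subset=cols)
        n_dropped = len(self.df) - len(out)
        if n_dropped:
            log.info("dropped %d rows with missing values in %s", n_dropped, cols)
        return out


def read_trial_table(path: str | Path, schema: TrialSchema) -> TrialTable:
    """Read a delimited trial table, validating against ``schema``.

    Auto-detects the delimiter (tab/comma/semicolon) and decimal mark.
    An empty file with a header yields an empty (valid) table with a
    logged warning.
    """
    df = _read_delimited(path)
    if df.empty:
        log.warning("trial table %s contains a header but no rows", path)
    return TrialTable(df=df, schema=schema)


def write_trial_table(table: TrialTable, path: str | Path) -> None:
    table.df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Blood pressure
# ---------------------------------------------------------------------------

#: Canonical reading counts per phase: 8 pre-baseline, 1 training,
#: 5 scenario (one per risk domain), 6 post-baseline.
CANONICAL_BP_LAYOUT = {"pre_baseline": 8, "training": 1, "scenario": 5, "post_baseline": 6}


@dataclass
class BPSeries:
    """Ordered cuff readings for one subject.

    ``readings`` columns: phase, scenario_domain (domain label when
    phase == "scenario", else NA), systolic, diastolic (mmHg).  Rows
    preserve acquisition order.
    """

    subject_id: Any
    readings: pd.DataFrame

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        df = self.readings
        for col in ("phase", "systolic", "diastolic"):
            if col not in df.columns:
                raise SchemaError(f"BP series missing column {col!r}")
        unknown = set(df["phase"]) - set(BP_PHASES)
        if unknown:
            raise SchemaError(f"unknown BP phases {sorted(unknown)}")
        sy = df["systolic"].to_numpy(float)
        dy = df["diastolic"].to_numpy(float)
        bad = ~((sy > dy) & (dy > 0))
        if bad.any():
            raise IntegrityError(
                f"subject {self.subject_id}: readings with systolic <= diastolic "
                f"or non-positive pressure at rows {list(np.flatnonzero(bad)[:5])}"
            )


def read_bp_series(path: str | Path) -> list[BPSeries]:
    """Read a delimited file of cuff readings for one or more subjects.

    Expected columns: subject_id, phase, scenario_domain, systolic,
    diastolic.  Row order within subject is acquisition order.
    """
    df = _read_delimited(path)
    if "subject_id" not in df.columns:
        raise SchemaError("BP file missing column 'subject_id'")
    out = []
    for sid, grp in df.groupby("subject_id", sort=False):
        out.append(BPSeries(subject_id=sid, readings=grp.drop(columns="subject_id").reset_index(drop=True)))
    return out


def write_bp_series(series: Iterable[BPSeries], path: str | Path) -> None:
    frames = []
    for s in series:
        df = s.readings.copy()
        df.insert(0, "subject_id", s.subject_id)
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# PANAS
# ---------------------------------------------------------------------------


@dataclass
class PANASRecord:
    """Positive/negative affect sums (10 items each, range 10-50) pre and
    post the imagery task, for one subject."""

    subject_id: Any
    pa_pre: float
    pa_post: float
    na_pre: float
    na_post: float

    def __post_init__(self):
        for name in ("pa_pre", "pa_post", "na_pre", "na_post"):
            v = getattr(self, name)
            if not (10 <= v <= 50):
                raise IntegrityError(
                    f"subject {self.subject_id}: {name}={v} outside PANAS range [10, 50]"
                )


def read_panas(path: str | Path) -> list[PANASRecord]:
    df = _read_delimited(path)
    needed = {"subject_id", "pa_pre", "pa_post", "na_pre", "na_post"}
    missing = needed - set(df.columns)
    if missing:
        raise SchemaError(f"PANAS file missing columns {sorted(missing)}")
    return [
        PANASRecord(r.subject_id, r.pa_pre, r.pa_post, r.na_pre, r.na_post)
        for r in df.itertuples(index=False)
    ]


def write_panas(records: Iterable[PANASRecord], path: str | Path) -> None:
    pd.DataFrame([dataclasses.asdict(r) for r in records]).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# EEG
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Segment:
    """An event segment: 0-based, half-open [start_sample, end_sample)."""

    segment_kind: str
    scenario_id: Any
    domain: str | None
    start_sample: int
    end_sample: int

    @property
    def n_samples(self) -> int:
        return self.end_sample - self.start_sample


@dataclass
class EEGRecording:
    """Multichannel EEG signal (uV) plus event segments.

    ``signal`` has shape (n_samples, n_channels) matching ``channels``.
    Segments must lie within the signal and not overlap; visualization
    segments of risky scenarios span 30 s.
    """

    subject_id: Any
    sampling_rate: float
    channels: tuple[str, ...]
    signal: np.ndarray
    events: list[Segment]

    def __post_init__(self):
        self.signal = np.asarray(self.signal, dtype=float)
        self.channels = tuple(self.channels)
        self.validate()

    @property
    def n_samples(self) -> int:
        return self.signal.shape[0]

    def channel(self, name: str) -> np.ndarray:
        try:
            idx = self.channels.index(name)
        except ValueError:
            raise CoverageError(f"channel {name!r} not present in recording") from None
        return self.signal[:, idx]

    def validate(self) -> None:
        unknown = set(self.channels) - set(CHANNELS)
        if unknown:
            raise SchemaError(f"unknown channel names {sorted(unknown)}")
        if self.signal.ndim != 2 or self.signal.shape[1] != len(self.channels):
            raise SchemaError(
                f"signal shape {self.signal.shape} does not match "
                f"{len(self.channels)} channels"
            )
        n = self.n_samples
        spans = []
        for ev in self.events:
            if ev.segment_kind not in SEGMENT_KINDS:
                raise SchemaError(f"unknown segment kind {ev.segment_kind!r}")
            if not (0 <= ev.start_sample < ev.end_sample <= n):
                raise IntegrityError(
                    f"segment {ev} outside signal of length {n}"
                )
            if ev.segment_kind == "visualization" and ev.domain is not None:
                expect = round(30 * self.sampling_rate)
                if ev.n_samples != expect:
                    raise IntegrityError(
                        f"risky visualization segment spans {ev.n_samples} samples, "
                        f"expected {expect} (30 s)"
                    )
            spans.append((ev.start_sample, ev.end_sample))
        spans.sort()
        for (s0, e0), (s1, e1) in zip(spans, spans[1:]):
            if s1 < e0:
                raise IntegrityError(f"overlapping segments [{s0},{e0}) and [{s1},{e1})")


def read_eeg(path_signal: str | Path, path_events: str | Path,
             subject_id: Any = None, sampling_rate: float = 200.0) -> EEGRecording:
    """Read an EEG recording from a delimited numeric matrix plus a JSON
    event sidecar.

    The signal file has one column per channel with a header row of
    channel names.  The events file is a JSON array of segment records
    with keys segment_kind, scenario_id, domain, start_sample, end_sample;
    it may also carry top-level metadata under a ``{"meta": ..., "events":
    [...]}`` layout written by :func:`write_eeg`.
    """
    df = _read_delimited(path_signal)
    payload = json.loads(Path(path_events).read_text())
    if isinstance(payload, dict):
        meta = payload.get("meta", {})
        subject_id = subject_id if subject_id is not None else meta.get("subject_id")
        sampling_rate = meta.get("sampling_rate", sampling_rate)
        raw_events = payload["events"]
    else:
        raw_events = payload
    events = [
        Segment(
            segment_kind=e["segment_kind"],
            scenario_id=e.get("scenario_id"),
            domain=e.get("domain"),
            start_sample=int(e["start_sample"]),
            end_sample=int(e["end_sample"]),
        )
        for e in raw_events
    ]
    return EEGRecording(
        subject_id=subject_id,
        sampling_rate=sampling_rate,
        channels=tuple(df.columns),
        signal=df.to_numpy(float),
        events=events,
    )


def write_eeg(rec: EEGRecording, path_signal: str | Path, path_events: str | Path) -> None:
    pd.DataFrame(rec.signal, columns=list(rec.channels)).to_csv(path_signal, sep="\t", index=False)
    payload = {
        "meta": {"subject_id": rec.subject_id, "sampling_rate": rec.sampling_rate},
        "events": [dataclasses.asdict(ev) for ev in rec.events],
    }
    Path(path_events).write_text(json.dumps(payload, indent=1))


# ---------------------------------------------------------------------------
# IAI table
# ---------------------------------------------------------------------------


@dataclass
class IAITable:
    """Imagery Alpha Index per subject x electrode x domain x phase.

    The IAI is baseline alpha power divided by task alpha power, so it is a
    dimensionless positive ratio; values above 1 indicate task-related
    alpha attenuation (stronger imagery-related activation).
    """

    df: pd.DataFrame

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        needed = {"subject_id", "electrode", "domain", "phase", "iai"}
        missing = needed - set(self.df.columns)
        if missing:
            raise SchemaError(f"IAI table missing columns {sorted(missing)}")
        vals = self.df["iai"].to_numpy(float)
        if not (vals > 0).all():
            raise IntegrityError("IAI values must be strictly positive")
        dup = self.df.duplicated(subset=["subject_id", "electrode", "domain", "phase"])
        if dup.any():
            raise IntegrityError("duplicate (subject, electrode, domain, phase) IAI rows")


def read_iai_table(path: str | Path) -> IAITable:
    return IAITable(_read_delimited(path))


def write_iai_table(table: IAITable, path: str | Path) -> None:
    table.df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Result serialization
# ---------------------------------------------------------------------------


def _fingerprint() -> dict:
    from . import __version__

    return {
        "package": "riskimagery",
        "version": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
    }


def _to_jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        if hasattr(obj, "to_dict"):
            return _to_jsonable(obj.to_dict())
        return {f.name: _to_jsonable(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, Mapping):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="list")
    return obj


def write_results(result: Any, path: str | Path) -> None:
    """Serialize any result object to structured JSON.

    The payload carries estimates, SEs, CIs, test statistics and seeds as
    produced by the analysis, plus a software fingerprint.
    """
    payload = {"result": _to_jsonable(result), "fingerprint": _fingerprint()}
    Path(path).write_text(json.dumps(payload, indent=1, allow_nan=True))


def read_results(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())["result"]
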