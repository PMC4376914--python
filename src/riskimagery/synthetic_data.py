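"""Synthetic datasets with the statistical structure each study assumes.

Every generator draws from an explicit ground-truth model, so pipeline
stages can be tested by parameter recovery without any real recordings:

* ``gen_study1`` — 60 subjects x 10 scenarios (2 per risk domain) of
  ratings following the serial chain x -> stress -> risk perception ->
  risk taking with crossed subject/item random intercepts, plus
  trait-anxiety and risk-propensity covariates correlated with the
  subject-level predictor.
* ``gen_study2`` — 22 subjects x 5 risk domains of vividness-driven
  ratings, a canonical 20-reading cuff blood-pressure series per subject
  (visualization readings elevated in proportion to the subject's
  vividness), and PANAS pre/post records with configured shifts.
* ``gen_study3`` — 16 subjects x 5 domains of ratings following the
  moderated model risk_taking ~ risk_perception * imagery-ability, and
  (optionally) a full 6-channel, 200 Hz EEG recording per subject in
  which the parieto-occipital 10 Hz alpha amplitude during risky
  visualization is attenuated by the subject's imagery factor g, so the
  measured IAI recovers g.

Ratings are generated on a continuous latent scale; ``discretize`` rounds
and clips them to the printed 1-10 / 1-5 scales for end-to-end realism
(recovery tests need the un-coarsened model, so it is off by default).
All draws come from one ``numpy`` Generator seeded explicitly — identical
(config, seed) gives byte-identical output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import (
    BPSeries,
    CHANNELS,
    DOMAINS,
    EEGRecording,
    PANASRecord,
    Segment,
    TrialSchema,
    TrialTable,
)
from .exceptions import ConfigError

__all__ = [
    "Study1Config",
    "Study2Config",
    "Study3Config",
    "gen_study1",
    "gen_study2",
    "gen_study3",
]

log = logging.getLogger(__name__)


def _truncnorm(rng: np.random.Generator, loc, scale: float, lo: float, hi: float, size) -> np.ndarray:
    loc = np.broadcast_to(np.asarray(loc, float), size).ravel()
    if scale == 0:
        return np.clip(loc, lo, hi).reshape(size)
    a = (lo - loc) / scale
    b = (hi - loc) / scale
    draws = stats.truncnorm.rvs(a, b, loc=loc, scale=scale, random_state=rng)
    return draws.reshape(size)


def _check_positive(cfg, names: Sequence[str]) -> None:
    for nm in names:
        if getattr(cfg, nm) < 0:
            raise ConfigError(f"{nm} must be >= 0, got {getattr(cfg, nm)}")


# ---------------------------------------------------------------------------
# Study 1: ratings with a serial mediation chain
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Study1Config:
    """Ground truth for the Study-1-style ratings generator.

    Path coefficients follow the serial chain; variance components are per
    response (the same triple for stress, risk perception and risk
    taking).  The predictor x emulates recoded thought valence: a
    truncated normal on [-2, 2] with a negative-consequence mean of 0.83
    and SD 0.98, plus a subject-level shift correlated with trait anxiety.
    """

    n_subjects: int = 60
    n_items: int = 10
    # serial path coefficients
    a1: float = 1.0
    a2: float = 0.3
    d21: float = 0.5
    b1: float = 0.1
    b2: float = -0.6
    c_prime: float = -0.15
    # predictor (recoded valence)
    x_mean: float = 0.83
    x_sd: float = 0.98
    x_bounds: tuple[float, float] = (-2.0, 2.0)
    x_between_sd: float = 0.6
    # variance components per response (the *_m1/_m2/_y overrides default
    # to the shared values; setting them separately keeps e.g. a noiseless
    # outcome identifiable while the mediators stay stochastic)
    subject_sd: float = 0.5
    item_sd: float = 0.3
    resid_sd: float = 1.0
    resid_sd_m1: float | None = None
    resid_sd_m2: float | None = None
    resid_sd_y: float | None = None
    # intercepts keep ratings near mid-scale
    intercept_m1: float = 4.5
    intercept_m2: float = 5.0
    intercept_y: float = 3.0
    # subject-level covariates
    stai_mean: float = 40.0
    stai_sd: float = 9.0
    stai_x_corr: float = 0.6  # correlation of anxiety latent with x shift
    stai_on_y: float = 0.0
    siri_mean: float = 5.0
    siri_sd: float = 2.0
    siri_on_y: float = 0.15
    discretize: bool = False
    seed: int | None = None


def gen_study1(config: Study1Config = Study1Config(), seed: int | None = None) -> TrialTable:
    """Generate a Study-1-style trial table with known ground truth."""
    cfg = config
    _check_positive(cfg, ["x_sd", "subject_sd", "item_sd", "resid_sd", "stai_sd", "siri_sd"])
    if not (-1 <= cfg.stai_x_corr <= 1):
        raise ConfigError(f"stai_x_corr={cfg.stai_x_corr} outside [-1, 1]")
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    nS, nI = cfg.n_subjects, cfg.n_items
    subj = np.repeat(np.arange(nS), nI)
    item = np.tile(np.arange(nI), nS)
    n = nS * nI

    z_anx = rng.normal(size=nS)  # anxiety latent
    stai = cfg.stai_mean + cfg.stai_sd * (
        cfg.stai_x_corr * z_anx + np.sqrt(1 - cfg.stai_x_corr**2) * rng.normal(size=nS)
    )
    siri = cfg.siri_mean + cfg.siri_sd * rng.normal(size=nS)

    x_subj = cfg.x_mean + cfg.x_between_sd * z_anx
    x = _truncnorm(rng, x_subj[subj], cfg.x_sd, *cfg.x_bounds, size=(n,))

    def effects(resid_sd: float | None) -> np.ndarray:
        us = rng.normal(0, cfg.subject_sd, nS)[subj]
        ui = rng.normal(0, cfg.item_sd, nI)[item]
        e_sd = cfg.resid_sd if resid_sd is None else resid_sd
        return us + ui + rng.normal(0, 1.0, n) * e_sd

    m1 = cfg.intercept_m1 + cfg.a1 * x + effects(cfg.resid_sd_m1)
    m2 = cfg.intercept_m2 + cfg.a2 * x + cfg.d21 * m1 + effects(cfg.resid_sd_m2)
    y = (
        cfg.intercept_y
        + cfg.c_prime * x
        + cfg.b1 * m1
        + cfg.b2 * m2
        + cfg.stai_on_y * (stai[subj] - cfg.stai_mean)
        + cfg.siri_on_y * (siri[subj] - cfg.siri_mean)
        + effects(cfg.resid_sd_y)
    )

    domains = np.array([DOMAINS[i % 5] for i in range(nI)])
    df = pd.DataFrame(
        {
            "subject_id": [f"s{k + 1:02d}" for k in subj],
            "item_id": [f"i{k + 1:02d}" for k in item],
            "domain": domains[item],
            "x": x,
            "stress": m1,
            "risk_perception": m2,
            "risk_taking": y,
            "stai": stai[subj],
            "siri": siri[subj],
        }
    )
    if cfg.discretize:
        schema = TrialSchema.study1()
        for col in ("stress", "risk_perception", "risk_taking"):
            lo, hi = schema.bounds[col]
            df[col] = np.clip(np.round(df[col]), lo, hi)
        df["x"] = np.clip(np.round(df["x"] * 3) / 3, -2, 2)  # mean of 3 thought ratings
        return TrialTable(df=df, schema=schema)
    return TrialTable(df=df, schema=TrialSchema.unbounded())


# ---------------------------------------------------------------------------
# Study 2: vividness ratings, blood pressure, PANAS
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Study2Config:
    """Ground truth for the Study-2-style generator.

    The blood-pressure block emulates cuff readings: a subject-level
    resting MAP with device-scale reading noise (+/- 3 mmHg cuff error),
    elevated during the five visualization readings by ``delta_map`` mmHg
    scaled by the subject's mean vividness relative to the population
    mean.  Systolic and diastolic values are reconstructed from MAP and a
    drawn pulse pressure so that MAP = 2/3 DY + 1/3 SY holds exactly.
    """

    n_subjects: int = 22
    n_items: int = 5  # the five risk domains
    # serial paths (vividness -> stress -> risk perception -> risk taking)
    a1: float = 0.64
    a2: float = 0.3
    d21: float = 0.52
    b1: float = 0.05
    b2: float = -0.64
    c_prime: float = 0.10
    # vividness predictor
    x_mean: float = 6.0
    x_sd: float = 2.0
    x_bounds: tuple[float, float] = (1.0, 10.0)
    x_between_sd: float = 0.8
    subject_sd: float = 0.5
    item_sd: float = 0.3
    resid_sd: float = 1.0
    intercept_m1: float = 1.5
    intercept_m2: float = 2.5
    intercept_y: float = 7.0
    siri_mean: float = 5.0
    siri_sd: float = 2.0
    siri_on_y: float = 0.15
    # blood pressure
    map_mean: float = 90.0
    map_between_sd: float = 7.0
    reading_noise_sd: float = 3.0
    delta_map: float = 4.6  # visualization elevation (mmHg) at mean vividness
    # (calibrated so the mean visualization z-score is ~ +0.8)
    pulse_pressure_mean: float = 40.0
    pulse_pressure_sd: float = 8.0
    # PANAS
    pa_pre_mean: float = 30.0
    na_pre_mean: float = 15.0
    panas_pre_sd: float = 5.0
    pa_shift: float = -2.50
    na_shift: float = 2.67
    panas_change_sd: float = 5.0
    discretize: bool = False
    seed: int | None = None


def gen_study2(
    config: Study2Config = Study2Config(), seed: int | None = None
) -> dict:
    """Generate ratings, BP series and PANAS records for a Study-2 cohort.

    Returns a dict with keys ``trials`` (:class:`TrialTable`), ``bp``
    (list of :class:`BPSeries`) and ``panas`` (list of
    :class:`PANASRecord`).
    """
    cfg = config
    _check_positive(
        cfg,
        [
            "x_sd", "subject_sd", "item_sd", "resid_sd", "map_between_sd",
            "reading_noise_sd", "pulse_pressure_sd", "panas_pre_sd", "panas_change_sd",
        ],
    )
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    nS, nI = cfg.n_subjects, cfg.n_items
    if nI != len(DOMAINS):
        raise ConfigError(f"Study 2 uses the {len(DOMAINS)} risk domains as items")
    subj = np.repeat(np.arange(nS), nI)
    item = np.tile(np.arange(nI), nS)
    n = nS * nI

    siri = cfg.siri_mean + cfg.siri_sd * rng.normal(size=nS)
    x_subj = cfg.x_mean + cfg.x_between_sd * rng.normal(size=nS)
    x = _truncnorm(rng, x_subj[subj], cfg.x_sd, *cfg.x_bounds, size=(n,))

    def effects() -> np.ndarray:
        us = rng.normal(0, cfg.subject_sd, nS)[subj]
        ui = rng.normal(0, cfg.item_sd, nI)[item]
        return us + ui + rng.normal(0, cfg.resid_sd, n)

    m1 = cfg.intercept_m1 + cfg.a1 * x + effects()
    m2 = cfg.intercept_m2 + cfg.a2 * x + cfg.d21 * m1 + effects()
    y = (
        cfg.intercept_y + cfg.c_prime * x + cfg.b1 * m1 + cfg.b2 * m2
        + cfg.siri_on_y * (siri[subj] - cfg.siri_mean) + effects()
    )
    df = pd.DataFrame(
        {
            "subject_id": [f"s{k + 1:02d}" for k in subj],
            "item_id": [DOMAINS[k] for k in item],
            "domain": [DOMAINS[k] for k in item],
            "x": x,
            "stress": m1,
            "risk_perception": m2,
            "risk_taking": y,
            "siri": siri[subj],
        }
    )
    if cfg.discretize:
        schema = TrialSchema.study2()
        for col in ("x", "stress", "risk_perception", "risk_taking"):
            lo, hi = schema.bounds[col]
            df[col] = np.clip(np.round(df[col]), lo, hi)
        trials = TrialTable(df=df, schema=schema)
    else:
        trials = TrialTable(df=df, schema=TrialSchema.unbounded())

    # --- blood pressure ---------------------------------------------------
    bp: list[BPSeries] = []
    x_means = df.groupby("subject_id", sort=False)["x"].mean().to_numpy()
    for s in range(nS):
        sid = f"s{s + 1:02d}"
        base = cfg.map_mean + cfg.map_between_sd * rng.normal()
        elev = cfg.delta_map * (x_means[s] / cfg.x_mean)
        phases = ["pre_baseline"] * 8 + ["training"] + ["scenario"] * 5 + ["post_baseline"] * 6
        dom_order = list(rng.permutation(np.array(DOMAINS)))
        doms = [None] * 9 + dom_order + [None] * 6
        intended = np.full(20, base)
        intended[8] += elev  # training scenario is also a visualization
        intended[9:14] += elev
        map_read = intended + cfg.reading_noise_sd * rng.normal(size=20)
        pp = np.maximum(rng.normal(cfg.pulse_pressure_mean, cfg.pulse_pressure_sd, 20), 10.0)
        sy = map_read + (2.0 / 3.0) * pp
        dy = map_read - (1.0 / 3.0) * pp
        if np.any(dy <= 0):
            raise ConfigError("configuration produced non-positive diastolic pressure")
        bp.append(
            BPSeries(
                subject_id=sid,
                readings=pd.DataFrame(
                    {
                        "phase": phases,
                        "scenario_domain": doms,
                        "systolic": sy,
                        "diastolic": dy,
                    }
                ),
            )
        )

    # --- PANAS --------------------------------------------------------------
    panas: list[PANASRecord] = []
    for s in range(nS):
        pa_pre = np.clip(rng.normal(cfg.pa_pre_mean, cfg.panas_pre_sd), 10, 50)
        na_pre = np.clip(rng.normal(cfg.na_pre_mean, cfg.panas_pre_sd), 10, 50)
        pa_post = np.clip(pa_pre + cfg.pa_shift + cfg.panas_change_sd * rng.normal(), 10, 50)
        na_post = np.clip(na_pre + cfg.na_shift + cfg.panas_change_sd * rng.normal(), 10, 50)
        panas.append(
            PANASRecord(
                subject_id=f"s{s + 1:02d}",
                pa_pre=float(pa_pre), pa_post=float(pa_post),
                na_pre=float(na_pre), na_post=float(na_post),
            )
        )
    return {"trials": trials, "bp": bp, "panas": panas}


# ---------------------------------------------------------------------------
# Study 3: EEG + moderated ratings
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Study3Config:
    """Ground truth for the Study-3-style generator.

    Each subject carries an imagery-ability factor g > 0 (the true IAI):
    during risky-scenario visualization the 10 Hz alpha amplitude on the
    parieto-occipital channels is attenuated to A / sqrt(g), so baseline
    alpha power divided by task alpha power recovers g; prefrontal control
    channels stay unmodulated.  Risk-taking ratings follow the moderated
    model y = b0 + b1*risk + b2*g + b3*risk*g + effects + noise.
    """

    n_subjects: int = 16
    # imagery ability (true IAI)
    g_mean: float = 1.06
    g_sd: float = 0.06
    g_min: float = 0.85
    g_max: float = 1.35
    # moderation coefficients
    b0: float = 31.0
    b1: float = -3.5
    b2: float = -25.0
    b3: float = 3.0
    # risk perception predictor
    risk_mean: float = 6.0
    risk_sd: float = 1.5
    risk_bounds: tuple[float, float] = (1.0, 10.0)
    subject_sd: float = 0.3
    domain_sd: float = 0.15
    resid_sd: float = 0.4
    # EEG
    sampling_rate: float = 200.0
    alpha_freq: float = 10.0
    alpha_amp: float = 20.0  # uV
    noise_sd: float = 5.0  # broadband white noise, uV
    artifact_rate: float = 0.05
    artifact_amp: float = 150.0  # uV
    baseline_seconds: float = 120.0  # 4x a 30 s risky scenario
    listening_seconds: float = 30.0
    visualization_seconds: float = 30.0
    n_scenarios: int = 10
    discretize: bool = False
    seed: int | None = None


def _study3_signal(
    cfg: Study3Config, rng: np.random.Generator, g: float
) -> tuple[np.ndarray, list[Segment]]:
    fs = cfg.sampling_rate
    n_base = int(round(cfg.baseline_seconds * fs))
    n_lis = int(round(cfg.listening_seconds * fs))
    n_vis = int(round(cfg.visualization_seconds * fs))
    events: list[Segment] = []
    pos = 0
    plan: list[tuple[str, object, str | None, int]] = []
    plan.append(("baseline", "weather1", None, n_base))
    scen_domains = [DOMAINS[i % 5] for i in range(cfg.n_scenarios)]
    for s, dom in enumerate(scen_domains):
        plan.append(("listening", f"scn{s + 1:02d}", dom, n_lis))
        plan.append(("visualization", f"scn{s + 1:02d}", dom, n_vis))
    plan.append(("baseline", "weather2", None, n_base))
    total = sum(p[3] for p in plan)

    t = np.arange(total) / fs
    carrier = np.sin(2 * np.pi * cfg.alpha_freq * t)
    amp_po = np.full(total, cfg.alpha_amp)  # parieto-occipital envelope
    for kind, scen, dom, ns in plan:
        if kind == "visualization" and dom is not None:
            amp_po[pos : pos + ns] = cfg.alpha_amp / np.sqrt(g)
        events.append(Segment(kind, scen, dom, pos, pos + ns))
        pos += ns

    sig = np.empty((total, len(CHANNELS)))
    for ci, ch in enumerate(CHANNELS):
        amp = amp_po if ch in ("O1", "O2", "P3", "P4") else cfg.alpha_amp
        chan = amp * carrier
        if cfg.noise_sd > 0:
            chan = chan + rng.normal(0, cfg.noise_sd, total)
        sig[:, ci] = chan
    # inject artifact epochs (common across channels, as real movement is)
    if cfg.artifact_rate > 0:
        epoch_len = int(round(2.0 * fs))
        for ev in events:
            n_ep = (ev.end_sample - ev.start_sample) // epoch_len
            hit = rng.random(n_ep) < cfg.artifact_rate
            for e in np.flatnonzero(hit):
                s0 = ev.start_sample + e * epoch_len + epoch_len // 4
                sig[s0 : s0 + epoch_len // 10, :] += cfg.artifact_amp
    return sig, events


def gen_study3(
    config: Study3Config = Study3Config(),
    seed: int | None = None,
    include_eeg: bool = True,
) -> dict:
    """Generate Study-3-style data: moderated ratings and EEG recordings.

    Returns ``{"trials": TrialTable, "recordings": list[EEGRecording],
    "g": per-subject imagery factors}``.  With ``include_eeg=False`` only
    the ratings table is built (handy for moderation-model simulations
    that do not need the signal chain).
    """
    cfg = config
    _check_positive(cfg, ["g_sd", "risk_sd", "subject_sd", "domain_sd", "resid_sd", "noise_sd"])
    if not (0 <= cfg.artifact_rate < 1):
        raise ConfigError(f"artifact_rate={cfg.artifact_rate} outside [0, 1)")
    if cfg.g_min <= 0:
        raise ConfigError("imagery factors must be positive")
    for nm in ("baseline_seconds", "listening_seconds", "visualization_seconds"):
        if getattr(cfg, nm) < 2.0:
            raise ConfigError(f"{nm} must cover at least one 2 s epoch")
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    nS, nD = cfg.n_subjects, len(DOMAINS)

    g = _truncnorm(rng, cfg.g_mean, cfg.g_sd, cfg.g_min, cfg.g_max, size=(nS,))
    subj = np.repeat(np.arange(nS), nD)
    dom = np.tile(np.arange(nD), nS)
    n = nS * nD
    risk = _truncnorm(rng, cfg.risk_mean, cfg.risk_sd, *cfg.risk_bounds, size=(n,))
    us = rng.normal(0, cfg.subject_sd, nS)[subj]
    ud = rng.normal(0, cfg.domain_sd, nD)[dom]
    gv = g[subj]
    y = cfg.b0 + cfg.b1 * risk + cfg.b2 * gv + cfg.b3 * risk * gv + us + ud + rng.normal(0, cfg.resid_sd, n)

    df = pd.DataFrame(
        {
            "subject_id": [f"s{k + 1:02d}" for k in subj],
            "item_id": [DOMAINS[k] for k in dom],
            "domain": [DOMAINS[k] for k in dom],
            "x": gv,
            "risk_perception": risk,
            "risk_taking": y,
        }
    )
    if cfg.discretize:
        schema = TrialSchema.study3()
        df["risk_perception"] = np.clip(np.round(df["risk_perception"]), 1, 10)
        df["risk_taking"] = np.clip(np.round(df["risk_taking"]), 1, 5)
        trials = TrialTable(df=df, schema=schema)
    else:
        trials = TrialTable(df=df, schema=TrialSchema.unbounded())

    recordings: list[EEGRecording] = []
    if include_eeg:
        for s in range(nS):
            sig, events = _study3_signal(cfg, rng, g[s])
            recordings.append(
                EEGRecording(
                    subject_id=f"s{s + 1:02d}",
                    sampling_rate=cfg.sampling_rate,
                    channels=CHANNELS,
                    signal=sig,
                    events=events,
                )
            )
    return {"trials": trials, "recordings": recordings, "g": g}
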