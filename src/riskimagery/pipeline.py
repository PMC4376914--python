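"""End-to-end orchestration of the three study analyses.

Each ``run_study*`` function takes a plain config dict (typically loaded
from YAML), executes the study's stages in order, writes a results JSON
and a reproducibility manifest into the output directory, and returns the
results dict.  Stage-level logging reports the row/epoch counts after
every filter, because silent data loss in the reduction steps is the main
failure mode of pipelines like this one.

Config layout (YAML/JSON)::

    study: 1            # or 2, 3
    seed: 17
    input:              # either file paths ...
      trials: path.tsv
      schema: study1    # scale declaration to validate against
    generate: {}        # ... or synthetic-generation overrides (mutually
                        # exclusive with input); fields of Study*Config
    mediation:
      draws: 100000

Reruns with the same config and seed produce identical results; manifests
differ only in their timing fields.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Callable

import numpy as np
import pandas as pd

from . import __version__
from .anova_reliability import (
    icc_consistency,
    panas_change,
    posthoc_vs_neutral,
    rm_anova,
    subject_level_correlation,
)
from .bp_reduction import phase_contrast, reduce_bp_series
from .data_model import (
    IMAGERY_CHANNELS,
    TrialSchema,
    TrialTable,
    _to_jsonable,
    read_bp_series,
    read_eeg,
    read_panas,
    read_trial_table,
    write_results,
)
from .eeg_iai import aggregate_iai, iai_table_from_recording
from .exceptions import ConfigError
from .jn_moderation import fit_interaction, jn_regions, simple_slopes
from .serial_mediation import serial_mediation
from .synthetic_data import Study1Config, Study2Config, Study3Config, gen_study1, gen_study2, gen_study3

__all__ = ["RunManifest", "run_study1", "run_study2", "run_study3", "run_study"]

log = logging.getLogger(__name__)


@dataclass
class RunManifest:
    """Reproducibility record for one pipeline run."""

    config: dict
    seed: int | None
    package_version: str = __version__
    input_digests: dict = field(default_factory=dict)
    stages: list = field(default_factory=list)  # (name, seconds)
    outputs: list = field(default_factory=list)

    def add_stage(self, name: str, seconds: float) -> None:
        self.stages.append({"stage": name, "seconds": round(seconds, 6)})

    def digest(self, label: str, path: str | Path) -> None:
        h = hashlib.sha256(Path(path).read_bytes()).hexdigest()
        self.input_digests[label] = h

    def to_dict(self) -> dict:
        return {
            "config": _to_jsonable(self.config),
            "seed": self.seed,
            "package_version": self.package_version,
            "input_digests": self.input_digests,
            "stages": self.stages,
            "outputs": [str(p) for p in self.outputs],
        }


def _staged(manifest: RunManifest, name: str, fn: Callable[[], Any]) -> Any:
    t0 = time.perf_counter()
    log.info("stage %s ...", name)
    out = fn()
    manifest.add_stage(name, time.perf_counter() - t0)
    return out


def _schema_from_name(name: str) -> TrialSchema:
    try:
        return getattr(TrialSchema, name)()
    except AttributeError:
        raise ConfigError(f"unknown schema {name!r}")


def _finish(results: dict, manifest: RunManifest, out_dir: str | Path | None) -> dict:
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        res_path = out_dir / "results.json"
        write_results(results, res_path)
        manifest.outputs.append(res_path)
        (out_dir / "manifest.json").write_text(json.dumps(manifest.to_dict(), indent=1))
    return results


# ---------------------------------------------------------------------------
# Study 1
# ---------------------------------------------------------------------------


def run_study1(config: dict, out_dir: str | Path | None = None) -> dict:
    """Valence ANOVA vs. neutral with Holm post-hocs, ICC reliability,
    covariate correlations, and the serial mediation model."""
    seed = config.get("seed")
    manifest = RunManifest(config=config, seed=seed)

    def load() -> TrialTable:
        if "input" in config:
            path = config["input"]["trials"]
            manifest.digest("trials", path)
            return read_trial_table(path, _schema_from_name(config["input"].get("schema", "study1")))
        gen_cfg = Study1Config(**config.get("generate", {}))
        return gen_study1(gen_cfg, seed=seed)

    table = _staged(manifest, "load", load)
    log.info("study 1: %d rows, %d subjects, %d items", table.n_rows, table.n_subjects, table.n_items)

    def descriptives() -> dict:
        wide = table.df.pivot(index="subject_id", columns="item_id", values="x").to_numpy()
        # neutral reference modeled as an explicit constant level, so the
        # scenario factor has one more level than there are scenarios
        with_neutral = np.column_stack([wide, np.zeros(len(wide))])
        anova = rm_anova(with_neutral, factors=[("scenario", with_neutral.shape[1])])["scenario"]
        post = posthoc_vs_neutral(wide)
        iccs = {}
        for col in ("x", "stress", "risk_perception", "risk_taking"):
            mat = table.df.pivot(index="subject_id", columns="item_id", values=col).to_numpy()
            iccs[col] = float(icc_consistency(mat))
        corrs = {}
        for a, b in (("stai", "x"), ("stai", "stress"), ("stai", "risk_perception"), ("siri", "risk_taking")):
            if a in table.df.columns:
                corrs[f"{a}~{b}"] = subject_level_correlation(table, a, b).to_dict()
        return {
            "valence_anova": anova.to_dict(),
            "posthoc_vs_neutral": post.to_dict(),
            "icc": iccs,
            "correlations": corrs,
        }

    desc = _staged(manifest, "descriptives", descriptives)

    med_cfg = config.get("mediation", {})
    med = _staged(
        manifest,
        "mediation",
        lambda: serial_mediation(
            table,
            x="x", m1="stress", m2="risk_perception", y="risk_taking",
            covariates_on_y=tuple(med_cfg.get("covariates", ("stai", "siri"))),
            k=int(med_cfg.get("draws", 100_000)),
            seed=seed,
        ),
    )

    results = {"study": 1, "seed": seed, "descriptives": desc, "mediation": med.to_dict()}
    manifest.add_stage("write", 0.0)
    return _finish(results, manifest, out_dir)


# ---------------------------------------------------------------------------
# Study 2
# ---------------------------------------------------------------------------


def run_study2(config: dict, out_dir: str | Path | None = None) -> dict:
    """PANAS change, MAP reduction with phase contrast, affect-pressure
    correlation, and the vividness mediation model."""
    seed = config.get("seed")
    manifest = RunManifest(config=config, seed=seed)

    def load() -> dict:
        if "input" in config:
            paths = config["input"]
            for label in ("trials", "bp", "panas"):
                manifest.digest(label, paths[label])
            return {
                "trials": read_trial_table(paths["trials"], _schema_from_name(paths.get("schema", "study2"))),
                "bp": read_bp_series(paths["bp"]),
                "panas": read_panas(paths["panas"]),
            }
        gen_cfg = Study2Config(**config.get("generate", {}))
        return gen_study2(gen_cfg, seed=seed)

    bundle = _staged(manifest, "load", load)
    trials = bundle["trials"]

    panas = _staged(manifest, "panas_change", lambda: panas_change(bundle["panas"]))

    def bp_stage() -> dict:
        reduced = [reduce_bp_series(s) for s in bundle["bp"]]
        log.info("study 2: reduced %d BP series (15 retained readings each)", len(reduced))
        contrast = phase_contrast(reduced)
        # correlation between PA change and mean visualization pressure
        d_pa = {r.subject_id: r.pa_post - r.pa_pre for r in bundle["panas"]}
        pairs = np.array([[d_pa[r.subject_id], r.visualization_mean] for r in reduced if r.subject_id in d_pa])
        from scipy import stats as _st

        r, p = _st.pearsonr(pairs[:, 0], pairs[:, 1])
        return {
            "reduced": [r_.to_dict() for r_ in reduced],
            "phase_contrast": contrast.to_dict(),
            "pa_change_vs_bp": {"r": float(r), "p": float(p), "n": len(pairs)},
        }

    bp = _staged(manifest, "bp_reduction", bp_stage)

    med_cfg = config.get("mediation", {})
    med = _staged(
        manifest,
        "mediation",
        lambda: serial_mediation(
            trials,
            x="x", m1="stress", m2="risk_perception", y="risk_taking",
            covariates_on_y=tuple(med_cfg.get("covariates", ("siri",))),
            k=int(med_cfg.get("draws", 100_000)),
            seed=seed,
        ),
    )

    results = {
        "study": 2,
        "seed": seed,
        "panas": panas.to_dict(),
        "bp": bp,
        "mediation": med.to_dict(),
    }
    manifest.add_stage("write", 0.0)
    return _finish(results, manifest, out_dir)


# ---------------------------------------------------------------------------
# Study 3
# ---------------------------------------------------------------------------


def run_study3(config: dict, out_dir: str | Path | None = None) -> dict:
    """EEG -> IAI -> phase ANOVA -> moderation with simple slopes and the
    Johnson-Neyman grid."""
    seed = config.get("seed")
    manifest = RunManifest(config=config, seed=seed)

    def load() -> dict:
        if "input" in config:
            paths = config["input"]
            manifest.digest("trials", paths["trials"])
            trials = read_trial_table(paths["trials"], _schema_from_name(paths.get("schema", "study3")))
            recs = []
            for pair in paths.get("eeg", []):
                manifest.digest(pair["signal"], pair["signal"])
                recs.append(read_eeg(pair["signal"], pair["events"]))
            return {"trials": trials, "recordings": recs, "g": None}
        gen_cfg = Study3Config(**config.get("generate", {}))
        return gen_study3(gen_cfg, seed=seed)

    bundle = _staged(manifest, "load", load)

    def iai_stage() -> pd.DataFrame:
        frames = []
        for rec in bundle["recordings"]:
            tab = iai_table_from_recording(rec)
            frames.append(tab.df)
        return pd.concat(frames, ignore_index=True)

    iai_df = _staged(manifest, "iai", iai_stage)
    log.info("study 3: %d IAI rows from %d recordings", len(iai_df), len(bundle["recordings"]))

    def anova_stage() -> dict:
        from .data_model import IAITable

        # Phase main effect: listening vs visualization, subject-level means
        piv = iai_df.pivot_table(index="subject_id", columns="phase", values="iai")
        mat = piv[["listening", "visualization"]].to_numpy()
        eff = rm_anova(mat, factors=[("phase", 2)])["phase"]
        agg = aggregate_iai(IAITable(iai_df), electrodes=IMAGERY_CHANNELS)
        return {"phase_anova": eff.to_dict(), "iai_mean_by_subject_domain": agg}

    anova = _staged(manifest, "iai_anova", anova_stage)
    agg = anova.pop("iai_mean_by_subject_domain")

    def moderation_stage() -> dict:
        df = bundle["trials"].df.merge(
            agg, left_on=["subject_id", "domain"], right_on=["subject_id", "domain"], how="inner"
        )
        log.info("study 3: %d rows enter the moderation model", len(df))
        mod = fit_interaction(df, y="risk_taking", x_focal="risk_perception", moderator="iai_mean")
        slopes = simple_slopes(mod)
        jn = jn_regions(mod)
        out = {
            "model": mod.to_dict(),
            "simple_slopes": {f"{k:.6g}": v for k, v in slopes.items()},
            "johnson_neyman": jn.to_dict(),
            "iai_range": [float(df["iai_mean"].min()), float(df["iai_mean"].max())],
        }
        return {"results": out, "jn_grid": jn.grid}

    mod = _staged(manifest, "moderation", moderation_stage)

    results = {
        "study": 3,
        "seed": seed,
        "iai_anova": anova["phase_anova"],
        "moderation": mod["results"],
    }

    manifest.add_stage("write", 0.0)
    out = _finish(results, manifest, out_dir)
    if out_dir is not None:
        grid_path = Path(out_dir) / "jn_grid.tsv"
        mod["jn_grid"].to_csv(grid_path, sep="\t", index=False)
        manifest.outputs.append(grid_path)
        (Path(out_dir) / "manifest.json").write_text(json.dumps(manifest.to_dict(), indent=1))
    return out


def run_study(study: int, config: dict, out_dir: str | Path | None = None) -> dict:
    runner = {1: run_study1, 2: run_study2, 3: run_study3}.get(int(study))
    if runner is None:
        raise ConfigError(f"unknown study {study}; expected 1, 2 or 3")
    return runner(config, out_dir)
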