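"""File formats, pipeline configuration and the end-to-end orchestration.

Sessions travel as a tidy long-format CSV (one row per time sample) plus a
JSON metadata sidecar carrying the session parameters and the
instrument-grade per-segment kinematics.  Feature tables and reports are
plain CSV/JSON.  ``run_pipeline`` chains the stages in study order:
simulate -> features -> distributions -> stochastic rule -> signatures.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import yaml

from . import distributions as dist
from . import kinematics as kin
from . import signatures as sig
from . import stochastic_rule as rule
from . import synth

_log = logging.getLogger(__name__)

TRIAL_COLUMNS = ["session_id", "subject_id", "trial_index", "segment",
                 "speed_level", "context", "design", "block",
                 "t_s", "x_m", "y_m", "z_m"]

TRIALS_FILE = "trials.csv"
META_FILE = "meta.json"


class SchemaError(ValueError):
    """A malformed session/feature file (missing columns, bad rows)."""


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


# ---------------------------------------------------------------------------
# Session round trip
# ---------------------------------------------------------------------------

def write_trials(session: synth.SessionRecord, out_dir: Union[str, Path],
                 ) -> Path:
    """Write a session as ``trials.csv`` plus a ``meta.json`` sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    frames = []
    for t in session.trials:
        frames.append(pd.DataFrame({
            "session_id": t.session_id, "subject_id": t.subject_id,
            "trial_index": t.trial_index, "segment": t.segment,
            "speed_level": t.speed_level, "context": t.context,
            "design": t.design, "block": t.block,
            "t_s": t.time, "x_m": t.position[:, 0],
            "y_m": t.position[:, 1], "z_m": t.position[:, 2],
        }))
    pd.concat(frames, ignore_index=True).to_csv(out / TRIALS_FILE,
                                                index=False)
    meta = {
        "session_id": session.session_id,
        "design": session.design,
        "sampling_rate": session.sampling_rate,
        "upsilon": session.upsilon,
        "seed": session.seed,
        "recorded_features": session.features.to_dict(orient="records"),
    }
    (out / META_FILE).write_text(json.dumps(meta, indent=1))
    return out


def read_trials(path: Union[str, Path]) -> synth.SessionRecord:
    """Read a session directory (``trials.csv`` + ``meta.json``) back.

    Rows are validated: all schema columns present, strictly increasing
    uniform time within each segment; violations raise :class:`SchemaError`
    naming the column or row.
    """
    path = Path(path)
    csv_path = path / TRIALS_FILE if path.is_dir() else path
    meta_path = csv_path.parent / META_FILE
    frame = pd.read_csv(csv_path)
    missing = [c for c in TRIAL_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"missing column(s): {', '.join(missing)}")
    meta: Dict[str, Any] = {}
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
    trials: List[kin.TrialRecord] = []
    for (ti, segment), grp in frame.groupby(["trial_index", "segment"],
                                            sort=False):
        t = grp["t_s"].to_numpy(dtype=float)
        if len(t) >= 3:
            dt = np.diff(t)
            bad = np.nonzero(np.abs(dt - np.median(dt)) > 1e-6)[0]
            if len(bad):
                row = int(grp.index[bad[0] + 1])
                raise SchemaError(
                    f"non-uniform time step at row {row} "
                    f"(trial {ti}, {segment})")
        first = grp.iloc[0]
        trials.append(kin.TrialRecord(
            session_id=str(first["session_id"]),
            subject_id=str(first["subject_id"]),
            trial_index=int(ti), segment=str(segment),
            speed_level=str(first["speed_level"]),
            context=str(first["context"]), design=str(first["design"]),
            block=str(first["block"]), time=t,
            position=grp[["x_m", "y_m", "z_m"]].to_numpy(dtype=float)))
    trials.sort(key=lambda t: (t.trial_index, 0 if t.segment == "strike"
                               else 1))
    features = pd.DataFrame(meta.get("recorded_features", []),
                            columns=kin.FEATURE_COLUMNS) \
        if meta.get("recorded_features") else None
    if features is None:
        session = synth.SessionRecord(
            session_id=str(frame["session_id"].iloc[0]),
            design=str(frame["design"].iloc[0]),
            sampling_rate=1.0 / float(np.median(np.diff(
                trials[0].time))) if trials else 240.0,
            upsilon=synth.UPSILON_DEFAULT, seed=-1, trials=trials,
            features=kin.features_table(
                type("S", (), {"trials": trials, "features": None})()))
        return session
    return synth.SessionRecord(
        session_id=meta.get("session_id", str(frame["session_id"].iloc[0])),
        design=meta.get("design", str(frame["design"].iloc[0])),
        sampling_rate=float(meta.get("sampling_rate", 240.0)),
        upsilon=float(meta.get("upsilon", synth.UPSILON_DEFAULT)),
        seed=int(meta.get("seed", -1)), trials=trials, features=features)


def write_features(features: pd.DataFrame, path: Union[str, Path]) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    features.to_csv(path, index=False)
    return path


def read_features(path: Union[str, Path]) -> pd.DataFrame:
    frame = pd.read_csv(path)
    missing = [c for c in ("trial_index", "segment", "vmax", "amax")
               if c not in frame.columns]
    if missing:
        raise SchemaError(f"missing column(s): {', '.join(missing)}")
    return frame


def write_report(results: Mapping[str, Any], path: Union[str, Path]) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(results, indent=1, default=_jsonable))
    return path


def _jsonable(obj: Any):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return dataclasses.asdict(obj)
    if isinstance(obj, Mapping):
        return {str(k): v for k, v in obj.items()}
    raise TypeError(f"not JSON-serializable: {type(obj)}")


# ---------------------------------------------------------------------------
# Pipeline configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnalysisOptions:
    upsilon: float = synth.UPSILON_DEFAULT
    smoothing_window: int = kin.DEFAULT_SMOOTHING_WINDOW
    n_frames: int = 100               # linearity resampling frames
    n_boot: int = 2000                # dip bootstrap draws
    alpha: float = 0.05
    bandwidth_threshold: float = sig.BANDWIDTH_THRESHOLD
    fano_threshold: float = sig.FANO_THRESHOLD
    fatigue_k: int = 10
    signature_value: str = "vmax"     # column fed to the Gamma fits
    use_recorded_features: bool = True


@dataclass(frozen=True)
class PipelineConfig:
    generator: synth.SynthConfig
    analysis: AnalysisOptions = field(default_factory=AnalysisOptions)
    seed: int = 0
    verbosity: int = logging.INFO


def demo_config(seed: int = 0, trials_per_condition: int = 100,
                design: str = "blocked") -> PipelineConfig:
    """The demonstration study: expert + novice, bag/no-bag, two speeds."""
    gen = synth.cohort_config(seed=seed, design=design,
                              trials_per_condition=trials_per_condition)
    return PipelineConfig(generator=gen, seed=seed)


def load_config(path: Union[str, Path],
                seed: Optional[int] = None) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from a YAML/JSON file.

    Subjects are given either as ``preset: expert|novice`` or with explicit
    ``laws`` (``"<level>:<context>": {median, log_sd}``) and ``rule``
    (``{m, b, eps_sd}``) entries.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise SchemaError("config must be a mapping")
    cfg_seed = int(raw.get("seed", 0)) if seed is None else int(seed)
    contexts = tuple(raw.get("contexts", ("simulation",)))
    subjects = []
    for entry in raw.get("subjects", [{"preset": "novice"}]):
        preset = entry.get("preset")
        sid = entry.get("id")
        if preset == "expert":
            subjects.append(synth.expert_profile(sid or "expert_1"))
        elif preset == "novice":
            subjects.append(synth.novice_profile(sid or "novice_1"))
        else:
            laws = {}
            for key, law in entry["laws"].items():
                level, ctx = key.split(":")
                laws[(level, ctx)] = synth.SpeedLaw(
                    math.log(float(law["median"])), float(law["log_sd"]))
            r = entry.get("rule", {})
            subjects.append(synth.SubjectProfile(
                sid or "subject_1", entry.get("class", "novice"), laws,
                synth.RuleParams(m=float(r.get("m", 1.0)),
                                 b=float(r.get("b", 0.0)),
                                 eps_sd=float(r.get("eps_sd", 0.0)))))
    gen = synth.SynthConfig(
        subjects=tuple(subjects),
        contexts=contexts,
        design=raw.get("design", "blocked"),
        trials_per_condition=int(raw.get("trials_per_condition", 100)),
        sampling_rate=float(raw.get("sampling_rate", 240.0)),
        seed=cfg_seed)
    ana = AnalysisOptions(**raw.get("analysis", {}))
    return PipelineConfig(generator=gen, analysis=ana, seed=cfg_seed)


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config: PipelineConfig,
                 out_dir: Optional[Union[str, Path]] = None,
                 ) -> Dict[str, Any]:
    """Run the full analysis on a freshly simulated session.

    Returns (and optionally writes) the report bundle: per-condition Gamma
    signatures, dip tests of merged speed distributions, rule fits in the
    regression-table vocabulary (p1, p2, SSE, R-square, ...), signature
    trajectories with gain shifts, expertise profiles, condition-comparison
    rows, linearity summaries and fatigue checks.  Deterministic given the
    config seed.
    """
    ana = config.analysis
    report: Dict[str, Any] = {
        "seed": config.seed,
        "design": config.generator.design,
        "upsilon": ana.upsilon,
        "stages": [],
    }

    def stage(name):
        _log.info("pipeline stage: %s", name)
        report["stages"].append(name)

    try:
        stage("simulate")
        session = synth.generate_session(config.generator)
    except Exception as e:                                    # noqa: BLE001
        raise PipelineError("simulate", e) from e

    try:
        stage("features")
        features = kin.features_table(
            session, use_recorded=ana.use_recorded_features,
            smoothing_window=ana.smoothing_window)
    except Exception as e:                                    # noqa: BLE001
        raise PipelineError("features", e) from e

    dip_seed = np.random.SeedSequence(config.seed).spawn(1)[0]
    dip_rng = np.random.default_rng(dip_seed)
    subjects = list(pd.unique(features["subject_id"]))
    try:
        stage("distributions")
        signatures_out: Dict[str, Any] = {}
        dip_out: Dict[str, Any] = {}
        for subject in subjects:
            strikes = features[(features["subject_id"] == subject)
                               & (features["segment"] == "strike")]
            sigs = sig.condition_signatures(strikes, ana.signature_value)
            signatures_out[subject] = {
                label: {"shape": s.shape, "scale": s.scale, "n": s.n,
                        "ci_shape": s.ci_shape, "ci_scale": s.ci_scale,
                        "mean": s.mean, "variance": s.variance,
                        "fano": s.fano}
                for label, s in sigs.items()}
            merged = strikes["vmax"].to_numpy(dtype=float)
            if len(merged) >= 30:
                d, p = dist.dip_unimodality(merged, ana.n_boot, dip_rng)
                dip_out[subject] = {"dip": d, "p_value": p,
                                    "rejects_unimodality": p < 0.01}
        report["signatures"] = signatures_out
        report["dip_merged_vmax"] = dip_out
    except Exception as e:                                    # noqa: BLE001
        raise PipelineError("distributions", e) from e

    try:
        stage("rule")
        rule_out: Dict[str, Any] = {}
        for subject in subjects:
            rule_out[subject] = {}
            for segment in ("strike", "retraction"):
                seg = features[(features["subject_id"] == subject)
                               & (features["segment"] == segment)]
                seg = seg.sort_values("trial_index")
                scatter = rule.build_rule_scatter(seg, ana.upsilon)
                fit = rule.fit_rule(scatter, "single")
                entry = _fit_record(fit)
                if len(set(scatter.speed_level)) >= 2:
                    decision = rule.split_decision(scatter, ana.alpha)
                    entry["split"] = {"decision": decision.decision,
                                      "F": decision.f_statistic,
                                      "p": decision.p_value}
                    if decision.decision == "per_level":
                        per = rule.fit_rule(scatter, "per_level")
                        entry["per_level"] = {
                            lvl: _fit_record(f)
                            for lvl, f in per.per_level.items()}
                pf = rule.power_form(
                    fit, (float(np.exp(scatter.x.min())),
                          float(np.exp(scatter.x.max()))))
                entry["delta"] = pf.delta
                entry["delta_squared"] = pf.delta_squared
                rule_out[subject][segment] = entry
        report["rule_fits"] = rule_out
    except Exception as e:                                    # noqa: BLE001
        raise PipelineError("rule", e) from e

    try:
        stage("signatures")
        traj_out: Dict[str, Any] = {}
        expertise_out: Dict[str, Any] = {}
        fatigue_out: Dict[str, Any] = {}
        for subject in subjects:
            strikes = features[(features["subject_id"] == subject)
                               & (features["segment"] == "strike")]
            strikes = strikes.sort_values("trial_index")
            traj = sig.signature_trajectory(strikes, ana.signature_value)
            traj_out[subject] = {
                "blocks": list(traj.labels),
                "shapes": [s.shape for s in traj.signatures],
                "scales": [s.scale for s in traj.signatures],
                "transitions": list(traj.transitions)}
            sigs = sig.condition_signatures(strikes, ana.signature_value)
            if len(sigs) >= 2:
                prof = sig.expertise_profile(
                    sigs, ana.bandwidth_threshold, ana.fano_threshold)
                expertise_out[subject] = {
                    "bandwidth": prof.bandwidth,
                    "max_fano": prof.max_fano,
                    "expert_like": prof.expert_like,
                    "separability": {f"{a}|{b}": v for (a, b), v
                                     in prof.separability.items()}}
            if config.generator.design == "blocked":
                fatigue_out[subject] = {}
                for block, grp in strikes.groupby("block", sort=False):
                    if len(grp) >= 2 * ana.fatigue_k:
                        fr = sig.fatigue_check(grp, ana.fatigue_k)
                        fatigue_out[subject][str(block)] = {
                            "vmax_p": fr.vmax_p,
                            "duration_p": fr.duration_p}
        report["signature_trajectories"] = traj_out
        report["expertise"] = expertise_out
        report["fatigue"] = fatigue_out
        comparisons = sig.comparison_table(
            features, value_column="vmax", by=("speed_level",),
            within=("subject_id", "segment"))
        report["comparisons"] = comparisons.to_dict(orient="records")
    except Exception as e:                                    # noqa: BLE001
        raise PipelineError("signatures", e) from e

    try:
        stage("linearity")
        lin_rows = []
        for t in session.trials:
            if t.segment != "retraction":
                continue
            prof = kin.linearity_profile(t.position, ana.n_frames)
            lin_rows.append({
                "subject_id": t.subject_id, "trial_index": t.trial_index,
                "speed_level": t.speed_level, "context": t.context,
                "max_deviation": prof.max_deviation,
                "mean_deviation": prof.mean_deviation,
                "superposition_ok": prof.superposition_ok})
        lin = pd.DataFrame(lin_rows)
        lin_summary: Dict[str, Any] = {}
        if len(lin):
            for subject, grp in lin.groupby("subject_id", sort=False):
                groups = {str(k): g["max_deviation"].to_numpy()
                          for k, g in grp.groupby("speed_level",
                                                  sort=False)}
                entry = {k: {"median_max_deviation":
                             float(np.median(v))} for k, v in groups.items()}
                if len(groups) == 2:
                    row = sig.compare_conditions(groups, "ranksum")
                    entry["fast_vs_slow_p"] = row.p_value
                lin_summary[str(subject)] = entry
        report["linearity_retraction"] = lin_summary
    except Exception as e:                                    # noqa: BLE001
        raise PipelineError("linearity", e) from e

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_trials(session, out / "session")
        write_features(features, out / "features.csv")
        comparisons.to_csv(out / "comparisons.csv", index=False)
        write_report(report, out / "report.json")
    return report


def _fit_record(fit: rule.RuleFit) -> Dict[str, Any]:
    """The regression-table vocabulary for one fitted line."""
    return {"p1": fit.m, "p2": fit.b,
            "p1_ci": fit.ci_m, "p2_ci": fit.ci_b,
            "SSE": fit.sse, "R-square": fit.r_squared,
            "Adjusted R-square": fit.adj_r_squared,
            "RMSE": fit.rmse, "n": fit.n_points}
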