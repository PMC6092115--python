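"""Study orchestration: a directory of trials in, outcome statistics out.

``run_study`` walks ``input_dir/<subject>/<condition>/`` for the three trial
paradigms (``walk_*.csv``, ``step_*.csv``, ``perturb_*.csv``), analyses each
trial, writes per-trial metric JSONs, and aggregates everything into
``summary.tsv``, ``percent_change.tsv`` and ``ttests.json``, plus a run
manifest recording parameters, per-trial status and warnings.  Malformed
trials are logged and skipped; only configuration errors abort the run.
Outputs are a pure function of config + input files (re-running with the
same config and seed is byte-identical).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .apa import ApaParams, apa_metrics
from .core import FilterSpec, InvalidParameterError, PfkError
from .fog import BandSpec, detect_fog
from .io import read_perturbation_trial, read_step_trial, read_walk_trial
from .reactive import ReactiveParams, load_anthropometric_model, reactive_metrics
from .stats import CONDITIONS, summarize_study

log = logging.getLogger("pfk")


@dataclass(frozen=True)
class SubjectSpec:
    id: str
    foot_length_cm: float = 26.0
    stepping_side: str = "left"


@dataclass(frozen=True)
class StudyConfig:
    input_dir: Path
    output_dir: Path
    subjects: tuple[SubjectSpec, ...]
    conditions: tuple[str, ...] = CONDITIONS
    seed: int = 0
    filter_cutoff: float = 10.0
    filter_order_per_pass: int = 2
    fog_span: float = 7.5
    fog_hop: float = 0.25
    fog_threshold: float = 2.0
    loco_band: tuple[float, float] = (0.5, 3.0)
    freeze_band: tuple[float, float] = (3.0, 8.0)
    onset_k: float = 2.0
    min_hold: float = 0.15
    analysis_window: float = 2.5
    model_path: str | None = None
    fail_on_skip: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        path = Path(path)
        raw = yaml.safe_load(path.read_text())
        if not isinstance(raw, dict):
            raise InvalidParameterError(f"{path}: config must be a mapping")
        subjects = tuple(
            SubjectSpec(
                id=str(s["id"]),
                foot_length_cm=float(s.get("foot_length_cm", 26.0)),
                stepping_side=str(s.get("stepping_side", "left")),
            )
            for s in raw.get("subjects", [])
        )
        if not subjects:
            raise InvalidParameterError(f"{path}: config lists no subjects")
        base = path.parent
        params = raw.get("params", {})
        cfg = cls(
            input_dir=(base / raw.get("input_dir", ".")).resolve(),
            output_dir=(base / raw.get("output_dir", "out")).resolve(),
            subjects=subjects,
            conditions=tuple(raw.get("conditions", CONDITIONS)),
            seed=int(raw.get("seed", 0)),
            **{k: v if not isinstance(v, list) else tuple(v) for k, v in params.items()},
        )
        if not cfg.input_dir.is_dir():
            raise InvalidParameterError(f"input dir {cfg.input_dir} does not exist")
        unknown = set(cfg.conditions) - set(CONDITIONS)
        if unknown:
            raise InvalidParameterError(f"unknown conditions {sorted(unknown)}")
        return cfg

    @property
    def filter_spec(self) -> FilterSpec:
        return FilterSpec(cutoff=self.filter_cutoff, order_per_pass=self.filter_order_per_pass)

    @property
    def band_spec(self) -> BandSpec:
        return BandSpec(
            loco_band=self.loco_band, freeze_band=self.freeze_band, threshold=self.fog_threshold
        )


def _analyze_walk(path: Path, cfg: StudyConfig) -> dict:
    series, meta = read_walk_trial(path)
    marks = None
    if "walk_start" in meta and "walk_stop" in meta:
        marks = (float(meta["walk_start"]), float(meta["walk_stop"]))
    result = detect_fog(
        series,
        bands=cfg.band_spec,
        span=cfg.fog_span,
        hop=cfg.fog_hop,
        filter_spec=cfg.filter_spec,
        walk_marks=marks,
    )
    return {
        "events": [[e.t_start, e.t_end] for e in result.events],
        "fog_time": result.total_fog_time,
        "gait_time": result.gait_time,
    }


def _analyze_step(path: Path, cfg: StudyConfig) -> dict:
    trial, _ = read_step_trial(path)
    params = ApaParams(k=cfg.onset_k, min_hold=cfg.min_hold, filter_spec=cfg.filter_spec)
    m = apa_metrics(trial, params)
    return {
        "apa_onset": m.apa_onset,
        "step_onset": m.step_onset,
        "apa_duration": m.apa_duration,
        "apa_amplitude": m.apa_peak_amplitude,
        "ml_channel_convention": "absolute deviation from baseline mean",
    }


def _analyze_perturb(path: Path, cfg: StudyConfig, model) -> dict:
    trial, _ = read_perturbation_trial(path)
    params = ReactiveParams(filter_spec=cfg.filter_spec)
    m = reactive_metrics(trial, model, params)
    return {"com_ap_rms": m.rms_com_ap, "cop_ap_rms": m.rms_cop_ap}


_PARADIGM_VARS = {
    "walk": ("gait_time", "fog_time"),
    "step": ("apa_duration", "apa_amplitude"),
    "perturb": ("com_ap_rms", "cop_ap_rms"),
}


def run_study(config: StudyConfig) -> Path:
    """Run the full pipeline; returns the output directory."""
    out = config.output_dir
    (out / "trials").mkdir(parents=True, exist_ok=True)
    model = load_anthropometric_model(config.model_path)

    rows: list[dict] = []
    manifest_trials: list[dict] = []
    n_skipped = 0
    any_trial = False
    for subj in config.subjects:
        for condition in config.conditions:
            cdir = config.input_dir / subj.id / condition
            if not cdir.is_dir():
                continue
            for paradigm, analyze in (
                ("walk", lambda p: _analyze_walk(p, config)),
                ("step", lambda p: _analyze_step(p, config)),
                ("perturb", lambda p: _analyze_perturb(p, config, model)),
            ):
                for path in sorted(cdir.glob(f"{paradigm}_*.csv")):
                    any_trial = True
                    entry = {
                        "subject": subj.id,
                        "condition": condition,
                        "paradigm": paradigm,
                        "file": str(path.relative_to(config.input_dir)),
                    }
                    try:
                        metrics = analyze(path)
                    except PfkError as exc:
                        entry["status"] = f"skipped: {exc}"
                        n_skipped += 1
                        log.warning("%s %s %s: skipped (%s)", subj.id, condition, path.name, exc)
                    else:
                        entry["status"] = "ok"
                        log.info("%s %s %s: ok", subj.id, condition, path.name)
                        trial_out = out / "trials" / f"{subj.id}_{condition}_{path.stem}.json"
                        trial_out.write_text(json.dumps(metrics, indent=1, sort_keys=True) + "\n")
                        for var in _PARADIGM_VARS[paradigm]:
                            rows.append(
                                {
                                    "subject": subj.id,
                                    "condition": condition,
                                    "variable": var,
                                    "value": metrics[var],
                                }
                            )
                    manifest_trials.append(entry)
    if not any_trial:
        raise InvalidParameterError(f"no trials found under {config.input_dir}")

    trials = pd.DataFrame(rows, columns=["subject", "condition", "variable", "value"])
    trials.to_csv(out / "trial_metrics.tsv", sep="\t", index=False, float_format="%.10g")
    summary, pct, tests, notes = summarize_study(trials)
    summary.to_csv(out / "summary.tsv", sep="\t", index=False, float_format="%.10g")
    pct.to_csv(out / "percent_change.tsv", sep="\t", index=False, float_format="%.10g")
    (out / "ttests.json").write_text(
        json.dumps(
            [
                {
                    "variable": r.variable,
                    "condition": r.condition,
                    "t": r.t,
                    "df": r.df,
                    "p": r.p,
                    "n": r.n,
                    "significant": r.significant,
                }
                for r in tests
            ],
            indent=1,
            sort_keys=True,
        )
        + "\n"
    )
    manifest = {
        "pfk_version": __version__,
        "seed": config.seed,
        "parameters": {
            "filter_cutoff": config.filter_cutoff,
            "filter_order_per_pass": config.filter_order_per_pass,
            "fog_span": config.fog_span,
            "fog_hop": config.fog_hop,
            "fog_threshold": config.fog_threshold,
            "loco_band": list(config.loco_band),
            "freeze_band": list(config.freeze_band),
            "onset_k": config.onset_k,
            "min_hold": config.min_hold,
            "analysis_window": config.analysis_window,
        },
        "n_trials": len(manifest_trials),
        "n_skipped": n_skipped,
        "trials": manifest_trials,
        "stat_notes": notes,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    if n_skipped and config.fail_on_skip:
        raise PfkError(f"{n_skipped} trial(s) skipped; see manifest")
    return out
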