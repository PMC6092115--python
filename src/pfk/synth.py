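"""Synthetic trial generators with known ground truth.

The three trial paradigms the pipeline analyses are not publicly deposited,
so every analysis stage is exercised against generated trials whose truth
(freeze intervals, onsets, target COP/COM trajectories) is known exactly:

* **walk** — a ~2 Hz locomotor sinusoid in lumbar vertical acceleration with
  freeze episodes of 3–8 Hz trembling that *replace* the locomotor component
  (forward progression halts while the legs tremble); white noise on top.
  An additive mode exists for robustness testing.
* **step** — quiet-standing baseline, then a smooth (half-cosine) mediolateral
  force ramp at the APA onset, a plateau, and a sigmoidal anteroposterior
  foot-marker displacement at the step onset.
* **perturb** — a trapezoidal-velocity backward platform translation with the
  protocol kinematics (12 cm, 15 cm/s, 100 cm/s², preparatory interval drawn
  uniformly from 1–3 s); markers ride the platform plus a second-order
  damped-oscillator sway response scaled with marker height; plate channels
  are built by inverse statics so the record's COP_ap equals a known target
  trajectory.

Every generator is a pure function of its spec and seed (bit-reproducible);
seeds are recorded in every truth payload.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy import signal as _sig

from .apa import StepTrial
from .core import FilterSpec, InvalidParameterError, UniformTimeSeries, butterworth_dual_pass
from .io import (
    write_json,
    write_perturbation_trial,
    write_step_trial,
    write_walk_trial,
)
from .reactive import (
    MARKER_NAMES,
    AnthropometricModel,
    ForcePlateRecord,
    MarkerSet,
    PerturbationTrial,
    load_anthropometric_model,
)

GRAVITY = 9.81  # m/s^2


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# walk trials


@dataclass(frozen=True)
class FreezeEpisode:
    t_start: float
    t_end: float
    freeze_freq: float = 5.0
    amp: float = 3.0

    def __post_init__(self) -> None:
        if not self.t_end > self.t_start:
            raise InvalidParameterError("episode must have t_end > t_start")
        if not 3.0 <= self.freeze_freq <= 8.0:
            raise InvalidParameterError("freeze_freq must lie in the 3-8 Hz trembling band")


@dataclass(frozen=True)
class WalkGenSpec:
    """Walk-trial generator settings.

    Amplitudes are in m/s^2.  ``loco_amp=1.0`` approximates the vertical
    trunk acceleration oscillation of slow walking; freeze trembling defaults
    to 3x the locomotor amplitude (episodic trembling dominates the trace).
    ``walk_start``/``walk_stop`` delimit the active walking span; the trial
    begins and ends in quiet standing.
    """

    duration: float = 20.0
    fs: float = 200.0
    loco_freq: float = 2.0
    loco_amp: float = 1.0
    freeze_episodes: tuple[FreezeEpisode, ...] = ()
    noise_sd: float = 0.05
    walk_start: float = 1.5
    walk_stop: float | None = None
    additive: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        stop = self.duration - 1.5 if self.walk_stop is None else self.walk_stop
        if not 0 <= self.walk_start < stop <= self.duration:
            raise InvalidParameterError("walk interval must fit inside the trial")
        eps = sorted(self.freeze_episodes, key=lambda e: e.t_start)
        for a, b in zip(eps, eps[1:]):
            if b.t_start < a.t_end:
                raise InvalidParameterError("freeze episodes must not overlap")
        for e in eps:
            if e.t_start < self.walk_start or e.t_end > stop:
                raise InvalidParameterError("freeze episodes must lie within the walking span")

    @property
    def resolved_walk_stop(self) -> float:
        return self.duration - 1.5 if self.walk_stop is None else self.walk_stop


def gen_walk_trial(spec: WalkGenSpec) -> tuple[UniformTimeSeries, dict]:
    """Generate one walk trial; returns (acceleration series, truth payload)."""
    rng = _rng(spec.seed)
    n = int(round(spec.duration * spec.fs)) + 1
    t = np.arange(n) / spec.fs
    stop = spec.resolved_walk_stop

    walking = (t >= spec.walk_start) & (t <= stop)
    loco = spec.loco_amp * np.sin(2 * math.pi * spec.loco_freq * t) * walking
    x = loco.copy()
    for ep in spec.freeze_episodes:
        mask = (t >= ep.t_start) & (t < ep.t_end)
        tremble = ep.amp * np.sin(2 * math.pi * ep.freeze_freq * t) * mask
        if spec.additive:
            x += tremble
        else:
            x = np.where(mask, tremble, x)
    x += rng.normal(0.0, spec.noise_sd, size=n)

    series = UniformTimeSeries(x, fs=spec.fs, label="acc_vertical", units="m/s^2")
    truth = {
        "seed": spec.seed,
        "episodes": [[ep.t_start, ep.t_end] for ep in spec.freeze_episodes],
        "total_freeze_time": sum(ep.t_end - ep.t_start for ep in spec.freeze_episodes),
        "walk_start": spec.walk_start,
        "walk_stop": stop,
        "gait_time": stop - spec.walk_start,
    }
    return series, truth


# ---------------------------------------------------------------------------
# step-initiation trials


@dataclass(frozen=True)
class StepGenSpec:
    """Step-trial generator settings.

    The mediolateral force rises over ``apa_rise`` seconds (half-cosine) from
    the APA onset to its peak, holds through the step, then returns to
    baseline.  ``apa_rise=0.10`` s models the fast initial weight transfer of
    gait initiation.  Force noise defaults to 5% of the APA peak; marker
    noise is at the sub-millimetre level of an optical capture system.
    """

    duration: float = 6.0
    fs: float = 200.0
    apa_onset: float = 2.5
    apa_peak: float = 33.6  # N; 1.2 N/cm for a 28 cm foot
    apa_rise: float = 0.10
    step_onset: float = 3.05
    step_amp: float = 20.0  # cm
    step_rise: float = 0.25
    release_after: float = 0.10
    release_time: float = 0.30
    noise_sd: float = 33.6 * 0.05
    disp_noise_sd: float = 0.05
    foot_length: float = 28.0
    stepping_side: str = "left"
    baseline_interval: tuple[float, float] = (0.0, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.baseline_interval[1] <= self.apa_onset <= self.step_onset:
            raise InvalidParameterError("need baseline end <= apa_onset <= step_onset")
        if self.apa_peak <= 0 or self.step_amp <= 0:
            raise InvalidParameterError("amplitudes must be positive")
        if self.step_onset + self.step_rise >= self.duration:
            raise InvalidParameterError("step must complete within the trial")


def _half_cosine_rise(t: np.ndarray, onset: float, rise: float) -> np.ndarray:
    """0 before onset, half-cosine ramp to 1 over ``rise``, 1 after."""
    phase = np.clip((t - onset) / rise, 0.0, 1.0)
    return 0.5 * (1.0 - np.cos(math.pi * phase))


def gen_step_trial(spec: StepGenSpec) -> tuple[StepTrial, dict]:
    """Generate one step-initiation trial; returns (trial, truth payload)."""
    rng = _rng(spec.seed)
    n = int(round(spec.duration * spec.fs)) + 1
    t = np.arange(n) / spec.fs

    ml = spec.apa_peak * _half_cosine_rise(t, spec.apa_onset, spec.apa_rise)
    release_at = spec.step_onset + spec.release_after
    ml *= 1.0 - _half_cosine_rise(t, release_at, spec.release_time)
    ml += rng.normal(0.0, spec.noise_sd, size=n)

    disp = spec.step_amp * _half_cosine_rise(t, spec.step_onset, spec.step_rise)
    disp += rng.normal(0.0, spec.disp_noise_sd, size=n)

    trial = StepTrial(
        ml_force=UniformTimeSeries(ml, fs=spec.fs, label="ml_force", units="N"),
        ap_foot_disp=UniformTimeSeries(disp, fs=spec.fs, label="ap_foot_disp", units="cm"),
        foot_length=spec.foot_length,
        baseline_interval=spec.baseline_interval,
        stepping_side=spec.stepping_side,
    )
    truth = {
        "seed": spec.seed,
        "apa_onset": spec.apa_onset,
        "step_onset": spec.step_onset,
        "apa_duration": spec.step_onset - spec.apa_onset,
        "apa_peak_amplitude": spec.apa_peak / spec.foot_length,
    }
    return trial, truth


# ---------------------------------------------------------------------------
# platform perturbation trials


@dataclass(frozen=True)
class PerturbGenSpec:
    """Perturbation-trial generator settings (protocol defaults).

    Platform kinematics follow a trapezoidal velocity profile: constant
    acceleration to peak velocity, cruise, symmetric deceleration; the triple
    must satisfy v^2/a <= amplitude.  The perturbation onset is drawn
    uniformly from ``preparatory_range`` unless fixed explicitly.
    """

    amplitude: float = 12.0  # cm
    peak_velocity: float = 15.0  # cm/s
    peak_acceleration: float = 100.0  # cm/s^2
    fs: float = 200.0
    onset: float | None = None
    preparatory_range: tuple[float, float] = (1.0, 3.0)
    post_window: float = 4.0  # recording length after onset, s
    sway_gain: float = 0.25
    sway_freq: float = 0.5  # Hz
    sway_damping: float = 0.3
    body_mass: float = 70.0  # kg
    com_height: float = 0.95  # m
    force_noise_sd: float = 1.0  # N
    moment_noise_sd: float = 0.5  # N*m
    marker_noise_sd: float = 0.02  # cm
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.amplitude, self.peak_velocity, self.peak_acceleration) <= 0:
            raise InvalidParameterError("platform kinematic parameters must be positive")
        if self.peak_velocity**2 / self.peak_acceleration > self.amplitude + 1e-12:
            raise InvalidParameterError(
                "infeasible platform profile: requires v^2/a <= amplitude"
            )


#: Marker heights above the platform surface, metres, and quiet-stance AP
#: positions, cm (positive forward).  Only used by the generator.
MARKER_HEIGHTS = {"meta5": 0.02, "malleolus": 0.08, "knee": 0.47, "trochanter": 0.92, "shoulder": 1.40}
MARKER_BASE_AP = {"meta5": 14.0, "malleolus": 4.0, "knee": 7.0, "trochanter": 6.0, "shoulder": 5.0}


def platform_phase_times(spec: PerturbGenSpec) -> tuple[float, float, float]:
    """(acceleration time, cruise time, total movement time)."""
    t_acc = spec.peak_velocity / spec.peak_acceleration
    d_acc = 0.5 * spec.peak_acceleration * t_acc**2
    cruise_dist = spec.amplitude - 2.0 * d_acc
    if cruise_dist < -1e-12:
        # triangular profile: peak velocity is not reached
        t_acc = math.sqrt(spec.amplitude / spec.peak_acceleration)
        return t_acc, 0.0, 2.0 * t_acc
    t_cruise = cruise_dist / spec.peak_velocity
    return t_acc, t_cruise, 2.0 * t_acc + t_cruise


def platform_switch_times(spec: PerturbGenSpec, onset: float = 0.0) -> tuple[float, ...]:
    """Piecewise-kinematic switch instants of the profile (for differentiation)."""
    t_acc, t_cruise, t_total = platform_phase_times(spec)
    pts = [onset, onset + t_acc, onset + t_acc + t_cruise, onset + t_total]
    return tuple(dict.fromkeys(pts))


def _trapezoid_displacement(tau: np.ndarray, spec: PerturbGenSpec) -> np.ndarray:
    """|displacement| (cm) at time tau >= 0 after movement onset."""
    t_acc, t_cruise, t_total = platform_phase_times(spec)
    a = spec.amplitude / t_acc**2 if t_cruise == 0.0 else spec.peak_acceleration
    v = a * t_acc
    d_acc = 0.5 * a * t_acc**2
    out = np.empty_like(tau)
    ph1 = tau < t_acc
    ph2 = (tau >= t_acc) & (tau < t_acc + t_cruise)
    ph3 = (tau >= t_acc + t_cruise) & (tau < t_total)
    done = tau >= t_total
    out[ph1] = 0.5 * a * tau[ph1] ** 2
    out[ph2] = d_acc + v * (tau[ph2] - t_acc)
    out[ph3] = spec.amplitude - 0.5 * a * (t_total - tau[ph3]) ** 2
    out[done] = spec.amplitude
    out[tau < 0] = 0.0
    return out


def gen_platform_profile(
    spec: PerturbGenSpec, onset: float = 0.0, duration: float | None = None
) -> UniformTimeSeries:
    """Backward platform AP displacement (cm, negative = backward).

    The profile is zero before ``onset``, follows the trapezoidal-velocity
    kinematics, and holds at -amplitude afterwards.
    """
    _, _, t_total = platform_phase_times(spec)
    if duration is None:
        duration = onset + t_total + 0.25
    n = int(round(duration * spec.fs)) + 1
    t = np.arange(n) / spec.fs
    disp = -_trapezoid_displacement(t - onset, spec)
    return UniformTimeSeries(disp, fs=spec.fs, label="platform_ap", units="cm")


def _sway_response(platform: UniformTimeSeries, spec: PerturbGenSpec) -> np.ndarray:
    """Damped-oscillator sway (cm, at COM height) driven by platform acceleration."""
    if spec.sway_gain == 0.0:
        return np.zeros(platform.n)
    omega = 2.0 * math.pi * spec.sway_freq
    t = platform.times()
    acc = np.gradient(np.gradient(platform.values, t), t)  # cm/s^2
    system = _sig.lti([-spec.sway_gain], [1.0, 2.0 * spec.sway_damping * omega, omega**2])
    _, s, _ = _sig.lsim(system, U=acc, T=t)
    return np.asarray(s)


def gen_perturbation_trial(
    spec: PerturbGenSpec, model: AnthropometricModel | None = None
) -> tuple[PerturbationTrial, dict]:
    """Generate one perturbation trial; returns (trial, truth payload).

    Marker trajectories share the platform translation plus height-scaled
    sway; plate channels are constructed by inverse statics so that the
    record's COP_ap equals the target COP trajectory exactly.  The truth
    payload carries the noise-free target COM and COP series and their
    analysis-window RMS (referenced to the 1 s pre-onset mean).
    """
    if model is None:
        model = load_anthropometric_model()
    rng = _rng(spec.seed)

    if spec.onset is None:
        lo, hi = spec.preparatory_range
        onset = lo + (hi - lo) * rng.uniform()
    else:
        onset = spec.onset
    onset = round(onset * spec.fs) / spec.fs
    duration = onset + spec.post_window

    platform = gen_platform_profile(spec, onset=onset, duration=duration)
    t = platform.times()
    n = t.size
    sway = _sway_response(platform, spec)

    clean = {}
    for name in MARKER_NAMES:
        alpha = MARKER_HEIGHTS[name] / spec.com_height
        clean[name] = MARKER_BASE_AP[name] + platform.values + alpha * sway

    # noise-free target COM (cm) via the segmental weighted sum
    com = np.zeros(n)
    for seg in model.segments:
        seg_com = clean[seg.proximal_marker] + seg.com_fraction * (
            clean[seg.distal_marker] - clean[seg.proximal_marker]
        )
        com += seg.count * seg.mass_fraction * seg_com

    # target COP in the (moving) plate frame: inverted-pendulum-style
    # exchange between COM position and COM acceleration.  The inertial term
    # is band-limited to the 10 Hz measurement band so the target trajectory
    # carries no energy the analysis chain is designed to reject (the raw
    # second derivative has steps at the platform's kinematic switch points).
    com_rel = com - platform.values
    com_rel_acc = np.gradient(np.gradient(com_rel, t), t)  # cm/s^2
    acc_series = UniformTimeSeries(com_rel_acc, fs=spec.fs, label="com_rel_acc")
    com_rel_acc = butterworth_dual_pass(acc_series, FilterSpec(cutoff=10.0)).values
    cop_target = com_rel + (spec.com_height / GRAVITY) * com_rel_acc

    com_acc_abs = np.gradient(np.gradient(com, t), t) / 100.0  # m/s^2

    def ts(vals, label, units):
        return UniformTimeSeries(vals, fs=spec.fs, label=label, units=units)

    fz = spec.body_mass * GRAVITY + rng.normal(0.0, spec.force_noise_sd, n)
    fx = spec.body_mass * com_acc_abs + rng.normal(0.0, spec.force_noise_sd, n)
    fy = rng.normal(0.0, spec.force_noise_sd, n)
    d_ap, d_ml, d_z = 0.0, 0.0, 0.0
    my = -(cop_target / 100.0 - d_ap) * fz - fx * d_z
    mx = rng.normal(0.0, spec.moment_noise_sd, n)
    mz = rng.normal(0.0, spec.moment_noise_sd, n)

    plate = ForcePlateRecord(
        fx=ts(fx, "Fx", "N"),
        fy=ts(fy, "Fy", "N"),
        fz=ts(fz, "Fz", "N"),
        mx=ts(mx, "Mx", "N*m"),
        my=ts(my, "My", "N*m"),
        mz=ts(mz, "Mz", "N*m"),
        origin_offset=(d_ap, d_ml, d_z),
    )
    markers = MarkerSet(
        **{
            name: ts(clean[name] + rng.normal(0.0, spec.marker_noise_sd, n), f"{name}_ap", "cm")
            for name in MARKER_NAMES
        }
    )
    trial = PerturbationTrial(markers=markers, plate=plate, perturbation_onset=onset)

    def _window_rms(vals: np.ndarray) -> float:
        i_on = int(round(onset * spec.fs))
        i_ref = int(round((onset - 1.0) * spec.fs))
        i_end = int(round((onset + trial.analysis_window) * spec.fs))
        ref = float(np.mean(vals[i_ref:i_on]))
        return float(np.sqrt(np.mean((vals[i_on:i_end] - ref) ** 2)))

    truth = {
        "seed": spec.seed,
        "perturbation_onset": onset,
        "com_ap": com.tolist(),
        "cop_ap": cop_target.tolist(),
        "rms_com_ap": _window_rms(com),
        "rms_cop_ap": _window_rms(cop_target),
    }
    return trial, truth


# ---------------------------------------------------------------------------
# whole synthetic study


#: Per-condition effect table for the synthetic study.  300 Hz stimulation
#: shortens APA duration and freeze time and raises APA amplitude; 60 Hz has
#: marginal effects; reactive metrics are unaffected by condition (the sway
#: model is condition-independent), mirroring a dissociation between
#: anticipatory and reactive postural control.
CONDITION_EFFECTS: dict[str, dict] = {
    "OFF": dict(step_onset=3.05, apa_peak=33.6, freeze_dur=8.0, walk_stop=14.5),
    "HZ60": dict(step_onset=3.05, apa_peak=33.6, freeze_dur=8.0, walk_stop=14.5),
    "HZ300": dict(step_onset=2.90, apa_peak=39.0, freeze_dur=3.0, walk_stop=12.0),
}

#: Which synthetic subjects exhibit freezing at all (half do not, as happens
#: even among severe freezers assessed in a gait laboratory).
SUBJECT_FREEZES = {"s01": False, "s02": True, "s03": True, "s04": False}
SUBJECT_FOOT_CM = {"s01": 26.0, "s02": 28.0, "s03": 25.0, "s04": 27.0}


def _trial_seed(root_seed: int, *parts: str) -> np.random.SeedSequence:
    key = [root_seed] + [abs(hash_str(p)) % (2**31) for p in parts]
    return np.random.SeedSequence(key)


def hash_str(s: str) -> int:
    """Deterministic small hash of a string (stable across processes)."""
    h = 0
    for ch in s:
        h = (h * 131 + ord(ch)) % (2**31 - 1)
    return h


def generate_study(
    out_dir: str | Path,
    seed: int = 0,
    subjects: tuple[str, ...] = ("s01", "s02", "s03", "s04"),
    conditions: tuple[str, ...] = ("OFF", "HZ60", "HZ300"),
    n_walk: int = 3,
    n_step: int = 10,
    n_perturb: int = 5,
) -> Path:
    """Emit a full synthetic study tree and its config; returns the config path.

    Layout: ``<out_dir>/<subject>/<condition>/{walk,step,perturb}_NN.csv`` with
    JSON sidecars and ``*_truth.json`` ground-truth files, plus ``study.yaml``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for subject in subjects:
        freezes = SUBJECT_FREEZES.get(subject, False)
        for condition in conditions:
            eff = CONDITION_EFFECTS[condition]
            cdir = out_dir / subject / condition
            cdir.mkdir(parents=True, exist_ok=True)
            for i in range(n_walk):
                ss = _trial_seed(seed, subject, condition, f"walk{i}")
                jit = np.random.default_rng(ss.spawn(1)[0])
                walk_stop = round(eff["walk_stop"] + jit.uniform(-0.3, 0.3), 3)
                episodes = ()
                if freezes and eff["freeze_dur"] > 0:
                    e0 = 4.0 + jit.uniform(-0.5, 0.5)
                    dur = eff["freeze_dur"] * (1.0 + jit.uniform(-0.1, 0.1))
                    episodes = (FreezeEpisode(round(e0, 3), round(e0 + dur, 3)),)
                spec = WalkGenSpec(
                    duration=20.0,
                    walk_stop=walk_stop,
                    freeze_episodes=episodes,
                    seed=int(ss.generate_state(1)[0] % (2**31)),
                )
                series, truth = gen_walk_trial(spec)
                path = cdir / f"walk_{i + 1:02d}.csv"
                write_walk_trial(
                    path,
                    series,
                    {
                        "subject": subject,
                        "condition": condition,
                        "fs": spec.fs,
                        "units": "m/s^2",
                        "walk_start": spec.walk_start,
                        "walk_stop": spec.resolved_walk_stop,
                        "seed": spec.seed,
                    },
                )
                write_json(cdir / f"walk_{i + 1:02d}_truth.json", truth)
            for i in range(n_step):
                ss = _trial_seed(seed, subject, condition, f"step{i}")
                jit = np.random.default_rng(ss.spawn(1)[0])
                step_onset = eff["step_onset"] + jit.uniform(-0.03, 0.03)
                apa_peak = eff["apa_peak"] * (1.0 + jit.uniform(-0.05, 0.05))
                spec = StepGenSpec(
                    step_onset=round(step_onset, 3),
                    apa_peak=round(apa_peak, 3),
                    noise_sd=round(apa_peak * 0.05, 4),
                    foot_length=SUBJECT_FOOT_CM.get(subject, 26.0),
                    seed=int(ss.generate_state(1)[0] % (2**31)),
                )
                trial, truth = gen_step_trial(spec)
                path = cdir / f"step_{i + 1:02d}.csv"
                write_step_trial(path, trial, {"subject": subject, "condition": condition, "seed": spec.seed})
                write_json(cdir / f"step_{i + 1:02d}_truth.json", truth)
            for i in range(n_perturb):
                ss = _trial_seed(seed, subject, condition, f"perturb{i}")
                jit = np.random.default_rng(ss.spawn(1)[0])
                spec = PerturbGenSpec(
                    sway_gain=round(0.25 * (1.0 + jit.uniform(-0.15, 0.15)), 4),
                    seed=int(ss.generate_state(1)[0] % (2**31)),
                )
                trial, truth = gen_perturbation_trial(spec)
                path = cdir / f"perturb_{i + 1:02d}.csv"
                write_perturbation_trial(
                    path, trial, {"subject": subject, "condition": condition, "seed": spec.seed}
                )
                slim = {k: v for k, v in truth.items() if k not in ("com_ap", "cop_ap")}
                write_json(cdir / f"perturb_{i + 1:02d}_truth.json", slim)

    config = {
        "seed": seed,
        "input_dir": ".",
        "output_dir": "out",
        "subjects": [
            {
                "id": s,
                "foot_length_cm": SUBJECT_FOOT_CM.get(s, 26.0),
                "stepping_side": "left",
            }
            for s in subjects
        ],
        "conditions": list(conditions),
    }
    config_path = out_dir / "study.yaml"
    config_path.write_text(yaml.safe_dump(config, sort_keys=True))
    return config_path
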