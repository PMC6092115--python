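"""Reactive postural control under support-surface perturbation.

Two anteroposterior (AP) displacement series characterise the response to a
backward platform translation:

* **COP_ap** — the point of application of the ground reaction force on the
  plate, from plate statics:  ``COP_ap = -(M_ml + F_ap * d_z) / F_z + d_ap``
  where ``M_ml`` is the moment about the mediolateral axis and ``d`` the
  plate-origin offset.  Output in cm.
* **COM_ap** — the whole-body centre of mass estimated sagittally from five
  hemibody markers through a segmental anthropometric model (Winter-style
  mass and COM fractions; bilateral segments counted twice under the
  symmetric-displacement assumption).

Both series are low-pass filtered (10 Hz, dual-pass Butterworth), referenced
to their quiet-stance mean over the second preceding perturbation onset, and
summarised as RMS over the post-perturbation analysis window.

Axis convention: x = anteroposterior (positive forward), y = mediolateral,
z = vertical; ``M_ml`` is therefore the ``My`` channel.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from .core import (
    EmptyIntervalError,
    FilterSpec,
    InvalidParameterError,
    PfkError,
    UniformTimeSeries,
    butterworth_dual_pass,
    rms_displacement,
)

#: Vertical load below which plate statics are ill-conditioned, N.
DEFAULT_FZ_MIN = 50.0

#: Default post-perturbation analysis window, seconds.  The platform motion
#: itself lasts under a second and recovery completes within ~2-3 s.
DEFAULT_ANALYSIS_WINDOW = 2.5

MARKER_NAMES = ("meta5", "malleolus", "knee", "trochanter", "shoulder")


class LowLoadError(PfkError):
    """Vertical plate load fell below the statics floor."""


@dataclass(frozen=True)
class ForcePlateRecord:
    """Six-channel force-plate record (forces N, moments N·m about the plate
    origin) plus the origin offset (ap, ml, vertical) in metres."""

    fx: UniformTimeSeries
    fy: UniformTimeSeries
    fz: UniformTimeSeries
    mx: UniformTimeSeries
    my: UniformTimeSeries
    mz: UniformTimeSeries
    origin_offset: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        chans = [self.fx, self.fy, self.fz, self.mx, self.my, self.mz]
        if len({(c.fs, c.n, c.t0) for c in chans}) != 1:
            raise InvalidParameterError("all six plate channels must share fs, length and t0")


@dataclass(frozen=True)
class MarkerSet:
    """AP-coordinate series (cm) for the five sagittal hemibody markers."""

    meta5: UniformTimeSeries
    malleolus: UniformTimeSeries
    knee: UniformTimeSeries
    trochanter: UniformTimeSeries
    shoulder: UniformTimeSeries

    def __post_init__(self) -> None:
        chans = [getattr(self, name) for name in MARKER_NAMES]
        if len({(c.fs, c.n, c.t0) for c in chans}) != 1:
            raise InvalidParameterError("all markers must share fs, length and t0")

    def __getitem__(self, name: str) -> UniformTimeSeries:
        if name not in MARKER_NAMES:
            raise KeyError(name)
        return getattr(self, name)


@dataclass(frozen=True)
class Segment:
    name: str
    proximal_marker: str
    distal_marker: str
    mass_fraction: float
    com_fraction: float
    count: int = 1


@dataclass(frozen=True)
class AnthropometricModel:
    segments: tuple[Segment, ...]

    def __post_init__(self) -> None:
        total = sum(s.mass_fraction * s.count for s in self.segments)
        if abs(total - 1.0) > 1e-6:
            raise InvalidParameterError(
                f"segment mass fractions x counts must sum to 1, got {total:.8f}"
            )
        for s in self.segments:
            for m in (s.proximal_marker, s.distal_marker):
                if m not in MARKER_NAMES:
                    raise InvalidParameterError(f"segment {s.name!r} references unknown marker {m!r}")


def load_anthropometric_model(path: str | Path | None = None) -> AnthropometricModel:
    """Load a segment table from JSON; default is the shipped Winter-style table."""
    if path is None:
        text = resources.files("pfk.data").joinpath("winter_segments.json").read_text()
    else:
        text = Path(path).read_text()
    raw = json.loads(text)
    return AnthropometricModel(
        segments=tuple(
            Segment(
                name=s["name"],
                proximal_marker=s["proximal_marker"],
                distal_marker=s["distal_marker"],
                mass_fraction=float(s["mass_fraction"]),
                com_fraction=float(s["com_fraction"]),
                count=int(s.get("count", 1)),
            )
            for s in raw["segments"]
        )
    )


@dataclass(frozen=True)
class PerturbationTrial:
    markers: MarkerSet
    plate: ForcePlateRecord
    perturbation_onset: float
    analysis_window: float = DEFAULT_ANALYSIS_WINDOW

    def __post_init__(self) -> None:
        ref = self.plate.fz
        if not (ref.t0 <= self.perturbation_onset <= ref.t_end):
            raise InvalidParameterError("perturbation onset lies outside the recording")
        if self.analysis_window <= 0:
            raise InvalidParameterError("analysis window must be positive")


@dataclass(frozen=True)
class ReactiveMetrics:
    rms_com_ap: float
    rms_cop_ap: float

    def __post_init__(self) -> None:
        if self.rms_com_ap < 0 or self.rms_cop_ap < 0:
            raise InvalidParameterError("RMS metrics must be non-negative")


def cop_ap(plate: ForcePlateRecord, fz_min: float = DEFAULT_FZ_MIN) -> UniformTimeSeries:
    """AP centre-of-pressure coordinate from plate statics, in cm.

    Raises :class:`LowLoadError` naming the first offending timestamp when
    |Fz| does not exceed ``fz_min`` at every sample.
    """
    fz = plate.fz.values
    low = np.flatnonzero(np.abs(fz) <= fz_min)
    if low.size:
        t_bad = plate.fz.t0 + low[0] / plate.fz.fs
        raise LowLoadError(
            f"|Fz| <= {fz_min:g} N at t = {t_bad:.4f} s; plate statics ill-conditioned"
        )
    d_ap, _, d_z = plate.origin_offset
    cop_m = -(plate.my.values + plate.fx.values * d_z) / fz + d_ap
    return plate.fz.with_values(cop_m * 100.0, units="cm")


def com_ap(markers: MarkerSet, model: AnthropometricModel | None = None) -> UniformTimeSeries:
    """Whole-body AP centre of mass (cm) from the segmental model.

    Each segment's COM is ``proximal + com_fraction * (distal - proximal)``;
    the whole-body COM is the count- and mass-fraction-weighted sum.
    """
    if model is None:
        model = load_anthropometric_model()
    total = np.zeros(markers.meta5.n)
    for seg in model.segments:
        prox = markers[seg.proximal_marker].values
        dist = markers[seg.distal_marker].values
        seg_com = prox + seg.com_fraction * (dist - prox)
        total += seg.count * seg.mass_fraction * seg_com
    return markers.meta5.with_values(total, units="cm")


@dataclass(frozen=True)
class ReactiveParams:
    filter_spec: FilterSpec = FilterSpec()
    fz_min: float = DEFAULT_FZ_MIN
    reference_window: float = 1.0  # quiet-stance averaging span before onset, s
    prefilter: bool = True


def reactive_metrics(
    trial: PerturbationTrial,
    model: AnthropometricModel | None = None,
    params: ReactiveParams | None = None,
) -> ReactiveMetrics:
    """RMS of COP_ap and COM_ap over the post-perturbation window.

    Both series are filtered, referenced to their mean over the
    ``reference_window`` seconds immediately preceding perturbation onset,
    and summarised over ``[onset, onset + analysis_window)``.
    """
    params = params or ReactiveParams()
    onset = trial.perturbation_onset
    window = (onset, onset + trial.analysis_window)
    ref_iv = (onset - params.reference_window, onset)

    series_pairs = []
    for raw in (com_ap(trial.markers, model), cop_ap(trial.plate, params.fz_min)):
        if window[1] > raw.t_end + 0.5 / raw.fs:
            raise EmptyIntervalError(
                f"analysis window {window} extends past the recording (ends {raw.t_end:g} s)"
            )
        filt = butterworth_dual_pass(raw, params.filter_spec) if params.prefilter else raw
        reference = float(np.mean(filt.segment(ref_iv)))
        series_pairs.append(rms_displacement(filt, window, reference))
    rms_com, rms_cop = series_pairs
    return ReactiveMetrics(rms_com_ap=rms_com, rms_cop_ap=rms_cop)
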