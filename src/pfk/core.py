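"""Shared time-series primitives.

Every analysis stage in this package consumes one atom: a uniformly sampled
single-channel time series.  This module provides that type together with the
signal-conditioning primitives used throughout — zero-phase (dual-pass)
Butterworth low-pass filtering, baseline statistics over a quiet interval,
threshold-crossing onset detection (the "mean + k·SD" rule used for
anticipatory-postural-adjustment and step onsets), and RMS displacement.

Conventions
-----------
* Sample ``i`` of a series sits at ``t0 + i / fs`` seconds; all timestamps are
  seconds relative to trial start.
* Every interval is half-open, ``[start, end)``, so boundary samples are never
  counted twice by adjacent intervals.
* ``fourth-order dual-pass`` filtering is realised as a 2nd-order Butterworth
  applied forward and backward (effective 4th order, the usual biomechanics
  convention).  ``FilterSpec.order_per_pass`` makes the alternative reading
  (4th order per pass, effective 8th) available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as _sig


class PfkError(Exception):
    """Base class for all errors raised by this package."""


class InvalidParameterError(PfkError):
    """A parameter violates its documented constraint (e.g. cutoff >= Nyquist)."""


class SeriesTooShortError(PfkError):
    """The series has too few samples for the requested operation."""


class EmptyIntervalError(PfkError):
    """An analysis interval contains no samples or lies outside the series."""


class InvalidTrialError(PfkError):
    """A trial cannot yield the requested metrics (e.g. no onset crossing)."""


@dataclass(frozen=True, eq=False)
class UniformTimeSeries:
    """One channel sampled at a fixed rate.

    Parameters
    ----------
    values : array-like of float
        Ordered samples; at least two, all finite.
    fs : float
        Sampling rate in Hz (> 0).
    t0 : float
        Time of the first sample, seconds.
    label, units : str
        Free-text channel name and physical units (e.g. ``"N"``, ``"m/s^2"``).
    """

    values: np.ndarray
    fs: float
    t0: float = 0.0
    label: str = ""
    units: str = ""

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 1 or vals.size < 2:
            raise SeriesTooShortError(
                f"series {self.label!r} needs >= 2 samples, got shape {vals.shape}"
            )
        if not np.all(np.isfinite(vals)):
            raise InvalidParameterError(f"series {self.label!r} contains non-finite samples")
        if not (self.fs > 0 and math.isfinite(self.fs)):
            raise InvalidParameterError(f"sampling rate must be positive, got {self.fs}")
        object.__setattr__(self, "values", vals)

    # -- basic geometry -----------------------------------------------------
    @property
    def n(self) -> int:
        return self.values.size

    @property
    def t_end(self) -> float:
        """Time of the last sample."""
        return self.t0 + (self.n - 1) / self.fs

    @property
    def duration(self) -> float:
        """Span between first and last sample, seconds."""
        return (self.n - 1) / self.fs

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n) / self.fs

    def with_values(self, values: np.ndarray, units: str | None = None) -> "UniformTimeSeries":
        return replace(self, values=values, units=self.units if units is None else units)

    # -- interval indexing --------------------------------------------------
    def index_range(self, interval: tuple[float, float]) -> tuple[int, int]:
        """Sample index range [i0, i1) covering the half-open time interval.

        Boundary samples are resolved with a small tolerance so that an
        interval edge that coincides with a sample time behaves exactly:
        a sample at ``start`` is included, a sample at ``end`` is excluded.
        """
        start, end = interval
        if not (end > start):
            raise EmptyIntervalError(f"interval must satisfy end > start, got {interval}")
        i0 = max(0, math.ceil((start - self.t0) * self.fs - 1e-9))
        i1 = min(self.n, math.ceil((end - self.t0) * self.fs - 1e-9))
        if i1 <= i0:
            raise EmptyIntervalError(f"interval {interval} contains no samples")
        return i0, i1

    def segment(self, interval: tuple[float, float]) -> np.ndarray:
        i0, i1 = self.index_range(interval)
        return self.values[i0:i1]


@dataclass(frozen=True)
class BaselineStats:
    """Mean and sample SD of a quiet-interval segment."""

    interval: tuple[float, float]
    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise EmptyIntervalError("baseline needs >= 2 samples")
        if self.sd < 0:
            raise InvalidParameterError("baseline sd must be >= 0")


@dataclass(frozen=True)
class FilterSpec:
    """Dual-pass (forward-backward) Butterworth low-pass specification.

    ``order_per_pass=2`` gives the effective 4th-order zero-phase filter.
    ``correct_cutoff`` optionally raises the design cutoff so that the
    *combined* two-pass response is −3 dB at ``cutoff`` (off by default: the
    nominal cutoff is used as designed, and the combined −3 dB point sits
    slightly below it).
    """

    cutoff: float = 10.0
    order_per_pass: int = 2
    correct_cutoff: bool = False
    passes: int = field(default=2)

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise InvalidParameterError("cutoff must be positive")
        if self.order_per_pass < 1:
            raise InvalidParameterError("order_per_pass must be >= 1")
        if self.passes != 2:
            raise InvalidParameterError("only forward-backward (passes=2) filtering is supported")

    def design_cutoff(self) -> float:
        if not self.correct_cutoff:
            return self.cutoff
        # Combined gain of two Butterworth passes of order n:
        # G(f) = [1 + (f/fc)^(2n)]^-2 ; G = 1/2 at f_design when
        # fc = f / (sqrt(2) - 1)^(1/(2n)).
        n = self.order_per_pass
        return self.cutoff / (math.sqrt(2.0) - 1.0) ** (1.0 / (2 * n))


def butterworth_dual_pass(series: UniformTimeSeries, spec: FilterSpec | None = None) -> UniformTimeSeries:
    """Zero-phase low-pass filter: one Butterworth pass forward, one backward.

    The magnitude response is the single-pass Butterworth magnitude squared
    and the net phase shift is zero.  Edge transients are suppressed by
    odd-reflection padding of ``3 * (2 * order_per_pass + 1)`` samples,
    stripped after filtering, so outputs are reproducible bit for bit.

    Raises
    ------
    InvalidParameterError
        If the cutoff is at or above the Nyquist frequency.
    SeriesTooShortError
        If the series is not longer than the padding length.
    """
    if spec is None:
        spec = FilterSpec()
    nyquist = series.fs / 2.0
    if spec.design_cutoff() >= nyquist:
        raise InvalidParameterError(
            f"cutoff {spec.design_cutoff():g} Hz must be below Nyquist {nyquist:g} Hz"
        )
    padlen = 3 * (2 * spec.order_per_pass + 1)
    if series.n <= padlen:
        raise SeriesTooShortError(
            f"need > {padlen} samples for order {spec.order_per_pass} dual-pass, got {series.n}"
        )
    b, a = _sig.butter(spec.order_per_pass, spec.design_cutoff(), btype="low", fs=series.fs)
    filtered = _sig.filtfilt(b, a, series.values, padtype="odd", padlen=padlen)
    return series.with_values(filtered)


def baseline_stats(series: UniformTimeSeries, interval: tuple[float, float]) -> BaselineStats:
    """Mean and sample SD (n−1 denominator) over the half-open interval."""
    seg = series.segment(interval)
    if seg.size < 2:
        raise EmptyIntervalError(f"baseline interval {interval} holds < 2 samples")
    return BaselineStats(
        interval=(float(interval[0]), float(interval[1])),
        mean=float(np.mean(seg)),
        sd=float(np.std(seg, ddof=1)),
        n=int(seg.size),
    )


def onset_by_threshold(
    series: UniformTimeSeries,
    baseline: BaselineStats,
    k: float = 2.0,
    search_from: float | None = None,
    min_hold: float = 0.05,
    polarity: str = "absolute",
    sd_floor: float = 1e-9,
) -> float | None:
    """First time the signal leaves the baseline band and stays out.

    The threshold is ``k * max(baseline.sd, sd_floor)`` on the deviation from
    ``baseline.mean``; ``polarity`` selects the deviation sense (``"above"``,
    ``"below"`` or ``"absolute"``).  The crossing must persist for at least
    ``min_hold`` seconds (rejects single-sample noise spikes).  ``sd_floor``
    keeps noise-free baselines (SD exactly 0) detectable.

    Returns the timestamp of the first qualifying sample at/after
    ``search_from`` (default: end of the baseline interval), or ``None`` when
    no qualifying crossing exists — absence of a crossing is a valid outcome,
    not an error.
    """
    if polarity not in ("above", "below", "absolute"):
        raise InvalidParameterError(f"unknown polarity {polarity!r}")
    if min_hold < 0:
        raise InvalidParameterError("min_hold must be >= 0")
    if search_from is None:
        search_from = baseline.interval[1]

    dev = series.values - baseline.mean
    if polarity == "below":
        dev = -dev
    elif polarity == "absolute":
        dev = np.abs(dev)
    threshold = k * max(baseline.sd, sd_floor)
    exceed = dev > threshold

    i0 = max(0, math.ceil((search_from - series.t0) * series.fs - 1e-9))
    if i0 >= series.n:
        raise InvalidParameterError(f"search_from {search_from} s is beyond the series")

    # number of consecutive samples whose span covers min_hold seconds
    n_hold = int(math.floor(min_hold * series.fs + 1e-9)) + 1
    ok = exceed[i0:]
    if n_hold > 1:
        if ok.size < n_hold:
            return None
        windows = np.lib.stride_tricks.sliding_window_view(ok, n_hold)
        ok = windows.all(axis=1)
    hits = np.flatnonzero(ok)
    if hits.size == 0:
        return None
    return series.t0 + (i0 + int(hits[0])) / series.fs


def rms_displacement(
    series: UniformTimeSeries, interval: tuple[float, float], reference: float = 0.0
) -> float:
    """Root-mean-square deviation from ``reference`` over the interval."""
    seg = series.segment(interval)
    return float(np.sqrt(np.mean((seg - reference) ** 2)))


def moving_rms(series: UniformTimeSeries, window: float = 0.5) -> UniformTimeSeries:
    """Centered moving-RMS envelope with the given window length (seconds)."""
    from scipy.ndimage import uniform_filter1d

    n_win = max(1, int(round(window * series.fs)))
    sq = uniform_filter1d(series.values**2, size=n_win, mode="nearest")
    return series.with_values(np.sqrt(np.maximum(sq, 0.0)))
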