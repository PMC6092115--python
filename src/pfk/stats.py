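"""Outcome statistics: %change vs the unstimulated condition and t-tests.

Trial-level metrics are averaged per subject and stimulation condition
(OFF, 60 Hz, 300 Hz).  For each ON condition the percent change relative to
OFF is ``(ON - OFF) / OFF``; the improvement score flips the sign for
variables where a *decrease* is better (gait time, freeze time, APA
duration, COP/COM RMS) so that improvement is always positive.  Group
percent changes are compared against zero with a one-sample Student t-test
(two-sided by default), significance at p <= 0.05.

Subjects with an undefined baseline (OFF mean of exactly zero — e.g. no
freeze episodes in the OFF condition) are excluded for that variable, with
a logged note; no multiple-testing correction is applied by default (a
Holm option exists).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _st

from .core import InvalidParameterError, PfkError

CONDITIONS = ("OFF", "HZ60", "HZ300")
ON_CONDITIONS = ("HZ60", "HZ300")

#: Outcome variables and whether an increase or a decrease counts as
#: improvement.  Only the APA amplitude improves by increasing.
IMPROVEMENT_DIRECTION: dict[str, str] = {
    "gait_time": "decrease",
    "fog_time": "decrease",
    "apa_duration": "decrease",
    "apa_amplitude": "increase",
    "cop_ap_rms": "decrease",
    "com_ap_rms": "decrease",
}

ALPHA = 0.05


class DegenerateSampleError(PfkError):
    """Too few values, or zero variance, for a t-test."""


class UndefinedBaselineError(PfkError):
    """Percent change is undefined because the OFF value is zero."""


@dataclass(frozen=True)
class TTestResult:
    variable: str
    condition: str
    t: float
    df: int
    p: float
    n: int

    def __post_init__(self) -> None:
        if self.df != self.n - 1 or self.df < 1:
            raise InvalidParameterError("t-test requires df = n - 1 >= 1")

    @property
    def significant(self) -> bool:
        return self.p <= ALPHA


def percent_change(on_value: float, off_value: float) -> float:
    """(ON - OFF) / OFF; raises :class:`UndefinedBaselineError` when OFF = 0."""
    if off_value == 0:
        raise UndefinedBaselineError("percent change undefined for OFF baseline of 0")
    return (on_value - off_value) / off_value


def improvement_score(variable: str, pct: float) -> float:
    """Signed percent change with improvement always positive."""
    if not math.isfinite(pct):
        raise InvalidParameterError("percent change must be finite")
    direction = IMPROVEMENT_DIRECTION.get(variable)
    if direction is None:
        raise InvalidParameterError(f"unknown outcome variable {variable!r}")
    return pct if direction == "increase" else -pct


def one_sample_t(values: list[float] | np.ndarray, two_sided: bool = True) -> tuple[float, int, float]:
    """Student t-test of the sample mean against zero.

    Returns ``(t, df, p)``.  Raises :class:`DegenerateSampleError` for fewer
    than two values or zero sample SD.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 2:
        raise DegenerateSampleError(f"need >= 2 values, got {n}")
    sd = float(np.std(x, ddof=1))
    if sd == 0:
        raise DegenerateSampleError("sample SD is zero")
    t = float(np.mean(x) / (sd / math.sqrt(n)))
    df = n - 1
    if two_sided:
        p = 2.0 * float(_st.t.sf(abs(t), df))
    else:
        p = float(_st.t.sf(t, df))
    return t, df, min(p, 1.0)


def holm_adjust(pvalues: list[float]) -> list[float]:
    """Holm step-down adjusted p-values (optional; off by default upstream)."""
    order = np.argsort(pvalues)
    m = len(pvalues)
    adjusted = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * pvalues[idx])
        adjusted[idx] = min(1.0, running)
    return adjusted.tolist()


def summarize_study(
    trials: pd.DataFrame,
    *,
    two_sided: bool = True,
    holm: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame, list[TTestResult], list[str]]:
    """Aggregate a tidy trial table into the study outcome statistics.

    Parameters
    ----------
    trials : DataFrame with columns ``subject``, ``condition``, ``variable``,
        ``value`` — one row per trial metric.  Conditions must come from
        ``{OFF, HZ60, HZ300}`` and variables from the known outcome set.

    Returns
    -------
    summary : subject x condition x variable trial means and counts.
    pct : percent-change rows (subject, condition in {HZ60, HZ300}, variable,
        pct_change, improvement).  OFF rows never appear.
    tests : one :class:`TTestResult` per (variable, ON condition) with enough
        subjects; degenerate combinations are reported in ``notes`` instead.
    notes : human-readable log of exclusions and skipped tests.
    """
    required = {"subject", "condition", "variable", "value"}
    if not required.issubset(trials.columns):
        raise InvalidParameterError(f"trial table must have columns {sorted(required)}")
    bad_cond = set(trials["condition"]) - set(CONDITIONS)
    if bad_cond:
        raise InvalidParameterError(f"unknown conditions {sorted(bad_cond)}")
    bad_var = set(trials["variable"]) - set(IMPROVEMENT_DIRECTION)
    if bad_var:
        raise InvalidParameterError(f"unknown variables {sorted(bad_var)}")
    if not np.all(np.isfinite(trials["value"].to_numpy(dtype=float))):
        raise InvalidParameterError("trial values must be finite")

    notes: list[str] = []
    summary = (
        trials.groupby(["subject", "condition", "variable"], sort=True)["value"]
        .agg(mean="mean", n_trials="count")
        .reset_index()
    )

    means = summary.set_index(["subject", "condition", "variable"])["mean"]
    pct_rows = []
    for (subject, variable), group in summary.groupby(["subject", "variable"], sort=True):
        have = set(group["condition"])
        if "OFF" not in have:
            notes.append(f"{subject}/{variable}: no OFF data, subject excluded")
            continue
        off = float(means[(subject, "OFF", variable)])
        for cond in ON_CONDITIONS:
            if cond not in have:
                notes.append(f"{subject}/{variable}: missing {cond}, dropped pairwise")
                continue
            on = float(means[(subject, cond, variable)])
            try:
                pct = percent_change(on, off)
            except UndefinedBaselineError:
                notes.append(f"{subject}/{variable}: OFF mean is 0, percent change undefined")
                continue
            pct_rows.append(
                {
                    "subject": subject,
                    "condition": cond,
                    "variable": variable,
                    "pct_change": pct,
                    "improvement": improvement_score(variable, pct),
                }
            )
    pct = pd.DataFrame(pct_rows, columns=["subject", "condition", "variable", "pct_change", "improvement"])

    tests: list[TTestResult] = []
    if not pct.empty:
        for (variable, cond), group in pct.groupby(["variable", "condition"], sort=True):
            vals = group["pct_change"].to_numpy()
            try:
                t, df, p = one_sample_t(vals, two_sided=two_sided)
            except DegenerateSampleError as exc:
                notes.append(f"{variable}/{cond}: t-test skipped ({exc})")
                continue
            tests.append(TTestResult(variable=variable, condition=cond, t=t, df=df, p=p, n=len(vals)))
        if holm and tests:
            adj = holm_adjust([r.p for r in tests])
            tests = [
                TTestResult(r.variable, r.condition, r.t, r.df, a, r.n)
                for r, a in zip(tests, adj)
            ]
    return summary, pct, tests, notes
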