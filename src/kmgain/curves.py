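"""Digitized Kaplan-Meier curves: containers, IO, cleaning, step-function form.

A *digitized curve* is the sequence of (time, survival probability) pairs read
off a published KM plot with a plot digitizer.  Digitizer exports come in two
probability dialects (0-1 or 0-100%), with comma/tab/semicolon delimiters, and
carry pixel-level jitter that can locally break monotonicity; this module
normalizes all of that into a validated, non-increasing curve anchored at
(0, 1.0), and converts it to the right-continuous step function that a true
product-limit estimate is.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "DigitizedCurve",
    "SurvivalStepFunction",
    "read_digitized_curve",
    "enforce_km_shape",
    "to_step_function",
    "write_curve_csv",
]

# any digitized probability above this is taken to be on the percent scale
_PERCENT_THRESHOLD = 1.5


@dataclass(frozen=True)
class DigitizedCurve:
    """One arm's digitized survival curve.

    Parameters
    ----------
    arm_label : str
        Human-readable arm name (e.g. ``"CAR-T"``).
    times : ndarray
        Follow-up times in months, non-decreasing.  Duplicate adjacent times
        encode the two corners of a vertical KM drop.
    probs : ndarray
        Survival probabilities in [0, 1], same length as ``times``.  May be
        non-monotone for a raw digitization; :func:`enforce_km_shape` repairs
        that.
    n_subjects : int
        Cohort size at time zero.
    """

    arm_label: str
    times: np.ndarray
    probs: np.ndarray
    n_subjects: int

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        probs = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "probs", probs)
        if times.ndim != 1 or probs.ndim != 1 or times.size != probs.size:
            raise ValueError("times and probs must be 1-D sequences of equal length")
        if times.size < 2:
            raise ValueError("a digitized curve needs at least 2 points")
        if np.any(np.diff(times) < 0):
            raise ValueError("times must be non-decreasing")
        if times[0] < 0:
            raise ValueError("negative follow-up time")
        if np.any(probs < 0) or np.any(probs > 1):
            raise ValueError("survival probabilities must lie in [0, 1]")
        if not (isinstance(self.n_subjects, (int, np.integer)) and self.n_subjects > 0):
            raise ValueError("n_subjects must be a positive integer")

    @property
    def follow_up(self) -> float:
        """Maximum digitized time (months)."""
        return float(self.times[-1])

    def is_km_shaped(self) -> bool:
        """True if anchored at (0, 1.0) and non-increasing."""
        return (
            self.times[0] == 0.0
            and self.probs[0] == 1.0
            and bool(np.all(np.diff(self.probs) <= 0))
        )


@dataclass(frozen=True)
class SurvivalStepFunction:
    """Right-continuous, piecewise-constant, non-increasing survival function.

    S(t) = 1 for t before the first drop; after drop i the value is
    ``post_drop_probs[i]``.  Serves as the exact-integration oracle for the
    trapezoidal AUC and as the generative truth in the digitization emulator.
    """

    drop_times: np.ndarray
    post_drop_probs: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.drop_times, dtype=float)
        p = np.asarray(self.post_drop_probs, dtype=float)
        object.__setattr__(self, "drop_times", t)
        object.__setattr__(self, "post_drop_probs", p)
        if t.size != p.size:
            raise ValueError("drop_times and post_drop_probs must have equal length")
        if t.size and (np.any(np.diff(t) <= 0) or t[0] < 0):
            raise ValueError("drop_times must be strictly increasing and >= 0")
        if np.any(p < 0) or np.any(p > 1):
            raise ValueError("post-drop probabilities must lie in [0, 1]")
        if p.size and np.any(np.diff(p) > 0):
            raise ValueError("step function must be non-increasing")

    def __call__(self, t) -> np.ndarray | float:
        t_arr = np.asarray(t, dtype=float)
        levels = np.concatenate(([1.0], self.post_drop_probs))
        idx = np.searchsorted(self.drop_times, t_arr, side="right")
        out = levels[idx]
        return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out

    def corner_curve(
        self, arm_label: str, n_subjects: int, follow_up: float | None = None
    ) -> DigitizedCurve:
        """Emit both corners of every drop as a :class:`DigitizedCurve`.

        The trapezoidal rule applied to a corner-pair curve integrates the
        step function exactly (each vertical drop contributes zero area).
        ``follow_up`` extends the final plateau past the last drop.
        """
        times = [0.0]
        probs = [1.0]
        level = 1.0
        for t, p in zip(self.drop_times, self.post_drop_probs):
            times.extend([t, t])
            probs.extend([level, p])
            level = p
        last = times[-1] if len(times) > 1 else 0.0
        if follow_up is not None and follow_up > last:
            times.append(float(follow_up))
            probs.append(level)
        elif len(times) == 1:  # no drops at all: need a second point
            times.append(float(follow_up) if follow_up else 1.0)
            probs.append(1.0)
        return DigitizedCurve(arm_label, np.array(times), np.array(probs), n_subjects)


def _sniff_delimiter(sample: str) -> str:
    try:
        return csv.Sniffer().sniff(sample, delimiters=",;\t").delimiter
    except csv.Error:
        return ","


def read_digitized_curve(path, arm_label: str, n_subjects: int) -> DigitizedCurve:
    """Read a two-column (time, survival) delimited text file.

    The header row is optional; the delimiter (comma, tab or semicolon) is
    sniffed.  Probabilities on the percent scale (any value > 1.5) are divided
    by 100.  Rows are sorted by time, preserving the order of duplicate times
    so corner pairs stay intact.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"digitized-curve file not found: {path}")
    text = path.read_text()
    delim = _sniff_delimiter(text[:2048])
    df = pd.read_csv(io.StringIO(text), sep=delim, header=None, comment="#",
                     skip_blank_lines=True)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (time, survival)")
    df = df.iloc[:, :2]
    # drop a header row if the first row is not numeric
    first = pd.to_numeric(df.iloc[0], errors="coerce")
    if first.isna().any():
        df = df.iloc[1:]
    vals = df.apply(pd.to_numeric, errors="coerce")
    bad = vals.isna().any(axis=1)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(f"{path}: non-numeric value in data row {row}")
    times = vals.iloc[:, 0].to_numpy(dtype=float)
    probs = vals.iloc[:, 1].to_numpy(dtype=float)
    if times.size < 2:
        raise ValueError(f"{path}: fewer than 2 data rows")
    for i, (t, p) in enumerate(zip(times, probs)):
        if t < 0:
            raise ValueError(f"{path}: negative time {t} in data row {i}")
        if p < 0 or p > 100:
            raise ValueError(
                f"{path}: survival probability {p} outside [0, 100] in data row {i}"
            )
    if np.any(probs > _PERCENT_THRESHOLD):
        probs = probs / 100.0
    order = np.argsort(times, kind="stable")
    return DigitizedCurve(arm_label, times[order], probs[order], int(n_subjects))


def enforce_km_shape(curve: DigitizedCurve) -> DigitizedCurve:
    """Repair digitization noise so the curve satisfies KM-shape invariants.

    Prepends (0, 1.0) when absent, clamps probabilities into [0, 1], and
    replaces the probability sequence with its running minimum so it is
    non-increasing.  Idempotent; returns a new curve.
    """
    times = curve.times
    probs = np.clip(curve.probs, 0.0, 1.0)
    if not (times[0] == 0.0 and probs[0] == 1.0):
        times = np.concatenate(([0.0], times))
        probs = np.concatenate(([1.0], probs))
    probs = np.minimum.accumulate(probs)
    return replace(curve, times=times, probs=probs)


def to_step_function(curve: DigitizedCurve) -> SurvivalStepFunction:
    """Convert a KM-shaped digitized curve to its step-function form.

    Every strict decrease becomes one drop at its time; multiple decreases
    recorded at the same time (corner pairs) merge into a single drop to the
    lowest value.
    """
    drop_times: list[float] = []
    drop_probs: list[float] = []
    level = 1.0
    for t, p in zip(curve.times, curve.probs):
        if p < level:
            if drop_times and drop_times[-1] == t:
                drop_probs[-1] = p
            else:
                drop_times.append(float(t))
                drop_probs.append(float(p))
            level = p
    return SurvivalStepFunction(np.array(drop_times), np.array(drop_probs))


def write_curve_csv(curve: DigitizedCurve, path) -> None:
    """Write ``time,survival`` CSV (header included) for audit."""
    pd.DataFrame({"time": curve.times, "survival": curve.probs}).to_csv(
        path, index=False
    )
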