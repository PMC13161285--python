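"""Peak-intensity extraction from chemiluminescence time courses.

A luminol reaction is recorded as an intensity series on a 15-s grid over
15 minutes.  Because camera exposure time is adjusted per sample (longer
exposures for older, dimmer bones), raw intensities are normalized to a
common reference exposure before the peak is taken: detector response is
assumed proportional to exposure time, so

    corrected = raw * (reference_exposure / exposure).

Ipeak is the maximum of the corrected sampled values; no interpolation or
smoothing is applied between bins, and ties resolve to the earliest time.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import NamedTuple

import numpy as np

__all__ = [
    "TimeCourse",
    "IpeakResult",
    "SignalError",
    "DEFAULT_REFERENCE_EXPOSURE_S",
    "correct_intensity",
    "extract_ipeak",
    "resample_to_grid",
    "read_timecourse",
    "write_timecourse",
]

DEFAULT_REFERENCE_EXPOSURE_S = 30.0


class SignalError(ValueError):
    """Invalid time course or correction parameters."""


@dataclass(frozen=True)
class TimeCourse:
    """An emission series: strictly increasing times (s), intensities (A.U.)."""

    sample_id: int | str
    times_s: np.ndarray
    intensities_au: np.ndarray
    exposure_s: float

    def __post_init__(self) -> None:
        t = np.asarray(self.times_s, dtype=float)
        y = np.asarray(self.intensities_au, dtype=float)
        object.__setattr__(self, "times_s", t)
        object.__setattr__(self, "intensities_au", y)
        if t.ndim != 1 or y.ndim != 1 or t.size != y.size or t.size < 1:
            raise SignalError("times and intensities must be 1-D, same length, non-empty")
        if np.any(t <= 0) or np.any(np.diff(t) <= 0):
            raise SignalError("times must be positive and strictly increasing")
        if np.any(y < 0) or not np.all(np.isfinite(y)):
            raise SignalError("intensities must be finite and non-negative")
        if not self.exposure_s > 0:
            raise SignalError(f"exposure_s must be positive, got {self.exposure_s}")

    def __len__(self) -> int:
        return int(self.times_s.size)


class IpeakResult(NamedTuple):
    ipeak_au: float
    time_s: float


def correct_intensity(raw_au, exposure_s: float, reference_exposure_s: float):
    """Normalize a raw intensity to the reference exposure time.

    Returns ``raw_au * (reference_exposure_s / exposure_s)``; linear in the
    raw value, identity when the exposures match.  Accepts scalars or
    arrays.
    """
    if not exposure_s > 0:
        raise SignalError(f"exposure_s must be positive, got {exposure_s}")
    if not reference_exposure_s > 0:
        raise SignalError(
            f"reference_exposure_s must be positive, got {reference_exposure_s}"
        )
    raw = np.asarray(raw_au, dtype=float)
    if np.any(raw < 0):
        raise SignalError("raw intensity must be non-negative")
    out = raw * (reference_exposure_s / exposure_s)
    return float(out) if np.isscalar(raw_au) else out


def extract_ipeak(
    tc: TimeCourse,
    reference_exposure_s: float = DEFAULT_REFERENCE_EXPOSURE_S,
) -> IpeakResult:
    """Maximum corrected emission of a series and the time it occurs.

    Ties on the maximum resolve to the earliest time bin.  An all-zero
    series has no measurable reaction and raises :class:`SignalError`.
    """
    if not np.any(tc.intensities_au > 0):
        raise SignalError(f"sample {tc.sample_id}: no emission detected (all-zero series)")
    corrected = correct_intensity(tc.intensities_au, tc.exposure_s, reference_exposure_s)
    idx = int(np.argmax(corrected))  # argmax takes the first occurrence on ties
    return IpeakResult(ipeak_au=float(corrected[idx]), time_s=float(tc.times_s[idx]))


def resample_to_grid(tc: TimeCourse, step_s: float = 15.0) -> TimeCourse:
    """Aggregate a series onto the canonical grid ``step, 2*step, ...``.

    Each output bin ``k`` holds the mean of the input samples with
    ``(k-1)*step < t <= k*step``; empty bins are omitted.  A series already
    on the grid passes through unchanged.
    """
    if not step_s > 0:
        raise SignalError(f"step_s must be positive, got {step_s}")
    if len(tc) == 0:  # unreachable via constructor; defensive
        raise SignalError("empty series")
    bins = np.ceil(tc.times_s / step_s - 1e-12).astype(int)
    out_t, out_y = [], []
    for b in np.unique(bins):
        m = bins == b
        out_t.append(b * step_s)
        out_y.append(float(np.mean(tc.intensities_au[m])))
    return replace(tc, times_s=np.array(out_t), intensities_au=np.array(out_y))


def read_timecourse(path: str | Path) -> TimeCourse:
    """Read a time-course CSV with columns sample_id,time_s,intensity_au,exposure_s."""
    path = Path(path)
    times, vals = [], []
    sid: int | str | None = None
    exposure: float | None = None
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        required = {"sample_id", "time_s", "intensity_au", "exposure_s"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise SignalError(f"{path}: expected columns {sorted(required)}")
        for row in reader:
            sid = row["sample_id"]
            times.append(float(row["time_s"]))
            vals.append(float(row["intensity_au"]))
            exposure = float(row["exposure_s"])
    if sid is None or exposure is None:
        raise SignalError(f"{path}: no data rows")
    return TimeCourse(sample_id=sid, times_s=np.array(times),
                      intensities_au=np.array(vals), exposure_s=exposure)


def write_timecourse(tc: TimeCourse, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["sample_id", "time_s", "intensity_au", "exposure_s"])
        for t, y in zip(tc.times_s, tc.intensities_au):
            writer.writerow([tc.sample_id, repr(float(t)), repr(float(y)), repr(float(tc.exposure_s))])
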