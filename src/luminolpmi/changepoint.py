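"""Slope-ratio changepoint grid search on log-transformed intensities.

The intensity-PMI relation is biphasic: a steep early decay and a
near-flat long-term phase.  To locate the transition, Ipeak is
log-transformed (which linearizes the exponential phase) and, for each
candidate split index c, straight lines are fitted to points 1..c and
c+1..n of the PMI-sorted data.  The ratio of the two slopes jumps sharply
once the early segment stops absorbing long-term points, so the optimal
last index of the early segment is the candidate with the largest absolute
change in slope ratio relative to the previous candidate.

Indices are 1-based on the PMI-sorted dataset (approximate-PMI samples
excluded), so the published candidate range "points 5 to 19" maps directly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io import LuminolDataset, drop_approximate

__all__ = [
    "ChangepointScan",
    "NoChangepointError",
    "scan_changepoint",
    "breakpoint_value",
    "DEFAULT_FLATNESS_TOL",
]

DEFAULT_FLATNESS_TOL = 0.5


class NoChangepointError(RuntimeError):
    """The scan found no changepoint evidence; supply a breakpoint manually."""


@dataclass(frozen=True)
class ChangepointScan:
    """Profile of the slope-ratio grid search.

    ``candidate_last_indices[i]`` is the 1-based index of the last point
    assigned to the early segment; ``variation[i]`` is
    ``|ratio[i] - ratio[i-1]|`` (NaN for the first candidate).
    """

    candidate_last_indices: np.ndarray
    slope1: np.ndarray
    slope2: np.ndarray
    slope_ratios: np.ndarray
    variation: np.ndarray
    optimal_last_index: int
    optimal_transition_pmi: tuple[float, float]
    no_changepoint_evidence: bool
    flatness_tol: float

    def to_rows(self) -> list[dict]:
        """Per-candidate profile rows (for CSV export)."""
        return [
            {
                "candidate_last_index": int(c),
                "slope1": float(s1),
                "slope2": float(s2),
                "slope_ratio": float(r),
                "variation": float(v),
            }
            for c, s1, s2, r, v in zip(
                self.candidate_last_indices,
                self.slope1,
                self.slope2,
                self.slope_ratios,
                self.variation,
            )
        ]


def _ols_slope(x: np.ndarray, y: np.ndarray, candidate: int) -> float:
    if np.ptp(x) == 0:
        raise ValueError(f"candidate {candidate}: segment has zero x-variance")
    slope, _ = np.polyfit(x, y, 1)
    return float(slope)


def scan_changepoint(
    ds: LuminolDataset,
    c_min: int = 5,
    c_max: int = 19,
    flatness_tol: float = DEFAULT_FLATNESS_TOL,
    exclude_approximate: bool = True,
) -> ChangepointScan:
    """Grid-search the early-segment last index over ``[c_min, c_max]``.

    The dataset is PMI-sorted internally and approximate-PMI samples are
    dropped by default, so the result is invariant to input row order.
    When the maximum variation falls below ``flatness_tol`` the scan is
    flagged as showing no changepoint evidence (single-phase data).
    """
    work = drop_approximate(ds) if exclude_approximate else ds
    work = work.sorted_by_pmi()
    n = len(work)
    if not (3 <= c_min < c_max <= n - 3):
        raise ValueError(
            f"candidate range [{c_min}, {c_max}] must satisfy 3 <= c_min < c_max <= n-3 (n={n})"
        )
    x = work.pmi
    lny = np.log(work.ipeak)

    candidates = np.arange(c_min, c_max + 1)
    s1 = np.empty(candidates.size)
    s2 = np.empty(candidates.size)
    ratios = np.empty(candidates.size)
    for i, c in enumerate(candidates):
        s1[i] = _ols_slope(x[:c], lny[:c], int(c))
        s2[i] = _ols_slope(x[c:], lny[c:], int(c))
        if s2[i] == 0:
            warnings.warn(f"candidate {c}: flat late segment, slope ratio undefined; skipped")
            ratios[i] = np.nan
        else:
            ratios[i] = s1[i] / s2[i]

    variation = np.full(candidates.size, np.nan)
    variation[1:] = np.abs(np.diff(ratios))
    if np.all(np.isnan(variation)):
        raise ValueError("no usable candidate pairs in the scan")
    # ties and NaNs: nanargmax takes the first (smallest index) maximum
    best = int(np.nanargmax(variation))
    max_var = float(variation[best])
    opt = int(candidates[best])
    transition = (float(x[opt - 1]), float(x[opt]))

    return ChangepointScan(
        candidate_last_indices=candidates,
        slope1=s1,
        slope2=s2,
        slope_ratios=ratios,
        variation=variation,
        optimal_last_index=opt,
        optimal_transition_pmi=transition,
        no_changepoint_evidence=max_var < flatness_tol,
        flatness_tol=flatness_tol,
    )


def breakpoint_value(scan: ChangepointScan) -> float:
    """Midpoint of the optimal transition interval, in years.

    Raises :class:`NoChangepointError` for scans flagged as single-phase;
    callers should then supply a breakpoint explicitly.
    """
    if scan.no_changepoint_evidence:
        raise NoChangepointError(
            "scan shows no changepoint evidence "
            f"(max slope-ratio variation < {scan.flatness_tol}); "
            "supply breakpoint_years manually"
        )
    a, b = scan.optimal_transition_pmi
    return (a + b) / 2.0
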