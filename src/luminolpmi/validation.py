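"""Leave-one-out cross-validation of the segmented model.

Each segment is validated separately: every retained point is held out in
turn, the segment model is refitted on the rest, and the held-out Ipeak is
predicted.  Predictive error is aggregated as RMSPE (percent).  Outlier
exclusions are frozen before validation — folds re-use the final model's
point sets rather than re-screening, so fold counts are stable and the
procedure is fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .io import LuminolDataset
from .pipeline import SegmentedModel
from .regression import FitError, fit_decay, fit_line, rmspe

__all__ = ["LoocvResult", "loocv_segment", "loocv_model"]


@dataclass(frozen=True)
class LoocvResult:
    """Per-segment LOOCV outcome."""

    segment_label: str
    fold_predictions: tuple[tuple[int, float, float], ...]  # (id, y_true, y_pred)
    rmspe_percent: float
    n_folds: int
    failures: frozenset[int]

    def to_dict(self) -> dict:
        return {
            "segment": self.segment_label,
            "rmspe_percent": self.rmspe_percent,
            "n_folds": self.n_folds,
            "failures": sorted(self.failures),
            "folds": [
                {"id": i, "y_true": yt, "y_pred": yp}
                for i, yt, yp in self.fold_predictions
            ],
        }


def loocv_segment(
    x,
    y,
    model_kind: Literal["decay", "line"],
    ids=None,
    fix_x0_at: float | Literal["min"] = "min",
    segment_label: str = "",
) -> LoocvResult:
    """Leave-one-out validation of one segment.

    Decay folds pin x0 at the full segment's value and start from the
    full-fit parameters, which keeps the refits deterministic and robust
    at small n.  Folds whose refit fails are recorded in ``failures`` and
    excluded from the RMSPE (with a warning).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    ids = np.arange(1, n + 1) if ids is None else np.asarray(ids, dtype=int)
    min_n = 5 if model_kind == "decay" else 4
    if n < min_n:
        raise ValueError(f"LOOCV for {model_kind} needs at least {min_n} points, got {n}")

    init = None
    pin = None
    if model_kind == "decay":
        pin = float(np.min(x)) if fix_x0_at == "min" else float(fix_x0_at)
        full = fit_decay(x, y, fix_x0_at=pin)
        init = (full.a1, full.t1)

    folds: list[tuple[int, float, float]] = []
    failures: set[int] = set()
    for i in range(n):
        keep = np.ones(n, dtype=bool)
        keep[i] = False
        try:
            if model_kind == "decay":
                sub = fit_decay(x[keep], y[keep], fix_x0_at=pin, p0=init)
            else:
                sub = fit_line(x[keep], y[keep])
        except FitError:
            failures.add(int(ids[i]))
            continue
        folds.append((int(ids[i]), float(y[i]), float(sub.predict(x[i]))))
    if failures:
        import warnings

        warnings.warn(f"LOOCV: {len(failures)} fold(s) failed to refit: {sorted(failures)}")
    if not folds:
        raise FitError("every LOOCV fold failed to refit")
    y_true = np.array([f[1] for f in folds])
    y_pred = np.array([f[2] for f in folds])
    return LoocvResult(
        segment_label=segment_label or model_kind,
        fold_predictions=tuple(folds),
        rmspe_percent=rmspe(y_true, y_pred),
        n_folds=len(folds),
        failures=frozenset(failures),
    )


def loocv_model(model: SegmentedModel, ds: LuminolDataset | None = None) -> tuple[LoocvResult, LoocvResult]:
    """LOOCV of both segments of a fitted model.

    Uses the model's retained point sets (outlier flags frozen); the
    optional dataset argument is accepted for interface symmetry but the
    retained arrays stored on the model are authoritative.
    """
    res1 = loocv_segment(
        model.seg1_x,
        model.seg1_y,
        "decay",
        ids=np.asarray(model.seg1_ids),
        fix_x0_at=model.seg1.x0 if model.seg1.fixed_x0 else "min",
        segment_label="seg1",
    )
    res2 = loocv_segment(
        model.seg2_x, model.seg2_y, "line", ids=np.asarray(model.seg2_ids), segment_label="seg2"
    )
    return res1, res2
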