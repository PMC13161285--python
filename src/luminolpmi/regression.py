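"""Segment models and influence diagnostics.

Two regression families describe peak luminol intensity against PMI:

* an exponential decay ``y = A1 * exp(-(x - x0) / t1)`` for the steep
  early-PMI phase, fitted by nonlinear least squares on the raw intensity
  scale and initialized from a log-linear regression of ln(y) on x;
* an ordinary least-squares line ``y = intercept + slope * x`` for the
  near-flat long-term phase.

In the decay model, A1 and x0 trade off exactly — only ``A1 * exp(x0/t1)``
is identified — so by default x0 is fixed at the minimum x of the fitted
segment and (A1, t1) are estimated.  A free-x0 mode exists for parity with
three-parameter reports, but its per-parameter confidence intervals are
flagged unreliable.

Fit quality is summarized by R^2 on the training data, wMAPE
(sum|y-yhat| / sum|y|), and, for prediction, RMSPE (percent).  Influence
screening uses Cook's distance: the exact classical formula for the linear
model and a deletion-refit generalization for the decay model.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import statsmodels.api as sm
from scipy import optimize, stats

__all__ = [
    "DecayFit",
    "LineFit",
    "InfluenceReport",
    "FitError",
    "TopK",
    "ThresholdOverN",
    "AbsoluteThreshold",
    "fit_decay",
    "predict_decay",
    "fit_line",
    "predict_line",
    "wmape",
    "rmspe",
    "cooks_distances",
    "deletion_cooks_distances",
    "flag_outliers",
]

MAX_NFEV = 2000  # function-evaluation cap for the decay optimizer
GTOL = 1e-10


class FitError(RuntimeError):
    """Nonlinear fit failed to converge or the design is degenerate."""


def wmape(y, yhat) -> float:
    """Weighted mean absolute percentage error, sum|y-yhat| / sum|y|.

    Dimensionless fraction; invariant under common positive rescaling.
    """
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.size == 0:
        raise ValueError("wmape of empty input")
    if y.shape != yhat.shape:
        raise ValueError("y and yhat must have equal length")
    if np.any(y <= 0):
        raise ValueError("wmape requires positive observations")
    return float(np.sum(np.abs(y - yhat)) / np.sum(np.abs(y)))


def rmspe(y, yhat) -> float:
    """Root mean square percentage error, 100 * sqrt(mean(((y-yhat)/y)^2))."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.size == 0:
        raise ValueError("rmspe of empty input")
    if y.shape != yhat.shape:
        raise ValueError("y and yhat must have equal length")
    if np.any(y <= 0):
        raise ValueError("rmspe requires positive observations")
    return float(100.0 * np.sqrt(np.mean(((y - yhat) / y) ** 2)))


def _r2(y: np.ndarray, yhat: np.ndarray) -> float:
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    return 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else -np.inf)


def _ci95(params: np.ndarray, cov: np.ndarray, dof: int) -> tuple[tuple[float, float], ...]:
    if dof <= 0:
        return tuple((float("nan"), float("nan")) for _ in params)
    tq = stats.t.ppf(0.975, dof)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    return tuple((float(p - tq * s), float(p + tq * s)) for p, s in zip(params, se))


@dataclass(frozen=True)
class DecayFit:
    """Fitted exponential decay segment ``A1 * exp(-(x - x0)/t1)``."""

    a1: float
    x0: float
    t1: float
    fixed_x0: bool
    covariance: np.ndarray
    r2: float
    wmape: float
    residuals: np.ndarray
    n_points: int
    ci95: tuple[tuple[float, float], ...]
    #: CIs from a free-x0 fit are unreliable: A1 and x0 are jointly unidentified.
    ci_reliable: bool = True

    @property
    def n_free_params(self) -> int:
        return 2 if self.fixed_x0 else 3

    def predict(self, x) -> np.ndarray:
        return predict_decay(self, x)

    def to_dict(self) -> dict:
        names = ("a1", "t1") if self.fixed_x0 else ("a1", "x0", "t1")
        return {
            "kind": "exponential_decay",
            "params": {"a1": self.a1, "x0": self.x0, "t1": self.t1},
            "fixed_x0": self.fixed_x0,
            "ci95": {n: list(ci) for n, ci in zip(names, self.ci95)},
            "ci_reliable": self.ci_reliable,
            "r2": self.r2,
            "wmape": self.wmape,
            "n": self.n_points,
        }


@dataclass(frozen=True)
class LineFit:
    """Ordinary least-squares line ``intercept + slope * x``."""

    intercept: float
    slope: float
    covariance: np.ndarray
    r2: float
    wmape: float
    residuals: np.ndarray
    n_points: int
    ci95: tuple[tuple[float, float], ...]

    def predict(self, x) -> np.ndarray:
        return predict_line(self, x)

    def to_dict(self) -> dict:
        return {
            "kind": "line",
            "params": {"intercept": self.intercept, "slope": self.slope},
            "ci95": {"intercept": list(self.ci95[0]), "slope": list(self.ci95[1])},
            "r2": self.r2,
            "wmape": self.wmape,
            "n": self.n_points,
        }


def _decay_model_fixed(x0: float):
    def f(x, a1, t1):
        return a1 * np.exp(-(x - x0) / t1)

    return f


def _log_linear_init(x: np.ndarray, y: np.ndarray, x0: float) -> tuple[float, float]:
    """Deterministic starting values from OLS of ln(y) on x."""
    slope, intercept = np.polyfit(x, np.log(y), 1)
    if slope < 0:
        t1_0 = -1.0 / slope
    else:  # non-decreasing data; fall back to the x span
        t1_0 = float(np.ptp(x)) or 1.0
    # ln y = (ln a1 + x0/t1) - x/t1, so the intercept is ln a1 + x0/t1
    a1_0 = float(np.exp(intercept - x0 / t1_0))
    return max(a1_0, 1e-12), max(t1_0, 1e-6)


def fit_decay(
    x,
    y,
    fix_x0_at: float | Literal["free", "min"] = "min",
    p0: Sequence[float] | None = None,
) -> DecayFit:
    """Least-squares exponential-decay fit on the raw intensity scale.

    Parameters
    ----------
    x, y
        PMI (years) and Ipeak (A.U.); all ``y`` must be positive.
    fix_x0_at
        ``"min"`` (default) pins x0 at ``min(x)``; a number pins it there;
        ``"free"`` estimates (A1, x0, t1) jointly, with CIs flagged
        unreliable because A1 and x0 are not separately identified.
    p0
        Optional starting values ``(a1, t1)`` (fixed x0) or
        ``(a1, x0, t1)`` (free); defaults to a log-linear initializer.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    if np.any(y <= 0):
        raise ValueError("fit_decay requires positive intensities")
    free_x0 = fix_x0_at == "free"
    n, p = x.size, (3 if free_x0 else 2)
    if n < p + 1:
        raise FitError(f"need at least {p + 1} points for {p} free parameters, got {n}")

    x0_pin = float(np.min(x)) if fix_x0_at == "min" else (None if free_x0 else float(fix_x0_at))

    try:
        with warnings.catch_warnings():
            # the parameter covariance is rebuilt below (sandwich form), so
            # curve_fit's own singular-covariance warning is redundant
            warnings.simplefilter("ignore", optimize.OptimizeWarning)
            if free_x0:
                x0_start = float(np.min(x))
                a1_0, t1_0 = _log_linear_init(x, y, x0_start)
                start = list(p0) if p0 is not None else [a1_0, x0_start, t1_0]
                popt, _ = optimize.curve_fit(
                    lambda xx, a1, x0, t1: a1 * np.exp(-(xx - x0) / t1),
                    x, y, p0=start, maxfev=MAX_NFEV, gtol=GTOL,
                )
                a1, x0_hat, t1 = (float(v) for v in popt)
            else:
                model = _decay_model_fixed(x0_pin)
                start = list(p0) if p0 is not None else list(_log_linear_init(x, y, x0_pin))
                popt, _ = optimize.curve_fit(model, x, y, p0=start, maxfev=MAX_NFEV, gtol=GTOL)
                a1, t1 = (float(v) for v in popt)
                x0_hat = x0_pin
    except RuntimeError as exc:
        raise FitError(f"decay fit did not converge (start={start}): {exc}") from exc
    if not (a1 > 0 and t1 > 0 and np.all(np.isfinite(popt))):
        raise FitError(f"decay fit converged to an invalid solution {popt} (start={start})")

    yhat = a1 * np.exp(-(x - x0_hat) / t1)
    resid = y - yhat
    cov = _decay_sandwich_cov(x, yhat, resid, a1, x0_hat, t1, free_x0)
    return DecayFit(
        a1=a1,
        x0=x0_hat,
        t1=t1,
        fixed_x0=not free_x0,
        covariance=cov,
        r2=_r2(y, yhat),
        wmape=wmape(y, yhat),
        residuals=resid,
        n_points=n,
        ci95=_ci95(popt, cov, n - p),
        ci_reliable=not free_x0,
    )


def _decay_sandwich_cov(
    x: np.ndarray,
    yhat: np.ndarray,
    resid: np.ndarray,
    a1: float,
    x0: float,
    t1: float,
    free_x0: bool,
) -> np.ndarray:
    """Heteroscedasticity-robust (HC3) covariance of the decay parameters.

    Intensity noise is close to multiplicative, so the residual variance
    grows with the mean; the model-based least-squares covariance then
    undercovers.  The sandwich estimator with leverage-corrected squared
    residuals restores near-nominal interval coverage without weighting
    the fit itself.
    """
    cols = [yhat / a1]
    if free_x0:
        cols.append(yhat / t1)
    cols.append(yhat * (x - x0) / t1**2)
    J = np.column_stack(cols)
    bread = np.linalg.pinv(J.T @ J)
    h = np.clip(np.einsum("ij,jk,ik->i", J, bread, J), 0.0, 1.0 - 1e-8)
    scale = float(np.mean(np.abs(yhat))) or 1.0
    if np.max(np.abs(resid)) <= 1e-9 * scale:  # essentially perfect fit
        return np.zeros((J.shape[1], J.shape[1]))
    w = (resid / (1.0 - h)) ** 2
    return bread @ (J.T @ (J * w[:, None])) @ bread


def predict_decay(fit: DecayFit, x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return fit.a1 * np.exp(-(x - fit.x0) / fit.t1)


def fit_line(x, y) -> LineFit:
    """Ordinary least squares with intercept (closed-form normal equations)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    if np.unique(x).size < 2:
        raise FitError("degenerate design: all x identical")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    yhat = np.asarray(res.fittedvalues)
    params = np.asarray(res.params)
    cov = np.asarray(res.cov_params())
    return LineFit(
        intercept=float(params[0]),
        slope=float(params[1]),
        covariance=cov,
        r2=_r2(y, yhat),
        wmape=wmape(y, yhat) if np.all(y > 0) else float("nan"),
        residuals=y - yhat,
        n_points=x.size,
        ci95=_ci95(params, cov, x.size - 2),
    )


def predict_line(fit: LineFit, x) -> np.ndarray:
    return fit.intercept + fit.slope * np.asarray(x, dtype=float)


# ---------------------------------------------------------------------------
# Influence diagnostics

@dataclass
class InfluenceReport:
    """Cook's distances for one fitted segment, plus flagging state."""

    ids: np.ndarray
    distances: np.ndarray
    model_kind: Literal["decay", "line"]
    threshold: float | None = None
    flagged_ids: frozenset[int] = field(default_factory=frozenset)
    rule: str = "unflagged"

    def to_dict(self) -> dict:
        return {
            "model_kind": self.model_kind,
            "distances": {int(i): float(d) for i, d in zip(self.ids, self.distances)},
            "threshold": self.threshold,
            "flagged_ids": sorted(int(i) for i in self.flagged_ids),
            "rule": self.rule,
        }


@dataclass(frozen=True)
class TopK:
    """Flag the k largest Cook's distances."""

    k: int

    def label(self) -> str:
        return f"top_k({self.k})"


@dataclass(frozen=True)
class ThresholdOverN:
    """Flag distances above multiplier/n (classical 4/n screen by default)."""

    multiplier: float = 4.0

    def label(self) -> str:
        return f"threshold_{self.multiplier:g}_over_n"


@dataclass(frozen=True)
class AbsoluteThreshold:
    """Flag distances above a fixed cutoff (classical D > 1 by default)."""

    value: float = 1.0

    def label(self) -> str:
        return f"threshold_{self.value:g}"


OutlierRule = TopK | ThresholdOverN | AbsoluteThreshold


def _is_perfect_fit(y: np.ndarray, resid: np.ndarray) -> bool:
    scale = float(np.mean(np.abs(y))) or 1.0
    return bool(np.max(np.abs(resid)) <= 1e-9 * scale)


def _classical_line_cooks(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    res = sm.OLS(y, sm.add_constant(x)).fit()
    if _is_perfect_fit(y, np.asarray(res.resid)):
        return np.zeros(x.size)  # no observation moves an exact fit
    d, _ = res.get_influence().cooks_distance
    return np.asarray(d, dtype=float)


def deletion_cooks_distances(
    x,
    y,
    model_kind: Literal["decay", "line"],
    fix_x0_at: float | Literal["free", "min"] = "min",
) -> np.ndarray:
    """Cook's distances by the deletion definition.

    ``D_i = sum_j (yhat_j - yhat_j^(-i))^2 / (p * s^2)`` where
    ``yhat^(-i)`` are full-data predictions from a refit without point i,
    ``p`` the number of free parameters, and ``s^2 = SSres/(n-p)`` from the
    full fit.  For the linear model this equals the classical hat-matrix
    formula exactly.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if model_kind == "decay":
        # pin x0 once for the whole screen so deletions share one model family
        pin = float(np.min(x)) if fix_x0_at == "min" else fix_x0_at
        full = fit_decay(x, y, fix_x0_at=pin)
        yhat_full = full.predict(x)
        p = full.n_free_params
        init = (full.a1, full.t1) if full.fixed_x0 else (full.a1, full.x0, full.t1)
    else:
        full = fit_line(x, y)
        yhat_full = full.predict(x)
        p = 2
        init = None
    if n <= p + 1:
        raise FitError(f"need more than {p + 1} points for influence screening, got {n}")
    if _is_perfect_fit(y, y - yhat_full):
        return np.zeros(n)
    s2 = float(np.sum((y - yhat_full) ** 2)) / (n - p)
    out = np.empty(n)
    for i in range(n):
        keep = np.ones(n, dtype=bool)
        keep[i] = False
        try:
            if model_kind == "decay":
                sub = fit_decay(x[keep], y[keep], fix_x0_at=pin, p0=init)
            else:
                sub = fit_line(x[keep], y[keep])
        except FitError as exc:
            raise FitError(f"deletion refit failed for point index {i}: {exc}") from exc
        out[i] = float(np.sum((yhat_full - sub.predict(x)) ** 2)) / (p * s2)
    return out


def cooks_distances(
    x,
    y,
    model_kind: Literal["decay", "line"],
    ids=None,
    fix_x0_at: float | Literal["free", "min"] = "min",
) -> InfluenceReport:
    """Influence screen for one segment.

    Uses the exact classical Cook's distance for the linear model and the
    deletion-refit generalization for the decay model.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ids = np.arange(1, x.size + 1) if ids is None else np.asarray(ids, dtype=int)
    if model_kind == "line":
        d = _classical_line_cooks(x, y)
    elif model_kind == "decay":
        d = deletion_cooks_distances(x, y, "decay", fix_x0_at=fix_x0_at)
    else:
        raise ValueError(f"unknown model_kind {model_kind!r}")
    return InfluenceReport(ids=ids, distances=d, model_kind=model_kind)


def flag_outliers(report: InfluenceReport, rule: OutlierRule) -> frozenset[int]:
    """Apply a flagging rule to an influence report.

    The rule, cutoff, and flagged ids are recorded on the report; the
    flagged id set is returned.
    """
    n = report.distances.size
    if isinstance(rule, TopK):
        if rule.k > n:
            raise ValueError(f"top_k({rule.k}) exceeds segment size {n}")
        if rule.k == 0:
            flagged: frozenset[int] = frozenset()
        else:
            order = np.argsort(-report.distances, kind="stable")
            flagged = frozenset(int(i) for i in report.ids[order[: rule.k]])
        report.threshold = None
    elif isinstance(rule, ThresholdOverN):
        cut = rule.multiplier / n
        flagged = frozenset(int(i) for i, d in zip(report.ids, report.distances) if d > cut)
        report.threshold = cut
    elif isinstance(rule, AbsoluteThreshold):
        flagged = frozenset(int(i) for i, d in zip(report.ids, report.distances) if d > rule.value)
        report.threshold = rule.value
    else:
        raise TypeError(f"unknown outlier rule {rule!r}")
    report.flagged_ids = flagged
    report.rule = rule.label()
    return flagged
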