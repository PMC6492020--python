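"""Vulnerability-curve fitting and threshold statistics.

The curve family is a two-parameter Weibull on the water-potential
magnitude::

    PLC(psi) = 100 * (1 - exp(-(|psi|/b)**c)),   b, c > 0

fitted by unweighted nonlinear least squares with multi-start
initialisation. Thresholds ``psi_p`` solve ``PLC = p`` in closed form and
95% confidence intervals come from nonparametric case resampling of the
(psi, PLC) observations. Psi is carried as negative MPa everywhere; only
the fitting internals work on |psi|.

A logistic-sigmoid alternative (:func:`fit_logistic`) is provided for
sensitivity analysis only; every reported statistic uses the Weibull fit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import ConvergenceError, ValidationError

__all__ = [
    "WeibullFit",
    "ThresholdSet",
    "VulnerabilityCurve",
    "CurveComparison",
    "weibull_plc",
    "solve_weibull_parameters",
    "fit_weibull",
    "fit_logistic",
    "threshold_psi",
    "bootstrap_thresholds",
    "fit_curve",
    "compare_curves",
]

THRESHOLD_LEVELS = (12.0, 50.0, 88.0)


@dataclass(frozen=True)
class WeibullFit:
    scale_mpa: float  # b > 0, on |psi|
    shape: float      # c > 0
    converged: bool
    rss: float
    n: int

    def plc(self, psi_mpa) -> np.ndarray:
        return weibull_plc(psi_mpa, self.scale_mpa, self.shape)


@dataclass(frozen=True)
class ThresholdSet:
    """Psi at 12/50/88% loss with percentile bootstrap CIs (signed MPa)."""

    psi12_mpa: float
    psi50_mpa: float
    psi88_mpa: float
    ci: dict[str, tuple[float, float]]  # key "psi50" -> (low, high), low <= high
    n: int
    n_boot: int = 0
    n_failed: int = 0

    def value(self, which: str) -> float:
        return {"psi12": self.psi12_mpa, "psi50": self.psi50_mpa,
                "psi88": self.psi88_mpa}[which]


@dataclass
class VulnerabilityCurve:
    organ: str
    method: str  # "hydraulic" | "microct"
    points: pd.DataFrame  # columns psi_mpa, plc_pct
    fit: WeibullFit | None = None
    thresholds: ThresholdSet | None = None


@dataclass(frozen=True)
class CurveComparison:
    threshold: str
    value_a: float
    value_b: float
    ci_a: tuple[float, float]
    ci_b: tuple[float, float]
    significant: bool


def weibull_plc(psi_mpa, scale_mpa: float, shape: float):
    """Evaluate the Weibull PLC curve at (negative) psi, in percent."""
    x = np.abs(np.asarray(psi_mpa, dtype=float))
    with np.errstate(over="ignore"):
        out = 100.0 * (1.0 - np.exp(-((x / scale_mpa) ** shape)))
    return float(out) if np.isscalar(psi_mpa) else out


def _loss_quantile(p_pct: float) -> float:
    if not (0.0 < p_pct < 100.0):
        raise ValidationError("loss percentage must lie strictly in (0, 100)")
    return -math.log(1.0 - p_pct / 100.0)


def threshold_psi(fit: WeibullFit, p_pct: float) -> float:
    """Signed water potential at ``p_pct`` percent loss: ``-b*(-ln(1-p/100))**(1/c)``."""
    if not fit.converged:
        raise ConvergenceError("cannot evaluate thresholds of a non-converged fit")
    return -fit.scale_mpa * _loss_quantile(p_pct) ** (1.0 / fit.shape)


def solve_weibull_parameters(psi_a_mpa: float, p_a_pct: float,
                             psi_b_mpa: float, p_b_pct: float) -> WeibullFit:
    """Solve (scale, shape) exactly from two distinct (psi, loss%) thresholds.

    Inverts the threshold relation for two points; used to reconstruct a
    curve from published threshold pairs such as (psi12, psi50).
    """
    xa, xb = abs(psi_a_mpa), abs(psi_b_mpa)
    if xa <= 0 or xb <= 0 or xa == xb:
        raise ValidationError("need two distinct negative water potentials")
    qa, qb = _loss_quantile(p_a_pct), _loss_quantile(p_b_pct)
    if qa == qb:
        raise ValidationError("need two distinct loss percentages")
    shape = math.log(qa / qb) / math.log(xa / xb)
    if shape <= 0:
        raise ValidationError("thresholds imply a non-increasing curve")
    scale = xa / qa ** (1.0 / shape)
    return WeibullFit(scale_mpa=scale, shape=shape, converged=True, rss=0.0, n=2)


def _validate_points(psi_mpa, plc_pct) -> tuple[np.ndarray, np.ndarray]:
    psi = np.asarray(psi_mpa, dtype=float).ravel()
    plc = np.asarray(plc_pct, dtype=float).ravel()
    if psi.size != plc.size:
        raise ValidationError("psi and plc must have equal length")
    if psi.size < 2:
        raise ValidationError("need at least two observations")
    if not (np.all(np.isfinite(psi)) and np.all(np.isfinite(plc))):
        raise ValidationError("non-finite observations")
    if np.any(psi > 0):
        raise ValidationError("psi must be <= 0 (negative MPa convention)")
    if np.any((plc < -1e-9) | (plc > 100.0 + 1e-9)):
        raise ValidationError("PLC values must lie in [0, 100]")
    if np.ptp(np.abs(psi)) == 0:
        raise ValidationError("all psi identical: curve is not identifiable")
    return np.abs(psi), np.clip(plc, 0.0, 100.0)


# parameter sanity bounds; estimates escaping them mean the data carry no
# curve information (e.g. all PLC = 0 drives b -> inf)
_SHAPE_LIMITS = (1e-2, 1e3)


def _fit_from_starts(x: np.ndarray, y: np.ndarray,
                     starts: Sequence[tuple[float, float]]) -> WeibullFit:
    def resid(logbc):
        with np.errstate(over="ignore", divide="ignore"):
            b, c = np.exp(logbc)
            return 100.0 * (1.0 - np.exp(-((x / b) ** c))) - y

    best: tuple[float, np.ndarray, float] | None = None  # (rss, params, c0)
    for b0, c0 in starts:
        try:
            res = least_squares(resid, np.log([b0, c0]), method="lm",
                                xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=300)
        except Exception:
            continue
        if not np.all(np.isfinite(res.x)):
            continue
        rss = float(2.0 * res.cost)
        # ties (within numerical noise) broken by the smaller shape start
        if best is None or rss < best[0] - 1e-10 or (
                abs(rss - best[0]) <= 1e-10 and c0 < best[2]):
            best = (rss, res.x, c0)

    n = x.size
    if best is None:
        return WeibullFit(math.nan, math.nan, False, math.nan, n)
    rss, logbc, _ = best
    with np.errstate(over="ignore"):
        b, c = float(np.exp(logbc[0])), float(np.exp(logbc[1]))
    ok = (_SHAPE_LIMITS[0] <= c <= _SHAPE_LIMITS[1]
          and 1e-3 * float(np.min(x[x > 0], initial=1.0)) <= b <= 50.0 * float(np.max(x)))
    return WeibullFit(b if ok else math.nan, c if ok else math.nan, ok, rss, n)


def fit_weibull(psi_mpa, plc_pct, *, x0: tuple[float, float] | None = None) -> WeibullFit:
    """Least-squares Weibull fit of PLC versus water potential.

    Multi-start initialisation: scale over the quartiles of |psi|, shape
    over {1, 2, 4, 8}; the start with the lowest residual sum of squares
    wins, ties going to the smaller shape. Passing ``x0=(scale, shape)``
    replaces the grid by that single start (used for bootstrap replicates).
    Degenerate data (constant PLC, runaway parameters) yield an explicit
    non-converged result, never a silent estimate.
    """
    x, y = _validate_points(psi_mpa, plc_pct)
    if np.ptp(y) == 0.0:
        # flat PLC (e.g. all 0 or all 100): scale is unidentifiable
        return WeibullFit(math.nan, math.nan, False, 0.0, x.size)
    if x0 is not None:
        starts = [(float(x0[0]), float(x0[1]))]
    else:
        bs = np.unique(np.quantile(x[x > 0], [0.25, 0.5, 0.75]))
        starts = [(float(b0), float(c0)) for b0 in bs if b0 > 0
                  for c0 in (1.0, 2.0, 4.0, 8.0)]
    return _fit_from_starts(x, y, starts)


def fit_logistic(psi_mpa, plc_pct) -> tuple[float, float, float]:
    """Sensitivity-analysis alternative: ``PLC = 100/(1+exp(s*(x50-|psi|)))``.

    Returns ``(x50, s, rss)``; not used by any reported statistic.
    """
    x, y = _validate_points(psi_mpa, plc_pct)

    def resid(p):
        x50, s = p
        with np.errstate(over="ignore"):
            return 100.0 / (1.0 + np.exp(s * (x50 - x))) - y

    res = least_squares(resid, [float(np.median(x)), 2.0], method="lm")
    return float(res.x[0]), float(res.x[1]), float(2.0 * res.cost)


def bootstrap_thresholds(psi_mpa, plc_pct, *, n_boot: int = 1000, seed: int,
                         ci_level: float = 95.0,
                         base_fit: WeibullFit | None = None) -> ThresholdSet:
    """Percentile bootstrap CIs for psi12/psi50/psi88 by case resampling.

    Observations (independent plants, one psi each) are resampled with
    replacement ``n_boot`` times; each replicate is refitted starting from
    the full-data estimate. Replicates that fail to converge (or collapse
    to a single psi value) are dropped and counted; more than 50% failures
    aborts with diagnostics.
    """
    if n_boot < 200:
        raise ValidationError("n_boot must be >= 200")
    x, y = _validate_points(psi_mpa, plc_pct)
    fit0 = base_fit if base_fit is not None else fit_weibull(psi_mpa, plc_pct)
    if not fit0.converged:
        raise ConvergenceError("point-estimate fit did not converge")

    rng = np.random.default_rng(seed)
    n = x.size
    reps = {p: [] for p in THRESHOLD_LEVELS}
    failed = 0
    x0 = (fit0.scale_mpa, fit0.shape)
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        xb, yb = x[idx], y[idx]
        if np.ptp(xb) == 0 or np.ptp(yb) == 0:
            failed += 1
            continue
        fb = _fit_from_starts(xb, yb, [x0])
        if not fb.converged:
            failed += 1
            continue
        for p in THRESHOLD_LEVELS:
            reps[p].append(threshold_psi(fb, p))
    if failed > 0.5 * n_boot:
        raise ConvergenceError(
            f"{failed}/{n_boot} bootstrap replicates failed to converge"
        )

    alpha = (100.0 - ci_level) / 2.0
    ci = {}
    for p in THRESHOLD_LEVELS:
        lo, hi = np.percentile(reps[p], [alpha, 100.0 - alpha])
        ci[f"psi{int(p)}"] = (float(lo), float(hi))
    return ThresholdSet(
        psi12_mpa=threshold_psi(fit0, 12.0),
        psi50_mpa=threshold_psi(fit0, 50.0),
        psi88_mpa=threshold_psi(fit0, 88.0),
        ci=ci,
        n=n,
        n_boot=n_boot,
        n_failed=failed,
    )


def fit_curve(points: pd.DataFrame, organ: str, method: str, *,
              n_boot: int = 1000, seed: int) -> VulnerabilityCurve:
    """Fit one organ/method observation set and attach bootstrap thresholds."""
    if method not in ("hydraulic", "microct"):
        raise ValidationError("method must be 'hydraulic' or 'microct'")
    psi = points["psi_mpa"].to_numpy()
    plc = points["plc_pct"].to_numpy()
    fit = fit_weibull(psi, plc)
    curve = VulnerabilityCurve(organ=organ, method=method,
                               points=points.reset_index(drop=True), fit=fit)
    if fit.converged:
        curve.thresholds = bootstrap_thresholds(
            psi, plc, n_boot=n_boot, seed=seed, base_fit=fit)
    return curve


def compare_curves(a: VulnerabilityCurve, b: VulnerabilityCurve,
                   threshold: str = "psi50") -> CurveComparison:
    """Declare a difference at one threshold iff the 95% CIs do not overlap."""
    if threshold not in ("psi12", "psi50", "psi88"):
        raise ValidationError("threshold must be psi12|psi50|psi88")
    for curve in (a, b):
        if curve.thresholds is None:
            raise ValidationError(
                f"curve {curve.organ}/{curve.method} has no bootstrap thresholds")
    ci_a = tuple(sorted(a.thresholds.ci[threshold]))
    ci_b = tuple(sorted(b.thresholds.ci[threshold]))
    disjoint = ci_a[1] < ci_b[0] or ci_b[1] < ci_a[0]
    return CurveComparison(
        threshold=threshold,
        value_a=a.thresholds.value(threshold),
        value_b=b.thresholds.value(threshold),
        ci_a=ci_a,
        ci_b=ci_b,
        significant=bool(disjoint),
    )


def plot_curve(curve: VulnerabilityCurve, ax=None, psi_grid: np.ndarray | None = None):
    """Scatter + fitted curve + psi50 line and CI band (requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    pts = curve.points
    ax.plot(pts["psi_mpa"], pts["plc_pct"], "o", ms=4, color="k", alpha=0.7)
    if curve.fit is not None and curve.fit.converged:
        if psi_grid is None:
            psi_grid = np.linspace(float(pts["psi_mpa"].min()), 0.0, 200)
        ax.plot(psi_grid, curve.fit.plc(psi_grid), "-", color="C3")
        if curve.thresholds is not None:
            ts = curve.thresholds
            ax.axvline(ts.psi50_mpa, color="C3", lw=1)
            lo, hi = ts.ci["psi50"]
            ax.axvspan(lo, hi, color="C3", alpha=0.15)
    ax.set_xlabel("water potential (MPa)")
    ax.set_ylabel("PLC (%)")
    ax.set_ylim(-2, 102)
    ax.set_title(f"{curve.organ} ({curve.method})")
    return ax
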