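"""Noncompartmental (moment) analysis and prediction-adequacy metrics.

NCA uses the linear-up/log-down trapezoidal rule for AUC and AUMC, a
log-linear terminal fit over the last quantifiable points for the
elimination rate constant, and the usual extrapolations:

    AUC_inf  = AUC_last  + C_last / lz
    AUMC_inf = AUMC_last + C_last * t_last / lz + C_last / lz**2
    CLp = dose / AUC_inf            (IV)
    Vss = dose * AUMC / AUC**2      (IV bolus, = CLp * MRT)

Prediction adequacy follows the fold-error framework: per-point
fold error = C_predicted / C_observed, absolute average fold error
AAFE = 10 ** mean(|log10 fold error|), plus the percentage of points
outside the 2-fold [0.5, 2] and 3-fold [0.33, 3] ranges. Acceptance
thresholds: < 30% outside 2-fold, < 20% outside 3-fold, AAFE <= 1.9.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "NcaResult",
    "ValidationReport",
    "nca",
    "fold_errors",
    "aafe",
    "caafe",
    "outlier_percentages",
    "validate_prediction",
    "resample_profile",
]

#: default number of terminal points in the lambda-z regression
DEFAULT_TERMINAL_POINTS = 3

TWOFOLD = (0.5, 2.0)
THREEFOLD = (1.0 / 3.0, 3.0)
MAX_PCT_OUTSIDE_TWOFOLD = 30.0
MAX_PCT_OUTSIDE_THREEFOLD = 20.0
MAX_AAFE = 1.9


@dataclass(frozen=True)
class NcaResult:
    """Moment-analysis summary of one concentration-time profile."""

    cmax: float                 # ug/mL
    tmax: float                 # h
    auc_last: float             # ug*h/mL
    auc_inf: float | None       # ug*h/mL
    lambda_z: float | None      # 1/h
    t_half: float | None        # h
    clp: float | None = None    # L/h (dose in mg, AUC in ug*h/mL = mg*h/L)
    vss: float | None = None    # L, moment-based (IV bolus only)
    aumc_inf: float | None = None


def _trapezoid_segments(t: np.ndarray, c: np.ndarray) -> tuple[float, float]:
    """AUC and AUMC by linear-up/log-down trapezoids."""
    auc = aumc = 0.0
    for i in range(t.size - 1):
        t1, t2 = t[i], t[i + 1]
        c1, c2 = c[i], c[i + 1]
        dt = t2 - t1
        if c1 > 0 and 0 < c2 < c1:
            k = np.log(c1 / c2) / dt
            auc += (c1 - c2) / k
            aumc += (t1 * c1 - t2 * c2) / k + (c1 - c2) / k**2
        else:
            auc += dt * (c1 + c2) / 2.0
            aumc += dt * (t1 * c1 + t2 * c2) / 2.0
    return auc, aumc


def nca(times: Sequence[float], concentrations: Sequence[float],
        dose_mg: float | None = None, iv: bool = False,
        n_terminal: int = DEFAULT_TERMINAL_POINTS) -> NcaResult:
    """Noncompartmental analysis of a single profile.

    ``times`` in h, ``concentrations`` in ug/mL. ``dose_mg`` enables CLp
    (and, with ``iv=True``, moment Vss). The terminal slope uses the last
    ``n_terminal`` positive concentrations; when it cannot be estimated
    (fewer than 3 positive terminal points, or a non-negative slope) the
    extrapolated quantities are left unset with a warning.
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(concentrations, dtype=float)
    if t.size != c.size:
        raise ValueError("times and concentrations differ in length")
    if t.size < 2:
        raise ValueError("need at least 2 points")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    if np.any(c < 0):
        raise ValueError("negative concentrations")

    imax = int(np.argmax(c))
    cmax, tmax = float(c[imax]), float(t[imax])
    auc_last, aumc_last = _trapezoid_segments(t, c)

    pos = np.nonzero(c > 0)[0]
    lambda_z = None
    if pos.size >= max(3, n_terminal):
        idx = pos[-n_terminal:]
        slope = np.polyfit(t[idx], np.log(c[idx]), 1)[0]
        if slope < 0:
            lambda_z = float(-slope)
    if lambda_z is None:
        warnings.warn("terminal slope not estimable; AUC_inf unset", stacklevel=2)
        return NcaResult(cmax=cmax, tmax=tmax, auc_last=float(auc_last),
                         auc_inf=None, lambda_z=None, t_half=None)

    c_last, t_last = float(c[pos[-1]]), float(t[pos[-1]])
    auc_inf = auc_last + c_last / lambda_z
    aumc_inf = aumc_last + c_last * t_last / lambda_z + c_last / lambda_z**2
    t_half = float(np.log(2.0) / lambda_z)

    clp = vss = None
    if dose_mg is not None:
        clp = dose_mg / auc_inf
        if iv:
            vss = dose_mg * aumc_inf / auc_inf**2
    return NcaResult(cmax=cmax, tmax=tmax, auc_last=float(auc_last),
                     auc_inf=float(auc_inf), lambda_z=lambda_z,
                     t_half=t_half, clp=clp, vss=vss,
                     aumc_inf=float(aumc_inf))


def resample_profile(times: np.ndarray, concentrations: np.ndarray,
                     target_times: np.ndarray) -> np.ndarray:
    """Explicit log-linear resampling of a profile onto a target grid."""
    times = np.asarray(times, dtype=float)
    c = np.asarray(concentrations, dtype=float)
    target = np.asarray(target_times, dtype=float)
    if target.min() < times.min() or target.max() > times.max():
        raise ValueError("target times outside the sampled range")
    safe = np.clip(c, 1e-30, None)
    return np.exp(np.interp(target, times, np.log(safe))) * (c.max() > 0)


def fold_errors(predicted: Sequence[float], observed: Sequence[float]) -> np.ndarray:
    """Element-wise prediction/observation ratios on matched time grids.

    No silent interpolation: mismatched lengths raise; use
    :func:`resample_profile` first if grids differ.
    """
    p = np.asarray(predicted, dtype=float)
    o = np.asarray(observed, dtype=float)
    if p.shape != o.shape:
        raise ValueError(
            f"mismatched grids ({p.shape} vs {o.shape}); "
            "resample explicitly before comparing")
    if np.any(o <= 0):
        raise ValueError("observed concentrations must be > 0")
    if np.any(p <= 0):
        raise ValueError("predicted concentrations must be > 0")
    return p / o


def aafe(ratios: Sequence[float]) -> float:
    """Absolute average fold error: 10 ** mean(|log10 ratio|); >= 1."""
    r = np.asarray(ratios, dtype=float)
    if r.size == 0:
        raise ValueError("empty fold-error input")
    if np.any(r <= 0):
        raise ValueError("fold errors must be > 0")
    return float(10.0 ** np.mean(np.abs(np.log10(r))))


def caafe(arms: Sequence[Sequence[float]], pool_points: bool = True) -> float:
    """Combined AAFE across study arms.

    By default all points are pooled before averaging the absolute log
    fold errors; ``pool_points=False`` instead averages the per-arm AAFEs
    on the log scale.
    """
    if len(arms) == 0:
        raise ValueError("no arms supplied")
    if pool_points:
        pooled = np.concatenate([np.asarray(a, dtype=float) for a in arms])
        return aafe(pooled)
    logs = [np.log10(aafe(a)) for a in arms]
    return float(10.0 ** np.mean(logs))


def outlier_percentages(ratios: Sequence[float]) -> tuple[float, float]:
    """Percent of fold errors outside the 2-fold and 3-fold ranges.

    Boundary convention: the intervals are closed, so a ratio of exactly
    2.0 (or 0.5) is not an outlier.
    """
    r = np.asarray(ratios, dtype=float)
    if r.size == 0:
        raise ValueError("empty fold-error input")
    out2 = np.mean((r < TWOFOLD[0]) | (r > TWOFOLD[1])) * 100.0
    out3 = np.mean((r < THREEFOLD[0]) | (r > THREEFOLD[1])) * 100.0
    return float(out2), float(out3)


@dataclass(frozen=True)
class ValidationReport:
    """Prediction-adequacy metrics for one or more study arms."""

    fold_errors_per_arm: tuple[np.ndarray, ...]
    aafe_per_arm: tuple[float, ...]
    caafe: float
    pct_outside_twofold: float
    pct_outside_threefold: float
    acceptable_twofold: bool
    acceptable_threefold: bool
    acceptable_aafe: bool

    @property
    def acceptable(self) -> bool:
        return (self.acceptable_twofold and self.acceptable_threefold
                and self.acceptable_aafe)


def validate_prediction(predicted_arms: Sequence[Sequence[float]],
                        observed_arms: Sequence[Sequence[float]]) -> ValidationReport:
    """Full adequacy report over matched predicted/observed arms."""
    if len(predicted_arms) != len(observed_arms):
        raise ValueError("predicted and observed arm counts differ")
    fes = tuple(fold_errors(p, o)
                for p, o in zip(predicted_arms, observed_arms))
    pooled = np.concatenate(fes)
    out2, out3 = outlier_percentages(pooled)
    combined = aafe(pooled)
    return ValidationReport(
        fold_errors_per_arm=fes,
        aafe_per_arm=tuple(aafe(f) for f in fes),
        caafe=combined,
        pct_outside_twofold=out2,
        pct_outside_threefold=out3,
        acceptable_twofold=out2 < MAX_PCT_OUTSIDE_TWOFOLD,
        acceptable_threefold=out3 < MAX_PCT_OUTSIDE_THREEFOLD,
        acceptable_aafe=combined <= MAX_AAFE,
    )
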