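"""In-vitro assay calculations.

Turns raw assay observations — Caco-2 transwell transport amounts,
equilibrium-dialysis chamber concentrations, blood-partitioning
concentrations, and metabolic depletion time courses — into the drug
parameters the PBPK model consumes:

* apparent permeability ``Papp`` (cm/s) and efflux ratio,
* unbound fractions ``fu`` (plasma, microsomal or hepatocyte incubation),
* blood-to-plasma concentration ratio ``B:P``,
* intrinsic clearance ``CLint`` (microsomal: uL/min/mg protein;
  hepatocyte: uL/min/1e6 cells),
* whole-blood degradation clearance ``CLblood`` (L/h).

All depletion kinetics are assumed first order; the rate constant is the
negative slope of an ordinary least-squares line through
``(time, ln concentration)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "TransportAssay",
    "DepletionCourse",
    "BindingAssay",
    "fit_first_order_k",
    "calc_papp",
    "calc_efflux_ratio",
    "calc_fraction_unbound",
    "calc_bp",
    "calc_clint_mic",
    "calc_clint_hep",
    "calc_clblood",
]

#: r-squared below which a depletion fit is flagged as poorly log-linear.
R2_WARN_THRESHOLD = 0.90


class InvalidAssayError(ValueError):
    """Raised when assay data violate a precondition."""


@dataclass(frozen=True)
class TransportAssay:
    """One direction of a bidirectional transwell permeability assay.

    Parameters
    ----------
    direction:
        ``"a2b"`` (apical-to-basolateral) or ``"b2a"``.
    c0:
        Initial donor concentration (amount/volume, e.g. nmol/mL).
    area_cm2:
        Surface area of the insert (cm^2).
    times_s:
        Receiver sampling times (s), strictly increasing.
    receiver_amounts:
        Cumulative amount recovered in the receiver chamber at each time,
        same amount unit as ``c0`` * mL.
    """

    direction: Literal["a2b", "b2a"]
    c0: float
    area_cm2: float
    times_s: tuple[float, ...]
    receiver_amounts: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.c0 <= 0:
            raise InvalidAssayError("initial donor concentration must be > 0")
        if self.area_cm2 <= 0:
            raise InvalidAssayError("insert surface area must be > 0")
        t = np.asarray(self.times_s, dtype=float)
        q = np.asarray(self.receiver_amounts, dtype=float)
        if t.size != q.size:
            raise InvalidAssayError("times and receiver amounts differ in length")
        if t.size < 2:
            raise InvalidAssayError("need at least 2 receiver samples")
        if np.any(np.diff(t) <= 0):
            raise InvalidAssayError("sampling times must be strictly increasing")
        if np.any(q < 0):
            raise InvalidAssayError("receiver amounts must be non-negative")


@dataclass(frozen=True)
class DepletionCourse:
    """First-order depletion time course in an incubation matrix.

    ``matrix`` identifies the scaling route: microsomal courses scale by
    protein (mg/mL), hepatocyte courses by cell density (1e6 cells/mL),
    blood courses by total blood volume.
    """

    matrix: Literal["microsome", "hepatocyte", "blood", "plasma"]
    times: tuple[float, ...]
    concentrations: tuple[float, ...]
    #: incubation volume in uL (microsome/hepatocyte) or L (blood)
    volume: float | None = None
    #: mg protein (microsome) or 1e6 cells (hepatocyte) in the incubation
    scaling_amount: float | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.concentrations, dtype=float)
        if t.size != c.size:
            raise InvalidAssayError("times and concentrations differ in length")
        if t.size < 3:
            raise InvalidAssayError("need at least 3 time points for a depletion fit")
        if t[0] != 0:
            raise InvalidAssayError("first time point must be 0")
        if np.any(np.diff(t) <= 0):
            raise InvalidAssayError("times must be strictly increasing")
        if np.any(c <= 0):
            raise InvalidAssayError("concentrations must be positive for log transform")


@dataclass(frozen=True)
class BindingAssay:
    """Equilibrium dialysis / blood partitioning concentrations.

    For fraction-unbound use, ``buffer_chamber`` and ``sample_chamber`` are
    required; for blood:plasma partitioning, ``c_plasma_ref`` (plasma spiked
    at the blood concentration) and ``c_plasma`` (plasma separated from the
    incubated blood) are required.
    """

    buffer_chamber: float | None = None
    sample_chamber: float | None = None
    c_plasma_ref: float | None = None
    c_plasma: float | None = None


def _ols_slope(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Unweighted OLS slope, intercept and r^2."""
    slope, intercept = np.polyfit(x, y, 1)
    yhat = slope * x + intercept
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return float(slope), float(intercept), r2


def fit_first_order_k(course: DepletionCourse) -> tuple[float, float]:
    """Fit the first-order disappearance rate constant of a depletion course.

    Returns ``(k, r_squared)`` where ``k`` is the negative OLS slope of
    ln(concentration) versus time, in reciprocal units of the course's time
    axis. A flat course gives ``k = 0`` with ``r^2 = 1``. Fits with
    ``r^2 < 0.90`` trigger a warning (poor log-linearity).
    """
    t = np.asarray(course.times, dtype=float)
    logc = np.log(np.asarray(course.concentrations, dtype=float))
    slope, _, r2 = _ols_slope(t, logc)
    k = -slope
    if r2 < R2_WARN_THRESHOLD:
        warnings.warn(
            f"depletion fit poorly log-linear (r^2 = {r2:.3f})", stacklevel=2
        )
    return k, r2


def calc_papp(assay: TransportAssay) -> float:
    """Apparent permeability coefficient Papp = (dQ/dt) / (C0 * A), in cm/s.

    ``dQ/dt`` is the OLS slope of cumulative receiver amount versus time
    (amount/s). A non-positive slope (no measurable transport) returns 0
    with a warning rather than a negative permeability.
    """
    t = np.asarray(assay.times_s, dtype=float)
    q = np.asarray(assay.receiver_amounts, dtype=float)
    slope, _, _ = _ols_slope(t, q)
    if slope <= 0:
        if np.any(q > 0):
            warnings.warn("non-positive transport slope; returning Papp = 0", stacklevel=2)
        return 0.0
    return slope / (assay.c0 * assay.area_cm2)


def calc_efflux_ratio(papp_b2a: float, papp_a2b: float) -> float:
    """Efflux ratio Papp(B-to-A) / Papp(A-to-B); > 2 suggests active efflux."""
    if papp_a2b <= 0:
        raise InvalidAssayError("A-to-B permeability must be > 0")
    return papp_b2a / papp_a2b


def calc_fraction_unbound(assay: BindingAssay, tol: float = 1e-6) -> float:
    """Unbound fraction = C(buffer chamber) / C(sample chamber), in [0, 1].

    A ratio exceeding 1 indicates dialysis equilibrium was not reached; the
    value is clipped to 1 with a warning.
    """
    if assay.buffer_chamber is None or assay.sample_chamber is None:
        raise InvalidAssayError("fraction unbound needs buffer and sample chamber concentrations")
    if assay.sample_chamber <= 0:
        raise InvalidAssayError("sample-chamber concentration must be > 0")
    if assay.buffer_chamber < 0:
        raise InvalidAssayError("buffer-chamber concentration must be >= 0")
    fu = assay.buffer_chamber / assay.sample_chamber
    if fu > 1 + tol:
        warnings.warn(
            f"buffer exceeds sample chamber (ratio {fu:.3f}); equilibrium not reached",
            stacklevel=2,
        )
    return min(fu, 1.0)


def calc_bp(assay: BindingAssay) -> float:
    """Blood-to-plasma concentration ratio B:P = C(plasma, reference) / C(plasma)."""
    if assay.c_plasma_ref is None or assay.c_plasma is None:
        raise InvalidAssayError("B:P needs reference and separated plasma concentrations")
    if assay.c_plasma <= 0:
        raise InvalidAssayError("separated plasma concentration must be > 0")
    return assay.c_plasma_ref / assay.c_plasma


def calc_clint_mic(k_per_min: float, incubation_volume_ul: float, protein_mg: float) -> float:
    """Microsomal intrinsic clearance, uL/min/mg protein: k * V / protein."""
    if k_per_min < 0:
        raise InvalidAssayError("rate constant must be >= 0")
    if protein_mg <= 0:
        raise InvalidAssayError("protein amount must be > 0")
    return k_per_min * incubation_volume_ul / protein_mg


def calc_clint_hep(k_per_min: float, incubation_volume_ul: float, million_cells: float) -> float:
    """Hepatocyte intrinsic clearance, uL/min/1e6 cells: k * V / cells."""
    if k_per_min < 0:
        raise InvalidAssayError("rate constant must be >= 0")
    if million_cells <= 0:
        raise InvalidAssayError("cell number must be > 0")
    return k_per_min * incubation_volume_ul / million_cells


def calc_clblood(k_per_h: float, blood_volume_l: float, bp: float) -> float:
    """Whole-blood degradation clearance, L/h: k * V(blood) * B:P.

    The B:P factor references the blood-volume clearance to plasma
    concentration, so the result adds directly to plasma clearance.
    """
    if k_per_h < 0:
        raise InvalidAssayError("rate constant must be >= 0")
    if k_per_h > 0 and (blood_volume_l <= 0 or bp <= 0):
        raise InvalidAssayError("blood volume and B:P must be > 0")
    return k_per_h * blood_volume_l * bp
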