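"""Compartmental absorption and transit (CAT) gut model.

Six serial GI compartments — stomach plus five intestinal segments
(three small-intestinal, two large-intestinal) — with first-order gastric
emptying (Ks), segmental transit (Kt,i) and segmental absorption (ka,i).
No absorption occurs from the stomach; transit out of the last segment is
fecal loss.

Segmental absorption rate constants derive from the Caco-2 permeability:
an empirical log-log correlation maps Papp onto the human jejunal
effective permeability Peff, the human segmental rate constant is
ka = 2 * Peff / R, and animal segments are scaled by a fitted
interspecies factor SF (all segments) plus, in rodents only, a
large-intestinal factor ASF on segments 4-5 that captures the slow
colonic absorption behind flip-flop kinetics.

The asymptotic fraction absorbed has the closed form
Fa = 1 - prod_i Kt,i / (Kt,i + ka,i), which the ODE system reproduces.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import math
import warnings

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "N_SEGMENTS",
    "CatParameters",
    "peff_from_papp",
    "ka_human",
    "ka_species",
    "cat_rhs",
    "fraction_absorbed",
    "simulate_cat",
]

#: number of absorbing intestinal segments (3 small + 2 large intestinal)
N_SEGMENTS = 5

# Unit convention of the Caco-2 -> Peff correlation: Papp expressed in
# 1e-6 cm/s, Peff returned in 1e-4 cm/s (the convention of jejunal-perfusion
# permeability scales). Applying the correlation in raw cm/s would give a
# physiologically impossible Peff ~ 4e-3 cm/s.
_PEFF_SLOPE = 0.4926
_PEFF_INTERCEPT = -0.1454


@dataclass(frozen=True)
class CatParameters:
    """Rate constants of the six-compartment gut model (all 1/h).

    ``kt`` holds the five segmental transit constants; ``ka`` the five
    segmental absorption constants. For rodents segments 4-5 carry
    ka * ASF; for dog and human ka is uniform across segments.
    """

    ks: float
    kt: tuple[float, float, float, float, float]
    ka: tuple[float, float, float, float, float]
    species: str = ""
    peff_cm_per_s: float | None = None
    sf: float | None = None
    asf: float | None = None

    def __post_init__(self) -> None:
        if self.ks < 0 or any(k < 0 for k in self.kt) or any(k < 0 for k in self.ka):
            raise ValueError("all CAT rate constants must be >= 0")
        if len(self.kt) != N_SEGMENTS or len(self.ka) != N_SEGMENTS:
            raise ValueError(f"need exactly {N_SEGMENTS} intestinal segments")


def peff_from_papp(papp_cm_per_s: float) -> float:
    """Effective intestinal permeability (cm/s) from Caco-2 Papp (cm/s).

    log10 Peff[1e-4 cm/s] = 0.4926 * log10 Papp[1e-6 cm/s] - 0.1454.
    """
    if papp_cm_per_s <= 0:
        raise ValueError("Papp must be > 0")
    papp_scaled = papp_cm_per_s / 1e-6
    log_peff = _PEFF_SLOPE * math.log10(papp_scaled) + _PEFF_INTERCEPT
    return 10.0 ** log_peff * 1e-4


def ka_human(peff_cm_per_s: float, radius_cm: float) -> float:
    """Human segmental absorption rate constant ka = 2 * Peff / R, in 1/h."""
    if radius_cm <= 0:
        raise ValueError("intestinal radius must be > 0")
    if peff_cm_per_s < 0:
        raise ValueError("Peff must be >= 0")
    return 2.0 * peff_cm_per_s / radius_cm * 3600.0


def ka_species(ka_human_per_h: float, sf: float, asf: float | None,
               species: str) -> tuple[float, float, float, float, float]:
    """Segmental ka values for a species from the human value and SF/ASF.

    Rodents (mouse, rat): segments 1-3 get ka_human * SF, segments 4-5 get
    ka_human * SF * ASF. Dog: all five segments ka_human * SF. Human: all
    five segments ka_human (SF and ASF are identities). Supplying an ASF
    for dog or human triggers a warning and is ignored.
    """
    species = species.lower()
    if sf <= 0:
        raise ValueError("SF must be > 0")
    if species in ("mouse", "rat"):
        if asf is None or asf <= 0:
            raise ValueError("rodents require ASF > 0")
        small = ka_human_per_h * sf
        large = small * asf
        return (small, small, small, large, large)
    if species == "dog":
        if asf is not None:
            warnings.warn("ASF is not used for dogs; ignoring", stacklevel=2)
        v = ka_human_per_h * sf
        return (v,) * N_SEGMENTS
    if species == "human":
        if asf is not None:
            warnings.warn("ASF is not used for humans; ignoring", stacklevel=2)
        return (ka_human_per_h,) * N_SEGMENTS
    raise ValueError(f"unknown species {species!r}")


def cat_rhs(state: np.ndarray, params: CatParameters) -> np.ndarray:
    """Time derivatives of the GI state.

    ``state`` is ``[Ms, M1..M5, absorbed, exited]`` (amounts). The stomach
    empties into segment 1; each segment loses drug to downstream transit
    and to absorption; the last segment's transit flux exits unabsorbed.
    Total mass (compartments + absorbed + exited) is conserved.
    """
    ms = state[0]
    mi = state[1:1 + N_SEGMENTS]
    kt = np.asarray(params.kt)
    ka = np.asarray(params.ka)
    d = np.empty_like(state)
    d[0] = -params.ks * ms
    inflow = np.empty(N_SEGMENTS)
    inflow[0] = params.ks * ms
    inflow[1:] = kt[:-1] * mi[:-1]
    d[1:1 + N_SEGMENTS] = inflow - (kt + ka) * mi
    d[1 + N_SEGMENTS] = float(np.dot(ka, mi))      # cumulative absorbed
    d[2 + N_SEGMENTS] = kt[-1] * mi[-1]            # cumulative fecal exit
    return d


def fraction_absorbed(params: CatParameters) -> float:
    """Asymptotic fraction absorbed, Fa = 1 - prod Kt,i / (Kt,i + ka,i)."""
    prod = 1.0
    for kt_i, ka_i in zip(params.kt, params.ka):
        if kt_i + ka_i <= 0:
            raise ValueError("Kt,i + ka,i must be > 0 for every segment")
        prod *= kt_i / (kt_i + ka_i)
    return 1.0 - prod


def simulate_cat(params: CatParameters, dose: float, t_end: float,
                 n_points: int = 200, rtol: float = 1e-10,
                 atol: float = 1e-12) -> dict[str, np.ndarray]:
    """Integrate the stand-alone gut model for an oral dose.

    Returns arrays keyed ``t``, ``stomach``, ``segments`` (n x 5),
    ``absorbed``, ``exited``. Serves as the independent oracle for the
    closed-form Fa.
    """
    if dose <= 0 or t_end <= 0:
        raise ValueError("dose and t_end must be > 0")
    y0 = np.zeros(3 + N_SEGMENTS)
    y0[0] = dose
    t_eval = np.linspace(0.0, t_end, n_points)
    sol = solve_ivp(
        lambda _t, y: cat_rhs(y, params), (0.0, t_end), y0,
        t_eval=t_eval, method="LSODA", rtol=rtol, atol=atol,
    )
    if not sol.success:
        raise RuntimeError(f"CAT integration failed: {sol.message}")
    return {
        "t": sol.t,
        "stomach": sol.y[0],
        "segments": sol.y[1:1 + N_SEGMENTS].T,
        "absorbed": sol.y[1 + N_SEGMENTS],
        "exited": sol.y[2 + N_SEGMENTS],
    }
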