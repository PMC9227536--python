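"""In-vitro-to-in-vivo extrapolation of hepatic clearance.

Scales incubation-level intrinsic clearance to the whole liver
(via MPPGL or hepatocellularity and liver mass), then to organ clearance
with the well-stirred liver model:

    CLh = QLI * BP * fu_p * CLu_int_H / (QLI * BP + fu_p * CLu_int_H)

CLh is plasma-referenced (dose / plasma AUC); QLI * BP is the flow
ceiling. The hepatic extraction ratio is ER = CLh / (QLI * BP) and
theoretical oral bioavailability follows F = Fa * Fg * (1 - ER).
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "LiverScalingInputs",
    "HepaticClearanceInputs",
    "scale_to_whole_liver",
    "well_stirred_clh",
    "extraction_ratio",
    "theoretical_bioavailability",
]


@dataclass(frozen=True)
class LiverScalingInputs:
    """Inputs for whole-liver scaling of intrinsic clearance.

    Exactly one of the microsomal (``clint_mic`` + ``fu_mic`` + ``mppgl``)
    or hepatocyte (``clint_hep`` + ``fu_hep`` + ``hpgl``) branches must be
    populated.

    Units: clint_mic uL/min/mg; clint_hep uL/min/1e6 cells; mppgl mg/g
    liver; hpgl 1e6 cells/g liver; liver_volume_ml mL; liver_density g/mL.
    """

    liver_volume_ml: float
    liver_density: float = 1.07
    clint_mic: float | None = None
    fu_mic: float | None = None
    mppgl: float | None = None
    clint_hep: float | None = None
    fu_hep: float | None = None
    hpgl: float | None = None

    def __post_init__(self) -> None:
        mic = (self.clint_mic, self.fu_mic, self.mppgl)
        hep = (self.clint_hep, self.fu_hep, self.hpgl)
        mic_set = all(v is not None for v in mic)
        hep_set = all(v is not None for v in hep)
        if mic_set == hep_set:
            raise ValueError("populate exactly one of the microsome/hepatocyte branches")
        if self.liver_volume_ml <= 0 or self.liver_density <= 0:
            raise ValueError("liver volume and density must be > 0")
        clint, fu, per_g = mic if mic_set else hep
        if clint < 0:
            raise ValueError("intrinsic clearance must be >= 0")
        if fu <= 0 or per_g <= 0:
            raise ValueError("unbound fraction and scaling factor must be > 0")


@dataclass(frozen=True)
class HepaticClearanceInputs:
    """Well-stirred model inputs: flows in L/h, fractions dimensionless."""

    qli: float          # liver blood flow, L/h
    bp: float           # blood:plasma concentration ratio
    fu_p: float         # unbound fraction in plasma
    clu_int_h: float    # whole-liver unbound intrinsic clearance, L/h

    def __post_init__(self) -> None:
        if min(self.qli, self.bp, self.clu_int_h) < 0 or self.fu_p < 0:
            raise ValueError("all inputs must be non-negative")
        if not self.fu_p <= 1:
            raise ValueError("fu_p must be <= 1")


def scale_to_whole_liver(inputs: LiverScalingInputs) -> float:
    """Whole-liver unbound intrinsic clearance CLu_int_H in L/h.

    (CLint / fu) * (MPPGL or HPGL) * liver mass, converted from uL/min
    to L/h. The unbound-fraction division corrects for nonspecific binding
    in the incubation.
    """
    liver_g = inputs.liver_volume_ml * inputs.liver_density
    if inputs.clint_mic is not None:
        per_g = (inputs.clint_mic / inputs.fu_mic) * inputs.mppgl
    else:
        per_g = (inputs.clint_hep / inputs.fu_hep) * inputs.hpgl
    # uL/min -> L/h
    return per_g * liver_g * 60.0 / 1e6


def well_stirred_clh(inputs: HepaticClearanceInputs) -> float:
    """Plasma-referenced hepatic clearance CLh (L/h), well-stirred model."""
    flow = inputs.qli * inputs.bp
    intrinsic = inputs.fu_p * inputs.clu_int_h
    if flow + intrinsic == 0:
        return 0.0
    return flow * intrinsic / (flow + intrinsic)


def extraction_ratio(clh: float, qli: float, bp: float) -> float:
    """Hepatic extraction ratio ER = CLh / (QLI * BP), in [0, 1) for well-stirred CLh."""
    denom = qli * bp
    if denom <= 0:
        raise ValueError("QLI * BP must be > 0")
    return clh / denom


def theoretical_bioavailability(fa: float, er: float, fg: float = 1.0) -> float:
    """Theoretical oral bioavailability F = Fa * Fg * (1 - ER).

    ``fg`` defaults to 1 (no gut-wall metabolism assumed for IDP-73152).
    """
    for name, v in (("fa", fa), ("fg", fg), ("er", er)):
        if not 0 <= v <= 1:
            raise ValueError(f"{name} must lie in [0, 1]")
    return fa * fg * (1.0 - er)
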