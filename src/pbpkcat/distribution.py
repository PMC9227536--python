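"""Tissue partitioning and steady-state volume of distribution.

The distribution model rests on experimentally measured steady-state
tissue-to-plasma ratios (Kp,ss) rather than on tissue-composition
predictions. Three corrections/derivations sit on top of the raw ratios:

* the erythrocyte:plasma partition coefficient EP from the blood:plasma
  ratio and hematocrit, via the mass balance BP = (1 - Hct) + Hct * EP;
* the liver Kp correction Kp,LI = Kp,ss,LI / (1 - ER), which undoes the
  concentration-lowering effect of hepatic elimination on the measured
  steady-state ratio of the eliminating organ;
* cross-species scaling of Kp,ss assuming Kp,ss / fu_p is conserved.

Vss (plasma-referenced) is the composite volume
Vss = Vp + Vrbc * EP + sum_i V_T,i * Kp,ss,i.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Mapping

__all__ = [
    "TISSUES",
    "TissuePartitionSet",
    "VolumeInputs",
    "VssResult",
    "calc_kpss",
    "erythrocyte_partition",
    "calc_vss",
    "correct_liver_kp",
    "scale_kp",
]

#: The ten perfusion-limited tissues of the whole-body model.
TISSUES = (
    "adipose",
    "brain",
    "heart",
    "kidney",
    "liver",
    "lung",
    "muscle",
    "skin",
    "spleen",
    "testis",
)


@dataclass(frozen=True)
class TissuePartitionSet:
    """Steady-state tissue:plasma ratios for one species.

    ``fu_p`` records the plasma unbound fraction used for cross-species
    scaling (Kp,ss / fu_p assumed conserved).
    """

    kp: Mapping[str, float]
    species: str
    fu_p: float

    def __post_init__(self) -> None:
        missing = [t for t in TISSUES if t not in self.kp]
        if missing:
            raise ValueError(f"missing tissues in partition set: {missing}")
        bad = [t for t in TISSUES if self.kp[t] <= 0]
        if bad:
            raise ValueError(f"non-positive Kp,ss for tissues: {bad}")
        if self.fu_p <= 0:
            raise ValueError("fu_p must be > 0")

    def __getitem__(self, tissue: str) -> float:
        return self.kp[tissue]


@dataclass(frozen=True)
class VolumeInputs:
    """Absolute volumes (L) entering the composite Vss equation."""

    v_plasma: float
    v_rbc: float
    v_tissue: Mapping[str, float]
    hematocrit: float
    bp: float

    def __post_init__(self) -> None:
        if self.v_plasma <= 0 or self.v_rbc <= 0:
            raise ValueError("plasma and RBC volumes must be > 0")
        if not 0 < self.hematocrit < 1:
            raise ValueError("hematocrit must lie in (0, 1)")
        if self.bp <= 0:
            raise ValueError("B:P must be > 0")


@dataclass(frozen=True)
class VssResult:
    vss_l: float
    vss_l_per_kg: float | None = None


def calc_kpss(c_tissue_ss: float, c_plasma_ss: float) -> float:
    """Steady-state tissue:plasma concentration ratio."""
    if c_plasma_ss <= 0:
        raise ValueError("steady-state plasma concentration must be > 0")
    return c_tissue_ss / c_plasma_ss


def erythrocyte_partition(bp: float, hematocrit: float) -> float:
    """Erythrocyte:plasma partition coefficient EP.

    From the blood mass balance BP = (1 - Hct) + Hct * EP:
    EP = (BP - (1 - Hct)) / Hct = 1 + (BP - 1) / Hct. A negative EP
    (BP below its plasma-only bound 1 - Hct) is physically impossible and
    triggers a warning.
    """
    if not 0 < hematocrit < 1:
        raise ValueError("hematocrit must lie in (0, 1)")
    ep = (bp - (1.0 - hematocrit)) / hematocrit
    if ep < 0:
        warnings.warn(
            f"B:P = {bp} below plasma-only bound {1 - hematocrit:.3f}; EP < 0",
            stacklevel=2,
        )
    return ep


def calc_vss(partitions: TissuePartitionSet, vols: VolumeInputs,
             body_weight_kg: float | None = None) -> VssResult:
    """Composite steady-state volume of distribution, plasma-referenced.

    Vss = Vp + Vrbc * EP + sum over the ten tissues of V_T * Kp,ss.
    If ``body_weight_kg`` is given the per-kg value is also returned.
    """
    missing = [t for t in TISSUES if t not in vols.v_tissue]
    if missing:
        raise ValueError(f"missing tissue volumes: {missing}")
    ep = erythrocyte_partition(vols.bp, vols.hematocrit)
    vss = vols.v_plasma + vols.v_rbc * ep
    vss += sum(vols.v_tissue[t] * partitions[t] for t in TISSUES)
    per_kg = vss / body_weight_kg if body_weight_kg else None
    return VssResult(vss_l=vss, vss_l_per_kg=per_kg)


def correct_liver_kp(kp_ss_li: float, er: float) -> float:
    """PBPK-operative liver partition coefficient Kp,LI = Kp,ss,LI / (1 - ER).

    The measured steady-state liver ratio understates true partitioning
    because hepatic elimination continuously removes drug from the organ.
    """
    if not 0 <= er < 1:
        raise ValueError("extraction ratio must lie in [0, 1)")
    if kp_ss_li <= 0:
        raise ValueError("Kp,ss must be > 0")
    return kp_ss_li / (1.0 - er)


def scale_kp(source: TissuePartitionSet, target_fu_p: float,
             target_species: str = "") -> TissuePartitionSet:
    """Scale a partition set to another species assuming conserved Kp,ss/fu_p.

    Every tissue Kp,ss is multiplied by ``target_fu_p / source.fu_p``.
    """
    if target_fu_p <= 0:
        raise ValueError("target fu_p must be > 0")
    factor = target_fu_p / source.fu_p
    scaled = {t: source.kp[t] * factor for t in TISSUES}
    return replace(source, kp=scaled, fu_p=target_fu_p,
                   species=target_species or source.species)
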