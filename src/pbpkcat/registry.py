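"""Shipped parameter registries: species physiology and drug parameters.

Two YAML files under ``pbpkcat/data`` hold every constant the workflow
needs: a reference physiology per species (volumes, flows, hematocrit,
liver scaling factors, GI transit constants) and the IDP-73152 in-vitro
parameter set (permeability, binding, partitioning, intrinsic clearance,
measured rat Kp,ss table). Each constant carries a provenance comment in
the YAML; constants back-solved from the scaled in-vitro clearances are
tagged ``[assay-implied]`` and the literature alternative is retained
next to them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import Any, Mapping

import yaml

from .distribution import TISSUES

__all__ = [
    "SpeciesPhysiology",
    "GiTransit",
    "DrugSpeciesParams",
    "DrugParameters",
    "load_physiology",
    "load_drug",
    "SPECIES",
]

logger = logging.getLogger(__name__)

SPECIES = ("mouse", "rat", "dog", "human")


@dataclass(frozen=True)
class GiTransit:
    """GI transit constants (1/h) and absorption scale factors."""

    ks: float
    kt_small: float
    kt_large: float
    sf: float
    asf: float | None


@dataclass(frozen=True)
class SpeciesPhysiology:
    species: str
    body_weight_kg: float
    hematocrit: float
    blood_volume_l_per_kg: float
    tissue_volume_fraction: Mapping[str, float]
    blood_flow_l_per_h_per_kg: Mapping[str, float]
    mppgl_mg_per_g: float
    liver_density_g_per_ml: float
    gi: GiTransit
    hpgl_million_per_g: float | None = None
    liver_volume_fraction_literature: float | None = None
    intestinal_radius_cm: float | None = None

    @property
    def liver_volume_ml(self) -> float:
        """Default (assay-implied) liver volume in mL."""
        return self.tissue_volume_fraction["liver"] * self.body_weight_kg * 1000.0

    @property
    def liver_blood_flow_l_per_h(self) -> float:
        """Total liver blood inflow QLI = hepatic artery + splenic, L/h."""
        f = self.blood_flow_l_per_h_per_kg
        return (f["hepatic_artery"] + f["spleen"]) * self.body_weight_kg

    def tissue_volumes_l(self) -> dict[str, float]:
        return {
            t: self.tissue_volume_fraction[t] * self.body_weight_kg
            for t in TISSUES
        }


@dataclass(frozen=True)
class DrugSpeciesParams:
    fu_p: float
    fu_mic: float
    bp: float
    clint_mic: float
    fu_hep: float | None = None
    clint_hep: float | None = None
    cl_blood_l_per_h_per_kg: float = 0.0
    observed_clp_l_per_h_per_kg: float | None = None


@dataclass(frozen=True)
class DrugParameters:
    name: str
    papp_a2b_cm_per_s: float
    papp_b2a_cm_per_s: float
    species: Mapping[str, DrugSpeciesParams]
    kp_ss_rat: Mapping[str, float]


def _data_text(filename: str) -> str:
    return resources.files("pbpkcat").joinpath("data", filename).read_text()


def load_physiology(species: str, path: str | None = None) -> SpeciesPhysiology:
    """Load one species block from the physiology registry.

    ``path`` overrides the shipped registry with a user file of the same
    schema.
    """
    species = species.lower()
    if path is None:
        raw = yaml.safe_load(_data_text("physiology.yaml"))
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    try:
        block: dict[str, Any] = raw["species"][species]
    except KeyError as exc:
        raise KeyError(f"species {species!r} not in physiology registry") from exc

    vols = dict(block["tissue_volume_fraction"])
    missing = [t for t in TISSUES if t not in vols]
    if missing:
        raise ValueError(f"physiology registry missing tissue volumes: {missing}")
    gi_raw = block["gi"]
    gi = GiTransit(
        ks=float(gi_raw["ks_per_h"]),
        kt_small=float(gi_raw["kt_small_per_h"]),
        kt_large=float(gi_raw["kt_large_per_h"]),
        sf=float(gi_raw["sf"]),
        asf=None if gi_raw.get("asf") is None else float(gi_raw["asf"]),
    )
    phys = SpeciesPhysiology(
        species=species,
        body_weight_kg=float(block["body_weight_kg"]),
        hematocrit=float(block["hematocrit"]),
        blood_volume_l_per_kg=float(block["blood_volume_l_per_kg"]),
        tissue_volume_fraction=vols,
        blood_flow_l_per_h_per_kg=dict(block["blood_flow_l_per_h_per_kg"]),
        mppgl_mg_per_g=float(block["mppgl_mg_per_g"]),
        hpgl_million_per_g=(
            float(block["hpgl_million_per_g"])
            if block.get("hpgl_million_per_g") is not None else None
        ),
        liver_density_g_per_ml=float(block["liver_density_g_per_ml"]),
        liver_volume_fraction_literature=block.get("liver_volume_fraction_literature"),
        intestinal_radius_cm=block.get("intestinal_radius_cm"),
        gi=gi,
    )
    logger.debug("loaded physiology for %s: BW %.3g kg, QLI %.3g L/h",
                 species, phys.body_weight_kg, phys.liver_blood_flow_l_per_h)
    return phys


def load_drug(path: str | None = None) -> DrugParameters:
    """Load the IDP-73152 drug-parameter registry."""
    if path is None:
        raw = yaml.safe_load(_data_text("drug_idp73152.yaml"))
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    species = {}
    for name, blk in raw["species"].items():
        species[name] = DrugSpeciesParams(
            fu_p=float(blk["fu_p"]),
            fu_mic=float(blk["fu_mic"]),
            bp=float(blk["bp"]),
            clint_mic=float(blk["clint_mic_ul_per_min_per_mg"]),
            fu_hep=blk.get("fu_hep"),
            clint_hep=blk.get("clint_hep_ul_per_min_per_mcells"),
            cl_blood_l_per_h_per_kg=float(blk.get("cl_blood_l_per_h_per_kg", 0.0)),
            observed_clp_l_per_h_per_kg=blk.get("observed_clp_l_per_h_per_kg"),
        )
    kp = dict(raw["kp_ss_rat"])
    missing = [t for t in TISSUES if t not in kp]
    if missing:
        raise ValueError(f"drug registry missing rat Kp,ss entries: {missing}")
    return DrugParameters(
        name=raw["name"],
        papp_a2b_cm_per_s=float(raw["papp_a2b_cm_per_s"]),
        papp_b2a_cm_per_s=float(raw["papp_b2a_cm_per_s"]),
        species=species,
        kp_ss_rat=kp,
    )
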