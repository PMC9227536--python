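"""Run configuration: schema-validated YAML/JSON run descriptions.

A run config names a species, one or more dose events, an output window
and optional overrides of registry constants. Unknown keys are rejected
outright (silent typos in parameter names are how simulation studies go
wrong). Every constant resolved from the shipped registries is logged
with its provenance at DEBUG level by the registry loaders.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from .pbpk import DoseEvent, PbpkModel
from .registry import SPECIES
from .studies import build_species_model

__all__ = ["RunConfig", "ConfigError", "load_config"]

_TOP_KEYS = {"species", "dose", "doses", "t_end", "seed", "solver",
             "overrides", "output"}
_DOSE_KEYS = {"route", "amount", "per_kg", "start", "duration"}
_SOLVER_KEYS = {"method", "rtol", "atol", "rk4_step"}
_OVERRIDE_KEYS = {"sf", "asf", "qli_l_per_h", "physiology_path", "drug_path"}


class ConfigError(ValueError):
    """Raised on schema violations, listing the offending keys."""


@dataclass(frozen=True)
class RunConfig:
    species: str
    doses: tuple[DoseEvent, ...]
    t_end: float
    seed: int = 0
    solver: Mapping[str, Any] = field(default_factory=dict)
    overrides: Mapping[str, Any] = field(default_factory=dict)
    output: str | None = None

    def build_model(self) -> PbpkModel:
        ov = dict(self.overrides)
        ov.pop("output", None)
        return build_species_model(
            self.species,
            physiology_path=ov.get("physiology_path"),
            drug_path=ov.get("drug_path"),
            sf=ov.get("sf"),
            asf=ov.get("asf"),
            qli_l_per_h=ov.get("qli_l_per_h"),
        )


def _check_keys(block: Mapping[str, Any], allowed: set[str], where: str) -> None:
    unknown = sorted(set(block) - allowed)
    if unknown:
        raise ConfigError(f"unknown keys in {where}: {unknown}")


def _parse_dose(block: Mapping[str, Any]) -> DoseEvent:
    _check_keys(block, _DOSE_KEYS, "dose")
    try:
        return DoseEvent(
            route=block["route"],
            amount=float(block["amount"]),
            per_kg=bool(block.get("per_kg", False)),
            start=float(block.get("start", 0.0)),
            duration=(float(block["duration"])
                      if block.get("duration") is not None else None),
        )
    except (KeyError, ValueError, TypeError) as exc:
        raise ConfigError(f"invalid dose block: {exc}") from exc


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML or JSON run config.

    A minimal config needs only ``species`` plus ``dose`` (or ``doses``)
    and ``t_end``; everything else resolves from the shipped registries.
    """
    path = Path(path)
    text = path.read_text()
    raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    _check_keys(raw, _TOP_KEYS, "config")

    species = str(raw.get("species", "")).lower()
    if species not in SPECIES:
        raise ConfigError(f"species must be one of {SPECIES}, got {species!r}")

    if ("dose" in raw) == ("doses" in raw):
        raise ConfigError("provide exactly one of 'dose' or 'doses'")
    dose_blocks = [raw["dose"]] if "dose" in raw else list(raw["doses"])
    doses = tuple(_parse_dose(b) for b in dose_blocks)

    if "t_end" not in raw:
        raise ConfigError("missing required key 't_end'")

    solver = dict(raw.get("solver", {}))
    _check_keys(solver, _SOLVER_KEYS, "solver")
    overrides = dict(raw.get("overrides", {}))
    _check_keys(overrides, _OVERRIDE_KEYS, "overrides")

    return RunConfig(
        species=species,
        doses=doses,
        t_end=float(raw["t_end"]),
        seed=int(raw.get("seed", 0)),
        solver=solver,
        overrides=overrides,
        output=raw.get("output"),
    )
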