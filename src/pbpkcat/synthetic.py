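"""Synthetic "observed-like" concentration-time datasets.

Real plasma data for IDP-73152 exist only as published figures, so the
fitting, NCA and validation machinery is exercised on datasets generated
here: the true model profile sampled at a study-design schedule, with
multiplicative log-normal residual error (constant CV, the usual
behavior of plasma LC-MS/MS assays) and an additive quantification floor
below which points are censored (dropped). Everything is reproducible
from an integer seed.

What this emulates: sparse sampling (7-16 points), assay-scale noise,
LLOQ censoring. What it does not: inter-individual physiological
variability (no population model), dosing-time errors, or matrix-specific
assay bias.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pbpk import DoseEvent, PbpkModel, simulate

__all__ = ["ErrorModel", "SAMPLING_DESIGNS", "SyntheticProfile", "generate_dataset"]


@dataclass(frozen=True)
class ErrorModel:
    """Multiplicative log-normal residual error with an LLOQ-like floor.

    ``cv`` is the proportional coefficient of variation (fraction);
    ``floor_ug_per_ml`` the censoring limit (points strictly below are
    dropped).
    """

    cv: float = 0.15
    floor_ug_per_ml: float = 0.005

    def __post_init__(self) -> None:
        if self.cv < 0 or self.floor_ug_per_ml < 0:
            raise ValueError("CV and floor must be >= 0")

    @property
    def sigma(self) -> float:
        """Log-scale SD giving the configured CV: sqrt(ln(1 + CV^2))."""
        return float(np.sqrt(np.log1p(self.cv**2)))


#: Named sparse sampling schedules (h) of the in-vivo study designs.
SAMPLING_DESIGNS: dict[str, tuple[float, ...]] = {
    "rodent_iv": (0.167, 0.333, 0.5, 1.0, 2.0, 4.0, 8.0),
    "rodent_oral": (0.167, 0.333, 0.5, 1.0, 2.0, 4.0, 8.0),
    "dog_iv": (0.167, 0.33, 0.5, 1.0, 2.0, 4.0, 8.0),
    "dog_oral": (0.167, 0.33, 0.5, 1.0, 2.0, 4.0, 6.0, 8.0),
    "human_oral": (0.25, 0.5, 0.75, 1.0, 1.5, 2.0, 2.5, 3.0, 4.0, 6.0,
                   8.0, 10.0, 12.0, 24.0, 36.0, 48.0),
}


@dataclass(frozen=True)
class SyntheticProfile:
    """One subject's noisy sampled profile (censored points removed)."""

    times: np.ndarray
    conc: np.ndarray
    subject: int
    dose: DoseEvent
    species: str


def generate_dataset(model: PbpkModel, dose: DoseEvent,
                     design: str | tuple[float, ...],
                     error: ErrorModel | None = None,
                     n_subjects: int = 6, seed: int = 0,
                     rtol: float = 1e-8) -> list[SyntheticProfile]:
    """Simulate the true profile and emit noisy per-subject datasets.

    ``design`` is a named schedule key or an explicit tuple of times (h).
    With ``cv = 0`` and ``floor = 0`` the output equals the simulated
    truth at the design times; identical seeds give identical datasets.
    """
    error = error if error is not None else ErrorModel()
    times = np.asarray(
        SAMPLING_DESIGNS[design] if isinstance(design, str) else design,
        dtype=float)
    if np.any(times <= 0) or np.any(np.diff(times) <= 0):
        raise ValueError("design times must be positive and increasing")
    t_eval = np.concatenate([[0.0], times])
    truth = simulate(model, [dose], t_eval=t_eval, rtol=rtol).plasma[1:]

    rng = np.random.default_rng(seed)
    out = []
    for subject in range(n_subjects):
        noise = rng.normal(0.0, error.sigma, size=times.size) if error.cv > 0 \
            else np.zeros(times.size)
        conc = truth * np.exp(noise)
        keep = conc >= error.floor_ug_per_ml
        out.append(SyntheticProfile(
            times=times[keep], conc=conc[keep], subject=subject,
            dose=dose, species=model.species))
    return out
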