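"""Poisson encapsulation statistics for droplet loading.

Random encapsulation of particles (bacteria or mammalian cells) into
droplets follows Poisson statistics: with mean loading λ per droplet,
a fraction 1 − e^{−λ} of droplets is occupied, and of those a fraction
λe^{−λ}/(1 − e^{−λ}) holds exactly one particle.  Monoclonal library
amplification requires dilute loading — occupancy kept below ~10% so
occupied droplets are almost surely single-clone.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Union

import numpy as np
from pydantic import BaseModel, ConfigDict, Field

__all__ = [
    "ParticleKind",
    "LoadingModel",
    "LoadingStats",
    "occupancy_fraction",
    "clonal_fraction",
    "multiplet_fraction",
    "lambda_for_occupancy",
    "loading_stats",
    "sample_counts",
]


class ParticleKind(str, enum.Enum):
    BACTERIUM = "bacterium"
    MAMMALIAN_CELL = "mammalian_cell"


class LoadingModel(BaseModel):
    """Poisson loading with intensity ``mean_per_droplet`` (λ ≥ 0)."""

    model_config = ConfigDict(frozen=True, extra="forbid")

    mean_per_droplet: float = Field(ge=0)
    particle_kind: ParticleKind = ParticleKind.BACTERIUM


@dataclass(frozen=True)
class LoadingStats:
    """Occupancy and clonality fractions implied by a loading intensity."""

    occupancy: float
    clonal_fraction: float
    multiplet_fraction: float


def _lam(model: Union[LoadingModel, float]) -> float:
    lam = model.mean_per_droplet if isinstance(model, LoadingModel) else float(model)
    if lam < 0:
        raise ValueError(f"loading intensity must be non-negative, got {lam}")
    return lam


def occupancy_fraction(model: Union[LoadingModel, float]) -> float:
    """Fraction of droplets holding at least one particle: 1 − e^{−λ}."""
    return -math.expm1(-_lam(model))


def clonal_fraction(model: Union[LoadingModel, float]) -> float:
    """Fraction of *occupied* droplets holding exactly one particle.

    λe^{−λ} / (1 − e^{−λ}); requires λ > 0 (no occupied droplets exist
    at λ = 0).
    """
    lam = _lam(model)
    if lam <= 0:
        raise ValueError("clonal fraction is defined only for λ > 0")
    return lam * math.exp(-lam) / -math.expm1(-lam)


def multiplet_fraction(model: Union[LoadingModel, float]) -> float:
    """Fraction of occupied droplets holding two or more particles."""
    return 1.0 - clonal_fraction(model)


def lambda_for_occupancy(target_occupancy: float) -> float:
    """Loading intensity λ achieving a given occupancy: −ln(1 − target).

    Inverse of :func:`occupancy_fraction`; round-trips to ~1e−12
    relative accuracy.
    """
    if not 0 <= target_occupancy < 1:
        raise ValueError(
            f"target occupancy must lie in [0, 1), got {target_occupancy}"
        )
    return -math.log1p(-target_occupancy)


def loading_stats(model: Union[LoadingModel, float]) -> LoadingStats:
    occ = occupancy_fraction(model)
    if occ == 0:
        return LoadingStats(0.0, 1.0, 0.0)
    clon = clonal_fraction(model)
    return LoadingStats(occ, clon, 1.0 - clon)


def sample_counts(
    model: Union[LoadingModel, float], n_droplets: int, seed: int
) -> np.ndarray:
    """Draw i.i.d. Poisson(λ) per-droplet particle counts.

    Bit-reproducible given (λ, n_droplets, seed).
    """
    if n_droplets < 0:
        raise ValueError("n_droplets must be non-negative")
    lam = _lam(model)
    rng = np.random.default_rng(seed)
    return rng.poisson(lam, size=n_droplets)
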