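"""Herd composition, cattle diet, and the physiology that turns a diet into
nitrogen-cycling coefficients.

The herd is proportioned to the number of mother cows ``n_m``: every animal
category (bulls, replacement heifers, calves, ...) is a fixed per-cow ratio,
so forage demand, manure output, and beef output all track ``n_m`` linearly.
Defaults: 4 bulls and 16 replacement heifers per 100 cows, 0.7 calves per
cow per year.

The diet is forage of a named quality (high / medium / low) plus a small
mass fraction (default 5%, roughly today's share) of energy- and
protein-rich agroindustrial byproducts (millfeed, beet pulp, citrus peel).

Physiology is pluggable: an implementation maps (diet, herd structure,
parameters) to the cycling coefficients ``alpha`` (plant-available manure N
per cow-year) and ``beta`` (cow-years per kg forage N) plus beef output per
cow-year. The shipped default, ``"net_energy"``, uses standard beef
net-energy logic: dry-matter intake = energy requirement / diet energy
density; N intake = intake x diet N fraction; manure N = N intake - N
retained in live-mass growth; the plant-available share of manure N is a
configurable fraction. Calibrated coefficient sets can be registered under
other names without code change.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Literal

from .errors import ParameterError
from .farm_core import CyclingCoefficients

__all__ = [
    "HerdStructure",
    "CattleDiet",
    "HerdProfile",
    "PhysiologyParams",
    "build_herd",
    "herd_profile",
    "physiology_coefficients",
    "register_physiology",
    "available_physiologies",
]


@dataclass(frozen=True)
class HerdStructure:
    """Per-mother-cow ratios defining the herd's composition."""

    bulls_per_100_cows: float = 4.0
    replacement_heifers_per_100_cows: float = 16.0
    calves_per_cow_per_year: float = 0.7
    other_ratios: dict = field(default_factory=dict)  # category -> per-cow ratio

    def __post_init__(self) -> None:
        for name in (
            "bulls_per_100_cows",
            "replacement_heifers_per_100_cows",
            "calves_per_cow_per_year",
        ):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        for cat, ratio in self.other_ratios.items():
            if ratio < 0:
                raise ParameterError(f"ratio for category {cat!r} must be >= 0")

    def per_cow_ratios(self) -> dict:
        out = {
            "mother_cows": 1.0,
            "bulls": self.bulls_per_100_cows / 100.0,
            "replacement_heifers": self.replacement_heifers_per_100_cows / 100.0,
            "calves_per_year": self.calves_per_cow_per_year,
        }
        out.update(self.other_ratios)
        return out


@dataclass(frozen=True)
class CattleDiet:
    """Forage of a named quality plus an agroindustrial byproduct share.

    Energy densities are Mcal (net energy) per kg dry matter; N fractions
    are kg N per kg dry matter. Crude protein = 6.25 x N fraction.
    """

    forage_quality: Literal["high", "medium", "low"]
    forage_energy_density: float  # Mcal/kg DM
    forage_n_fraction: float  # kg N / kg DM
    byproduct_mass_fraction: float = 0.05
    byproduct_energy_density: float = 1.9
    byproduct_n_fraction: float = 0.028

    def __post_init__(self) -> None:
        if self.forage_energy_density <= 0 or self.byproduct_energy_density <= 0:
            raise ParameterError("diet energy densities must be > 0")
        for name in (
            "forage_n_fraction",
            "byproduct_n_fraction",
            "byproduct_mass_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} must lie in [0, 1], got {v}")

    @property
    def energy_density(self) -> float:
        """Mass-weighted diet energy density, Mcal/kg DM."""
        b = self.byproduct_mass_fraction
        return (1.0 - b) * self.forage_energy_density + b * self.byproduct_energy_density

    @property
    def n_fraction(self) -> float:
        """Mass-weighted diet N fraction, kg N/kg DM."""
        b = self.byproduct_mass_fraction
        return (1.0 - b) * self.forage_n_fraction + b * self.byproduct_n_fraction


@dataclass(frozen=True)
class PhysiologyParams:
    """Tunables of the default net-energy physiology (per cow-unit-year,
    i.e. one mother cow plus her associated animals).

    energy_requirement_mcal : aggregate net-energy requirement, Mcal y^-1.
    finished_live_weight_kg : live weight of a finished output animal.
    body_n_fraction : kg N per kg live mass (body protein / 6.25).
    plant_available_fraction : share of excreted manure N that becomes
        plant-available after collection, storage and application losses.
    edible_fraction : boneless edible beef per kg live weight.
    """

    energy_requirement_mcal: float = 11000.0
    finished_live_weight_kg: float = 570.0
    body_n_fraction: float = 0.025
    plant_available_fraction: float = 0.5
    edible_fraction: float = 0.43

    def __post_init__(self) -> None:
        if self.energy_requirement_mcal <= 0:
            raise ParameterError("energy_requirement_mcal must be > 0")
        if self.finished_live_weight_kg < 0:
            raise ParameterError("finished_live_weight_kg must be >= 0")
        for name in ("body_n_fraction", "plant_available_fraction", "edible_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} must lie in [0, 1], got {v}")


@dataclass(frozen=True)
class HerdProfile:
    """Herd scaled to an actual number of mother cows.

    counts : animals (or animal flows per year) per category, absolute.
    beef_output : boneless edible beef, kg y^-1 (for the whole herd).
    manure_plant_available_n : alpha x n_m, kg N y^-1.
    forage_n_demand : (1/beta) x n_m, kg forage N y^-1.
    """

    n_mother_cows: float
    counts: dict
    beef_output: float = 0.0
    manure_plant_available_n: float = 0.0
    forage_n_demand: float = 0.0


def build_herd(n_mother_cows: float, structure: HerdStructure | None = None) -> HerdProfile:
    """Scale the per-cow category ratios to ``n_mother_cows`` animals.

    Counts are exact products ratio x n_m; the herd is real-valued (a
    fraction of a cow per unit farm is meaningful once farms are counted in
    the tens of millions).
    """
    if n_mother_cows < 0:
        raise ParameterError(f"n_mother_cows must be >= 0, got {n_mother_cows}")
    structure = structure or HerdStructure()
    counts = {
        cat: ratio * n_mother_cows for cat, ratio in structure.per_cow_ratios().items()
    }
    return HerdProfile(n_mother_cows=n_mother_cows, counts=counts)


# --- pluggable physiology registry -------------------------------------

_PHYSIOLOGY_REGISTRY: dict[str, Callable] = {}


def register_physiology(name: str):
    """Decorator registering a physiology implementation under ``name``.

    An implementation has signature
    ``fn(diet: CattleDiet, structure: HerdStructure, params: PhysiologyParams)
    -> dict`` with keys ``alpha``, ``beta``, ``beef_output_per_cow``,
    ``n_intake``, ``n_retained``, ``manure_n``, ``dry_matter_intake``.
    """

    def deco(fn: Callable) -> Callable:
        _PHYSIOLOGY_REGISTRY[name] = fn
        return fn

    return deco


def available_physiologies() -> list[str]:
    return sorted(_PHYSIOLOGY_REGISTRY)


@register_physiology("net_energy")
def _net_energy_physiology(
    diet: CattleDiet, structure: HerdStructure, params: PhysiologyParams
) -> dict:
    """Energy-driven intake, N mass balance for excretion.

    All quantities are per cow-unit-year (one mother cow plus associated
    animals). Live-mass growth leaving the herd each year is
    calves_per_cow_per_year x finished live weight; its body N is the only
    N sink besides manure, so manure N = N intake - N retained exactly.
    """
    intake = params.energy_requirement_mcal / diet.energy_density  # kg DM/y
    n_intake = intake * diet.n_fraction
    live_growth = structure.calves_per_cow_per_year * params.finished_live_weight_kg
    n_retained = live_growth * params.body_n_fraction
    if n_retained > n_intake:
        raise ParameterError(
            f"diet supplies {n_intake:.3g} kg N/cow-y but growth retains "
            f"{n_retained:.3g} kg N/cow-y; the diet cannot sustain the herd"
        )
    manure_n = n_intake - n_retained
    alpha = manure_n * params.plant_available_fraction
    forage_n_demand = (
        intake * (1.0 - diet.byproduct_mass_fraction) * diet.forage_n_fraction
    )
    beta = 1.0 / forage_n_demand if forage_n_demand > 0 else 0.0
    beef = live_growth * params.edible_fraction
    return {
        "alpha": alpha,
        "beta": beta,
        "beef_output_per_cow": beef,
        "dry_matter_intake": intake,
        "n_intake": n_intake,
        "n_retained": n_retained,
        "manure_n": manure_n,
    }


def physiology_coefficients(
    diet: CattleDiet,
    structure: HerdStructure | None = None,
    params: PhysiologyParams | None = None,
    physiology: str = "net_energy",
) -> tuple[CyclingCoefficients, float, dict]:
    """Evaluate a registered physiology for one diet.

    Returns ``(CyclingCoefficients(alpha, beta), beef_output_per_cow,
    details)`` where ``details`` carries the intermediate energetics and the
    N balance (kg per cow-unit-year).
    """
    if physiology not in _PHYSIOLOGY_REGISTRY:
        raise ParameterError(
            f"unknown physiology {physiology!r}; registered: {available_physiologies()}"
        )
    structure = structure or HerdStructure()
    params = params or PhysiologyParams()
    out = _PHYSIOLOGY_REGISTRY[physiology](diet, structure, params)
    coeff = CyclingCoefficients(alpha=out["alpha"], beta=out["beta"])
    return coeff, out["beef_output_per_cow"], out


def herd_profile(
    n_mother_cows: float,
    diet: CattleDiet,
    structure: HerdStructure | None = None,
    params: PhysiologyParams | None = None,
    physiology: str = "net_energy",
) -> HerdProfile:
    """Full herd profile for a given herd size and diet: category counts
    plus beef output, plant-available manure N, and forage-N demand, all
    scaled linearly by ``n_mother_cows``."""
    base = build_herd(n_mother_cows, structure)
    coeff, beef_per_cow, details = physiology_coefficients(
        diet, structure, params, physiology
    )
    demand_per_cow = 1.0 / coeff.beta if coeff.beta > 0 else 0.0
    return HerdProfile(
        n_mother_cows=n_mother_cows,
        counts=base.counts,
        beef_output=beef_per_cow * n_mother_cows,
        manure_plant_available_n=coeff.alpha * n_mother_cows,
        forage_n_demand=demand_per_cow * n_mother_cows,
    )
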