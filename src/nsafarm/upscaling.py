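"""National upscaling: farms x area, per-capita diet, averted inputs.

Upscaling is deliberately naive and exactly linear: the chosen deployment
area (default ~105 million ha of high-quality, precipitation-rich cropland)
is assumed fully dedicated to unit farms, so the farm count is simply
area / (A_v + A_f) ~ area / 1.43. National production is farm means times
farm count; per-capita supply divides by the population (default 330
million) and 365 days.

Averted-input accounting is a production-side counterfactual: the synthetic
fertilizer and greenhouse-gas emissions that conventional agriculture would
have needed to produce the *same* per-capita diet, from per-item intensity
tables. Because field operations (tillage, harvest, transport) are still
required under the nitrogen-sparing model and typically account for 10-25%
of conventional emissions, only 75-90% of the gross GHG figure is a net
saving; both ends of that band are reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .errors import ParameterError, TableError

__all__ = [
    "DeploymentScenario",
    "NationalOutcome",
    "upscale",
    "national_outcome",
    "farm_count",
    "averted_fertilizer",
    "averted_ghg",
    "per_capita_daily",
    "conventional_benchmark",
]

DAYS_PER_YEAR = 365.0


@dataclass(frozen=True)
class DeploymentScenario:
    """National deployment assumptions and reference totals.

    Areas in ha, population in persons, fertilizer in kg N y^-1, GHG in
    kg CO2e y^-1. ``field_operations_share`` is the (low, high) band of the
    conventional-emissions share still incurred under the nitrogen-sparing
    model; documented band [0.10, 0.25].
    """

    deployment_area: float = 1.05e8
    population: float = 3.30e8
    national_fertilizer_use: float = 8.1e9
    national_ghg_total: float = 3.8e12
    national_ghg_agricultural: float = 3.5e11
    field_operations_share: tuple = (0.10, 0.25)

    def __post_init__(self) -> None:
        for name in (
            "deployment_area",
            "population",
            "national_fertilizer_use",
            "national_ghg_total",
            "national_ghg_agricultural",
        ):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be > 0")
        lo, hi = self.field_operations_share
        # the documented band is [0.10, 0.25]; 0 is allowed as the
        # no-field-operations limiting case (net saving = gross)
        if not (0.0 <= lo <= hi <= 0.25):
            raise ParameterError(
                "field_operations_share must be a (low, high) band inside "
                f"[0, 0.25], got {self.field_operations_share}"
            )


@dataclass
class NationalOutcome:
    """National consequences of full deployment."""

    farm_count: float
    per_capita_beef_g_day: float
    per_capita_protein_g_day: float
    per_capita_energy_kcal_day: float
    per_capita_nutrients: pd.Series  # per person per day, baseline units
    national_production: pd.Series  # kg y^-1 per item (incl. beef)
    averted_fertilizer_kg: float = 0.0
    averted_fertilizer_pct: float = 0.0
    averted_ghg_kg: float = 0.0
    averted_ghg_pct_agricultural: float = 0.0
    averted_ghg_pct_total: float = 0.0
    net_ghg_saving_range: tuple = (0.0, 0.0)
    extras: dict = field(default_factory=dict)

    def check_percentages(self, scenario: DeploymentScenario, rtol: float = 1e-9):
        """Recompute every stored percentage from its absolute value."""
        checks = [
            (self.averted_fertilizer_pct,
             100.0 * self.averted_fertilizer_kg / scenario.national_fertilizer_use),
            (self.averted_ghg_pct_agricultural,
             100.0 * self.averted_ghg_kg / scenario.national_ghg_agricultural),
            (self.averted_ghg_pct_total,
             100.0 * self.averted_ghg_kg / scenario.national_ghg_total),
        ]
        for stored, recomputed in checks:
            if abs(stored - recomputed) > rtol * max(abs(recomputed), 1.0):
                raise AssertionError(
                    f"stored percentage {stored} != recomputed {recomputed}"
                )


def farm_count(scenario: DeploymentScenario, unit_farm_area: float) -> float:
    if unit_farm_area <= 0:
        raise ParameterError("unit farm area must be > 0")
    return scenario.deployment_area / unit_farm_area


def per_capita_daily(total_per_year: float, population: float) -> float:
    """National annual total -> per person per day."""
    return total_per_year / population / DAYS_PER_YEAR


def upscale(farm_summary, scenario: DeploymentScenario, unit_farm_area: float = None):
    """Scale ensemble farm means to a :class:`NationalOutcome`.

    ``farm_summary`` is an :class:`~nsafarm.monte_carlo.EnsembleSummary`
    (its pooled means are used). ``unit_farm_area`` defaults to 10/7 ha
    (1 ha vegetal + 3/7 ha forage).
    """
    if unit_farm_area is None:
        unit_farm_area = 1.0 + 3.0 / 7.0
    n_farm = farm_count(scenario, unit_farm_area)
    pooled = farm_summary.pooled["mean"]

    production = {}
    for name in pooled.index:
        if name.startswith("item_mass_"):
            production[name.removeprefix("item_mass_")] = pooled[name] * n_farm
    production = pd.Series(production, dtype=float)

    nutrients = {}
    for name in pooled.index:
        if name.startswith("nut_"):
            nutrients[name.removeprefix("nut_")] = per_capita_daily(
                pooled[name] * n_farm, scenario.population
            )
    nutrients = pd.Series(nutrients, dtype=float)
    # beef mass in grams per person per day, alongside the nutrient index
    beef_g = per_capita_daily(pooled["beef_kg"] * n_farm, scenario.population) * 1000.0
    nutrients["beef_g"] = beef_g

    return NationalOutcome(
        farm_count=n_farm,
        per_capita_beef_g_day=beef_g,
        per_capita_protein_g_day=per_capita_daily(
            pooled["protein_kg"] * n_farm, scenario.population
        )
        * 1000.0,
        per_capita_energy_kcal_day=per_capita_daily(
            pooled["energy_gcal"] * 1e6 * n_farm, scenario.population
        ),
        per_capita_nutrients=nutrients,
        national_production=production,
    )


def _coverage_check(production: pd.Series, intensity: pd.Series, what: str) -> None:
    missing = [item for item in production.index if item not in intensity.index]
    if missing:
        raise TableError(f"{what} intensity table missing items: {missing}")


def averted_fertilizer(
    production: pd.Series, intensity: pd.Series, scenario: DeploymentScenario
) -> tuple[float, float]:
    """Synthetic fertilizer N that conventional production of the same
    items would have required.

    ``production`` is national kg y^-1 per item; ``intensity`` kg N per kg
    item under conventional practice. Returns (averted kg N y^-1, % of the
    national reference use).
    """
    _coverage_check(production, intensity, "fertilizer")
    averted = float((production * intensity.reindex(production.index)).sum())
    return averted, 100.0 * averted / scenario.national_fertilizer_use


def averted_ghg(
    production: pd.Series, intensity: pd.Series, scenario: DeploymentScenario
) -> dict:
    """Gross averted emissions and the net-saving band after field
    operations.

    ``intensity`` is kg CO2e per kg item under conventional practice.
    Net saving = gross x (1 - field_operations_share) over the configured
    share band.
    """
    _coverage_check(production, intensity, "GHG")
    gross = float((production * intensity.reindex(production.index)).sum())
    lo, hi = scenario.field_operations_share
    return {
        "gross_kg": gross,
        "pct_agricultural": 100.0 * gross / scenario.national_ghg_agricultural,
        "pct_total": 100.0 * gross / scenario.national_ghg_total,
        "net_saving_range_kg": (gross * (1.0 - hi), gross * (1.0 - lo)),
    }


def national_outcome(
    farm_summary,
    scenario: DeploymentScenario,
    fertilizer_intensity: pd.Series,
    ghg_intensity: pd.Series,
    unit_farm_area: float = None,
) -> NationalOutcome:
    """Convenience: upscale then attach both averted-input accounts."""
    out = upscale(farm_summary, scenario, unit_farm_area)
    fert_kg, fert_pct = averted_fertilizer(
        out.national_production, fertilizer_intensity, scenario
    )
    ghg = averted_ghg(out.national_production, ghg_intensity, scenario)
    out.averted_fertilizer_kg = fert_kg
    out.averted_fertilizer_pct = fert_pct
    out.averted_ghg_kg = ghg["gross_kg"]
    out.averted_ghg_pct_agricultural = ghg["pct_agricultural"]
    out.averted_ghg_pct_total = ghg["pct_total"]
    out.net_ghg_saving_range = ghg["net_saving_range_kg"]
    return out


def conventional_benchmark(
    kcal_per_capita_day: float,
    protein_g_per_capita_day: float,
    population: float = 3.30e8,
    harvested_area_ha: float = 2.60e8,
    unit_farm_area: float = 1.43,
) -> dict:
    """Per-hectare productivity of today's conventional US system.

    Converts national per-capita daily supplies into mean per-hectare
    annual deliveries over the harvested area, plus the same rescaled to
    one unit-farm's land (x unit_farm_area) for direct comparison with the
    per-farm outputs. Returns protein in kg ha^-1 y^-1 and energy in
    Gcal ha^-1 y^-1.
    """
    if population <= 0 or harvested_area_ha <= 0:
        raise ParameterError("population and harvested area must be > 0")
    protein_kg_ha = (
        protein_g_per_capita_day / 1000.0 * DAYS_PER_YEAR * population / harvested_area_ha
    )
    energy_gcal_ha = (
        kcal_per_capita_day / 1e6 * DAYS_PER_YEAR * population / harvested_area_ha
    )
    return {
        "protein_kg_per_ha_year": protein_kg_ha,
        "energy_gcal_per_ha_year": energy_gcal_ha,
        "protein_kg_per_farm_year": protein_kg_ha * unit_farm_area,
        "energy_gcal_per_farm_year": energy_gcal_ha * unit_farm_area,
    }
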