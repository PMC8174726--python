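"""Headline land-use scenarios and the adults-supported metric.

Three scenarios compare what one unit farm's land can deliver:

- ``reference`` — the main mixed model: 1 ha vegetal + 3/7 ha forage
  feeding the beef core whose manure boosts vegetal yields. Its protein is
  the ensemble mean pooled over the three forage qualities.
- ``rewild`` — the forage subunit is taken out of production entirely
  (no cattle, no manure); only the 1-ha vegetal subunit produces, at the
  lower no-manure yield. Rewilded land contributes zero food and zero N.
- ``all_vegetal`` — the full 1.43 ha grows vegetal food, still with no
  cattle and hence no manure.

Each scenario is summarized by per-farm protein, its fraction of the
reference, and the number of adults whose protein requirement (default
75 g per person per day) it fully meets.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, replace

from .errors import ParameterError
from .farm_core import FORAGE_TO_VEGETAL_RATIO, FarmGeometry
from .monte_carlo import run_ensemble

__all__ = ["ScenarioResult", "adults_supported", "run_scenarios", "PROTEIN_REQUIREMENT_G_DAY"]

#: Default adult protein requirement, g per person per day.
PROTEIN_REQUIREMENT_G_DAY = 75.0

DAYS_PER_YEAR = 365.0


@dataclass(frozen=True)
class ScenarioResult:
    name: str
    protein_kg_per_farm_year: float
    fraction_of_reference: float
    adults_supported: float
    land_in_production_ha: float


def adults_supported(
    protein_kg_per_year: float,
    requirement_g_day: float = PROTEIN_REQUIREMENT_G_DAY,
) -> float:
    """Number of adults whose annual protein need the given supply meets.

    Linear in protein and inversely proportional to the requirement:
    27.375 kg y^-1 (75 g x 365 d) supports exactly one person.
    """
    if requirement_g_day <= 0:
        raise ParameterError(
            f"protein requirement must be > 0, got {requirement_g_day}"
        )
    if protein_kg_per_year < 0:
        raise ParameterError("protein supply must be >= 0")
    return protein_kg_per_year / (requirement_g_day / 1000.0 * DAYS_PER_YEAR)


def _no_manure_config(config, area_vegetal: float):
    """Config variant with the herd removed: alpha = 0 via a zero
    plant-available fraction, no forage land, all land (if any) vegetal."""
    cfg = copy.deepcopy(config)
    cfg.geometry = FarmGeometry(area_vegetal=area_vegetal, area_forage=0.0, gamma=1.0)
    cfg.physiology_params = replace(cfg.physiology_params, plant_available_fraction=0.0)
    cfg.distributions.pop("plant_available_fraction", None)
    # rescale crop land shares to the new vegetal area
    frame = cfg.crop_table.frame.copy()
    is_crop = frame["item"] != "beef"
    old_area = cfg.crop_table.area_vegetal
    frame.loc[is_crop, "land_share_ha"] *= area_vegetal / old_area
    cfg.crop_table = type(cfg.crop_table)(
        frame, area_vegetal=area_vegetal, n_to_protein=cfg.crop_table.n_to_protein
    )
    return cfg


def run_scenarios(
    config,
    seed: int | None = None,
    n_realizations: int | None = None,
    requirement_g_day: float | None = None,
) -> list[ScenarioResult]:
    """Run reference, rewild, and all-vegetal ensembles with a common seed.

    The reference protein is the pooled ensemble mean over the configured
    forage qualities. The no-beef scenarios are solved with the same
    nitrogen-input draws (same seed) but zero manure; the rewild case on
    1 ha of vegetal land, the all-vegetal case on the full farm area. The
    same yield penalty applies throughout.
    """
    requirement = (
        requirement_g_day
        if requirement_g_day is not None
        else getattr(config, "protein_requirement_g_day", PROTEIN_REQUIREMENT_G_DAY)
    )
    area_v = config.geometry.area_vegetal
    area_total = config.geometry.total_area

    ref = run_ensemble(config, n_realizations=n_realizations, seed=seed)
    rewild = run_ensemble(
        _no_manure_config(config, area_v), n_realizations=n_realizations, seed=seed
    )
    allveg = run_ensemble(
        _no_manure_config(config, area_total), n_realizations=n_realizations, seed=seed
    )

    ref_protein = ref.mean("protein_kg")
    results = []
    for name, summary, land in (
        ("reference", ref, area_total),
        ("rewild", rewild, area_v),
        ("all_vegetal", allveg, area_total),
    ):
        protein = summary.mean("protein_kg")
        results.append(
            ScenarioResult(
                name=name,
                protein_kg_per_farm_year=protein,
                fraction_of_reference=protein / ref_protein if ref_protein > 0 else 0.0,
                adults_supported=adults_supported(protein, requirement),
                land_in_production_ha=land,
            )
        )
    return results
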