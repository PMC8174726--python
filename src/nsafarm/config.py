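"""Run configuration: the single object the pipeline consumes.

A :class:`RunConfig` bundles everything a run needs — farm geometry,
retention curves, herd structure and physiology, forage-quality diet
nominals, parameter distributions, the crop-nutrient and baseline tables,
intensity tables, the deployment scenario, and ensemble settings. It can be
built in memory (see :mod:`nsafarm.synthetic`) or round-tripped through a
YAML file plus CSV tables; every referenced file is checked and validated
before any computation starts.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .errors import ConfigError
from .farm_core import FarmGeometry, RetentionCurve
from .herd import HerdStructure, PhysiologyParams
from .monte_carlo import ParameterDistribution
from .nutrition import CropNutrientTable, load_mad_baseline
from .upscaling import DeploymentScenario

__all__ = ["RunConfig", "load_config", "save_config"]

TABLE_FILES = {
    "crop_table": "crop_table.csv",
    "mad_baseline": "mad_baseline.csv",
    "fertilizer_intensity": "fertilizer_intensity.csv",
    "ghg_intensity": "ghg_intensity.csv",
}


@dataclass
class RunConfig:
    geometry: FarmGeometry
    retention_vegetal: RetentionCurve
    retention_forage: RetentionCurve
    herd_structure: HerdStructure
    physiology: str
    physiology_params: PhysiologyParams
    byproduct: dict
    qualities: dict
    distributions: dict
    crop_table: CropNutrientTable
    mad_baseline: pd.DataFrame
    yield_penalty: float
    fertilizer_intensity: pd.Series
    ghg_intensity: pd.Series
    scenario: DeploymentScenario
    ensemble: dict = field(
        default_factory=lambda: {
            "n_realizations": 250,
            "seed": 0,
            "qualities": ["high", "medium", "low"],
        }
    )
    protein_requirement_g_day: float = 75.0

    def digest(self) -> str:
        """SHA-256 over the canonical serialized form (settings + tables)."""
        h = hashlib.sha256()
        h.update(
            yaml.safe_dump(self._settings_dict(), sort_keys=True).encode()
        )
        h.update(self.crop_table.frame.to_csv(index=False).encode())
        h.update(self.mad_baseline.to_csv(index=False).encode())
        h.update(
            self.fertilizer_intensity.rename("kg_n_per_kg")
            .rename_axis("item").to_csv().encode()
        )
        h.update(
            self.ghg_intensity.rename("kg_co2e_per_kg")
            .rename_axis("item").to_csv().encode()
        )
        return h.hexdigest()

    def _settings_dict(self) -> dict:
        g = self.geometry
        return {
            "geometry": {
                "area_vegetal": g.area_vegetal,
                "area_forage": g.area_forage,
                "gamma": g.gamma,
            },
            "retention": {
                "vegetal": {"kind": self.retention_vegetal.kind,
                            **self.retention_vegetal.parameters},
                "forage": {"kind": self.retention_forage.kind,
                           **self.retention_forage.parameters},
            },
            "herd": {
                "structure": {
                    "bulls_per_100_cows": self.herd_structure.bulls_per_100_cows,
                    "replacement_heifers_per_100_cows":
                        self.herd_structure.replacement_heifers_per_100_cows,
                    "calves_per_cow_per_year":
                        self.herd_structure.calves_per_cow_per_year,
                    "other_ratios": dict(self.herd_structure.other_ratios),
                },
                "physiology": self.physiology,
                "physiology_params": {
                    "energy_requirement_mcal":
                        self.physiology_params.energy_requirement_mcal,
                    "finished_live_weight_kg":
                        self.physiology_params.finished_live_weight_kg,
                    "body_n_fraction": self.physiology_params.body_n_fraction,
                    "plant_available_fraction":
                        self.physiology_params.plant_available_fraction,
                    "edible_fraction": self.physiology_params.edible_fraction,
                },
                "byproduct": dict(self.byproduct),
            },
            "qualities": {k: dict(v) for k, v in self.qualities.items()},
            "distributions": {
                name: {"family": d.family, "parameters": dict(d.parameters)}
                for name, d in self.distributions.items()
            },
            "nutrition": {"yield_penalty": self.yield_penalty},
            "scenario": {
                "deployment_area": self.scenario.deployment_area,
                "population": self.scenario.population,
                "national_fertilizer_use": self.scenario.national_fertilizer_use,
                "national_ghg_total": self.scenario.national_ghg_total,
                "national_ghg_agricultural":
                    self.scenario.national_ghg_agricultural,
                "field_operations_share":
                    list(self.scenario.field_operations_share),
            },
            "ensemble": dict(self.ensemble),
            "protein_requirement_g_day": self.protein_requirement_g_day,
            "tables": dict(TABLE_FILES),
        }


def save_config(config: RunConfig, out_dir) -> Path:
    """Write ``config.yaml`` plus the four CSV tables into ``out_dir``.

    Returns the path of the YAML file. Numbers are serialized at full
    precision (repr round-trip).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.crop_table.frame.to_csv(out / TABLE_FILES["crop_table"], index=False)
    config.mad_baseline.to_csv(out / TABLE_FILES["mad_baseline"], index=False)
    config.fertilizer_intensity.rename("kg_n_per_kg").rename_axis("item").to_csv(
        out / TABLE_FILES["fertilizer_intensity"]
    )
    config.ghg_intensity.rename("kg_co2e_per_kg").rename_axis("item").to_csv(
        out / TABLE_FILES["ghg_intensity"]
    )
    path = out / "config.yaml"
    path.write_text(yaml.safe_dump(config._settings_dict(), sort_keys=True))
    return path


def _build_retention(block: dict) -> RetentionCurve:
    block = dict(block)
    kind = block.pop("kind")
    return RetentionCurve(kind, block)


def load_config(path) -> RunConfig:
    """Load and fully validate a configuration written by
    :func:`save_config`. Raises :class:`ConfigError` naming the offending
    field or missing file; all tables are validated before returning."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"missing input: {path}")
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"unparseable config {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"config {path} is not a mapping")

    base = path.parent
    for key in ("geometry", "retention", "herd", "qualities", "distributions",
                "nutrition", "scenario", "ensemble", "tables"):
        if key not in raw:
            raise ConfigError(f"config missing required block {key!r}")

    tables = {}
    for name, fname in raw["tables"].items():
        fpath = base / fname
        if not fpath.exists():
            raise ConfigError(f"missing input: {fpath}")
        tables[name] = fpath

    try:
        geometry = FarmGeometry(**raw["geometry"])
        retention_v = _build_retention(raw["retention"]["vegetal"])
        retention_f = _build_retention(raw["retention"]["forage"])
        herd = raw["herd"]
        structure = HerdStructure(**herd["structure"])
        params = PhysiologyParams(**herd["physiology_params"])
        distributions = {
            name: ParameterDistribution(name, d["family"], d["parameters"])
            for name, d in raw["distributions"].items()
        }
        crop = CropNutrientTable.from_csv(
            tables["crop_table"], area_vegetal=raw["geometry"]["area_vegetal"]
        )
        mad = load_mad_baseline(tables["mad_baseline"])
        fert = pd.read_csv(
            tables["fertilizer_intensity"], index_col="item",
            float_precision="round_trip",
        )["kg_n_per_kg"]
        ghg = pd.read_csv(
            tables["ghg_intensity"], index_col="item",
            float_precision="round_trip",
        )["kg_co2e_per_kg"]
        scn = dict(raw["scenario"])
        scn["field_operations_share"] = tuple(scn["field_operations_share"])
        scenario = DeploymentScenario(**scn)
    except (TypeError, KeyError, ValueError) as exc:
        if isinstance(exc, ConfigError):
            raise
        raise ConfigError(f"invalid configuration field: {exc}") from exc

    return RunConfig(
        geometry=geometry,
        retention_vegetal=retention_v,
        retention_forage=retention_f,
        herd_structure=structure,
        physiology=herd["physiology"],
        physiology_params=params,
        byproduct=dict(herd["byproduct"]),
        qualities={k: dict(v) for k, v in raw["qualities"].items()},
        distributions=distributions,
        crop_table=crop,
        mad_baseline=mad,
        yield_penalty=float(raw["nutrition"]["yield_penalty"]),
        fertilizer_intensity=fert,
        ghg_intensity=ghg,
        scenario=scenario,
        ensemble=dict(raw["ensemble"]),
        protein_requirement_g_day=float(raw.get("protein_requirement_g_day", 75.0)),
    )
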