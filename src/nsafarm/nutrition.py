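"""Convert nitrogen yields into edible mass, energy, protein and nutrients.

The vegetal hectare is planted with a configurable mix of crop items, each
occupying a land share. Each item's share of the subunit's N yield is set by
its land share; the item's edible mass is that N divided by the item's
edible-mass N content, capped at (1 - yield_penalty) times its conventional
yield (the NSA model's yield penalty, default 15%, acts as a mass ceiling
relative to today's conventional practice). Surplus N above an item's cap
is counted but not converted (it ends in residues or feed, not human food).

Nutrient deliveries follow linearly from mass via the per-kg composition
columns of the crop table; beef contributes through its own composition
row. Per-capita deliveries are finally expressed as ratios to today's mean
American diet (MAD) availability baseline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ParameterError, TableError

__all__ = [
    "CropNutrientTable",
    "DietDelivery",
    "load_mad_baseline",
    "nitrogen_to_food",
    "beef_to_food",
    "mad_ratio",
    "N_TO_PROTEIN",
]

#: Default nitrogen -> crude protein conversion factor (kg protein per kg N).
N_TO_PROTEIN = 6.25

#: Columns every crop table must carry. Any further numeric column is
#: treated as a nutrient composition per kg edible mass.
REQUIRED_COLUMNS = (
    "item",
    "land_share_ha",
    "conv_yield_kg_per_ha",
    "n_content_kg_per_kg",
    "energy_kcal_per_kg",
    "protein_g_per_kg",
)


class CropNutrientTable:
    """Validated crop mix + composition table for the vegetal subunit.

    One row per crop item. ``land_share_ha`` must sum to the vegetal area
    (1e-6 tolerance); compositions must be non-negative; each item's protein
    must agree with ``n_to_protein x N content`` within the item's stated
    relative tolerance (column ``protein_n_tolerance``, default 0.2 — food
    proteins vary in N content, so this is a sanity check, not an equality).

    An optional single row with ``item == "beef"`` and zero land share
    carries the beef composition used by :func:`beef_to_food`.
    """

    def __init__(
        self,
        frame: pd.DataFrame,
        area_vegetal: float = 1.0,
        n_to_protein: float = N_TO_PROTEIN,
    ):
        missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
        if missing:
            raise TableError(f"crop table missing required columns: {missing}")
        frame = frame.reset_index(drop=True)
        crops = frame[frame["item"] != "beef"]
        share_sum = float(crops["land_share_ha"].sum())
        if abs(share_sum - area_vegetal) > 1e-6:
            raise TableError(
                f"crop land shares sum to {share_sum!r}, expected the vegetal "
                f"area {area_vegetal!r} (tolerance 1e-6)"
            )
        numeric = frame.drop(columns=["item"]).select_dtypes("number")
        if (numeric < 0).any().any():
            bad = numeric.columns[(numeric < 0).any()].tolist()
            raise TableError(f"negative composition entries in columns {bad}")
        tol = (
            frame["protein_n_tolerance"]
            if "protein_n_tolerance" in frame.columns
            else pd.Series(0.2, index=frame.index)
        )
        implied = n_to_protein * frame["n_content_kg_per_kg"] * 1000.0  # g/kg
        with np.errstate(divide="ignore", invalid="ignore"):
            rel = np.abs(frame["protein_g_per_kg"] - implied) / implied.replace(0, np.nan)
        bad = frame["item"][rel.fillna(0) > tol].tolist()
        if bad:
            raise TableError(
                f"protein inconsistent with {n_to_protein} x N content beyond "
                f"stated tolerance for items {bad}"
            )
        self.frame = frame
        self.area_vegetal = area_vegetal
        self.n_to_protein = n_to_protein
        # cached arrays for the hot path
        self._crops = crops.reset_index(drop=True)
        self._shares = self._crops["land_share_ha"].to_numpy(float)
        self._ncontent = self._crops["n_content_kg_per_kg"].to_numpy(float)
        self._conv_yield = self._crops["conv_yield_kg_per_ha"].to_numpy(float)
        self._nutrient_cols = [
            c
            for c in frame.columns
            if c not in ("item", "land_share_ha", "conv_yield_kg_per_ha",
                         "n_content_kg_per_kg", "protein_n_tolerance")
        ]
        self._compositions = self._crops[self._nutrient_cols].to_numpy(float)

    @property
    def items(self) -> list[str]:
        return self._crops["item"].tolist()

    @property
    def nutrient_columns(self) -> list[str]:
        return list(self._nutrient_cols)

    @property
    def nutrient_names(self) -> list[str]:
        """Column names with the per-kg suffix stripped — the index used for
        delivery totals (e.g. energy_kcal_per_kg -> energy_kcal)."""
        return [c.replace("_per_kg", "") for c in self._nutrient_cols]

    def beef_row(self) -> pd.Series:
        rows = self.frame[self.frame["item"] == "beef"]
        if rows.empty:
            raise TableError("crop table has no 'beef' composition row")
        return rows.iloc[0]

    @classmethod
    def from_csv(cls, path, **kwargs) -> "CropNutrientTable":
        # round_trip: bit-exact float parsing so digests survive save/load
        return cls(pd.read_csv(path, float_precision="round_trip"), **kwargs)


@dataclass(frozen=True)
class VegetalOutput:
    """Per-item masses and summed nutrient deliveries of the vegetal subunit
    for one solved farm-year."""

    per_item: pd.DataFrame  # item, n_allocated_kg, n_used_kg, mass_kg, capped
    totals: pd.Series  # mass_kg plus every nutrient column (column units x kg)
    surplus_n: float  # allocated N above the capped demand, kg


@dataclass(frozen=True)
class DietDelivery:
    """Vegetal and beef nutrient deliveries; ``total`` is their exact sum."""

    vegetal: pd.Series
    beef: pd.Series

    @property
    def total(self) -> pd.Series:
        return self.vegetal.add(self.beef, fill_value=0.0)


def nitrogen_to_food(
    yield_vegetal: float,
    table: CropNutrientTable,
    yield_penalty: float = 0.15,
) -> VegetalOutput:
    """Allocate the vegetal N yield over the crop mix and convert to food.

    ``yield_vegetal`` is kg N per ha of vegetal land; each item receives
    ``yield_vegetal x land_share`` kg N. Item edible mass is
    ``min(N / N_content, (1 - penalty) x conventional yield x share)``.
    """
    if not 0.0 <= yield_penalty < 1.0:
        raise ParameterError(f"yield_penalty must lie in [0, 1), got {yield_penalty}")
    if yield_vegetal < 0:
        raise ParameterError(f"yield_vegetal must be >= 0, got {yield_vegetal}")

    n_alloc = yield_vegetal * table._shares
    with np.errstate(divide="ignore"):
        uncapped = np.where(table._ncontent > 0, n_alloc / np.where(
            table._ncontent > 0, table._ncontent, 1.0), np.inf)
    cap = (1.0 - yield_penalty) * table._conv_yield * table._shares
    mass = np.minimum(uncapped, cap)
    capped = uncapped > cap
    n_used = mass * table._ncontent
    totals_vals = mass @ table._compositions
    totals = pd.Series(totals_vals, index=table.nutrient_names)
    totals["mass_kg"] = float(mass.sum())
    per_item = pd.DataFrame(
        {
            "item": table.items,
            "n_allocated_kg": n_alloc,
            "n_used_kg": n_used,
            "mass_kg": mass,
            "capped": capped,
        }
    )
    return VegetalOutput(
        per_item=per_item,
        totals=totals,
        surplus_n=float(n_alloc.sum() - n_used.sum()),
    )


def beef_to_food(beef_mass_kg: float, beef_row: pd.Series) -> pd.Series:
    """Linear mass -> nutrient conversion for the beef output.

    ``beef_row`` is a composition row (per-kg units, e.g. from
    :meth:`CropNutrientTable.beef_row`). Returns the same index as the
    vegetal totals: every nutrient column plus ``mass_kg``.
    """
    if beef_mass_kg < 0:
        raise ParameterError(f"beef mass must be >= 0, got {beef_mass_kg}")
    skip = {"item", "land_share_ha", "conv_yield_kg_per_ha",
            "n_content_kg_per_kg", "protein_n_tolerance"}
    nutrients = beef_row.drop(labels=[k for k in skip if k in beef_row.index])
    out = nutrients.astype(float) * beef_mass_kg
    out.index = [c.replace("_per_kg", "") for c in out.index]
    out["mass_kg"] = float(beef_mass_kg)
    return out


def load_mad_baseline(path_or_frame) -> pd.DataFrame:
    """Load the mean-American-diet availability baseline.

    Columns: ``nutrient`` (matching delivery index names), ``value``
    (per-capita daily availability, per-kg column units of the crop table
    divided by kg: kcal, g, mg, ug per person per day), optional
    ``source_note``. Values must be >= 0.
    """
    frame = (
        pd.read_csv(path_or_frame, float_precision="round_trip")
        if not isinstance(path_or_frame, pd.DataFrame)
        else path_or_frame.copy()
    )
    for col in ("nutrient", "value"):
        if col not in frame.columns:
            raise TableError(f"MAD baseline missing column {col!r}")
    if (frame["value"] < 0).any():
        raise TableError("MAD baseline values must be >= 0")
    return frame.reset_index(drop=True)


def mad_ratio(delivery: pd.Series, baseline: pd.DataFrame) -> pd.DataFrame:
    """Per-nutrient delivery as a multiple of the MAD baseline.

    ``delivery`` must be per-capita daily amounts in the baseline's units.
    Nutrients with a zero baseline are flagged ``ratioable = False`` and
    left NaN rather than divided. Baseline rows absent from the delivery
    are dropped.
    """
    rows = []
    for _, row in baseline.iterrows():
        name = row["nutrient"]
        if name not in delivery.index:
            continue
        base = float(row["value"])
        ratioable = base > 0
        rows.append(
            {
                "nutrient": name,
                "delivery": float(delivery[name]),
                "baseline": base,
                "ratio": float(delivery[name]) / base if ratioable else np.nan,
                "ratioable": ratioable,
            }
        )
    return pd.DataFrame(rows)
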