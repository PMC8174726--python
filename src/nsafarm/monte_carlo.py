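"""Monte Carlo ensemble over uncertain nitrogen inputs and forage quality.

The study design solves the unit farm repeatedly — by default 250
randomized realizations for each of 3 forage qualities, a pooled population
of 750 — with the uncertain right-hand-side parameters drawn from
configured distributions. Summaries report the pooled mean and +-1 standard
deviation over the full population (the whisker convention used for all
headline outputs), plus per-quality summaries.

Reproducibility: each (quality, realization) pair gets its own independent
RNG stream seeded from ``(seed, quality_index, realization_index)``, so any
subset of the ensemble can be regenerated bit-identically.

Realizations whose solve fails (e.g. a supercritical manure feedback under
an extreme draw) are recorded and excluded rather than resampled —
resampling would bias the ensemble toward benign parameter regions. More
than 10% failures aborts the run.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import EnsembleError, NSAFarmError, ParameterError
from .farm_core import NitrogenInputs, solve_fixed_point
from .herd import CattleDiet, physiology_coefficients
from .nutrition import beef_to_food, nitrogen_to_food

__all__ = [
    "ParameterDistribution",
    "EnsembleSummary",
    "run_ensemble",
    "sensitivity_sweep",
    "MAX_FAILURE_FRACTION",
]

#: Abort the ensemble if more than this fraction of realizations fail.
MAX_FAILURE_FRACTION = 0.10

#: Parameter names run_ensemble knows how to route into the model. Scale
#: parameters multiply the quality-specific nominal value.
KNOWN_PARAMETERS = (
    "deposition",
    "fixation_vegetal",
    "fixation_forage",
    "forage_energy_scale",
    "forage_n_scale",
    "plant_available_fraction",
)

_FAMILIES = ("point", "uniform", "truncnormal", "lognormal")


@dataclass(frozen=True)
class ParameterDistribution:
    """One uncertain parameter and the distribution it is drawn from.

    Families and their parameters (all in the parameter's natural units):

    - ``point``: {value} — degenerate, reproduces value exactly.
    - ``uniform``: {low, high}, low >= 0.
    - ``truncnormal``: {mean, sd} — normal truncated at 0 from below.
    - ``lognormal``: {mean_log, sigma_log} of the underlying normal.

    All families respect non-negativity, the sign constraint every
    nitrogen-budget parameter carries.
    """

    name: str
    family: str
    parameters: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ParameterError(
                f"unknown distribution family {self.family!r} for {self.name!r}; "
                f"choose from {_FAMILIES}"
            )
        p = self.parameters
        if self.family == "point":
            if "value" not in p or p["value"] < 0:
                raise ParameterError(f"{self.name}: point mass needs value >= 0")
        elif self.family == "uniform":
            if not (0 <= p.get("low", -1) <= p.get("high", -1)):
                raise ParameterError(f"{self.name}: uniform needs 0 <= low <= high")
        elif self.family == "truncnormal":
            if p.get("sd", -1) < 0 or "mean" not in p:
                raise ParameterError(f"{self.name}: truncnormal needs mean and sd >= 0")
        elif self.family == "lognormal":
            if p.get("sigma_log", -1) < 0 or "mean_log" not in p:
                raise ParameterError(
                    f"{self.name}: lognormal needs mean_log and sigma_log >= 0"
                )

    def draw(self, rng: np.random.Generator) -> float:
        p = self.parameters
        if self.family == "point":
            return float(p["value"])
        if self.family == "uniform":
            return float(rng.uniform(p["low"], p["high"]))
        if self.family == "truncnormal":
            if p["sd"] == 0:
                return float(p["mean"])
            a = (0.0 - p["mean"]) / p["sd"]
            return float(
                stats.truncnorm.rvs(
                    a, np.inf, loc=p["mean"], scale=p["sd"], random_state=rng
                )
            )
        return float(rng.lognormal(p["mean_log"], p["sigma_log"]))

    @property
    def mean_value(self) -> float:
        """Central value used for deterministic 'mean-parameter' solves."""
        p = self.parameters
        if self.family == "point":
            return float(p["value"])
        if self.family == "uniform":
            return float(0.5 * (p["low"] + p["high"]))
        if self.family == "truncnormal":
            return float(p["mean"])  # nominal, ignoring truncation shift
        return float(np.exp(p["mean_log"] + 0.5 * p["sigma_log"] ** 2))


@dataclass
class EnsembleSummary:
    """Mean +- SD of every farm output over the pooled population."""

    raw: pd.DataFrame  # one row per successful realization
    pooled: pd.DataFrame  # index = output, columns = mean, sd
    per_quality: dict  # quality -> DataFrame(mean, sd)
    population_size: int  # attempted realizations x qualities
    n_failures: int
    failures: list = field(default_factory=list)

    def mean(self, output: str) -> float:
        return float(self.pooled.loc[output, "mean"])

    def sd(self, output: str) -> float:
        return float(self.pooled.loc[output, "sd"])


def _validate_distributions(distributions: Mapping[str, ParameterDistribution]) -> None:
    unknown = sorted(set(distributions) - set(KNOWN_PARAMETERS))
    if unknown:
        raise ParameterError(
            f"distributions for unknown parameters {unknown}; known: "
            f"{list(KNOWN_PARAMETERS)}"
        )


def _draw_parameters(
    distributions: Mapping[str, ParameterDistribution], rng: np.random.Generator
) -> dict:
    return {name: dist.draw(rng) for name, dist in distributions.items()}


def realize_farm(config, quality: str, draws: Mapping[str, float]) -> dict:
    """Run the full farm chain (physiology -> budget -> food) for one
    parameter draw; returns a flat record of inputs and outputs."""
    q = config.qualities[quality]
    diet = CattleDiet(
        forage_quality=quality,
        forage_energy_density=q["forage_energy_density"]
        * draws.get("forage_energy_scale", 1.0),
        forage_n_fraction=q["forage_n_fraction"] * draws.get("forage_n_scale", 1.0),
        byproduct_mass_fraction=config.byproduct["mass_fraction"],
        byproduct_energy_density=config.byproduct["energy_density_mcal_per_kg"],
        byproduct_n_fraction=config.byproduct["n_fraction"],
    )
    params = config.physiology_params
    if "plant_available_fraction" in draws:
        params = _replace_paf(params, draws["plant_available_fraction"])
    coeff, beef_per_cow, _ = physiology_coefficients(
        diet, config.herd_structure, params, config.physiology
    )
    inputs = NitrogenInputs(
        deposition=draws["deposition"],
        fixation_vegetal=draws["fixation_vegetal"],
        fixation_forage=draws["fixation_forage"],
    )
    sol = solve_fixed_point(
        config.geometry, inputs, coeff, config.retention_vegetal, config.retention_forage
    )
    veg = nitrogen_to_food(sol.yield_vegetal, config.crop_table, config.yield_penalty)
    beef_kg = beef_per_cow * sol.n_mother_cows
    beef = beef_to_food(beef_kg, config.crop_table.beef_row())
    total = veg.totals.add(beef, fill_value=0.0)

    record = {f"draw_{k}": v for k, v in draws.items()}
    record.update(
        quality=quality,
        alpha=coeff.alpha,
        beta=coeff.beta,
        yield_vegetal=sol.yield_vegetal,
        yield_forage=sol.yield_forage,
        n_mother_cows=sol.n_mother_cows,
        leached_vegetal=sol.leached_vegetal,
        leached_forage=sol.leached_forage,
        rho_vegetal=sol.rho_vegetal,
        rho_forage=sol.rho_forage,
        beef_kg=beef_kg,
        vegetal_mass_kg=float(veg.totals["mass_kg"]),
        food_mass_kg=float(total["mass_kg"]),
        protein_vegetal_kg=float(veg.totals["protein_g"]) / 1000.0,
        protein_beef_kg=float(beef["protein_g"]) / 1000.0,
        protein_kg=float(total["protein_g"]) / 1000.0,
        energy_gcal=float(total["energy_kcal"]) / 1e6,
        surplus_n_kg=veg.surplus_n,
    )
    for name in total.index:
        record[f"nut_{name}"] = float(total[name])
    for item, mass in zip(veg.per_item["item"], veg.per_item["mass_kg"]):
        record[f"item_mass_{item}"] = float(mass)
    record["item_mass_beef"] = beef_kg
    return record


def _replace_paf(params, value):
    from dataclasses import replace

    return replace(params, plant_available_fraction=value)


def _summarize(frame: pd.DataFrame) -> pd.DataFrame:
    numeric = frame.select_dtypes("number").drop(
        columns=[c for c in ("realization",) if c in frame.columns]
    )
    return pd.DataFrame({"mean": numeric.mean(), "sd": numeric.std(ddof=1).fillna(0.0)})


def run_ensemble(
    config,
    n_realizations: int | None = None,
    qualities: Sequence[str] | None = None,
    seed: int | None = None,
) -> EnsembleSummary:
    """Run the farm chain over realizations x forage qualities.

    Arguments default to the ``ensemble`` block of ``config``. Deterministic
    given ``seed``; the raw per-realization table is retained on the
    returned :class:`EnsembleSummary`.
    """
    n_realizations = n_realizations or config.ensemble["n_realizations"]
    qualities = list(qualities or config.ensemble["qualities"])
    seed = config.ensemble["seed"] if seed is None else seed
    if n_realizations < 1:
        raise ParameterError(f"n_realizations must be >= 1, got {n_realizations}")
    for q in qualities:
        if q not in config.qualities:
            raise ParameterError(f"unknown forage quality {q!r}")
    _validate_distributions(config.distributions)

    rows, failures = [], []
    for qi, quality in enumerate(qualities):
        for r in range(n_realizations):
            rng = np.random.default_rng([seed, qi, r])
            draws = _draw_parameters(config.distributions, rng)
            try:
                record = realize_farm(config, quality, draws)
            except NSAFarmError as exc:
                failures.append(
                    {"quality": quality, "realization": r, "error": str(exc)}
                )
                continue
            record["realization"] = r
            rows.append(record)

    population = n_realizations * len(qualities)
    if len(failures) > MAX_FAILURE_FRACTION * population:
        raise EnsembleError(
            f"{len(failures)}/{population} realizations failed "
            f"(> {MAX_FAILURE_FRACTION:.0%} threshold); first error: "
            f"{failures[0]['error']}"
        )
    raw = pd.DataFrame(rows)
    per_quality = {
        q: _summarize(raw[raw["quality"] == q]) for q in qualities
    }
    return EnsembleSummary(
        raw=raw,
        pooled=_summarize(raw),
        per_quality=per_quality,
        population_size=population,
        n_failures=len(failures),
        failures=failures,
    )


def _set_config_parameter(config, parameter: str, value) -> None:
    """Resolve a dotted parameter path on a (deep-copied) config in place."""
    if parameter == "yield_penalty":
        config.yield_penalty = value
        return
    parts = parameter.split(".")
    if len(parts) == 3 and parts[0] == "distributions":
        _, name, key = parts
        if name not in config.distributions:
            raise ParameterError(f"unknown distribution {name!r}")
        dist = config.distributions[name]
        if key not in dist.parameters:
            raise ParameterError(f"distribution {name!r} has no parameter {key!r}")
        new_params = dict(dist.parameters)
        new_params[key] = value
        config.distributions[name] = ParameterDistribution(
            dist.name, dist.family, new_params
        )
        return
    raise ParameterError(
        f"unknown sweep parameter {parameter!r}; use 'yield_penalty' or "
        "'distributions.<name>.<param>'"
    )


def sensitivity_sweep(
    config,
    parameter: str,
    values: Iterable,
    n_realizations: int | None = None,
    qualities: Sequence[str] | None = None,
    seed: int | None = None,
) -> dict:
    """One ensemble per parameter value, common seed, tabulated together.

    Returns ``{value: EnsembleSummary}`` in input order. A single value is
    exactly one :func:`run_ensemble` call; an empty value list is rejected.
    """
    values = list(values)
    if not values:
        raise ParameterError("sensitivity_sweep requires at least one value")
    out = {}
    for v in values:
        cfg = copy.deepcopy(config)
        _set_config_parameter(cfg, parameter, v)
        out[v] = run_ensemble(cfg, n_realizations, qualities, seed)
    return out
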