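"""Nitrogen budget of one mixed vegetal/forage/beef unit farm.

The farm comprises a vegetal subunit (plant food for people, area ``A_v``),
a forage subunit (served cattle feed, area ``A_f``), and a confined cattle
core of negligible area. Nitrogen enters each cropped subunit by atmospheric
deposition ``d`` and symbiotic fixation (``f_v``, ``f_f``), and is augmented
by plant-available manure N from the herd. A fraction ``rho`` of each
subunit's available N ends in harvested biomass; the remainder leaches.

Governing steady-state conservation equations::

    y_v = rho_v * (d + f_v + gamma * alpha * n_m / A_v)
    y_f = rho_f * (d + f_f + (1 - gamma) * alpha * n_m / A_f)
    n_m = beta * A_f * y_f

where ``y_v``, ``y_f`` are subunit N yields (kg N ha^-1 y^-1), ``n_m`` the
number of mother cows, ``gamma`` in [0, 1] the share of manure applied to
the vegetal subunit, ``alpha`` the plant-available manure N produced per
cow-year (one cow plus her associated animals), and ``beta`` the herd's
demand in cow-years per kg of forage N.

With ``gamma = 1`` (the default, and the human-food-optimal choice) the
system is triangular and solves sequentially; for ``gamma < 1`` the
forage--manure loop is a linear feedback that is solved in closed form and
must be subcritical: ``beta * rho_f * (1 - gamma) * alpha < 1``.

Units package-wide: kg N, ha, years, cow-years.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

from .errors import ConvergenceError, DivergentFeedbackError, ParameterError

__all__ = [
    "FarmGeometry",
    "NitrogenInputs",
    "CyclingCoefficients",
    "RetentionCurve",
    "NitrogenBudgetSolution",
    "solve_closed_form",
    "solve_general_gamma",
    "solve_fixed_point",
    "gamma_sweep",
    "eq_single_expression_yield_vegetal",
]

#: Default forage:vegetal area ratio, conserving the share of cropland used
#: for feed production in the present US food system.
FORAGE_TO_VEGETAL_RATIO = 3.0 / 7.0


@dataclass(frozen=True)
class FarmGeometry:
    """Areas of the two cropped subunits and the manure partition.

    Parameters
    ----------
    area_vegetal : float
        Vegetal (human plant food) subunit area, ha. Default 1.
    area_forage : float
        Forage subunit area, ha. Default 3/7 ha (the feed share of cropland
        in today's US system). May be 0 for all-vegetal scenarios.
    gamma : float
        Fraction of plant-available manure N applied to the vegetal subunit
        (the remainder goes to the forage subunit). In [0, 1]; default 1.
    """

    area_vegetal: float = 1.0
    area_forage: float = FORAGE_TO_VEGETAL_RATIO
    gamma: float = 1.0

    def __post_init__(self) -> None:
        if not self.area_vegetal > 0:
            raise ParameterError(f"area_vegetal must be > 0, got {self.area_vegetal}")
        if self.area_forage < 0:
            raise ParameterError(f"area_forage must be >= 0, got {self.area_forage}")
        if not 0.0 <= self.gamma <= 1.0:
            raise ParameterError(f"gamma must lie in [0, 1], got {self.gamma}")

    @property
    def total_area(self) -> float:
        return self.area_vegetal + self.area_forage


@dataclass(frozen=True)
class NitrogenInputs:
    """External reactive-N fluxes, kg N ha^-1 y^-1.

    ``deposition`` applies to both subunits; fixation is subunit-specific
    (legume shares differ between food rotations and forage stands).
    """

    deposition: float
    fixation_vegetal: float
    fixation_forage: float

    def __post_init__(self) -> None:
        for name in ("deposition", "fixation_vegetal", "fixation_forage"):
            v = getattr(self, name)
            if v < 0:
                raise ParameterError(f"{name} must be >= 0, got {v}")


@dataclass(frozen=True)
class CyclingCoefficients:
    """Herd-mediated N cycling efficiencies.

    alpha : plant-available manure N per cow-year, kg N cow^-1 y^-1,
        aggregated over one mother cow and her associated animals.
    beta : herd forage demand expressed as cow-years supported per kg of
        forage N, cow-y (kg N)^-1.
    """

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ParameterError(f"alpha must be >= 0, got {self.alpha}")
        if self.beta < 0:
            raise ParameterError(f"beta must be >= 0, got {self.beta}")


@dataclass(frozen=True)
class RetentionCurve:
    """Retention fraction rho as a function of available N, kg N ha^-1 y^-1.

    kind="constant": rho(N) = rho, requires ``rho`` in parameters.
    kind="saturating": rho(N) = rho_max * K / (K + N); the retained fraction
        falls (leached fraction grows) as the subunit is loaded with more N.
        Requires ``rho_max`` in (0, 1] and ``half_saturation`` K > 0.
    """

    kind: Literal["constant", "saturating"]
    parameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind == "constant":
            rho = self.parameters.get("rho")
            if rho is None or not 0.0 < rho <= 1.0:
                raise ParameterError(
                    f"constant retention requires rho in (0, 1], got {rho}"
                )
        elif self.kind == "saturating":
            rho_max = self.parameters.get("rho_max")
            k = self.parameters.get("half_saturation")
            if rho_max is None or not 0.0 < rho_max <= 1.0:
                raise ParameterError(
                    f"saturating retention requires rho_max in (0, 1], got {rho_max}"
                )
            if k is None or not k > 0:
                raise ParameterError(
                    f"saturating retention requires half_saturation > 0, got {k}"
                )
        else:
            raise ParameterError(f"unknown retention curve kind {self.kind!r}")

    def __call__(self, n_available: float) -> float:
        if n_available < 0:
            raise ParameterError(f"available N must be >= 0, got {n_available}")
        if self.kind == "constant":
            return float(self.parameters["rho"])
        k = self.parameters["half_saturation"]
        return float(self.parameters["rho_max"] * k / (k + n_available))

    @classmethod
    def constant(cls, rho: float) -> "RetentionCurve":
        return cls("constant", {"rho": rho})

    @classmethod
    def saturating(cls, rho_max: float, half_saturation: float) -> "RetentionCurve":
        return cls(
            "saturating", {"rho_max": rho_max, "half_saturation": half_saturation}
        )


@dataclass(frozen=True)
class NitrogenBudgetSolution:
    """Steady-state solution of the unit-farm nitrogen budget.

    ``flux_ledger`` itemizes, per subunit, the input fluxes (deposition,
    fixation, manure), the harvested yield, and the leached remainder, all
    in kg N ha^-1 y^-1. Conservation (inputs = yield + leached) holds
    exactly per subunit.
    """

    yield_vegetal: float
    yield_forage: float
    n_mother_cows: float
    leached_vegetal: float
    leached_forage: float
    rho_vegetal: float
    rho_forage: float
    flux_ledger: dict

    def conservation_residual(self) -> float:
        """Largest relative imbalance |inputs - yield - leached| per subunit."""
        worst = 0.0
        for sub in ("vegetal", "forage"):
            led = self.flux_ledger[sub]
            inputs = led["deposition"] + led["fixation"] + led["manure"]
            resid = abs(inputs - led["yield"] - led["leached"])
            scale = max(inputs, 1.0)
            worst = max(worst, resid / scale)
        return worst


def _validate_rho(name: str, rho: float) -> None:
    if not 0.0 < rho <= 1.0:
        raise ParameterError(f"{name} must lie in (0, 1], got {rho}")


def _assemble(
    geometry: FarmGeometry,
    inputs: NitrogenInputs,
    coeff: CyclingCoefficients,
    rho_v: float,
    rho_f: float,
    n_m: float,
) -> NitrogenBudgetSolution:
    """Build the full flux ledger given the solved herd size n_m."""
    g = geometry.gamma
    manure_v = g * coeff.alpha * n_m / geometry.area_vegetal
    if geometry.area_forage > 0:
        manure_f = (1.0 - g) * coeff.alpha * n_m / geometry.area_forage
        avail_f = inputs.deposition + inputs.fixation_forage + manure_f
    else:
        manure_f = 0.0
        avail_f = 0.0
    avail_v = inputs.deposition + inputs.fixation_vegetal + manure_v

    y_v = rho_v * avail_v
    y_f = rho_f * avail_f
    leach_v = avail_v - y_v
    leach_f = avail_f - y_f
    ledger = {
        "vegetal": {
            "deposition": inputs.deposition,
            "fixation": inputs.fixation_vegetal,
            "manure": manure_v,
            "yield": y_v,
            "leached": leach_v,
        },
        "forage": {
            "deposition": inputs.deposition if geometry.area_forage > 0 else 0.0,
            "fixation": inputs.fixation_forage if geometry.area_forage > 0 else 0.0,
            "manure": manure_f,
            "yield": y_f,
            "leached": leach_f,
        },
    }
    return NitrogenBudgetSolution(
        yield_vegetal=y_v,
        yield_forage=y_f,
        n_mother_cows=n_m,
        leached_vegetal=leach_v,
        leached_forage=leach_f,
        rho_vegetal=rho_v,
        rho_forage=rho_f,
        flux_ledger=ledger,
    )


def solve_general_gamma(
    geometry: FarmGeometry,
    inputs: NitrogenInputs,
    coeff: CyclingCoefficients,
    rho_v: float,
    rho_f: float,
) -> NitrogenBudgetSolution:
    """Solve the budget for any manure partition gamma in [0, 1].

    The manure returned to the forage subunit feeds back on forage yield and
    hence herd size. Substituting the herd equation into the forage equation
    gives the linear feedback

        n_m = beta * A_f * rho_f * (d + f_f) / (1 - beta*rho_f*(1-gamma)*alpha)

    which is finite only when the loop gain ``beta*rho_f*(1-gamma)*alpha``
    is below 1 (subcritical). Raises :class:`DivergentFeedbackError`
    otherwise.
    """
    _validate_rho("rho_v", rho_v)
    _validate_rho("rho_f", rho_f)

    if geometry.area_forage == 0:
        return _assemble(geometry, inputs, coeff, rho_v, rho_f, n_m=0.0)

    loop_gain = coeff.beta * rho_f * (1.0 - geometry.gamma) * coeff.alpha
    if loop_gain >= 1.0:
        raise DivergentFeedbackError(
            "divergent manure feedback: beta*rho_f*(1-gamma)*alpha = "
            f"{loop_gain:.6g} >= 1 (beta={coeff.beta:.6g}, rho_f={rho_f:.6g}, "
            f"gamma={geometry.gamma:.6g}, alpha={coeff.alpha:.6g})"
        )
    n_m = (
        coeff.beta
        * geometry.area_forage
        * rho_f
        * (inputs.deposition + inputs.fixation_forage)
        / (1.0 - loop_gain)
    )
    return _assemble(geometry, inputs, coeff, rho_v, rho_f, n_m)


def solve_closed_form(
    geometry: FarmGeometry,
    inputs: NitrogenInputs,
    coeff: CyclingCoefficients,
    rho_v: float,
    rho_f: float,
) -> NitrogenBudgetSolution:
    """Sequential solve for the default gamma = 1 (all manure to vegetal).

    With gamma = 1 the forage subunit receives no manure and the system is
    triangular:

        y_f = rho_f * (d + f_f)
        n_m = beta * A_f * y_f
        y_v = rho_v * (d + f_v + alpha * n_m / A_v)

    Rejects geometries with gamma != 1; use :func:`solve_general_gamma` for
    partial manure return to the forage subunit.
    """
    if geometry.gamma != 1.0:
        raise ParameterError(
            f"solve_closed_form requires gamma = 1, got gamma = {geometry.gamma}; "
            "use solve_general_gamma instead"
        )
    _validate_rho("rho_v", rho_v)
    _validate_rho("rho_f", rho_f)
    if geometry.area_forage == 0:
        return _assemble(geometry, inputs, coeff, rho_v, rho_f, n_m=0.0)
    y_f = rho_f * (inputs.deposition + inputs.fixation_forage)
    n_m = coeff.beta * geometry.area_forage * y_f
    return _assemble(geometry, inputs, coeff, rho_v, rho_f, n_m)


def eq_single_expression_yield_vegetal(
    geometry: FarmGeometry,
    inputs: NitrogenInputs,
    coeff: CyclingCoefficients,
    rho_v: float,
    rho_f: float,
) -> float:
    """Vegetal N yield from the single combined expression (gamma = 1):

        y_v = rho_v * [ (d + f_v) + alpha*beta*rho_f*(A_f/A_v)*(d + f_f) ]

    This is the direct substitution of the sequential equations into one
    line. Note: rho_v multiplies *both* terms; a variant that leaves the
    (d + f_v) term un-multiplied is inconsistent with the sequential system
    (see docs/methods.md) and is not implemented.
    """
    _validate_rho("rho_v", rho_v)
    _validate_rho("rho_f", rho_f)
    d = inputs.deposition
    return rho_v * (
        (d + inputs.fixation_vegetal)
        + coeff.alpha
        * coeff.beta
        * rho_f
        * (geometry.area_forage / geometry.area_vegetal)
        * (d + inputs.fixation_forage)
    )


def solve_fixed_point(
    geometry: FarmGeometry,
    inputs: NitrogenInputs,
    coeff: CyclingCoefficients,
    rho_v_curve: RetentionCurve,
    rho_f_curve: RetentionCurve,
    *,
    tol: float = 1e-10,
    max_iter: int = 1000,
    damping: float = 0.5,
) -> NitrogenBudgetSolution:
    """Solve the budget with retention fractions that depend on available N.

    Damped Picard iteration: evaluate each curve at the current subunit
    available-N, re-solve the constant-rho budget, update availabilities,
    repeat. ``damping`` blends old and new availabilities (0.5 by default),
    adequate for the monotone saturating curves used here. With constant
    curves the first solve is already exact.

    Raises :class:`ConvergenceError` (reporting the last relative residual)
    if the iteration cap is hit.
    """
    if not 0.0 < damping <= 1.0:
        raise ParameterError(f"damping must lie in (0, 1], got {damping}")

    # Start from the manure-free availabilities.
    avail_v = inputs.deposition + inputs.fixation_vegetal
    avail_f = (
        inputs.deposition + inputs.fixation_forage if geometry.area_forage > 0 else 0.0
    )
    solution = None
    for _ in range(max_iter):
        rho_v = rho_v_curve(avail_v)
        rho_f = rho_f_curve(avail_f)
        solution = solve_general_gamma(geometry, inputs, coeff, rho_v, rho_f)
        led = solution.flux_ledger
        new_v = sum(led["vegetal"][k] for k in ("deposition", "fixation", "manure"))
        new_f = sum(led["forage"][k] for k in ("deposition", "fixation", "manure"))
        resid = max(
            abs(new_v - avail_v) / max(avail_v, 1e-30),
            abs(new_f - avail_f) / max(avail_f, 1e-30) if avail_f > 0 or new_f > 0 else 0.0,
        )
        if resid <= tol:
            # Re-assemble once at the converged availabilities so the ledger
            # is exactly self-consistent with the evaluated rho values.
            return solution
        avail_v = (1.0 - damping) * avail_v + damping * new_v
        avail_f = (1.0 - damping) * avail_f + damping * new_f
    raise ConvergenceError(
        f"retention fixed point did not converge in {max_iter} iterations "
        f"(last relative residual {resid:.3e})"
    )


def gamma_sweep(
    geometry: FarmGeometry,
    inputs: NitrogenInputs,
    coeff: CyclingCoefficients,
    rho_v: float,
    rho_f: float,
    n_points: int = 11,
):
    """Human-food (vegetal) N yield versus the manure partition gamma.

    Evaluates :func:`solve_general_gamma` on a uniform gamma grid over
    [0, 1] including both endpoints, holding everything else fixed. Returns
    a pandas DataFrame with columns ``gamma``, ``yield_vegetal``,
    ``yield_forage``, ``n_mother_cows``.
    """
    import pandas as pd

    if n_points < 2:
        raise ParameterError(f"n_points must be >= 2, got {n_points}")
    rows = []
    for i in range(n_points):
        g = i / (n_points - 1)
        geom = FarmGeometry(geometry.area_vegetal, geometry.area_forage, gamma=g)
        sol = solve_general_gamma(geom, inputs, coeff, rho_v, rho_f)
        rows.append(
            {
                "gamma": g,
                "yield_vegetal": sol.yield_vegetal,
                "yield_forage": sol.yield_forage,
                "n_mother_cows": sol.n_mother_cows,
            }
        )
    return pd.DataFrame(rows)
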