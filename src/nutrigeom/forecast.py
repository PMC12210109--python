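"""Forward numerical model: how small leverage moves large amounts of energy.

Given leverage parameters (P, L), daily food intake on a diet whose
protein mass proportion is p is ``P * p**L`` grams. What that does to
*energy* intake depends on what replaces the removed protein:

* isocaloric mode — protein is exchanged for components of equal energy
  density (e.g. carbohydrate, or a 50:50 fat/cellulose mix), so the
  diet's kJ/g stays at a fixed reference density and energy intake
  changes only through the leverage response;
* fat_for_protein mode — protein is replaced gram-for-gram by fat,
  roughly doubling the energy density of the swapped mass, so the
  leverage response and the rising energy density compound.

The daily differences are then accumulated over an experiment horizon
(a 12-week trial is 84 days).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diets import DEFAULT_FACTORS, DietSpec, EnergyFactors, energy_density

__all__ = [
    "SubstitutionScenario",
    "ForecastResult",
    "predict_food_intake",
    "forecast",
    "cumulative_difference",
]


class ForecastError(ValueError):
    pass


def predict_food_intake(P: float, L: float, p) -> float | np.ndarray:
    """Daily food intake (g) from the leverage power law, P * p**L.

    ``p`` is the proportion of protein in the diet by mass, in (0, 1].
    At p = 1 the prediction is P by construction.
    """
    p_arr = np.asarray(p, dtype=float)
    if P <= 0:
        raise ForecastError(f"P must be > 0, got {P}")
    if np.any(p_arr <= 0) or np.any(p_arr > 1):
        raise ForecastError(f"protein proportion must lie in (0, 1], got {p!r}")
    out = P * p_arr**L
    return float(out) if np.isscalar(p) else out


def _default_p_grid() -> tuple[float, ...]:
    return tuple(np.geomspace(0.05, 0.60, 100))


@dataclass(frozen=True)
class SubstitutionScenario:
    """How dietary protein is exchanged along a grid of protein proportions.

    In fat_for_protein mode the reference composition is
    (1 - base_fat - base_carbohydrate) protein, base_fat fat and
    base_carbohydrate carbohydrate by mass; carbohydrate stays fixed and
    fat absorbs whatever protein mass is removed (or donates it back).
    """

    mode: str = "isocaloric"
    p_grid: tuple[float, ...] = field(default_factory=_default_p_grid)
    reference_density: float = 17.0  # kJ/g held fixed in isocaloric mode
    base_fat: float = 0.05
    base_carbohydrate: float = 0.70
    factors: EnergyFactors = DEFAULT_FACTORS

    def __post_init__(self) -> None:
        if self.mode not in ("isocaloric", "fat_for_protein"):
            raise ForecastError(f"unknown substitution mode {self.mode!r}")
        grid = np.asarray(self.p_grid, float)
        if grid.size == 0 or np.any(grid <= 0) or np.any(grid > 1):
            raise ForecastError("p_grid values must lie in (0, 1]")
        if self.mode == "isocaloric" and self.reference_density <= 0:
            raise ForecastError("reference_density must be positive")

    @property
    def reference_protein(self) -> float:
        return 1.0 - self.base_fat - self.base_carbohydrate

    def composition_at(self, p: float) -> DietSpec:
        """Diet composition at protein proportion p under fat-for-protein swap."""
        fat = self.base_fat + (self.reference_protein - p)
        if fat < -1e-12 or p + fat + self.base_carbohydrate > 1 + 1e-12:
            raise ForecastError(
                f"fat-for-protein composition leaves [0, 1] at p = {p:.4g} "
                f"(fat would be {fat:.4g})"
            )
        return DietSpec.from_caloric(
            diet_id=f"substitution-p{p:.4g}",
            study_id="forecast",
            frac_protein=p,
            frac_carbohydrate=self.base_carbohydrate,
            frac_fat=max(fat, 0.0),
        )


@dataclass
class ForecastResult:
    """Per-grid-point food intake, energy density and energy intake."""

    scenario: SubstitutionScenario
    P: float
    L: float
    table: pd.DataFrame  # columns p, food_g_per_day, energy_density_kj_g, energy_kj_per_day

    def at(self, p: float) -> pd.Series:
        match = np.isclose(self.table["p"], p, rtol=1e-9, atol=1e-12)
        if not match.any():
            raise ForecastError(f"p = {p!r} is not on the forecast grid")
        return self.table[match].iloc[0]


def forecast(scenario: SubstitutionScenario, P: float, L: float) -> ForecastResult:
    """Evaluate the leverage forward model along the scenario's protein grid."""
    p = np.asarray(scenario.p_grid, float)
    food = predict_food_intake(P, L, p)
    if scenario.mode == "isocaloric":
        density = np.full_like(p, scenario.reference_density)
    else:
        density = np.array(
            [energy_density(scenario.composition_at(pi), scenario.factors) for pi in p]
        )
    table = pd.DataFrame(
        {
            "p": p,
            "food_g_per_day": food,
            "energy_density_kj_g": density,
            "energy_kj_per_day": food * density,
        }
    )
    return ForecastResult(scenario=scenario, P=P, L=L, table=table)


def cumulative_difference(
    result: ForecastResult,
    p_hi: float,
    p_lo: float,
    days: int,
    printed_precision: bool = False,
) -> float:
    """Extra energy (kJ) eaten on the low- vs high-protein diet over a horizon.

    Returns ``(energy at p_lo - energy at p_hi) * days``. With
    ``printed_precision=True`` the two daily energies are first rounded
    to 0.1 kJ/day, reproducing tabulated arithmetic chains that quote
    rounded daily intakes before accumulating them.
    """
    if days < 0:
        raise ForecastError(f"days must be >= 0, got {days}")
    e_hi = float(result.at(p_hi)["energy_kj_per_day"])
    e_lo = float(result.at(p_lo)["energy_kj_per_day"])
    if printed_precision:
        e_hi, e_lo = round(e_hi, 1), round(e_lo, 1)
    return (e_lo - e_hi) * days
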