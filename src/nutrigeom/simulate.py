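"""Synthetic two-study mouse feeding trials with known leverage structure.

The generator emulates the geometry of two experimental designs:

* ``solonbiet25`` — 10 macronutrient ratios spanning protein 5–60%,
  fat 20–75% and carbohydrate 20–75% of energy, each realized at a total
  energy density of 17, 13 and (for five ratios) 8 kJ/g by dilution with
  nondigestible cellulose, giving 25 diets. Units default to cages of
  three same-sex animals.
* ``hu29`` — 29 diets in four series: series 1 and 2 span 5–30% protein
  energy at fixed 60% or 20% fat energy (carbohydrate the remainder);
  series 3 and 4 span 10–80% fat energy at 10% or 25% protein energy.
  Diets carry a fixed 9% noncaloric residual by mass (minerals,
  vitamins, fiber), which places the six series-2 diets plus the five
  lowest-fat series-3/4 diets inside a 15.9–18 kJ/g near-isocaloric
  band, 11 diets in all. Units are single-housed animals.

Intake follows the leverage power law: a unit on a diet whose protein
mass fraction is ``p`` is expected to eat ``P * p**L`` grams of food per
day (L = -1 is complete compensation for protein dilution, L = 0 none).
Noise is multiplicative lognormal with unit mean, so the expected intake
stays on the power curve; downstream fits assume additive residuals, and
that deliberate mismatch is part of the robustness the test suite
probes. A between-study elevation is imposed as an additive food-mass
offset calibrated so the mean energy-intake gap across the design equals
the configured kJ/day figure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .diets import DEFAULT_FACTORS, DietSpec, EnergyFactors, energy_density

__all__ = ["SimulationConfig", "make_design", "simulate_intake", "DESIGN_NAMES"]

DESIGN_NAMES = ("solonbiet25", "hu29")

# energy-share triples (protein, carbohydrate, fat), an even spread of the
# stated ranges: protein 5-60%, carbohydrate 20-75%, fat 20-75% of energy
_SOLONBIET_TRIPLES = [
    (0.05, 0.20, 0.75),
    (0.05, 0.475, 0.475),
    (0.05, 0.75, 0.20),
    (0.15, 0.25, 0.60),
    (0.15, 0.60, 0.25),
    (0.25, 0.25, 0.50),
    (0.25, 0.50, 0.25),
    (0.40, 0.20, 0.40),
    (0.40, 0.40, 0.20),
    (0.60, 0.20, 0.20),
]
_SOLONBIET_TIERS = {17.0: range(10), 13.0: range(10), 8.0: range(0, 10, 2)}

_HU_RESIDUAL = 0.09  # noncaloric mass fraction in every hu29 diet


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class SimulationConfig:
    """Ground-truth parameters for one simulated feeding study.

    true_P is the daily food intake (g) a unit would show on a
    pure-protein diet; true_L the leverage exponent in [-1, 0]; noise_cv
    the coefficient of variation of the multiplicative intake noise;
    study_offset_kj an additive between-study energy-intake elevation
    (kJ/day) applied as the equivalent food-mass offset.
    """

    true_P: float = 3.15
    true_L: float = -0.07
    noise_cv: float = 0.10
    n_per_diet: int = 10
    study_offset_kj: float = 0.0
    seed: int = 0
    design_name: str = "solonbiet25"

    def __post_init__(self) -> None:
        if self.true_P <= 0:
            raise SimulationError(f"true_P must be > 0, got {self.true_P}")
        if not -1.0 <= self.true_L <= 0.0:
            raise SimulationError(f"true_L must lie in [-1, 0], got {self.true_L}")
        if self.noise_cv < 0:
            raise SimulationError(f"noise_cv must be >= 0, got {self.noise_cv}")
        if self.n_per_diet < 1:
            raise SimulationError(f"n_per_diet must be >= 1, got {self.n_per_diet}")

    def to_dict(self) -> dict:
        return {
            "true_P": self.true_P,
            "true_L": self.true_L,
            "noise_cv": self.noise_cv,
            "n_per_diet": self.n_per_diet,
            "study_offset_kj": self.study_offset_kj,
            "seed": self.seed,
            "design_name": self.design_name,
        }


def _energy_shares_to_mass(
    e_protein: float,
    e_carb: float,
    e_fat: float,
    caloric_mass: float,
    factors: EnergyFactors,
) -> tuple[float, float, float, float]:
    """Convert energy shares + caloric mass budget to mass fractions.

    The caloric components occupy ``caloric_mass`` grams per gram of
    diet in proportion to share/factor; the remainder is noncaloric.
    """
    w = np.array(
        [
            e_protein / factors.protein_kj_per_g,
            e_carb / factors.carbohydrate_kj_per_g,
            e_fat / factors.fat_kj_per_g,
        ]
    )
    w = caloric_mass * w / w.sum()
    return float(w[0]), float(w[1]), float(w[2]), 1.0 - float(w.sum())


def _solonbiet_design(factors: EnergyFactors) -> list[DietSpec]:
    diets = []
    for dens, idx in _SOLONBIET_TIERS.items():
        for i in idx:
            ep, ec, ef = _SOLONBIET_TRIPLES[i]
            # mass of each caloric component per gram of diet at target density
            mp = ep * dens / factors.protein_kj_per_g
            mc = ec * dens / factors.carbohydrate_kj_per_g
            mf = ef * dens / factors.fat_kj_per_g
            caloric = mp + mc + mf
            if caloric > 1 + 1e-9:
                raise SimulationError(
                    f"composition {i} unreachable at {dens} kJ/g with given factors"
                )
            diets.append(
                DietSpec(
                    diet_id=f"SB-{i + 1:02d}-{dens:g}kJ",
                    study_id="solonbiet",
                    series=f"{dens:g}kJ",
                    frac_protein=mp,
                    frac_carbohydrate=mc,
                    frac_fat=mf,
                    frac_cellulose=1.0 - caloric,
                )
            )
    return diets


def _hu_design(factors: EnergyFactors) -> list[DietSpec]:
    diets = []

    def add(series: str, e_protein: float, e_fat: float, label: str) -> None:
        e_carb = 1.0 - e_protein - e_fat
        mp, mc, mf, resid = _energy_shares_to_mass(
            e_protein, e_carb, e_fat, 1.0 - _HU_RESIDUAL, factors
        )
        diets.append(
            DietSpec(
                diet_id=f"HU-{series}-{label}",
                study_id="hu",
                series=series,
                frac_protein=mp,
                frac_carbohydrate=mc,
                frac_fat=mf,
                frac_cellulose=resid,
            )
        )

    protein_grid = np.linspace(0.05, 0.30, 6)
    for ep in protein_grid:  # series 1: fat fixed at 60% energy
        add("series1", float(ep), 0.60, f"P{100 * ep:02.0f}")
    for ep in protein_grid:  # series 2: fat fixed at 20% energy
        add("series2", float(ep), 0.20, f"P{100 * ep:02.0f}")
    for ef in np.linspace(0.10, 0.80, 10):  # series 3: protein fixed at 10% energy
        add("series3", 0.10, float(ef), f"F{100 * ef:04.1f}")
    # series 4: protein fixed at 25% energy; fat tops out at 70% so that
    # carbohydrate keeps a positive energy share (25% + 80% would exceed 1)
    for ef in np.linspace(0.10, 0.70, 7):
        add("series4", 0.25, float(ef), f"F{100 * ef:04.1f}")
    return diets


def make_design(
    name: str, factors: EnergyFactors = DEFAULT_FACTORS
) -> list[DietSpec]:
    """Construct one of the named diet designs as a list of DietSpec."""
    if name == "solonbiet25":
        return _solonbiet_design(factors)
    if name == "hu29":
        return _hu_design(factors)
    raise SimulationError(f"unknown design {name!r}; expected one of {DESIGN_NAMES}")


def simulate_intake(
    design: Sequence[DietSpec],
    cfg: SimulationConfig,
    factors: EnergyFactors = DEFAULT_FACTORS,
    study_id: str | None = None,
) -> pd.DataFrame:
    """Simulate per-unit mean daily intakes on every diet of a design.

    Returns a table with columns unit_id, diet_id, study_id, sex,
    strain, food_intake_g, energy_intake_kj. Identical config (including
    seed) gives identical output. Units are cages of three for
    Solon-Biet-style designs and single animals otherwise; intakes are
    per-animal daily means either way.
    """
    design = list(design)
    if not design:
        raise SimulationError("design is empty")
    p = np.array([d.frac_protein for d in design])
    if cfg.true_L != 0.0 and np.any(p <= 0):
        bad = [d.diet_id for d, pi in zip(design, p) if pi <= 0]
        raise SimulationError(
            f"power law undefined at zero protein for L != 0; offending diets: {bad}"
        )
    dens = np.array([energy_density(d, factors) for d in design])
    mu = cfg.true_P * np.where(p > 0, p, 1.0) ** cfg.true_L

    # additive food-mass offset reproducing the configured mean energy gap
    offset_g = cfg.study_offset_kj / dens.mean() if cfg.study_offset_kj else 0.0

    rng = np.random.default_rng(cfg.seed)
    if cfg.noise_cv > 0:
        sigma = np.sqrt(np.log1p(cfg.noise_cv**2))
        noise = rng.lognormal(-(sigma**2) / 2.0, sigma, size=(len(design), cfg.n_per_diet))
    else:
        noise = np.ones((len(design), cfg.n_per_diet))

    caged = all(d.study_id.startswith("solonbiet") for d in design)
    unit_prefix = "cage" if caged else "mouse"
    label = study_id or design[0].study_id

    rows = []
    unit = 0
    for i, d in enumerate(design):
        for j in range(cfg.n_per_diet):
            food = mu[i] * noise[i, j] + offset_g
            rows.append(
                {
                    "unit_id": f"{unit_prefix}_{unit:04d}",
                    "diet_id": d.diet_id,
                    "study_id": label,
                    "sex": ("F", "M")[j % 2],
                    "strain": "C57BL/6",
                    "food_intake_g": food,
                    "energy_intake_kj": food * dens[i],
                }
            )
            unit += 1
    return pd.DataFrame(rows)
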