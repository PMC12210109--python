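"""Mixture algebra for experimental diets.

A diet is described by its composition *by mass*: fractions of protein,
digestible carbohydrate, fat, and a noncaloric diluent class (cellulose).
Everything else — energy density (kJ/g), percentage of energy from each
macronutrient, and the protein / nonprotein energy axes used by the
response-surface models — is derived from the mass fractions and a set of
energy conversion factors. Percent-energy quantities are never stored
independently, so the two representations cannot drift apart.

The default conversion factors (protein = carbohydrate = 16.7 kJ/g,
fat = 37.7 kJ/g, cellulose = 0) are the unique solution of the two
worked diet densities used in the leverage forecast (a 25% protein / 5%
fat / 70% carbohydrate diet at 17.75 kJ/g and a 10/20/70 diet at
20.9 kJ/g); they encode the premise that fat is roughly twice as energy
dense as protein or carbohydrate while cellulose is nondigestible.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EnergyFactors",
    "DEFAULT_FACTORS",
    "DietSpec",
    "DietDerived",
    "CollinearityReport",
    "energy_density",
    "percent_energy",
    "derive_composition",
    "near_isocaloric_subset",
    "design_collinearity",
    "diets_to_frame",
    "read_diet_table",
    "write_diet_table",
]

_MASS_TOL = 1e-9


class DietValidationError(ValueError):
    """Raised when a diet specification or energy factor set is invalid."""


@dataclass(frozen=True)
class EnergyFactors:
    """Metabolizable energy density of each component class, in kJ/g."""

    protein_kj_per_g: float = 16.7
    carbohydrate_kj_per_g: float = 16.7
    fat_kj_per_g: float = 37.7
    cellulose_kj_per_g: float = 0.0

    def __post_init__(self) -> None:
        vals = (
            self.protein_kj_per_g,
            self.carbohydrate_kj_per_g,
            self.fat_kj_per_g,
            self.cellulose_kj_per_g,
        )
        if any(v < 0 for v in vals):
            raise DietValidationError(f"energy factors must be >= 0, got {vals}")
        if not self.fat_kj_per_g > self.protein_kj_per_g:
            raise DietValidationError(
                "fat energy factor must exceed the protein factor "
                f"(got fat={self.fat_kj_per_g}, protein={self.protein_kj_per_g})"
            )

    def as_array(self) -> np.ndarray:
        return np.array(
            [
                self.protein_kj_per_g,
                self.carbohydrate_kj_per_g,
                self.fat_kj_per_g,
                self.cellulose_kj_per_g,
            ]
        )


DEFAULT_FACTORS = EnergyFactors()


@dataclass(frozen=True)
class DietSpec:
    """One diet's composition by mass. Fractions must close to 1."""

    diet_id: str
    study_id: str
    frac_protein: float
    frac_carbohydrate: float
    frac_fat: float
    frac_cellulose: float
    series: str | None = None

    def __post_init__(self) -> None:
        fracs = self.mass_fractions
        if any(f < -_MASS_TOL or f > 1 + _MASS_TOL for f in fracs):
            raise DietValidationError(
                f"diet {self.diet_id!r}: mass fractions must lie in [0, 1], got {fracs}"
            )
        total = sum(fracs)
        if abs(total - 1.0) > 1e-9:
            raise DietValidationError(
                f"diet {self.diet_id!r}: mass fractions sum to {total!r}, not 1"
            )

    @property
    def mass_fractions(self) -> tuple[float, float, float, float]:
        return (
            self.frac_protein,
            self.frac_carbohydrate,
            self.frac_fat,
            self.frac_cellulose,
        )

    @classmethod
    def from_caloric(
        cls,
        diet_id: str,
        study_id: str,
        frac_protein: float,
        frac_carbohydrate: float,
        frac_fat: float,
        series: str | None = None,
    ) -> "DietSpec":
        """Build a diet from caloric-component fractions; cellulose absorbs the residual."""
        resid = 1.0 - (frac_protein + frac_carbohydrate + frac_fat)
        if resid < -_MASS_TOL:
            raise DietValidationError(
                f"diet {diet_id!r}: caloric fractions sum above 1 ({1 - resid:.6f})"
            )
        return cls(
            diet_id=diet_id,
            study_id=study_id,
            frac_protein=frac_protein,
            frac_carbohydrate=frac_carbohydrate,
            frac_fat=frac_fat,
            frac_cellulose=max(resid, 0.0),
            series=series,
        )


@dataclass(frozen=True)
class DietDerived:
    """Energy quantities derived from a DietSpec under given factors."""

    diet_id: str
    energy_density: float  # kJ per g of diet
    pct_energy_protein: float  # fraction of total energy
    pct_energy_carbohydrate: float
    pct_energy_fat: float
    protein_energy_axis: float  # protein kJ per g of diet
    nonprotein_energy_axis: float  # carbohydrate + fat kJ per g of diet


def energy_density(diet: DietSpec, factors: EnergyFactors = DEFAULT_FACTORS) -> float:
    """Total metabolizable energy per gram of diet, Σ fraction × factor."""
    return float(np.dot(diet.mass_fractions, factors.as_array()))


def percent_energy(diet: DietSpec, factors: EnergyFactors = DEFAULT_FACTORS) -> DietDerived:
    """Derive % energy from each macronutrient and the protein/nonprotein axes.

    Raises if the diet carries no energy (all-cellulose under a zero
    cellulose factor), since energy fractions are then undefined.
    """
    dens = energy_density(diet, factors)
    if dens <= 0:
        raise DietValidationError(
            f"diet {diet.diet_id!r} has zero energy density; % energy is undefined"
        )
    e_protein = diet.frac_protein * factors.protein_kj_per_g
    e_carb = diet.frac_carbohydrate * factors.carbohydrate_kj_per_g
    e_fat = diet.frac_fat * factors.fat_kj_per_g
    return DietDerived(
        diet_id=diet.diet_id,
        energy_density=dens,
        pct_energy_protein=e_protein / dens,
        pct_energy_carbohydrate=e_carb / dens,
        pct_energy_fat=e_fat / dens,
        protein_energy_axis=e_protein,
        nonprotein_energy_axis=e_carb + e_fat,
    )


_COMPONENT_CLASSES = ("protein", "carbohydrate", "fat", "cellulose", "other")


def derive_composition(
    ingredients: Sequence[tuple[float, str]],
    factors: EnergyFactors = DEFAULT_FACTORS,
    diet_id: str = "derived",
    study_id: str = "derived",
    series: str | None = None,
) -> DietSpec:
    """Recompute a diet's mass fractions from an ingredient list.

    Each ingredient is a ``(mass_g, component_class)`` pair with class in
    {protein, carbohydrate, fat, cellulose, other}. Mass labelled "other"
    (minerals, vitamins, moisture) is folded into the noncaloric residual
    alongside cellulose. Fractions are normalized to total ingredient
    mass, so the result is invariant to rescaling the recipe.
    """
    if not ingredients:
        raise DietValidationError("ingredient list is empty")
    unknown = sorted({c for _, c in ingredients} - set(_COMPONENT_CLASSES))
    if unknown:
        raise DietValidationError(
            f"unmapped component class(es): {unknown}; expected one of {_COMPONENT_CLASSES}"
        )
    masses = {c: 0.0 for c in _COMPONENT_CLASSES}
    for mass, cls in ingredients:
        if mass < 0:
            raise DietValidationError(f"negative ingredient mass {mass} ({cls})")
        masses[cls] += mass
    total = sum(masses.values())
    if total <= 0:
        raise DietValidationError("total ingredient mass must be positive")
    return DietSpec(
        diet_id=diet_id,
        study_id=study_id,
        series=series,
        frac_protein=masses["protein"] / total,
        frac_carbohydrate=masses["carbohydrate"] / total,
        frac_fat=masses["fat"] / total,
        frac_cellulose=(masses["cellulose"] + masses["other"]) / total,
    )


def near_isocaloric_subset(
    design: Iterable[DietSpec],
    lo: float,
    hi: float,
    factors: EnergyFactors = DEFAULT_FACTORS,
) -> list[DietSpec]:
    """Diets whose energy density lies in the closed band [lo, hi] kJ/g."""
    if lo > hi:
        raise DietValidationError(f"invalid band: lo={lo} > hi={hi}")
    tol = 1e-9  # tolerate float noise at the stated endpoints
    return [d for d in design if lo - tol <= energy_density(d, factors) <= hi + tol]


@dataclass
class CollinearityReport:
    """Pairwise Pearson correlations of diet-design axes, with confound flags."""

    matrix: pd.DataFrame
    threshold: float
    flagged: list[tuple[str, str, float]] = field(default_factory=list)
    undefined: list[tuple[str, str]] = field(default_factory=list)

    def is_confounded(self, a: str, b: str) -> bool:
        return any({a, b} == {x, y} for x, y, _ in self.flagged)


def design_collinearity(
    design: Sequence[DietSpec],
    factors: EnergyFactors = DEFAULT_FACTORS,
    threshold: float = 0.9,
) -> CollinearityReport:
    """Diagnose which diet-design axes covary and cannot be separated.

    Mixture designs inevitably entangle some axes: e.g. when fat (twice
    the kJ/g of the other macronutrients) is the manipulated component,
    % energy from fat and total energy density covary almost perfectly,
    so their effects cannot be distinguished by any model fit on that
    design. Pairs with |r| above ``threshold`` are flagged as
    non-separable. Constant columns yield undefined correlations, which
    are recorded (not silently propagated as NaN into the flags).
    """
    if len(design) < 3:
        raise DietValidationError("need at least 3 diets for collinearity diagnostics")
    rows = []
    for d in design:
        der = percent_energy(d, factors)
        rows.append(
            {
                "pct_energy_protein": der.pct_energy_protein,
                "pct_energy_fat": der.pct_energy_fat,
                "pct_energy_nonprotein": der.pct_energy_carbohydrate + der.pct_energy_fat,
                "energy_density": der.energy_density,
                "frac_cellulose": d.frac_cellulose,
            }
        )
    df = pd.DataFrame(rows)
    cols = list(df.columns)
    mat = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    flagged: list[tuple[str, str, float]] = []
    undefined: list[tuple[str, str]] = []
    for a, b in itertools.combinations(cols, 2):
        sa, sb = df[a].std(ddof=0), df[b].std(ddof=0)
        if sa == 0 or sb == 0:
            mat.loc[a, b] = mat.loc[b, a] = np.nan
            undefined.append((a, b))
            continue
        r = float(np.corrcoef(df[a], df[b])[0, 1])
        mat.loc[a, b] = mat.loc[b, a] = r
        if abs(r) > threshold:
            flagged.append((a, b, r))
    return CollinearityReport(matrix=mat, threshold=threshold, flagged=flagged, undefined=undefined)


# ---------------------------------------------------------------------------
# tabular IO

_BASE_COLUMNS = [
    "diet_id",
    "study_id",
    "series",
    "frac_protein",
    "frac_carbohydrate",
    "frac_fat",
    "frac_cellulose",
]


def diets_to_frame(
    design: Sequence[DietSpec],
    factors: EnergyFactors | None = DEFAULT_FACTORS,
) -> pd.DataFrame:
    """Diet table as a DataFrame; derived energy columns appended when factors given."""
    df = pd.DataFrame(
        [
            {
                "diet_id": d.diet_id,
                "study_id": d.study_id,
                "series": d.series,
                "frac_protein": d.frac_protein,
                "frac_carbohydrate": d.frac_carbohydrate,
                "frac_fat": d.frac_fat,
                "frac_cellulose": d.frac_cellulose,
            }
            for d in design
        ],
        columns=_BASE_COLUMNS,
    )
    if factors is not None:
        derived = [percent_energy(d, factors) for d in design]
        for fld in (
            "energy_density",
            "pct_energy_protein",
            "pct_energy_carbohydrate",
            "pct_energy_fat",
            "protein_energy_axis",
            "nonprotein_energy_axis",
        ):
            df[fld] = [getattr(x, fld) for x in derived]
    return df


def write_diet_table(
    design: Sequence[DietSpec],
    path: str | Path,
    factors: EnergyFactors | None = DEFAULT_FACTORS,
) -> None:
    diets_to_frame(design, factors).to_csv(path, index=False)


def read_diet_table(path: str | Path) -> list[DietSpec]:
    """Read a diet table CSV (derived columns, if present, are ignored)."""
    df = pd.read_csv(path)
    missing = [c for c in _BASE_COLUMNS if c != "series" and c not in df.columns]
    if missing:
        raise DietValidationError(f"diet table {path} missing columns: {missing}")
    out = []
    for _, row in df.iterrows():
        series = row.get("series")
        if isinstance(series, float) and np.isnan(series):
            series = None
        out.append(
            DietSpec(
                diet_id=str(row["diet_id"]),
                study_id=str(row["study_id"]),
                series=None if series is None else str(series),
                frac_protein=float(row["frac_protein"]),
                frac_carbohydrate=float(row["frac_carbohydrate"]),
                frac_fat=float(row["frac_fat"]),
                frac_cellulose=float(row["frac_cellulose"]),
            )
        )
    return out
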