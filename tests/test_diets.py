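"""Diet mixture algebra: energy conversion, derived axes, subsetting, collinearity."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from nutrigeom import (
    DEFAULT_FACTORS,
    DietSpec,
    EnergyFactors,
    derive_composition,
    design_collinearity,
    diets_to_frame,
    energy_density,
    near_isocaloric_subset,
    percent_energy,
    read_diet_table,
    write_diet_table,
)
from nutrigeom.diets import DietValidationError


def diet(p, c, f, diet_id="d"):
    return DietSpec.from_caloric(diet_id, "test", p, c, f)


class TestEnergyDensity:
    @pytest.mark.parametrize(
        "p,c,f,expected",
        [
            (0.25, 0.70, 0.05, 17.75),  # the 25% protein worked diet
            (0.10, 0.70, 0.20, 20.90),  # the 10% protein, fat-substituted diet
            (0.0, 0.0, 0.0, 0.0),  # pure cellulose carries no energy
        ],
    )
    def test_worked_examples(self, p, c, f, expected):
        assert energy_density(diet(p, c, f)) == pytest.approx(expected, abs=1e-9)

    def test_default_factors_solve_the_two_worked_diets(self):
        # independent linear solve of the two density equations:
        # 0.95x + 0.05y = 17.75 and 0.80x + 0.20y = 20.9
        A = np.array([[0.95, 0.05], [0.80, 0.20]])
        b = np.array([17.75, 20.9])
        assert np.linalg.matrix_rank(A) == 2  # the solution is unique
        x, y = np.linalg.solve(A, b)
        assert x == pytest.approx(DEFAULT_FACTORS.protein_kj_per_g, abs=1e-9)
        assert x == pytest.approx(DEFAULT_FACTORS.carbohydrate_kj_per_g, abs=1e-9)
        assert y == pytest.approx(DEFAULT_FACTORS.fat_kj_per_g, abs=1e-9)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(DietValidationError):
            DietSpec("bad", "s", -0.1, 0.6, 0.3, 0.2)
        with pytest.raises(DietValidationError):
            DietSpec("bad", "s", 0.5, 0.5, 0.5, 0.0)  # fractions exceed closure
        with pytest.raises(DietValidationError):
            EnergyFactors(protein_kj_per_g=-1.0)
        with pytest.raises(DietValidationError):
            EnergyFactors(fat_kj_per_g=10.0)  # fat must out-dense protein


class TestPercentEnergy:
    def test_equal_factors_symmetry(self):
        d = diet(0.5, 0.5, 0.0)
        assert percent_energy(d).pct_energy_protein == pytest.approx(0.5)

    def test_fat_energy_share_worked_diet(self):
        der = percent_energy(diet(0.25, 0.70, 0.05))
        assert der.pct_energy_fat == pytest.approx(0.05 * 37.7 / 17.75, rel=1e-12)

    @given(
        p=st.floats(0.01, 0.6),
        c=st.floats(0.01, 0.39),
        f=st.floats(0.01, 0.39),
    )
    def test_axes_additivity_for_cellulose_free_diets(self, p, c, f):
        total = p + c + f
        d = diet(p / total, c / total, f / total)
        der = percent_energy(d)
        assert der.protein_energy_axis + der.nonprotein_energy_axis == pytest.approx(
            der.energy_density, rel=1e-12
        )
        assert (
            der.pct_energy_protein + der.pct_energy_carbohydrate + der.pct_energy_fat
        ) == pytest.approx(1.0, rel=1e-12)

    def test_zero_energy_diet_is_undefined(self):
        with pytest.raises(DietValidationError, match="undefined"):
            percent_energy(diet(0, 0, 0))


class TestSubstitutionConsistency:
    def test_protein_for_carbohydrate_swap_is_energy_neutral(self):
        base = diet(0.25, 0.70, 0.05)
        swapped = diet(0.10, 0.85, 0.05)
        assert energy_density(base) == pytest.approx(energy_density(swapped), abs=1e-12)

    def test_protein_for_fat_swap_raises_density_by_factor_gap(self):
        base = diet(0.25, 0.70, 0.05)
        swapped = diet(0.10, 0.70, 0.20)
        gap = (DEFAULT_FACTORS.fat_kj_per_g - DEFAULT_FACTORS.protein_kj_per_g) * 0.15
        assert energy_density(swapped) - energy_density(base) == pytest.approx(gap, abs=1e-12)


class TestDeriveComposition:
    def test_two_component_mixture(self):
        d = derive_composition([(100.0, "protein"), (100.0, "carbohydrate")])
        assert d.frac_protein == pytest.approx(0.5)

    def test_round_trip_with_percent_energy(self):
        direct = diet(0.2, 0.5, 0.1)
        derived = derive_composition(
            [(20.0, "protein"), (50.0, "carbohydrate"), (10.0, "fat"), (20.0, "cellulose")]
        )
        a, b = percent_energy(direct), percent_energy(derived)
        assert a.pct_energy_protein == pytest.approx(b.pct_energy_protein, rel=1e-12)
        assert a.energy_density == pytest.approx(b.energy_density, rel=1e-12)

    def test_three_ingredient_recipe_against_hand_ledger(self):
        # ledger by hand: 180 g protein-class + 540 g carb-class + 80 g fat-class
        # + 200 g other = 1000 g -> fractions 0.18 / 0.54 / 0.08 / 0.20
        d = derive_composition(
            [(180.0, "protein"), (540.0, "carbohydrate"), (80.0, "fat"), (200.0, "other")]
        )
        assert d.mass_fractions == pytest.approx((0.18, 0.54, 0.08, 0.20), rel=1e-12)

    def test_unmapped_class_is_named_in_error(self):
        with pytest.raises(DietValidationError, match="sucrose"):
            derive_composition([(10.0, "sucrose")])

    @given(scale=st.floats(1e-3, 1e3))
    def test_scale_invariance(self, scale):
        recipe = [(30.0, "protein"), (50.0, "carbohydrate"), (20.0, "fat")]
        scaled = [(m * scale, c) for m, c in recipe]
        a = derive_composition(recipe)
        b = derive_composition(scaled)
        assert a.mass_fractions == pytest.approx(b.mass_fractions, rel=1e-9)


class TestNearIsocaloricSubset:
    def test_hu_band_contains_eleven_diets(self, hu_design):
        band = near_isocaloric_subset(hu_design, 15.9, 18.0)
        assert len(band) == 11
        series = sorted(d.series for d in band)
        assert series.count("series2") == 6  # plus five lower-energy series-3/4 diets
        assert all(15.9 <= energy_density(d) <= 18.0 for d in band)

    def test_point_band_selects_the_17_kj_tier(self, solonbiet_design):
        tier = near_isocaloric_subset(solonbiet_design, 17.0, 17.0)
        assert len(tier) == 10
        assert all(energy_density(d) == pytest.approx(17.0) for d in tier)

    def test_band_above_design_is_empty(self, hu_design):
        assert near_isocaloric_subset(hu_design, 100.0, 200.0) == []

    def test_inverted_band_rejected(self, hu_design):
        with pytest.raises(DietValidationError):
            near_isocaloric_subset(hu_design, 18.0, 15.9)


class TestDesignCollinearity:
    def test_fat_manipulation_ties_fat_share_to_density(self, hu_design):
        fat_series = [d for d in hu_design if d.series in ("series3", "series4")]
        rep = design_collinearity(fat_series)
        assert rep.matrix.loc["pct_energy_fat", "energy_density"] > 0.95
        assert rep.is_confounded("pct_energy_fat", "energy_density")

    def test_cellulose_dilution_series_has_exact_anticorrelation(self):
        dilutions = [
            DietSpec(f"dil{i}", "s", 0.2 * s, 0.5 * s, 0.1 * s, 1 - 0.8 * s)
            for i, s in enumerate((1.0, 0.75, 0.5))
        ]
        rep = design_collinearity(dilutions)
        assert rep.matrix.loc["energy_density", "frac_cellulose"] == pytest.approx(-1.0)
        # the macronutrient mix is fixed, so every % energy column is constant
        assert ("pct_energy_protein", "pct_energy_fat") in rep.undefined

    def test_matrix_symmetric_with_unit_diagonal(self, solonbiet_design):
        m = design_collinearity(solonbiet_design).matrix
        assert np.allclose(m.to_numpy(), m.to_numpy().T, equal_nan=True)
        assert np.allclose(np.diag(m.to_numpy()), 1.0)

    def test_too_small_design_rejected(self, solonbiet_design):
        with pytest.raises(DietValidationError):
            design_collinearity(solonbiet_design[:2])


class TestDesignTables:
    def test_mass_closure_of_generated_designs(self, solonbiet_design, hu_design):
        for d in solonbiet_design + hu_design:
            assert sum(d.mass_fractions) == pytest.approx(1.0, abs=1e-9)

    def test_csv_round_trip(self, tmp_path, hu_design):
        path = tmp_path / "diets.csv"
        write_diet_table(hu_design, path)
        again = read_diet_table(path)
        assert diets_to_frame(again).equals(
            diets_to_frame(hu_design)
        ) or np.allclose(
            diets_to_frame(again).select_dtypes("number"),
            diets_to_frame(hu_design).select_dtypes("number"),
        )
        assert [d.diet_id for d in again] == [d.diet_id for d in hu_design]

    def test_export_appends_derived_columns(self, tmp_path, tier17):
        path = tmp_path / "diets.csv"
        write_diet_table(tier17, path)
        df = pd.read_csv(path)
        assert "energy_density" in df.columns
        assert df["energy_density"].round(9).eq(17.0).all()
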