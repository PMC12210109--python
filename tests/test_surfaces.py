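"""Penalized bivariate intake surfaces: nulls, masking, topology, groups, oracle."""

import os
import subprocess
import tempfile

import numpy as np
import pytest

from nutrigeom import (
    SimulationConfig,
    diets_to_frame,
    fit_surface,
    fit_surface_by_group,
    simulate_intake,
    surface_summary,
)
from nutrigeom.surfaces import CollinearAxesError, SurfaceError


def _merge_axes(obs, design):
    cols = ["diet_id", "protein_energy_axis", "nonprotein_energy_axis"]
    return obs.merge(diets_to_frame(design)[cols], on="diet_id")


class TestNullSurface:
    def test_noiseless_flat_data_give_flat_surface(self, solonbiet_design, noiseless_obs):
        obs = noiseless_obs(solonbiet_design, true_L=0.0, true_P=3.0, n_per_diet=2)
        fit = fit_surface(obs, solonbiet_design, response="food")
        assert fit.smooth_edf < 0.01
        assert fit.p_smooth > 0.5
        vals = fit.grid.loc[fit.grid["in_hull"], "fitted"]
        assert vals.max() - vals.min() < 1e-6
        summ = surface_summary(fit)
        assert summ["range"] < 1e-6

    def test_fitted_residuals_average_to_zero(self, solonbiet_design):
        cfg = SimulationConfig(noise_cv=0.1, n_per_diet=5, seed=2)
        obs = simulate_intake(solonbiet_design, cfg)
        fit = fit_surface(obs, solonbiet_design, response="food")
        df = _merge_axes(obs, solonbiet_design)
        resid = df["food_intake_g"].to_numpy() - fit.predict(
            df["protein_energy_axis"].to_numpy(), df["nonprotein_energy_axis"].to_numpy()
        )
        assert abs(resid.mean()) < 1e-8


class TestMasking:
    def test_no_fitted_values_beyond_hull_resolution(self, solonbiet_design):
        import scipy.spatial

        cfg = SimulationConfig(noise_cv=0.1, n_per_diet=3, seed=4)
        obs = simulate_intake(solonbiet_design, cfg)
        fit = fit_surface(obs, solonbiet_design, grid_size=37)
        grid = fit.grid
        assert grid.loc[~grid["in_hull"], "fitted"].isna().all()
        assert grid.loc[grid["in_hull"], "fitted"].notna().all()
        # masked-in cells lie within half a lattice cell of the design hull
        df = _merge_axes(obs, solonbiet_design)
        pts = np.unique(
            np.round(df[["protein_energy_axis", "nonprotein_energy_axis"]].to_numpy(), 9), axis=0
        )
        hull = scipy.spatial.ConvexHull(pts)
        inhull = grid[grid["in_hull"]]
        dist = np.max(
            inhull[["x", "z"]].to_numpy() @ hull.equations[:, :2].T + hull.equations[:, 2],
            axis=1,
        )
        gx, gz = np.sort(grid["x"].unique()), np.sort(grid["z"].unique())
        half_cell = 0.5 * np.hypot(gx[1] - gx[0], gz[1] - gz[0])
        assert (dist <= half_cell + 1e-9).all()


class TestPreconditions:
    def test_collinear_axes_refused_with_confound_message(self, hu_design):
        series3 = [d for d in hu_design if d.series == "series3"]
        obs = simulate_intake(series3, SimulationConfig(noise_cv=0.1, n_per_diet=3, seed=1))
        with pytest.raises(CollinearAxesError, match="energy density"):
            fit_surface(obs, series3, response="food")

    def test_too_few_design_points_refused(self, tier17):
        few = tier17[:4]
        obs = simulate_intake(few, SimulationConfig(noise_cv=0.1, n_per_diet=3, seed=1))
        with pytest.raises(SurfaceError, match="design points"):
            fit_surface(obs, few)


class TestTopology:
    def test_leverage_surface_topography(self, solonbiet_design):
        cfg = SimulationConfig(true_L=-0.07, noise_cv=0.10, n_per_diet=20, seed=5)
        obs = simulate_intake(solonbiet_design, cfg)
        food = surface_summary(fit_surface(obs, solonbiet_design, response="food"))
        energy = surface_summary(fit_surface(obs, solonbiet_design, response="energy"))
        g = fit_surface(obs, solonbiet_design).grid
        g = g[g["in_hull"]]
        xlo, xspan = g["x"].min(), g["x"].max() - g["x"].min()
        zlo, zspan = g["z"].min(), g["z"].max() - g["z"].min()

        def norm(cell):
            return (cell["x"] - xlo) / xspan, (cell["z"] - zlo) / zspan

        fx, fz = norm(food["argmax"])
        assert fx < 0.2 and fz < 2 / 3  # food intake peaks at low protein, low nonprotein
        ex, ez = norm(energy["argmax"])
        assert ex < 0.2 and ez > 0.8  # energy intake peaks at low protein, high nonprotein
        # and the minimum of food intake sits at the protein-rich end
        mx, _ = norm(food["argmin"])
        assert mx > 0.5


class TestGroupedFits:
    def test_identical_groups_give_identical_surfaces(self, tier17, solonbiet_design):
        obs = simulate_intake(solonbiet_design, SimulationConfig(noise_cv=0.1, n_per_diet=4, seed=8))
        a = obs.assign(strain="X")
        b = obs.assign(strain="Y")
        both = __import__("pandas").concat([a, b], ignore_index=True)
        fits = fit_surface_by_group(both, solonbiet_design, group="strain")
        assert len(fits) == 2
        assert np.allclose(fits[0].grid["fitted"], fits[1].grid["fitted"], equal_nan=True)
        assert fits[0].scale == fits[1].scale

    def test_additive_offset_shifts_beta0_not_shape(self, solonbiet_design):
        base = simulate_intake(
            solonbiet_design, SimulationConfig(noise_cv=0.10, n_per_diet=50, seed=12), study_id="A"
        )
        lifted = simulate_intake(
            solonbiet_design,
            SimulationConfig(noise_cv=0.10, n_per_diet=50, seed=13, study_offset_kj=28.0),
            study_id="B",
        )
        both = __import__("pandas").concat([base, lifted], ignore_index=True)
        fits = {f.group: f for f in fit_surface_by_group(both, solonbiet_design, response="energy", group="study")}
        diff = fits["B"].beta0 - fits["A"].beta0
        assert diff == pytest.approx(28.0, abs=3.0)  # up to smoothing/sampling noise
        shape_a = fits["A"].grid["fitted"] - fits["A"].beta0
        shape_b = fits["B"].grid["fitted"] - fits["B"].beta0
        mask = fits["A"].grid["in_hull"]
        corr = np.corrcoef(shape_a[mask], shape_b[mask])[0, 1]
        assert corr > 0.95

    def test_single_group_matches_plain_fit(self, solonbiet_design):
        obs = simulate_intake(solonbiet_design, SimulationConfig(noise_cv=0.1, n_per_diet=4, seed=8))
        plain = fit_surface(obs, solonbiet_design)
        grouped = fit_surface_by_group(obs, solonbiet_design, group="study")
        assert len(grouped) == 1
        assert np.allclose(grouped[0].grid["fitted"], plain.grid["fitted"], equal_nan=True)

    def test_failing_group_is_skipped(self, hu_design):
        import pandas as pd

        ok = simulate_intake(hu_design, SimulationConfig(noise_cv=0.1, n_per_diet=3, seed=1))
        series3 = [d for d in hu_design if d.series == "series3"]
        bad = simulate_intake(series3, SimulationConfig(noise_cv=0.1, n_per_diet=3, seed=2)).assign(
            strain="collinear"
        )
        fits = fit_surface_by_group(pd.concat([ok, bad], ignore_index=True), hu_design, group="strain")
        assert [f.group for f in fits] == ["C57BL/6"]


class TestAgainstMgcv:
    def test_fitted_surface_matches_mgcv_thin_plate_gam(self, solonbiet_design):
        """Independent oracle: R mgcv's gam(y ~ s(x, z)) on the same data."""
        cfg = SimulationConfig(noise_cv=0.1, n_per_diet=10, seed=7)
        obs = simulate_intake(solonbiet_design, cfg)
        fit = fit_surface(obs, solonbiet_design, response="food", k=12)
        df = _merge_axes(obs, solonbiet_design).rename(
            columns={"protein_energy_axis": "x", "nonprotein_energy_axis": "z", "food_intake_g": "y"}
        )
        with tempfile.TemporaryDirectory() as td:
            fcsv, fout = os.path.join(td, "d.csv"), os.path.join(td, "out.csv")
            df[["x", "z", "y"]].to_csv(fcsv, index=False)
            script = (
                "library(mgcv); "
                f"d <- read.csv('{fcsv}'); "
                "m <- gam(y ~ s(x, z, k=12), data=d, method='GCV.Cp'); "
                "write.csv(data.frame(fit=fitted(m), p=summary(m)$s.pv[1]), "
                f"'{fout}', row.names=FALSE)"
            )
            proc = subprocess.run(
                ["Rscript", "-e", script], capture_output=True, text=True, timeout=300
            )
            assert proc.returncode == 0, proc.stderr
            ref = __import__("pandas").read_csv(fout)
        mine = fit.predict(df["x"].to_numpy(), df["z"].to_numpy())
        assert np.corrcoef(mine, ref["fit"])[0, 1] > 0.99
        rel_rmse = np.sqrt(np.mean((mine - ref["fit"]) ** 2)) / df["y"].std()
        assert rel_rmse < 0.05
        assert fit.p_smooth < 1e-6 and ref["p"][0] < 1e-6
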