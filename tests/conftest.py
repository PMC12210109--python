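import pytest

from nutrigeom import SimulationConfig, make_design, near_isocaloric_subset, simulate_intake


@pytest.fixture(scope="session")
def solonbiet_design():
    return make_design("solonbiet25")


@pytest.fixture(scope="session")
def hu_design():
    return make_design("hu29")


@pytest.fixture(scope="session")
def tier17(solonbiet_design):
    """The ten 17 kJ/g diets of the Solon-Biet-style design."""
    return near_isocaloric_subset(solonbiet_design, 17.0, 17.0)


@pytest.fixture(scope="session")
def hu_band(hu_design):
    """The 11 near-isocaloric (15.9-18 kJ/g) diets of the Hu-style design."""
    return near_isocaloric_subset(hu_design, 15.9, 18.0)


@pytest.fixture
def noiseless_obs():
    """Factory: deterministic intake table for a design under given (P, L)."""

    def _make(design, true_P=3.15, true_L=-0.07, n_per_diet=1, **kwargs):
        cfg = SimulationConfig(
            true_P=true_P, true_L=true_L, noise_cv=0.0, n_per_diet=n_per_diet, seed=0, **kwargs
        )
        return simulate_intake(design, cfg)

    return _make
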