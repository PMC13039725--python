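import numpy as np
import pandas as pd
import pytest

import betafutures as bf
from betafutures.community import SitePairTable


@pytest.fixture(scope="session")
def landscape():
    """Default 20x20 synthetic landscape."""
    return bf.generate_landscape(bf.LandscapeSpec(grid_dims=(20, 20), seed=11))


@pytest.fixture(scope="session")
def filled_landscape(landscape):
    env = landscape.copy()
    env.data["soil_ph"] = bf.idw_fill(env.data["soil_ph"])
    return env


@pytest.fixture(scope="session")
def communities(filled_landscape):
    from betafutures.synthetic import default_niches

    niches = default_niches(filled_landscape, n_species=80, seed=7)
    return bf.generate_communities(filled_landscape, niches, n_years=3, seed=7)


@pytest.fixture(scope="session")
def single_predictor_pairs():
    """1000 pairs simulated from eta = 1.2 * I_2(x), noise sd 0.02."""
    rng = np.random.default_rng(42)
    basis = bf.SplineBasisDef(knots=(0.0, 0.5, 1.0))
    n = 1000
    x1, x2 = rng.uniform(0, 1, n), rng.uniform(0, 1, n)
    i1 = bf.ispline_basis(x1, basis)
    i2 = bf.ispline_basis(x2, basis)
    eta = 1.2 * np.abs(i1[:, 1] - i2[:, 1])
    d = np.clip(1 - np.exp(-eta) + rng.normal(0, 0.02, n), 0.0, 1.0)
    frame = pd.DataFrame(
        {
            "site_i": np.arange(n),
            "site_j": np.arange(n) + n,
            "distance": d,
            "weight": 1.0,
            "s1.v": x1,
            "s2.v": x2,
        }
    )
    return SitePairTable(table=frame, predictors=["v"])


@pytest.fixture(scope="session")
def fitted_community_gdm(filled_landscape, communities):
    """GDM fitted to the synthetic communities on the default landscape."""
    from betafutures.community import build_site_pair_table, site_coverages

    coverages = site_coverages(communities, n_years=3)
    assemblages = {int(s): communities.assemblage(int(s)) for s in communities.sites}
    env_frame = pd.DataFrame(
        {
            v: filled_landscape.data[v].ravel()[communities.sites]
            for v in filled_landscape.variables
        },
        index=pd.Index(communities.sites, name="site_id"),
    )
    pairs = build_site_pair_table(assemblages, env_frame, coverages,
                                  max_pairs=3000, seed=5)
    model = bf.fit_gdm(pairs)
    return model, pairs


@pytest.fixture(scope="session")
def predicts_data():
    return bf.generate_predicts_like(n_studies=30, seed=19)


@pytest.fixture(scope="session")
def small_transformed(filled_landscape, fitted_community_gdm):
    """Current and shifted-future transformed grids for metric tests."""
    model, _ = fitted_community_gdm
    current = bf.gdm_transform(model, filled_landscape)
    scenario = bf.ScenarioSpec(
        name="test",
        climate_shift_severity={"tmin_annual": 0.5, "tmax_annual": 0.5,
                                "precip_annual": -30.0},
    )
    future_env = bf.generate_future_climate(filled_landscape, scenario, (2060, 2080))
    future = bf.gdm_transform(model, future_env)
    return model, current, future
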