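"""Shared fixtures: a small synthetic panel (2 countries per region) keeps
unit tests fast; model-fitting fixtures are session-scoped."""

import pytest

import heatburden as hb

SMALL_SIZES = {r: 2 for r in hb.REGIONS}


@pytest.fixture(scope="session")
def catalog():
    return hb.default_catalog()


@pytest.fixture(scope="session")
def pathway(catalog):
    return hb.default_pathway(catalog)


@pytest.fixture(scope="session")
def small_panel(catalog, pathway):
    """14 countries x 10 years, linear structural truth, seed 11."""
    model = hb.default_structural_model(catalog, pathway)
    panel, truth = hb.generate_panel(
        catalog, pathway, model, n_countries=14, region_sizes=SMALL_SIZES, seed=11
    )
    return panel, truth


@pytest.fixture(scope="session")
def small_normalized(small_panel):
    panel, truth = small_panel
    params = hb.fit_minmax(panel)
    return hb.apply_minmax(panel, params), params, truth


@pytest.fixture(scope="session")
def small_linear_model(small_normalized):
    normalized, params, _ = small_normalized
    train, test = hb.split_train_test(normalized, 0.7, seed=7)
    model = hb.fit(hb.PredictorSpec("linear_regression"), train)
    return model, train, test


@pytest.fixture(scope="session")
def template(catalog):
    return hb.InterventionSchedule(tuple(catalog.interventions))
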