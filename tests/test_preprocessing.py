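"""Missingness rules, imputation, min-max rescaling, splitting."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import heatburden as hb


def _panel(catalog, data: dict[str, list], countries=None, years=None):
    """Toy panel: data maps variable -> per-(country, year) values."""
    countries = countries or ["A"]
    years = years or list(range(2010, 2010 + len(next(iter(data.values()))) // len(countries)))
    frame = pd.DataFrame({
        "country": np.repeat(countries, len(years)),
        "year": years * len(countries),
    })
    for v in catalog.names:
        frame[v] = data.get(v, 1.0)
    mapping = {c: hb.REGIONS[i % 7] for i, c in enumerate(countries)}
    return hb.PanelDataset(frame, catalog, hb.RegionMap(mapping))


class TestMissingness:
    def test_fractions(self, catalog):
        series = [1.0, np.nan, 3.0, 4.0, 5.0, 6.0, 7.0, np.nan, 9.0, 10.0]
        panel = _panel(catalog, {"fertilizer_use": series})
        prof = hb.missingness(panel)
        assert prof.fraction("A", "fertilizer_use") == pytest.approx(0.2)
        assert prof.fraction("A", "sanitation") == 0.0

    def test_all_missing_is_one(self, catalog):
        panel = _panel(catalog, {"fertilizer_use": [np.nan] * 10})
        assert hb.missingness(panel).fraction("A", "fertilizer_use") == 1.0


class TestExclusion:
    def _two_country(self, catalog, frac_missing_b):
        years = list(range(2010, 2020))
        series_b = [np.nan] * int(frac_missing_b * 10) + [1.0] * (10 - int(frac_missing_b * 10))
        panel = _panel(
            catalog,
            {"fertilizer_use": [1.0] * 10 + series_b},
            countries=["A", "B"], years=years,
        )
        return panel

    def test_over_threshold_dropped(self, catalog):
        panel = self._two_country(catalog, 0.2)
        kept, dropped = hb.exclude_countries(panel, threshold=0.15)
        assert dropped == ["B"]
        assert kept.countries == ["A"]

    def test_complete_country_retained(self, catalog):
        panel = self._two_country(catalog, 0.1)
        kept, dropped = hb.exclude_countries(panel, threshold=0.15)
        assert dropped == []

    def test_threshold_one_keeps_partial_but_drops_outcomeless(self, catalog):
        panel = self._two_country(catalog, 0.9)
        panel.frame.loc[panel.frame["country"] == "B", hb.TOTAL_BURDEN] = np.nan
        kept, dropped = hb.exclude_countries(panel, threshold=1.0)
        assert dropped == ["B"]  # only for lacking the outcome entirely

    def test_monotone_in_threshold(self, catalog):
        rng = np.random.default_rng(5)
        years = list(range(2010, 2020))
        countries = [f"C{i}" for i in range(8)]
        values = [1.0 if rng.random() > 0.2 else np.nan
                  for _ in range(len(countries) * 10)]
        panel = _panel(catalog, {"fertilizer_use": values},
                       countries=countries, years=years)
        prev_kept: set[str] | None = None
        for thr in (0.05, 0.15, 0.35, 0.75, 1.0):
            try:
                kept, _ = hb.exclude_countries(panel, threshold=thr,
                                               require_outcome=False)
                now = set(kept.countries)
            except ValueError:  # a strict threshold may drop every country
                now = set()
            if prev_kept is not None:
                assert prev_kept <= now
            prev_kept = now

    def test_no_survivors_raises(self, catalog):
        panel = self._two_country(catalog, 0.0)
        panel.frame["fertilizer_use"] = np.nan
        with pytest.raises(ValueError, match="no countries"):
            hb.exclude_countries(panel, threshold=0.15)


class TestImpute:
    def test_interior_gap_interpolated(self, catalog):
        panel = _panel(catalog, {"fertilizer_use": [1.0, np.nan, 3.0]},
                       years=[2010, 2011, 2012])
        imputed, log = hb.impute(panel)
        assert imputed.frame["fertilizer_use"].tolist() == [1.0, 2.0, 3.0]
        assert log["method"].tolist() == ["linear_interpolation"]

    def test_boundary_gap_gets_country_mean(self, catalog):
        panel = _panel(catalog, {"fertilizer_use": [np.nan, 4.0, 6.0]},
                       years=[2010, 2011, 2012])
        imputed, log = hb.impute(panel)
        assert imputed.frame["fertilizer_use"].tolist() == [5.0, 4.0, 6.0]
        assert log["method"].tolist() == ["country_mean"]

    def test_complete_series_untouched(self, catalog):
        panel = _panel(catalog, {"fertilizer_use": [2.0, 9.0, 4.0]},
                       years=[2010, 2011, 2012])
        imputed, log = hb.impute(panel)
        assert imputed.frame["fertilizer_use"].tolist() == [2.0, 9.0, 4.0]
        assert log.empty

    def test_region_mean_fallback(self, catalog):
        years = [2010, 2011]
        panel = _panel(catalog, {"fertilizer_use": [np.nan, 6.0, 4.0, 8.0]},
                       countries=["A", "B"], years=years)
        # A and B must share a region for the region mean to be defined
        panel.region_map = hb.RegionMap({"A": hb.REGIONS[0], "B": hb.REGIONS[0]})
        imputed, log = hb.impute(panel, fallback="region")
        # leading gap of A <- region mean of observed values (6, 4, 8) = 6
        assert imputed.frame.loc[imputed.frame["country"] == "A",
                                 "fertilizer_use"].tolist() == [6.0, 6.0]
        assert set(log["method"]) == {"region_mean"}

    def test_all_missing_raises(self, catalog):
        panel = _panel(catalog, {"fertilizer_use": [np.nan, np.nan, np.nan]},
                       years=[2010, 2011, 2012])
        with pytest.raises(ValueError, match="all-missing"):
            hb.impute(panel)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        slope=st.floats(-5, 5, allow_nan=False),
        intercept=st.floats(-10, 10, allow_nan=False),
        gaps=st.sets(st.integers(1, 8), max_size=6),
    )
    def test_interpolation_exact_on_linear_series(self, slope, intercept, gaps):
        """Linear-in-year series with interior gaps are recovered exactly."""
        catalog = hb.default_catalog()
        years = list(range(2010, 2020))
        truth = [intercept + slope * (y - 2010) for y in years]
        observed = [np.nan if i in gaps else truth[i] for i in range(10)]
        panel = _panel(catalog, {"fertilizer_use": observed}, years=years)
        imputed, _ = hb.impute(panel)
        np.testing.assert_allclose(
            imputed.frame["fertilizer_use"].to_numpy(), truth, atol=1e-9
        )

    def test_observed_cells_never_change(self, small_panel):
        panel, _ = small_panel
        corrupted, _ = hb.inject_missingness(panel, 0.1, 0.05, seed=3)
        imputed, _ = hb.impute(corrupted)
        mask = corrupted.frame.notna()
        for col in panel.catalog.names:
            before = corrupted.frame.loc[mask[col], col]
            after = imputed.frame.loc[mask[col], col]
            pd.testing.assert_series_equal(before, after)
        assert not imputed.frame[panel.catalog.names].isna().any().any()


class TestMinMax:
    def test_fit(self, catalog):
        panel = _panel(catalog, {"fertilizer_use": [2.0, 4.0, 6.0]},
                       years=[2010, 2011, 2012])
        params = hb.fit_minmax(panel, ["fertilizer_use", "sanitation"])
        assert params.params["fertilizer_use"] == (2.0, 6.0)
        assert "sanitation" in params.degenerate  # constant column flagged
        assert len(params.params) == 2

    def test_apply_and_clip(self, catalog):
        panel = _panel(catalog, {"fertilizer_use": [2.0, 4.0, 6.0]},
                       years=[2010, 2011, 2012])
        params = hb.fit_minmax(panel, ["fertilizer_use"])
        normalized = hb.apply_minmax(panel, params)
        assert normalized.frame["fertilizer_use"].tolist() == [0.0, 0.5, 1.0]
        assert normalized.normalized
        out_of_range = _panel(catalog, {"fertilizer_use": [8.0]}, years=[2010])
        clipped = hb.apply_minmax(out_of_range, params)
        assert clipped.frame["fertilizer_use"].tolist() == [1.0]

    def test_degenerate_maps_to_zero(self, catalog):
        panel = _panel(catalog, {"fertilizer_use": [5.0, 5.0]}, years=[2010, 2011])
        params = hb.fit_minmax(panel, ["fertilizer_use"])
        normalized = hb.apply_minmax(panel, params)
        assert normalized.frame["fertilizer_use"].tolist() == [0.0, 0.0]

    def test_roundtrip_identity(self, small_panel):
        panel, _ = small_panel
        params = hb.fit_minmax(panel)
        back = hb.invert_minmax(hb.apply_minmax(panel, params), params)
        for v in params.params:
            np.testing.assert_allclose(back.frame[v], panel.frame[v], rtol=1e-10)

    def test_final_outcome_not_normalized(self, small_panel):
        panel, _ = small_panel
        params = hb.fit_minmax(panel)
        assert hb.TOTAL_BURDEN not in params
        normalized = hb.apply_minmax(panel, params)
        pd.testing.assert_series_equal(normalized.frame[hb.TOTAL_BURDEN],
                                       panel.frame[hb.TOTAL_BURDEN])

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-1e6, 1e6), min_size=2, max_size=20))
    def test_output_in_unit_interval_and_monotone(self, values):
        catalog = hb.default_catalog()
        panel = _panel(catalog, {"fertilizer_use": values},
                       years=list(range(2010, 2010 + len(values))))
        params = hb.fit_minmax(panel, ["fertilizer_use"])
        out = hb.apply_minmax(panel, params).frame["fertilizer_use"].to_numpy()
        assert ((out >= 0) & (out <= 1)).all()
        order = np.argsort(values, kind="stable")
        assert (np.diff(out[order]) >= -1e-12).all()

    def test_unknown_variable_raises(self, catalog):
        panel = _panel(catalog, {}, years=[2010])
        params = hb.NormalizationParams({"not_a_variable": (0.0, 1.0)})
        with pytest.raises(KeyError):
            hb.apply_minmax(panel, params)

    def test_json_roundtrip(self, small_panel, tmp_path):
        panel, _ = small_panel
        params = hb.fit_minmax(panel)
        params.to_json(tmp_path / "p.json")
        loaded = hb.NormalizationParams.from_json(tmp_path / "p.json")
        assert loaded.params == params.params


class TestSplit:
    def test_row_split_sizes(self, small_panel):
        panel, _ = small_panel  # 140 rows
        train, test = hb.split_train_test(panel, 0.7, seed=1)
        assert (train.n_rows, test.n_rows) == (98, 42)

    def test_930_rows_become_651_279(self, catalog, pathway):
        model = hb.default_structural_model(catalog, pathway)
        panel, _ = hb.generate_panel(catalog, pathway, model, seed=0)
        train, test = hb.split_train_test(panel, 0.7, seed=1)
        assert (train.n_rows, test.n_rows) == (651, 279)

    def test_country_split(self, small_panel):
        panel, _ = small_panel  # 14 countries
        train, test = hb.split_train_test(panel, 0.7, unit="country", seed=1)
        assert len(train.countries) == 9  # floor(14 * 0.7)
        assert set(train.countries).isdisjoint(test.countries)

    def test_deterministic_and_exhaustive(self, small_panel):
        panel, _ = small_panel
        a = hb.split_train_test(panel, 0.7, seed=42)
        b = hb.split_train_test(panel, 0.7, seed=42)
        pd.testing.assert_frame_equal(a[0].frame, b[0].frame)
        combined = len(a[0].frame) + len(a[1].frame)
        assert combined == panel.n_rows

    def test_seed_mandatory(self, small_panel):
        panel, _ = small_panel
        with pytest.raises(ValueError, match="seed"):
            hb.split_train_test(panel, 0.7)
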