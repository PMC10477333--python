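"""Surrogate pool model: modifiers, mass balance, equilibrium, simulation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cropcarb as cc
from cropcarb.soc_model import (
    NoEquilibriumError,
    _annual_c_input,
    c_to_co2e,
    sg_gapfill,
)


class TestModifiers:
    def test_reference_temperature_gives_unity(self, default_params):
        m_t, _, _ = cc.decomp_modifiers(default_params.t_ref, 0.5, "NT", default_params)
        assert m_t == pytest.approx(1.0)

    def test_q10_doubling(self):
        p = cc.ModelParams(q10=2.0, t_cap=4.0)
        m_t, _, _ = cc.decomp_modifiers(p.t_ref + 10.0, 0.5, "NT", p)
        assert m_t == pytest.approx(2.0)

    def test_temperature_response_monotone_below_cap(self, default_params):
        temps = np.linspace(0.0, 35.0, 50)
        m = np.array([cc.decomp_modifiers(t, 0.5, "NT", default_params)[0] for t in temps])
        below = m < default_params.t_cap
        assert np.all(np.diff(m[below]) > 0)

    def test_moisture_half_saturation(self, default_params):
        _, m_w, _ = cc.decomp_modifiers(10.0, default_params.w_half, "NT", default_params)
        assert m_w == pytest.approx(0.5)

    def test_invalid_moisture_rejected(self, default_params):
        with pytest.raises(ValueError):
            cc.decomp_modifiers(10.0, 1.5, "NT", default_params)

    def test_tillage_ordering(self, default_params):
        ms = [cc.decomp_modifiers(10.0, 0.5, t, default_params)[2] for t in ("NT", "RT", "FT")]
        assert ms[0] <= ms[1] <= ms[2]


class TestStepPools:
    def test_zero_input_zero_rates_is_identity(self):
        p = cc.ModelParams(k_active=1e-12, k_slow=1e-13, k_passive=1e-14)
        state = np.array([10.0, 20.0, 30.0])
        new, resp = cc.step_pools(state, 0.0, (1.0, 0.5, 1.0), p)
        np.testing.assert_allclose(new, state, rtol=1e-10)
        assert resp == pytest.approx(0.0, abs=1e-10)

    @given(
        active=st.floats(0.1, 50), slow=st.floats(0.1, 100), passive=st.floats(0.1, 100),
        inp=st.floats(0, 0.1), mt=st.floats(0.1, 2.0), mw=st.floats(0.05, 1.0),
        clay=st.floats(0.0, 0.6),
    )
    @settings(max_examples=200, deadline=None)
    def test_mass_balance_property(self, active, slow, passive, inp, mt, mw, clay):
        """Conservation: d(total) = input - respired, exactly."""
        p = cc.ModelParams()
        state = np.array([active, slow, passive])
        new, resp = cc.step_pools(state, inp, (mt, mw, 1.3), p, clay_frac=clay)
        total = state.sum()
        assert abs((new.sum() - total) - (inp - resp)) <= 1e-9 * max(1.0, total)

    def test_single_pool_exponential_decay(self):
        # all decayed flux respired; 1 year of daily steps vs exp(-k t)
        p = cc.ModelParams(k_active=0.1, k_slow=0.01, k_passive=0.001,
                           resp_active=1.0, resp_slow=1.0, resp_passive=1.0,
                           a2p_base=0.0, a2p_clay=0.0, s2p_base=0.0, s2p_clay=0.0)
        state = np.array([10.0, 0.0, 0.0])
        for _ in range(365):
            state, _ = cc.step_pools(state, 0.0, (1.0, 1.0, 1.0), p,
                                     clay_frac=0.0)
        # moisture modifier at full saturation: w/(w+w_half) < 1, so feed m=1
        # via mt=1/mw factor is avoided by using modifiers (1, 1, 1) directly
        assert state[0] == pytest.approx(10.0 * np.exp(-0.1), rel=1.5e-3)

    def test_negative_input_rejected(self, default_params):
        with pytest.raises(ValueError):
            cc.step_pools(np.array([1.0, 1.0, 1.0]), -0.1, (1.0, 0.5, 1.0), default_params)

    def test_unstable_step_raises(self):
        p = cc.ModelParams(k_active=7.3)
        with pytest.raises(cc.soc_model.NumericalInstabilityError):
            cc.step_pools(np.array([10.0, 1.0, 1.0]), 0.0, (2.0, 1.0, 1.3), p,
                          dt_days=400.0)


class TestEquilibrium:
    def test_single_pool_input_over_k(self):
        p = cc.ModelParams(k_active=0.5, k_slow=0.01, k_passive=0.001,
                           resp_active=1.0, resp_slow=1.0, resp_passive=1.0,
                           a2p_base=0.0, a2p_clay=0.0, s2p_base=0.0, s2p_clay=0.0)
        x = cc.solve_equilibrium(p, (p.t_ref, 1.0, "NT"), 1.0, clay_frac=0.0)
        m_w = 1.0 / (1.0 + p.w_half)
        assert x[0] == pytest.approx(1.0 / (0.5 * m_w), rel=1e-6)

    def test_analytic_matches_6000yr_spinup(self, default_params):
        x_solve = cc.solve_equilibrium(default_params, (12.0, 0.5, "NT"), 3.0, 0.25)
        x_spin = cc.spin_up(default_params, (12.0, 0.5, "NT"), 3.0, 0.25, years=6000)
        assert np.max(np.abs(x_solve - x_spin) / x_solve) < 5e-3

    def test_equilibrium_linear_in_input(self, default_params):
        x1 = cc.solve_equilibrium(default_params, (10.0, 0.4, "FT"), 2.0, 0.2)
        x2 = cc.solve_equilibrium(default_params, (10.0, 0.4, "FT"), 4.0, 0.2)
        np.testing.assert_allclose(x2, 2.0 * x1, rtol=1e-10)

    def test_higher_decomposition_never_raises_equilibrium(self, default_params):
        base = cc.solve_equilibrium(default_params, (12.0, 0.5, "NT"), 3.0, 0.2).sum()
        hotter = cc.solve_equilibrium(default_params, (18.0, 0.5, "NT"), 3.0, 0.2).sum()
        tilled = cc.solve_equilibrium(default_params, (12.0, 0.5, "FT"), 3.0, 0.2).sum()
        assert hotter <= base and tilled <= base


class TestSimulateLocation:
    def test_steady_history_keeps_stocks_flat(self, default_params):
        frame = cc.generate_frame(5, total_area=1e4, n_replicates=3, seed=7)
        weather = cc.generate_weather(frame, seed=7, temp_noise_sd=0.0)
        # grass/NT forever at the native input reproduces the equilibrium regime
        import pandas as pd
        years = np.arange(1979, 2016)
        rows = []
        for lid in frame.table.location_id:
            for y in years:
                rows.append({"location_id": lid, "year": y, "crop": "grass",
                             "tillage": "NT", "fert_n": 0.0, "manure_n": 0.0,
                             "cover_crop": False, "termination": "none",
                             "irrigated": False, "set_aside": False})
        hist = pd.DataFrame(rows)
        p = cc.ModelParams(
            crop_c_input={**default_params.crop_c_input, "grass": default_params.native_c_input}
        )
        batch = cc.simulate_batch(frame, weather, hist, p)
        # base-history cultivation perturbs pools, but late-series drift is small
        assert np.abs(batch.delta[:, -10:]).mean() < 0.5

    def test_no_till_never_below_full_till(self, small_frame, small_weather, default_params):
        import pandas as pd
        years = np.arange(1979, 2016)
        lids = small_frame.table.location_id.tolist()[:10]
        def hist(till):
            return pd.DataFrame([
                {"location_id": lid, "year": y, "crop": "corn", "tillage": till,
                 "fert_n": 120.0, "manure_n": 0.0, "cover_crop": False,
                 "termination": "none", "irrigated": False, "set_aside": False}
                for lid in lids for y in years
            ])
        nt = cc.simulate_batch(small_frame, small_weather, hist("NT"), default_params, location_ids=lids)
        ft = cc.simulate_batch(small_frame, small_weather, hist("FT"), default_params, location_ids=lids)
        assert np.all(nt.soc >= ft.soc - 1e-9)

    def test_tillage_termination_gains_less_than_herbicide(self, small_frame, small_weather, default_params):
        import pandas as pd
        years = np.arange(1979, 2016)
        lids = small_frame.table.location_id.tolist()[:10]
        def hist(term):
            return pd.DataFrame([
                {"location_id": lid, "year": y, "crop": "corn", "tillage": "NT",
                 "fert_n": 120.0, "manure_n": 0.0, "cover_crop": y >= 1995,
                 "termination": term if y >= 1995 else "none",
                 "irrigated": False, "set_aside": False}
                for lid in lids for y in years
            ])
        till = cc.simulate_batch(small_frame, small_weather, hist("tillage"), default_params, location_ids=lids)
        herb = cc.simulate_batch(small_frame, small_weather, hist("herbicide"), default_params, location_ids=lids)
        assert herb.soc[:, -1].mean() > till.soc[:, -1].mean()

    def test_missing_history_year_rejected(self, small_frame, small_weather, small_truth, default_params):
        broken = small_truth[small_truth.year != 1999]
        with pytest.raises(ValueError, match="missing"):
            cc.simulate_batch(small_frame, small_weather, broken, default_params)

    def test_practice_contrast_rates_in_plausible_band(self, small_batch):
        # order-of-magnitude guard on simulated annual stock changes
        assert np.abs(small_batch.delta).mean() < 1.0


class TestSGGapfill:
    def test_quadratic_reconstructed_exactly(self):
        x = np.arange(60, dtype=float)
        y = 0.02 * x**2 - 0.5 * x + 3.0
        gappy = y.copy()
        gappy[np.arange(60) % 8 != 0] = np.nan
        filled = sg_gapfill(gappy, window=33, poly_order=2)
        np.testing.assert_allclose(filled, y, rtol=1e-9, atol=1e-9)

    def test_constant_series_stays_constant(self):
        y = np.full(50, 4.2)
        gappy = y.copy()
        gappy[1::3] = np.nan
        filled = sg_gapfill(gappy, window=9, poly_order=2)
        np.testing.assert_allclose(filled, y)

    def test_observed_entries_preserved(self):
        rng = np.random.default_rng(0)
        y = np.sin(np.linspace(0, 6, 80)) + rng.normal(0, 0.1, 80)
        gappy = y.copy()
        gappy[::5] = np.nan
        filled = sg_gapfill(gappy, window=11, poly_order=3)
        obs = ~np.isnan(gappy)
        np.testing.assert_array_equal(filled[obs], y[obs])

    def test_noisy_sinusoid_rmse_below_noise(self):
        rng = np.random.default_rng(1)
        x = np.linspace(0, 4 * np.pi, 365)
        truth = np.sin(x)
        noise_sd = 0.3
        obs = truth + rng.normal(0, noise_sd, x.size)
        gappy = np.full(x.size, np.nan)
        gappy[::8] = obs[::8]
        filled = sg_gapfill(gappy, window=33, poly_order=2)
        miss = np.isnan(gappy)
        rmse = np.sqrt(np.mean((filled[miss] - truth[miss]) ** 2))
        assert rmse < noise_sd

    def test_window_validation(self):
        with pytest.raises(ValueError):
            sg_gapfill(np.ones(10), window=11, poly_order=2)
        with pytest.raises(ValueError):
            sg_gapfill(np.ones(30), window=8, poly_order=2)


class TestUnits:
    @pytest.mark.parametrize("mt_c,expected", [(0.0, 0.0), (12.0, 44.0), (16.6, 60.8667)])
    def test_c_to_co2e(self, mt_c, expected):
        assert c_to_co2e(mt_c) == pytest.approx(expected, abs=5e-4)


class TestProductionIndex:
    def test_unit_index_changes_nothing(self, small_frame, small_weather, small_truth, default_params):
        import pandas as pd
        lids = small_frame.table.location_id.tolist()[:8]
        idx = pd.DataFrame([{"location_id": lid, "year": y, "index": 1.0}
                            for lid in lids for y in range(1979, 2016)])
        a = cc.simulate_batch(small_frame, small_weather, small_truth, default_params,
                              location_ids=lids)
        b = cc.simulate_batch(small_frame, small_weather, small_truth, default_params,
                              location_ids=lids, production_index=idx)
        np.testing.assert_array_equal(a.soc, b.soc)

    def test_higher_index_raises_stocks(self, small_frame, small_weather, small_truth, default_params):
        import pandas as pd
        lids = small_frame.table.location_id.tolist()[:8]
        idx = pd.DataFrame([{"location_id": lid, "year": y, "index": 1.3}
                            for lid in lids for y in range(2000, 2016)])
        a = cc.simulate_batch(small_frame, small_weather, small_truth, default_params,
                              location_ids=lids)
        b = cc.simulate_batch(small_frame, small_weather, small_truth, default_params,
                              location_ids=lids, production_index=idx)
        assert b.soc[:, -1].mean() > a.soc[:, -1].mean()

    def test_growing_season_index_from_gappy_series(self):
        from cropcarb.soc_model import growing_season_index
        doy = np.arange(365, dtype=float)
        truth = 0.4 + 0.3 * np.sin((doy - 100) * np.pi / 200)
        gappy = np.full(365, np.nan)
        gappy[::8] = truth[::8]
        got = growing_season_index(gappy)
        assert got == pytest.approx(truth[120:270].mean(), abs=0.01)
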