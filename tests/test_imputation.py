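"""Imputation: trend harmonisation, maximal-stay coupling, tillage chains,
predictive mean matching, cover-crop ramp, and full imputation sets."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cropcarb as cc
from cropcarb.imputation import (
    ANCHOR_LABEL,
    BLOCK_LABELS,
    default_marginal_series,
    pmm_assign,
    year_block,
)


def _series(rows):
    return pd.DataFrame.from_dict(rows, orient="index", columns=["NT", "RT", "FT"])


class TestHarmonize:
    def test_identical_overlap_keeps_early_values(self):
        ctic = _series({1: [0.2, 0.3, 0.5], 2: [0.25, 0.3, 0.45], 3: [0.3, 0.3, 0.4]})
        ceap = _series({2: [0.25, 0.3, 0.45], 3: [0.3, 0.3, 0.4]})
        out = cc.harmonize_tillage_series(ctic, ceap, [2, 3])
        np.testing.assert_allclose(out.loc[1], [0.2, 0.3, 0.5], atol=1e-9)

    def test_constant_offset_shifts_then_renormalises(self):
        # hand-computed 2-point regression: ceap = ctic + 0.1 per class
        ctic = _series({1: [0.2, 0.3, 0.5], 2: [0.25, 0.35, 0.4], 3: [0.3, 0.4, 0.3]})
        ceap = _series({2: [0.35, 0.45, 0.5], 3: [0.4, 0.5, 0.4]})
        out = cc.harmonize_tillage_series(ctic, ceap, [2, 3])
        raw = np.array([0.3, 0.4, 0.6])  # 0.2+0.1, 0.3+0.1, 0.5+0.1
        np.testing.assert_allclose(out.loc[1], raw / raw.sum(), atol=1e-9)

    def test_missing_block_linearly_interpolated(self):
        ctic = _series({1: [0.28, 0.3, 0.42], 2: [0.3, 0.3, 0.4]})
        ceap = _series({1: [0.28, 0.3, 0.42], 2: [0.3, 0.3, 0.4],
                        3: [np.nan, np.nan, np.nan], 4: [0.4, 0.3, 0.3]})
        out = cc.harmonize_tillage_series(ctic, ceap, [1, 2])
        np.testing.assert_allclose(out.loc[3], [0.35, 0.3, 0.35], atol=1e-9)

    def test_no_overlap_rejected(self):
        ctic = _series({1: [0.3, 0.3, 0.4]})
        ceap = _series({5: [0.4, 0.3, 0.3]})
        with pytest.raises(ValueError):
            cc.harmonize_tillage_series(ctic, ceap, [2, 3])


class TestMaxStayCoupling:
    def test_equal_marginals_give_identity(self):
        p = np.array([0.2, 0.3, 0.5])
        T = cc.max_stay_transition(p, p)
        np.testing.assert_allclose(T, np.eye(3), atol=1e-12)

    def test_worked_example_stay_mass_and_residual(self):
        p = np.array([0.3, 0.3, 0.4])
        q = np.array([0.5, 0.3, 0.2])
        T = cc.max_stay_transition(p, q)
        J = T * p[:, None]
        assert np.trace(J) == pytest.approx(0.8, abs=1e-12)
        assert J[2, 0] == pytest.approx(0.2, abs=1e-12)  # FT -> NT carries the shift

    def test_forced_transport(self):
        T = cc.max_stay_transition(np.array([1.0, 0.0, 0.0]), np.array([0.0, 1.0, 0.0]))
        assert T[0, 1] == pytest.approx(1.0)

    def test_worked_example_matches_linear_program(self):
        # independent oracle: maximise diagonal mass subject to both marginals
        from scipy.optimize import linprog
        rng = np.random.default_rng(3)
        for _ in range(20):
            p = rng.dirichlet(np.ones(3))
            q = rng.dirichlet(np.ones(3))
            T = cc.max_stay_transition(p, q)
            diag_mass = float(np.trace(T * p[:, None]))
            c = -np.eye(3).ravel()  # maximise sum of diagonal of J
            A_eq = np.zeros((6, 9))
            for i in range(3):
                A_eq[i, i * 3:(i + 1) * 3] = 1.0      # row sums = p
                A_eq[3 + i, i::3] = 1.0               # col sums = q
            res = linprog(c, A_eq=A_eq, b_eq=np.concatenate([p, q]), bounds=(0, None))
            assert res.success
            assert diag_mass == pytest.approx(-res.fun, abs=1e-9)

    @given(st.integers(0, 10_000))
    @settings(max_examples=200, deadline=None)
    def test_marginal_reproduction_property(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.dirichlet(np.ones(3))
        q = rng.dirichlet(np.ones(3))
        T = cc.max_stay_transition(p, q)
        assert np.all(T >= -1e-15)
        np.testing.assert_allclose(T.sum(axis=1), 1.0, atol=1e-12)
        np.testing.assert_allclose(p @ T, q, atol=1e-12)
        assert np.trace(T * p[:, None]) == pytest.approx(np.minimum(p, q).sum(), abs=1e-12)

    def test_bad_marginals_rejected(self):
        with pytest.raises(ValueError):
            cc.max_stay_transition(np.array([0.5, 0.5, 0.5]), np.array([0.3, 0.3, 0.4]))


class TestImputeTillage:
    def test_marginals_tracked_at_large_n(self, small_truth):
        frame = cc.generate_frame(10_000, total_area=1e6, n_replicates=4, seed=31)
        truth = cc.generate_truth_histories(frame, seed=31)
        donors = cc.generate_donors(frame, truth, 400, seed=31)
        series = default_marginal_series()
        till = cc.impute_tillage(frame, donors, series, seed=31)
        w = frame.weights
        levels = ("NT", "RT", "FT")
        # expected marginals: the realised anchor distribution propagated
        # through the same chained transition matrices (exact expectation)
        anchor_real = np.array([np.sum(w * (till[ANCHOR_LABEL] == t)) / w.sum() for t in levels])
        a = BLOCK_LABELS.index(ANCHOR_LABEL)
        expected = {ANCHOR_LABEL: anchor_real}
        for direction in (range(a - 1, -1, -1), range(a + 1, len(BLOCK_LABELS))):
            cur, vec = ANCHOR_LABEL, anchor_real
            for bi in direction:
                nxt = BLOCK_LABELS[bi]
                T = cc.max_stay_transition(series.loc[cur, list(levels)].to_numpy(),
                                           series.loc[nxt, list(levels)].to_numpy())
                vec = vec @ T
                expected[nxt] = vec
                cur = nxt
        for blk in BLOCK_LABELS:
            real = np.array([np.sum(w * (till[blk] == t)) / w.sum() for t in levels])
            for ti, t in enumerate(levels):
                target = expected[blk][ti]
                se = np.sqrt(max(target * (1 - target), 1e-6) / len(frame.table))
                assert abs(real[ti] - target) < 4 * se + 0.005

    def test_constant_marginals_mean_no_switching(self, small_frame, small_donors):
        flat = default_marginal_series()
        flat.loc[:, :] = np.array([0.2, 0.3, 0.5])
        till = cc.impute_tillage(small_frame, small_donors, flat, seed=5)
        switches = (till[BLOCK_LABELS].to_numpy()[:, 1:] != till[BLOCK_LABELS].to_numpy()[:, :-1]).sum()
        assert switches == 0  # identity transition matrices throughout

    def test_full_shift_forces_all_transitions(self, small_frame, small_donors):
        series = default_marginal_series()
        series.loc[:, :] = np.array([0.0, 0.0, 1.0])
        series.loc["2011-2015"] = [1.0, 0.0, 0.0]
        till = cc.impute_tillage(small_frame, small_donors, series, seed=5)
        assert (till["2011-2015"] == "NT").all()
        assert (till["2006-2010"] == "FT").all()


class TestPMM:
    def test_worked_three_donor_case(self):
        # recipient prediction 78 is nearest donor prediction 80 -> donor 2
        assigned = pmm_assign(
            np.array([78.0]), np.array([50.0, 80.0, 110.0]),
            np.array([111.0, 222.0, 333.0]), np.array([1, 2, 3]),
        )
        assert assigned[0] == 222.0

    def test_tie_breaks_to_lowest_donor_id(self):
        assigned = pmm_assign(
            np.array([75.0]), np.array([70.0, 80.0]),
            np.array([1.0, 2.0]), np.array([9, 4]),
        )
        assert assigned[0] == 2.0  # donor_id 4 < 9 wins the tie

    def test_imputed_values_in_donor_support(self, small_frame, small_donors):
        out = cc.impute_n_inputs(small_frame, small_donors, None, seed=6)
        base = out[out.year == out.year.min()]
        assert set(np.round(base.fert_n, 9)) <= set(np.round(small_donors.fert_n, 9))
        assert set(np.round(base.manure_n, 9)) <= set(np.round(small_donors.manure_n, 9))

    def test_empty_donor_pool_rejected(self, small_frame, small_donors):
        with pytest.raises(RuntimeError):
            cc.impute_n_inputs(small_frame, small_donors.iloc[:0], None)

    def test_regional_trend_multiplier_applied(self, small_frame, small_donors):
        trend = lambda region, year: 2.0 if year >= 2000 else 1.0
        out = cc.impute_n_inputs(small_frame, small_donors, trend, seed=6)
        a = out[out.year == 1999].set_index("location_id").fert_n
        b = out[out.year == 2000].set_index("location_id").fert_n
        np.testing.assert_allclose(b, 2.0 * a)


class TestCoverCrops:
    def test_zero_adoption_in_1990_and_before(self, small_frame, small_donors):
        out = cc.impute_cover_crops(small_frame, small_donors, seed=7)
        assert not out.loc[out.year <= 1990, "cover_crop"].any()

    def test_1995_adoption_half_of_2000(self):
        frame = cc.generate_frame(8000, total_area=1e6, n_replicates=4, seed=33)
        truth = cc.generate_truth_histories(frame, seed=33)
        donors = cc.generate_donors(frame, truth, 300, seed=33)
        out = cc.impute_cover_crops(frame, donors, seed=33)
        w = frame.table.set_index("location_id")["weight"]

        def level(y):
            t = out[out.year == y]
            return np.average(t.cover_crop.to_numpy(dtype=float),
                              weights=w.reindex(t.location_id).to_numpy())

        l2000 = level(2000)
        se = np.sqrt(0.5 * l2000 * (1 - 0.5 * l2000) / 8000)
        assert abs(level(1995) - 0.5 * l2000) < 3 * se + 0.002

    def test_post_2005_target_matching(self, small_frame, small_donors):
        out_same = cc.impute_cover_crops(small_frame, small_donors, seed=8)
        # target equal to anchor level: expected no net change
        w = small_frame.table.set_index("location_id")["weight"]
        lvl = lambda df, y: np.average(
            df[df.year == y].cover_crop.to_numpy(dtype=float),
            weights=w.reindex(df[df.year == y].location_id).to_numpy())
        assert lvl(out_same, 2010) == pytest.approx(lvl(out_same, 2005), abs=1e-12)

    def test_invalid_target_rejected(self, small_frame, small_donors):
        with pytest.raises(ValueError):
            cc.impute_cover_crops(small_frame, small_donors, {"2011-2015": 1.5})

    def test_termination_set_only_on_cover_years(self, small_frame, small_donors):
        out = cc.impute_cover_crops(small_frame, small_donors, seed=7, termination="tillage")
        assert (out.loc[out.cover_crop, "termination"] == "tillage").all()
        assert (out.loc[~out.cover_crop, "termination"] == "none").all()


class TestBuildImputations:
    def test_default_six_complete_sets(self, small_frame, small_truth, small_donors):
        sets = cc.build_imputations(small_frame, small_donors, small_truth, M=6, seed=9)
        assert len(sets) == 6
        for s in sets:
            h = s.histories
            assert not h.isna().any().any()
            assert len(h) == len(small_truth)

    def test_sets_differ_but_share_observed_columns(self, small_frame, small_truth, small_donors):
        sets = cc.build_imputations(small_frame, small_donors, small_truth, M=2, seed=9)
        a, b = sets[0].histories, sets[1].histories
        assert not a[["tillage", "fert_n"]].equals(b[["tillage", "fert_n"]])
        pd.testing.assert_frame_equal(a[["location_id", "year", "crop", "irrigated", "set_aside"]],
                                      b[["location_id", "year", "crop", "irrigated", "set_aside"]])

    def test_adoption_statistics_agree_across_sets(self, small_frame, small_truth, small_donors):
        sets = cc.build_imputations(small_frame, small_donors, small_truth, M=4, seed=9)
        w = small_frame.table.set_index("location_id")["weight"]
        fracs = []
        for s in sets:
            h = s.histories[s.histories.year == 2010]
            fracs.append(np.average(h.tillage.isin(["NT", "RT"]).to_numpy(dtype=float),
                                    weights=w.reindex(h.location_id).to_numpy()))
        assert np.std(fracs) < 0.08  # between-imputation spread is sampling noise

    def test_set_aside_years_forced_clean(self, small_frame, small_truth, small_donors):
        sets = cc.build_imputations(small_frame, small_donors, small_truth, M=1, seed=9)
        h = sets[0].histories
        sa = h[h.set_aside]
        assert (sa.tillage == "NT").all()
        assert (sa.fert_n == 0).all() and (sa.manure_n == 0).all()
        assert not sa.cover_crop.any()

    def test_year_block_mapping(self):
        assert year_block(1979) == "1980-1985"
        assert year_block(1985) == "1980-1985"
        assert year_block(1986) == "1986-1990"
        assert year_block(2003) == ANCHOR_LABEL
        assert year_block(2015) == "2011-2015"
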