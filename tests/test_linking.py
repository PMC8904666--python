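"""Crosswalk construction, cut-point matching, rates and the inclusion rule."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from burnlink.errors import (
    IncompatibleCrosswalkError,
    LinkingUndefinedError,
    SchemaError,
)
from burnlink.io import load_anchor_cutpoints, load_reference_crosswalk
from burnlink.irt import LatentDensity
from burnlink.linking import (
    Crosswalk,
    ItemSet,
    anchor_raw_to_t_table,
    apply_crosswalk,
    closest_cutpoint,
    cross_target_cutpoint,
    equipercentile_link,
    filter_missingness,
    irt_link,
    rates_from_frequency_table,
)
from burnlink.scales import ScaleDef


@pytest.fixture(scope="module")
def ee_item_set(study_fixture):
    fx = study_fixture
    return ItemSet("set1", fx.scales["PFI-WE"], fx.scales["MBI-EE"],
                   fx.anchor_params("MBI-EE"), fx.matrix)


@pytest.fixture(scope="module")
def ee_crosswalk(ee_item_set):
    return irt_link(ee_item_set)


class TestIrtLink:
    def test_self_link_reproduces_anchor_table(self, study_fixture):
        fx = study_fixture
        iset = ItemSet("self", fx.scales["MBI-EE"], fx.scales["MBI-EE"],
                       fx.anchor_params("MBI-EE"), fx.matrix)
        cw = irt_link(iset)
        own = anchor_raw_to_t_table(fx.scales["MBI-EE"], fx.anchor_params("MBI-EE"))
        assert np.max(np.abs(cw.table["t"].to_numpy() - own["t"].to_numpy())) < 1e-10

    def test_crosswalk_monotone_and_spans_anchor_range(self, ee_crosswalk, study_fixture):
        cw = ee_crosswalk
        assert (np.diff(cw.table["t"]) > 0).all()
        assert (np.diff(cw.table["anchor_expected_raw"]) > 0).all()
        span = cw.table["anchor_expected_raw"].iloc[-1] - cw.table["anchor_expected_raw"].iloc[0]
        assert span > 0.8 * 54

    def test_single_item_target_has_five_rows(self, study_fixture):
        fx = study_fixture
        iset = ItemSet("set3", fx.scales["MZSIB"], fx.scales["MBI-EE"],
                       fx.anchor_params("MBI-EE"), fx.matrix)
        cw = irt_link(iset)
        assert list(cw.table["raw"]) == [1, 2, 3, 4, 5]

    def test_overlapping_scales_rejected(self, study_fixture):
        fx = study_fixture
        bad_target = ScaleDef("BAD", fx.scales["MBI-EE"].item_ids[:2], 7, 0)
        with pytest.raises(SchemaError):
            ItemSet("bad", bad_target, fx.scales["MBI-EE"],
                    fx.anchor_params("MBI-EE"), fx.matrix)


class TestEquipercentile:
    @staticmethod
    def _t_table(raws):
        return pd.DataFrame({"raw": raws, "t": 50.0 + 2.0 * np.asarray(raws, float)})

    def test_identity_equating(self):
        rng = np.random.default_rng(31)
        x = rng.integers(0, 9, 400)
        cw = equipercentile_link(x, x, self._t_table(np.arange(9)))
        obs = np.unique(x)
        e = cw.table.set_index("raw").loc[obs, "anchor_expected_raw"].to_numpy()
        assert np.allclose(e, obs, atol=1e-9)

    def test_textbook_hand_example(self):
        """X freqs {0:2, 1:2} against Y freqs {0:1, 1:2, 2:1}: PR_X(0)=25 -> e_Y(0)=0.5."""
        cw = equipercentile_link(
            np.array([0, 0, 1, 1]), np.array([0, 1, 1, 2]), self._t_table([0, 1, 2])
        )
        assert cw.table["anchor_expected_raw"].iloc[0] == pytest.approx(0.5)

    def test_degenerate_distribution_rejected(self):
        with pytest.raises(LinkingUndefinedError):
            equipercentile_link(np.ones(50), np.arange(50) % 3, self._t_table([0, 1, 2]))

    @given(st.lists(st.tuples(st.integers(0, 60), st.integers(0, 60)),
                    min_size=2, max_size=40))
    def test_equated_scores_monotone(self, pairs):
        xs = np.array([p[0] for p in pairs])
        ys = np.array([p[1] for p in pairs])
        if np.ptp(xs) == 0 or np.ptp(ys) == 0:
            return
        cw = equipercentile_link(xs, ys, self._t_table(np.arange(0, 61)))
        assert (np.diff(cw.table["anchor_expected_raw"]) >= -1e-9).all()

    def test_presmoothing_preserves_total_and_monotonicity(self):
        rng = np.random.default_rng(33)
        x = rng.binomial(16, 0.4, 500)
        y = rng.binomial(20, 0.5, 500)
        cw = equipercentile_link(x, y, self._t_table(np.arange(21)),
                                 presmooth_degree=3)
        assert (np.diff(cw.table["anchor_expected_raw"]) >= -1e-9).all()


class TestCutpoints:
    def test_published_equivalencies(self):
        cuts = load_anchor_cutpoints()
        cw1 = load_reference_crosswalk("pfi_we_to_mbi_ee")
        cw2 = load_reference_crosswalk("pfi_id_to_mbi_dp")
        cw3 = load_reference_crosswalk("mzsib_to_mbi_ee")
        ee, dp = cuts["MBI-EE"], cuts["MBI-DP"]
        assert closest_cutpoint(cw1, ee["t"], ee["raw"]).target_raw_cut == 7
        assert closest_cutpoint(cw3, ee["t"], ee["raw"]).target_raw_cut == 3
        assert closest_cutpoint(cw2, dp["t"], dp["raw"]).target_raw_cut == 9
        assert cross_target_cutpoint(cw3, 3, cw1).target_raw_cut == 8

    def test_boundary_and_tie_rules(self):
        table = pd.DataFrame({"raw": [0, 1, 2], "t": [55.0, 60.0, 65.0],
                              "se_t": 1.0, "anchor_expected_raw": [10.0, 20.0, 30.0]})
        cw = Crosswalk(table, "irt", "X", "A")
        # all rows above the cut -> minimum raw score
        assert closest_cutpoint(cw, anchor_cut_t=40.0).target_raw_cut == 0
        # equidistant -> lower raw score wins
        tie = Crosswalk(pd.DataFrame({"raw": [0, 1], "t": [48.0, 52.0], "se_t": 1.0,
                                      "anchor_expected_raw": [24.0, 30.0]}),
                        "irt", "X", "A")
        assert closest_cutpoint(tie, anchor_cut_t=50.0).target_raw_cut == 0

    def test_self_cross_target_is_identity(self):
        cw1 = load_reference_crosswalk("pfi_we_to_mbi_ee")
        assert cross_target_cutpoint(cw1, 5, cw1).target_raw_cut == 5

    def test_cross_metric_comparison_refused(self):
        cw2 = load_reference_crosswalk("pfi_id_to_mbi_dp")
        cw3 = load_reference_crosswalk("mzsib_to_mbi_ee")
        with pytest.raises(IncompatibleCrosswalkError):
            cross_target_cutpoint(cw3, 3, cw2)


class TestRatesAndSubstitution:
    def test_rate_from_reference_frequency_table(self):
        cw1 = load_reference_crosswalk("pfi_we_to_mbi_ee")
        # t(5) = 45.34 < 50.70 <= t(8) = 51.98
        assert rates_from_frequency_table({5: 10, 8: 10}, cw1, 50.70) == 0.5

    def test_rate_properties(self):
        cw1 = load_reference_crosswalk("pfi_we_to_mbi_ee")
        assert rates_from_frequency_table({4: 25}, cw1, 50.70) == 0.0
        assert rates_from_frequency_table({9: 7}, cw1, 50.70) == 1.0
        r1 = rates_from_frequency_table({5: 1, 8: 3}, cw1, 50.70)
        r2 = rates_from_frequency_table({5: 10, 8: 30}, cw1, 50.70)
        assert r1 == r2
        with pytest.raises(LinkingUndefinedError):
            rates_from_frequency_table({5: 0}, cw1, 50.70)

    def test_individual_and_frequency_routes_agree(self):
        cw1 = load_reference_crosswalk("pfi_we_to_mbi_ee")
        rng = np.random.default_rng(41)
        raws = rng.integers(0, 17, 300)
        sub = apply_crosswalk(raws, cw1, 50.70)
        freq = pd.Series(raws).value_counts().to_dict()
        assert sub.proportion_at_or_above == pytest.approx(
            rates_from_frequency_table(freq, cw1, 50.70)
        )
        at_cut = apply_crosswalk(np.full(5, 8), cw1, 50.70)
        assert at_cut.proportion_at_or_above == 1.0

    def test_out_of_range_and_empty_inputs_error(self):
        cw1 = load_reference_crosswalk("pfi_we_to_mbi_ee")
        with pytest.raises(SchemaError, match="17"):
            apply_crosswalk([3, 17], cw1, 50.70)
        with pytest.raises(SchemaError):
            apply_crosswalk([], cw1, 50.70)


class TestMissingnessRule:
    @staticmethod
    def _two_scale_frame():
        a = ScaleDef("A", ["a1", "a2", "a3"], 3, 0)
        b = ScaleDef("B", ["b1", "b2"], 3, 0)
        frame = pd.DataFrame({
            "a1": [2, 2, np.nan, 2], "a2": [1, np.nan, np.nan, 1], "a3": [0, 1, 1, 2],
            "b1": [1, 1, 2, np.nan], "b2": [2, 0, 2, np.nan],
        })
        return a, b, frame

    def test_exclusion_and_proration(self):
        a, b, frame = self._two_scale_frame()
        filt = filter_missingness(frame, [a, b])
        # row 1: one missing on A -> prorated; row 2: two missing on A -> out;
        # row 3: B fully missing -> out
        assert list(filt.mask) == [True, True, False, False]
        assert filt.n_excluded == 2
        assert filt.included["A_raw"].tolist()[1] == round((2 + 1) / 2 * 3 + 0.001)

    def test_prorated_total_rounds_half_up(self):
        # 9-item scale, 8 observed items summing to 16 -> round(16/8 * 9) = 18
        sc = ScaleDef("S", [f"s{j}" for j in range(9)], 7, 0)
        row = {f"s{j}": 2.0 for j in range(9)}
        row["s0"] = np.nan
        filt = filter_missingness(pd.DataFrame([row]), [sc])
        assert filt.included["S_raw"].iloc[0] == 18

    def test_complete_matrix_is_noop(self, study_fixture):
        fx = study_fixture
        complete = fx.matrix.dropna()
        filt = filter_missingness(complete, list(fx.scales.values()))
        assert filt.n_excluded == 0
        assert len(filt.included) == len(complete)


class TestMethodAgreement:
    def test_irt_and_equipercentile_agree_in_bulk(self):
        """On a large shared-trait sample the two crosswalks agree within
        2 t-units between the 5th and 95th percentile raw scores."""
        from burnlink.evaluation import build_crosswalk
        from burnlink.synthetic import default_study_fixture

        fx = default_study_fixture(seed=21, n_respondents=5000,
                                   construct_correlation=1.0)
        iset = ItemSet("set1", fx.scales["PFI-WE"], fx.scales["MBI-EE"],
                       fx.anchor_params("MBI-EE"), fx.matrix)
        cw_irt, _ = build_crosswalk(iset, "irt")
        cw_eqp, _ = build_crosswalk(iset, "equipercentile")
        raws = filter_missingness(fx.matrix, [iset.target]).included["PFI-WE_raw"]
        lo, hi = np.percentile(raws, [5, 95])
        mid = cw_irt.table["raw"].between(lo, hi)
        dt = np.abs(cw_irt.table.loc[mid, "t"].to_numpy()
                    - cw_eqp.table.loc[mid, "t"].to_numpy())
        assert dt.max() < 2.0
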