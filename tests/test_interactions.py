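"""Village aggregation, Spearman matrices, CCDM and deviational ellipse."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from esfringe.es_models import ES_NAMES, assemble_es_stack
from esfringe.interactions import (
    CCDMConfig,
    aggregate_villages,
    ccdm_table,
    classify_level,
    composite_index,
    coordination_degree,
    coupling_degree,
    deviational_ellipse,
    level_transfer,
    normalize,
    orient_disservices,
    spearman_matrix,
)


def _random_table(n: int, seed: int, date_tag: str = "t0") -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(rng.random((n, 8)), columns=list(ES_NAMES))
    df.insert(0, "village_id", np.arange(1, n + 1))
    df["date_tag"] = date_tag
    return df


class TestAggregation:
    def test_matches_brute_force_accumulation(self, small_pair, small_villages,
                                              small_scenario):
        es = assemble_es_stack(small_pair[0])
        rf = small_scenario.refine_factor
        table = aggregate_villages(es, small_villages, rf).set_index("village_id")
        labels_fine = np.kron(small_villages.labels,
                              np.ones((rf, rf), dtype=int))
        for name in ("FP", "HQ"):
            vals = es[name].values
            for vid in small_villages.ids[:5]:
                sel = labels_fine == vid
                expected = vals[sel][np.isfinite(vals[sel])].mean()
                assert table.loc[vid, name] == pytest.approx(expected)

    def test_constant_layer_gives_constant_means(self, small_pair, small_villages,
                                                 small_scenario):
        es = assemble_es_stack(small_pair[0])
        for layer in es.layers.values():
            layer.values[:] = 5.0
        table = aggregate_villages(es, small_villages, small_scenario.refine_factor)
        assert np.allclose(table[list(ES_NAMES)].to_numpy(), 5.0)


class TestNormalize:
    def test_endpoints_and_midpoint(self):
        df = _random_table(3, 0)
        df.loc[:, "FP"] = [2.0, 3.0, 4.0]
        out = normalize(df)
        assert list(out["FP"]) == pytest.approx([0.0, 0.5, 1.0])

    def test_constant_column_zeroed_with_warning(self, caplog):
        df = _random_table(4, 1)
        df.loc[:, "CS"] = 7.0
        with caplog.at_level("WARNING"):
            out = normalize(df)
        assert (out["CS"] == 0).all()
        assert any("constant" in r.message for r in caplog.records)

    def test_pooled_dates_share_scale(self):
        a = _random_table(5, 2, "t0")
        b = _random_table(5, 3, "t1")
        b["FP"] += 10  # all of t1 above t0
        out = normalize(pd.concat([a, b], ignore_index=True))
        assert out[out.date_tag == "t1"]["FP"].min() > out[out.date_tag == "t0"]["FP"].max()

    def test_rejects_single_row(self):
        with pytest.raises(ValueError):
            normalize(_random_table(1, 0))


class TestSpearman:
    def test_matches_rank_then_pearson_oracle(self):
        for seed in range(5):
            table = _random_table(50, seed)
            got = spearman_matrix(table).to_numpy()
            X = table[list(ES_NAMES)].to_numpy()
            ranks = np.apply_along_axis(stats.rankdata, 0, X)
            expected = np.corrcoef(ranks, rowvar=False)
            assert np.allclose(got, expected, atol=1e-12)

    def test_monotone_pairs_hit_plus_minus_one(self):
        table = _random_table(30, 4)
        x = np.linspace(0, 1, 30)
        table["FP"] = x
        table["CS"] = np.exp(x)       # strictly co-monotone
        table["WY"] = -x**3           # strictly anti-monotone
        m = spearman_matrix(table)
        assert m.loc["FP", "CS"] == pytest.approx(1.0)
        assert m.loc["FP", "WY"] == pytest.approx(-1.0)

    def test_invariant_to_monotone_transform(self):
        table = _random_table(40, 5)
        m1 = spearman_matrix(table)
        table["HQ"] = np.log1p(table["HQ"] * 10)
        m2 = spearman_matrix(table)
        assert np.allclose(m1.to_numpy(), m2.to_numpy(), atol=1e-12)

    def test_changes_mode_uses_differences(self):
        a = _random_table(20, 6, "t0")
        b = _random_table(20, 7, "t1")
        both = pd.concat([a, b], ignore_index=True)
        got = spearman_matrix(both, mode="changes").to_numpy()
        diff = (b[list(ES_NAMES)].to_numpy() - a[list(ES_NAMES)].to_numpy())
        expected = stats.spearmanr(diff).statistic
        assert np.allclose(got, expected, atol=1e-12)

    def test_zero_variance_indicator_flagged_nan(self, caplog):
        table = _random_table(20, 8)
        table["LA"] = 0.3
        with caplog.at_level("WARNING"):
            m = spearman_matrix(table)
        assert np.isnan(m.loc["LA", "FP"])
        assert m.loc["LA", "LA"] == 1.0

    def test_small_stratum_rejected(self):
        with pytest.raises(ValueError):
            spearman_matrix(_random_table(4, 9))


class TestCouplingDegree:
    def test_default_weights_sum_to_one_exactly(self):
        w = CCDMConfig().weight_vector()
        assert w.sum() == pytest.approx(1.0, abs=1e-12)
        assert w[ES_NAMES.index("HQ")] == 0.16

    def test_equal_indicators_full_coupling(self):
        for u in (0.2, 0.5, 1.0):
            assert coupling_degree(np.full(8, u)) == pytest.approx(1.0)

    def test_any_zero_indicator_no_coupling(self):
        U = np.full(8, 0.7)
        U[3] = 0.0
        assert coupling_degree(U) == 0.0

    def test_two_system_forced_arithmetic(self):
        # GM/AM: 2 sqrt(0.16) / 1.0 = 0.8
        assert coupling_degree(np.array([0.2, 0.8])) == pytest.approx(0.8)

    def test_printed_product_variant_violates_equal_contract(self):
        # the literal product form does not reach 1 at equal indicators,
        # which is why it is not the default
        c = coupling_degree(np.full(8, 0.5),
                            CCDMConfig(coupling_variant="printed_product"))
        assert 0 <= c < 1

    @given(st.lists(st.floats(0.01, 1.0), min_size=2, max_size=8))
    @settings(deadline=None, max_examples=100)
    def test_am_gm_bounds(self, us):
        U = np.array(us)
        c = coupling_degree(U)
        assert 0 < c <= 1 + 1e-12
        if np.ptp(U) > 1e-9:
            assert c < 1.0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            coupling_degree(np.array([0.5, 1.2]))


class TestCompositeAndCoordination:
    def test_uniform_half_gives_half(self):
        assert composite_index(np.full(8, 0.5)) == pytest.approx(0.5)
        assert composite_index(np.ones(8)) == pytest.approx(1.0)

    def test_habitat_quality_weight(self):
        U = np.zeros(8)
        U[ES_NAMES.index("HQ")] = 1.0
        assert composite_index(U) == pytest.approx(0.16)

    def test_disservice_inversion(self):
        cfg = CCDMConfig()
        U = np.zeros(8)
        U[ES_NAMES.index("TN")] = 1.0
        oriented = orient_disservices(U, cfg)
        assert oriented[ES_NAMES.index("TN")] == 0.0
        raw = orient_disservices(U, CCDMConfig(disservice_handling="raw"))
        assert raw[ES_NAMES.index("TN")] == 1.0

    def test_d_is_product_by_default_sqrt_behind_flag(self):
        assert coordination_degree(1.0, 0.5) == pytest.approx(0.5)
        assert coordination_degree(0.5, 0.5, CCDMConfig(d_combiner="sqrt_product")) \
            == pytest.approx(0.5)

    def test_d_monotone_in_each_argument(self):
        assert coordination_degree(0.8, 0.6) > coordination_degree(0.8, 0.5)
        assert coordination_degree(0.9, 0.6) > coordination_degree(0.8, 0.6)

    @pytest.mark.parametrize("d,level", [
        (0.0, "F"), (0.2, "F"), (0.25, "E"), (0.4, "E"), (0.45, "D"),
        (0.5, "D"), (0.55, "C"), (0.6, "C"), (0.7, "B"), (0.8, "B"),
        (0.9, "A"), (1.0, "A"),
    ])
    def test_level_boundaries(self, d, level):
        assert classify_level(d) == level

    @given(st.floats(0, 1))
    @settings(deadline=None, max_examples=200)
    def test_levels_partition_unit_interval(self, d):
        assert classify_level(d) in "ABCDEF"

    def test_invalid_weights_rejected(self):
        with pytest.raises(ValueError):
            CCDMConfig(weights={n: 0.2 for n in ES_NAMES})


class TestLevelTransfer:
    def test_identity_for_identical_results(self):
        t = _random_table(30, 10)
        c = ccdm_table(normalize(t))
        m = level_transfer(c, c)
        present = m.to_numpy().sum(axis=1) > 0
        assert np.allclose(m.to_numpy()[present],
                           np.eye(6)[present])

    def test_hand_built_three_village_example(self):
        c0 = pd.DataFrame({"village_id": [1, 2, 3], "level": ["A", "B", "B"],
                           "D": [0.9, 0.7, 0.7], "date_tag": "t0"})
        c1 = pd.DataFrame({"village_id": [1, 2, 3], "level": ["B", "B", "F"],
                           "D": [0.7, 0.7, 0.1], "date_tag": "t1"})
        m = level_transfer(c0, c1)
        assert m.loc["A", "B"] == 1.0
        assert m.loc["B", "B"] == 0.5
        assert m.loc["B", "F"] == 0.5

    def test_id_mismatch_rejected(self):
        c0 = pd.DataFrame({"village_id": [1, 2], "level": ["A", "B"]})
        c1 = pd.DataFrame({"village_id": [1, 3], "level": ["A", "B"]})
        with pytest.raises(ValueError):
            level_transfer(c0, c1)


class TestDeviationalEllipse:
    def test_square_corners_give_circle(self):
        pts = np.array([[0, 0], [0, 1], [1, 0], [1, 1]], dtype=float)
        e = deviational_ellipse(pts)
        assert e.semi_major == pytest.approx(e.semi_minor)
        assert e.center == pytest.approx((0.5, 0.5))

    def test_collinear_points_zero_minor_axis(self):
        pts = np.array([[0, 0], [1, 1], [2, 2], [3, 3]], dtype=float)
        e = deviational_ellipse(pts)
        assert e.semi_minor == pytest.approx(0.0, abs=1e-9)
        assert e.orientation_deg == pytest.approx(45.0)

    def test_matches_covariance_eigendecomposition_oracle(self):
        rng = np.random.default_rng(11)
        pts = rng.standard_normal((200, 2)) @ np.array([[2.0, 0.5], [0.0, 1.0]])
        w = rng.random(200)
        e = deviational_ellipse(pts, w)
        wn = w / w.sum()
        c = wn @ pts
        X = pts - c
        cov = (X * wn[:, None]).T @ X
        vals = np.linalg.eigvalsh(cov)
        assert e.semi_major == pytest.approx(np.sqrt(vals[1]), abs=1e-9)
        assert e.semi_minor == pytest.approx(np.sqrt(vals[0]), abs=1e-9)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            deviational_ellipse(np.array([[0.0, 0.0]]))
        with pytest.raises(ValueError):
            deviational_ellipse(np.zeros((3, 2)), np.array([-1.0, 1, 1]))
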