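"""Feature computation, zonation classifier, transitions and transfer matrices."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from esfringe.grids import LAND_USE_CODES, AlignmentError, LandscapeStack, RasterLayer
from esfringe.synthetic import generate_labeled_points
from esfringe.zonation import (
    FEATURE_NAMES,
    ClassifierSpec,
    PoiFunctionConfig,
    Transition,
    ZoneMap,
    assemble_features,
    classify_zones,
    compute_fragmentation,
    compute_pland,
    compute_poi_function,
    compute_poi_shares,
    mask_water,
    train_classifier,
    transfer_matrix,
    type_transitions,
)

W = LAND_USE_CODES["water"]
B = LAND_USE_CODES["builtup"]
C = LAND_USE_CODES["cropland"]
F = LAND_USE_CODES["forest"]


def _stack_from_land_use(lu: np.ndarray, cell_size_m: float = 1000.0) -> LandscapeStack:
    layers = {"land_use": RasterLayer(lu, "land_use", cell_size_m=cell_size_m)}
    for name in ("population_density", "gdp_density", "ntl"):
        layers[name] = RasterLayer(np.zeros_like(lu, dtype=float), name,
                                   cell_size_m=cell_size_m)
    return LandscapeStack(date_tag="t", layers=layers)


class TestMaskWater:
    def test_large_lake_masked_small_pond_kept(self):
        # 100 m cells: 150 cells = 1.5 km^2 lake, 50 cells = 0.5 km^2 pond
        lu = np.full((40, 40), C, dtype=float)
        lu[0:10, 0:15] = W          # 150 cells = 1.5 km2
        lu[30:35, 30:40] = W        # 50 cells = 0.5 km2
        stack = _stack_from_land_use(lu, cell_size_m=100.0)
        mask = mask_water(stack, min_area_km2=1.0)
        assert mask[0:10, 0:15].all()
        assert not mask[30:35, 30:40].any()

    def test_exactly_threshold_area_is_kept(self):
        lu = np.full((20, 20), C, dtype=float)
        lu[0:10, 0:10] = W  # exactly 1 km2 at 100 m cells
        mask = mask_water(_stack_from_land_use(lu, 100.0), min_area_km2=1.0)
        assert not mask.any()  # strictly greater-than comparison

    def test_all_land_empty_mask(self):
        lu = np.full((8, 8), C, dtype=float)
        assert not mask_water(_stack_from_land_use(lu), 1.0).any()

    def test_missing_land_use_raises(self):
        stack = _stack_from_land_use(np.full((8, 8), C, dtype=float))
        del stack.layers["land_use"]
        with pytest.raises(KeyError):
            mask_water(stack, 1.0)


class TestPland:
    @pytest.mark.parametrize("share", [0.0, 0.35, 1.0])
    def test_forced_arithmetic(self, share):
        win = np.full(100, C, dtype=float)
        win[: int(share * 100)] = B
        assert compute_pland(win.reshape(10, 10)) == pytest.approx(share * 100)

    def test_all_nodata_raises(self):
        with pytest.raises(ValueError):
            compute_pland(np.full((3, 3), np.nan))


class TestFragmentation:
    def test_single_type_zero(self):
        assert compute_fragmentation(np.full((5, 5), C, dtype=float)) == 0.0

    def test_fifty_fifty_ln2(self):
        win = np.array([[C, B], [C, B]], dtype=float)
        assert compute_fragmentation(win) == pytest.approx(np.log(2), abs=1e-12)

    def test_four_type_mixture_matches_direct_sum(self):
        # proportions (0.4, 0.3, 0.2, 0.1): oracle = -sum p ln p = 1.27985...
        win = np.array([C] * 4 + [B] * 3 + [F] * 2 + [W], dtype=float)
        expected = -sum(p * np.log(p) for p in (0.4, 0.3, 0.2, 0.1))
        got = compute_fragmentation(win.reshape(2, 5))
        assert got == pytest.approx(expected, abs=1e-12)
        assert got == pytest.approx(1.27985, abs=1e-5)

    @given(counts=st.lists(st.integers(1, 20), min_size=1, max_size=6))
    @settings(deadline=None, max_examples=50)
    def test_bounded_by_log_of_types_present(self, counts):
        codes = list(LAND_USE_CODES.values())[: len(counts)]
        win = np.concatenate([np.full(c, code, dtype=float)
                              for c, code in zip(counts, codes)])
        wval = compute_fragmentation(win.reshape(1, -1))
        assert -1e-12 <= wval <= np.log(len(counts)) + 1e-12

    def test_uniform_mixture_attains_maximum(self):
        win = np.array([C, B, F, W] * 5, dtype=float)
        assert compute_fragmentation(win.reshape(4, 5)) == pytest.approx(np.log(4))


class TestPoiFunction:
    def test_single_type_share_is_100(self):
        shares = compute_poi_shares({"commercial": 2.5}, {"commercial": 1.0})
        assert shares == {"commercial": pytest.approx(100.0)}

    def test_share_scale_invariance(self):
        dens = {"a": 1.0, "b": 3.0}
        w = {"a": 0.5, "b": 0.5}
        s1 = compute_poi_shares(dens, w)
        s2 = compute_poi_shares({k: 2 * v for k, v in dens.items()}, w)
        assert s1 == pytest.approx(s2)

    def test_no_pois_gives_zero_feature(self):
        empty = pd.DataFrame(columns=["x", "y", "category"])
        out = compute_poi_function(empty, PoiFunctionConfig(), (4, 4), 1000.0)
        assert (out == 0).all()

    def test_feature_peaks_at_cluster(self):
        poi = pd.DataFrame({
            "x": [500.0] * 10 + [3500.0],
            "y": [500.0] * 10 + [3500.0],
            "category": ["commercial"] * 11,
        })
        out = compute_poi_function(poi, PoiFunctionConfig(bandwidth_m=500), (4, 4), 1000.0)
        assert out[0, 0] == 100.0 and out.max() == 100.0

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            PoiFunctionConfig(weights={"a": 0.4, "b": 0.4}).validate()
        with pytest.raises(ValueError):
            PoiFunctionConfig(bandwidth_m=-5).validate()


class TestAssembleFeatures:
    def test_feature_count_and_masking(self, small_pair, small_scenario):
        stack = small_pair[0]
        water = mask_water(stack, 1.0)
        feats = assemble_features(stack, small_scenario.refine_factor, mask=water)
        assert feats.shape == (16, 16)
        for name in FEATURE_NAMES:
            assert np.isnan(feats.features[name][feats.mask]).all()
        X = feats.matrix()
        assert X.shape == (256, 6)

    def test_unmasked_cells_finite(self, small_pair, small_scenario):
        feats = assemble_features(small_pair[0], small_scenario.refine_factor)
        for name in FEATURE_NAMES:
            assert np.isfinite(feats.features[name][~feats.mask]).all()


class TestClassifier:
    @pytest.fixture()
    def labeled(self, small_pair, small_scenario):
        stack, _, z0, _ = small_pair
        return generate_labeled_points(stack, z0, 600, seed=3,
                                       refine_factor=small_scenario.refine_factor)

    def test_separable_gradient_beats_090(self, labeled):
        clf = train_classifier(labeled, ClassifierSpec(seed=0))
        assert clf.accuracy >= 0.90

    def test_permuted_labels_fall_to_chance(self, labeled):
        # permutation breaks the feature-label link but keeps the class
        # marginals, so chance level is bounded by the majority share
        shuffled = labeled.copy()
        rng = np.random.default_rng(0)
        shuffled["label"] = rng.permutation(shuffled["label"].to_numpy())
        clf = train_classifier(shuffled, ClassifierSpec(seed=0))
        majority = shuffled["label"].value_counts(normalize=True).max()
        assert clf.accuracy <= majority + 0.10
        assert clf.accuracy < 0.90  # far below the separable-gradient level

    def test_missing_class_raises(self, labeled):
        two = labeled[labeled.label != 2]
        with pytest.raises(ValueError):
            train_classifier(two, ClassifierSpec(seed=0))

    def test_classified_map_recalls_truth(self, small_pair, small_scenario, labeled):
        stack, _, z0, _ = small_pair
        clf = train_classifier(labeled, ClassifierSpec(seed=0))
        water = mask_water(stack, 1.0)
        feats = assemble_features(stack, small_scenario.refine_factor, mask=water)
        zm = classify_zones(feats, clf, date_tag="t0")
        ok = zm.valid_mask & z0.valid_mask
        for cls in (0, 1, 2):
            sel = ok & (z0.values == cls)
            recall = (zm.values[sel] == cls).mean()
            assert recall >= 0.85

    def test_masked_cells_stay_nodata(self, small_pair, small_scenario, labeled):
        stack = small_pair[0]
        clf = train_classifier(labeled, ClassifierSpec(seed=0))
        water = mask_water(stack, 1.0)
        feats = assemble_features(stack, small_scenario.refine_factor, mask=water)
        zm = classify_zones(feats, clf)
        assert np.isnan(zm.values[feats.mask]).all()


class TestTransitions:
    def _toy_maps(self):
        z0 = ZoneMap(np.array([[0, 0, 0], [1, 1, 1], [2, 2, 2]], dtype=float))
        z1 = ZoneMap(np.array([[0, 1, 2], [0, 1, 2], [0, 1, 2]], dtype=float))
        return z0, z1

    def test_all_nine_combinations(self):
        z0, z1 = self._toy_maps()
        t = type_transitions(z0, z1).values
        assert t[0, 0] == Transition.RURAL_RETENTION
        assert t[0, 1] == Transition.FRINGE_EXPANSION
        assert t[0, 2] == Transition.URBAN_EXPANSION  # rural->urban default
        assert t[1, 0] == Transition.EXCLUDED
        assert t[1, 1] == Transition.FRINGE_MAINTENANCE
        assert t[1, 2] == Transition.URBAN_EXPANSION
        assert t[2, 0] == Transition.EXCLUDED
        assert t[2, 1] == Transition.EXCLUDED
        assert t[2, 2] == Transition.URBAN_MAINTENANCE

    def test_rural_to_urban_switch(self):
        z0, z1 = self._toy_maps()
        t = type_transitions(z0, z1, rural_to_urban="excluded").values
        assert t[0, 2] == Transition.EXCLUDED

    def test_typing_is_total(self):
        z0, z1 = self._toy_maps()
        t = type_transitions(z0, z1).values
        assert np.isfinite(t).all()

    def test_identical_maps_only_maintenance(self):
        z0, _ = self._toy_maps()
        t = type_transitions(z0, z0).values
        assert set(np.unique(t)) <= {
            float(Transition.URBAN_MAINTENANCE),
            float(Transition.FRINGE_MAINTENANCE),
            float(Transition.RURAL_RETENTION),
        }

    def test_misaligned_maps_raise(self):
        z0 = ZoneMap(np.zeros((3, 3)))
        z1 = ZoneMap(np.zeros((4, 4)))
        with pytest.raises(AlignmentError):
            type_transitions(z0, z1)


class TestTransferMatrix:
    def test_identity_for_identical_maps(self):
        z = ZoneMap(np.array([[0, 1], [2, 1]], dtype=float))
        shares, _ = transfer_matrix(z, z)
        assert np.allclose(shares.to_numpy(), np.eye(3))

    def test_hand_counted_toy(self):
        z0 = ZoneMap(np.array([[0, 0], [1, 2]], dtype=float))
        z1 = ZoneMap(np.array([[0, 1], [2, 2]], dtype=float))
        shares, areas = transfer_matrix(z0, z1)
        expected = np.array([[0.5, 0.5, 0.0], [0.0, 0.0, 1.0], [0.0, 0.0, 1.0]])
        assert np.allclose(shares.to_numpy(), expected)
        assert areas.to_numpy().sum() == pytest.approx(4.0)  # 4 cells x 1 km2

    def test_rows_sum_to_one(self, small_pair):
        _, _, z0, z1 = small_pair
        shares, _ = transfer_matrix(z0, z1)
        sums = shares.sum(axis=1).to_numpy()
        present = shares.to_numpy().sum(axis=1) > 0
        assert np.allclose(sums[present], 1.0, atol=1e-9)

    def test_conserves_cell_counts(self, small_pair):
        _, _, z0, z1 = small_pair
        _, areas = transfer_matrix(z0, z1)
        n_valid = (np.isfinite(z0.values) & np.isfinite(z1.values)).sum()
        assert areas.to_numpy().sum() == pytest.approx(n_valid * 1.0)
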