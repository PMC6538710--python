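import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from qusrim import preprocess, synth
from qusrim.features import (
    PARAMETERS,
    GLCM,
    build_parametric_map,
    compute_glcm,
    estimate_maps,
    extract_features,
    glcm_features,
    nakagami_mom,
    quantize_db,
    roi_average,
    weighted_entropy,
)
from qusrim.preprocess import BModeImage, EnvelopeImage, detect_envelope, log_compress
from qusrim.roi import place_windows

# dB values landing in quantization bins 0 and 1 (bin width 4 dB over 20-100)
LEVEL0_DB, LEVEL1_DB = 21.0, 25.0


def checkerboard_db(n=4):
    board = np.indices((n, n)).sum(axis=0) % 2
    return np.where(board == 0, LEVEL0_DB, LEVEL1_DB)


def brute_force_glcm_features(block_db, direction, displacement, levels=20):
    """Independent oracle: explicit pair enumeration and direct sums."""
    low, high = 20.0, 100.0
    q = np.clip(
        ((np.asarray(block_db) - low) * levels / (high - low)).astype(int), 0, levels - 1
    )
    pairs = {}
    h, w = q.shape
    for r in range(h):
        for c in range(w):
            if direction == "vertical" and r + displacement < h:
                key = (q[r, c], q[r + displacement, c])
            elif direction == "horizontal" and c + displacement < w:
                key = (q[r, c], q[r, c + displacement])
            else:
                continue
            pairs[key] = pairs.get(key, 0) + 1
    total = sum(pairs.values())
    g = {k: v / total for k, v in pairs.items()}
    mu_i = sum(i * p for (i, _), p in g.items())
    mu_j = sum(j * p for (_, j), p in g.items())
    var_i = sum((i - mu_i) ** 2 * p for (i, _), p in g.items())
    var_j = sum((j - mu_j) ** 2 * p for (_, j), p in g.items())
    con = sum(abs(i - j) ** 2 * p for (i, j), p in g.items())
    ene = sum(p**2 for p in g.values())
    hom = sum(p / (1 + abs(i - j) ** 2) for (i, j), p in g.items())
    if var_i > 0 and var_j > 0:
        cor = sum(
            (i - mu_i) * (j - mu_j) * p for (i, j), p in g.items()
        ) / np.sqrt(var_i * var_j)
    else:
        cor = float("nan")
    return {"CON": con, "COR": cor, "ENE": ene, "HOM": hom, "VAR": var_i}


class TestNakagamiMoM:
    def test_hand_value(self):
        assert nakagami_mom(np.array([1.0, 1.0, 1.0, 3.0])) == pytest.approx(0.75)

    @pytest.mark.parametrize("c", [0.001, 0.5, 7.0, 1e4])
    def test_scale_invariance(self, c):
        a = np.array([1.0, 1.0, 1.0, 3.0])
        assert nakagami_mom(c * a) == pytest.approx(0.75, rel=1e-12)

    def test_rayleigh_monte_carlo(self):
        a = synth.sample_nakagami_envelope(100_000, 1.0, 1.0, seed=8)
        assert abs(nakagami_mom(a) - 1.0) < 0.03

    def test_constant_block_invalid(self):
        assert np.isnan(nakagami_mom(np.full(16, 2.0)))

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            nakagami_mom(np.array([1.0]))

    @pytest.mark.parametrize("nak", [0.5, 1.0, 2.0])
    def test_consistency(self, nak):
        rng = np.random.default_rng(12)
        est = np.mean(
            [
                nakagami_mom(synth.sample_nakagami_envelope(10_000, nak, 1.0, rng))
                for _ in range(20)
            ]
        )
        assert abs(est - nak) < 0.05


class TestWeightedEntropy:
    def test_constant_block_zero(self):
        assert weighted_entropy(np.full(8, 3.0)) == 0.0

    def test_hand_value_two_bins(self):
        assert weighted_entropy(np.array([1.0, 1.0, 3.0, 3.0]), n_bins=2) == pytest.approx(
            0.5
        )

    def test_all_zero_invalid(self):
        assert np.isnan(weighted_entropy(np.zeros(8)))

    @given(
        arrays(
            float,
            st.integers(min_value=4, max_value=64),
            elements=st.floats(min_value=1e-6, max_value=1e3),
        )
    )
    @settings(max_examples=100, deadline=None)
    def test_nonnegative(self, block):
        assert weighted_entropy(block, n_bins=8) >= 0.0


class TestGLCM:
    def test_constant_block_single_diagonal_entry(self):
        g = compute_glcm(np.full((6, 6), 50.0), "horizontal", displacement_px=1)
        q = quantize_db(np.array(50.0))
        assert g.matrix[q, q] == 1.0
        assert g.matrix.sum() == 1.0

    def test_checkerboard_horizontal(self):
        g = compute_glcm(checkerboard_db(), "horizontal", displacement_px=1)
        assert g.matrix[0, 1] == pytest.approx(0.5)
        assert g.matrix[1, 0] == pytest.approx(0.5)
        assert g.matrix.sum() == pytest.approx(1.0)

    def test_default_dimension_20x20(self):
        g = compute_glcm(np.random.default_rng(0).uniform(20, 100, (13, 13)), "vertical")
        assert g.matrix.shape == (20, 20)

    def test_too_small_block(self):
        with pytest.raises(ValueError):
            compute_glcm(np.full((3, 8), 40.0), "vertical", displacement_px=4)

    def test_top_of_range_in_top_bin(self):
        assert quantize_db(np.array(100.0)) == 19
        assert quantize_db(np.array(20.0)) == 0

    @given(
        arrays(
            float, (8, 8), elements=st.floats(min_value=20, max_value=100, allow_nan=False)
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_normalization(self, block):
        g = compute_glcm(block, "vertical", displacement_px=2)
        assert g.matrix.sum() == pytest.approx(1.0, abs=1e-12)


class TestGLCMFeatures:
    def test_constant_block(self):
        g = compute_glcm(np.full((6, 6), 50.0), "vertical", displacement_px=1)
        f = glcm_features(g)
        assert f["CON"] == 0.0
        assert f["ENE"] == 1.0
        assert f["HOM"] == 1.0
        assert f["VAR"] == 0.0
        assert np.isnan(f["COR"])

    def test_checkerboard(self):
        g = compute_glcm(checkerboard_db(), "horizontal", displacement_px=1)
        f = glcm_features(g)
        assert f["CON"] == pytest.approx(1.0)
        assert f["ENE"] == pytest.approx(0.5)
        assert f["HOM"] == pytest.approx(0.5)
        assert f["VAR"] == pytest.approx(0.25)
        assert f["COR"] == pytest.approx(-1.0)

    def test_brute_force_oracle_200_blocks(self):
        rng = np.random.default_rng(42)
        for trial in range(200):
            block = rng.uniform(20, 100, size=(10, 10))
            direction = "vertical" if trial % 2 else "horizontal"
            disp = 1 + trial % 4
            fast = glcm_features(compute_glcm(block, direction, displacement_px=disp))
            slow = brute_force_glcm_features(block, direction, disp)
            for key in ("CON", "ENE", "HOM", "VAR"):
                assert fast[key] == pytest.approx(slow[key], abs=1e-12), key
            assert fast["COR"] == pytest.approx(slow["COR"], abs=1e-12)

    @given(
        arrays(
            float, (8, 8), elements=st.floats(min_value=20, max_value=100, allow_nan=False)
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_bounds(self, block):
        f = glcm_features(compute_glcm(block, "horizontal", displacement_px=1))
        assert 0 < f["ENE"] <= 1
        assert 0 < f["HOM"] <= 1
        assert f["CON"] >= 0
        assert f["VAR"] >= 0
        if not np.isnan(f["COR"]):
            assert -1 - 1e-12 <= f["COR"] <= 1 + 1e-12


class TestParametricMaps:
    def test_homogeneous_nak_map(self, uniform_fine_scene):
        env = detect_envelope(uniform_fine_scene.frame)
        windows = place_windows(env.values.shape, env.pixel_mm, 1.0, 0.0)
        pmap = build_parametric_map(env, windows, "NAK")
        assert pmap.valid.all()
        # 13x13 windows carry a small positive method-of-moments bias
        assert abs(pmap.values.mean() - 1.0) < 0.1
        assert pmap.values.std() / np.sqrt(pmap.values.size) < 0.02

    def test_two_region_plateaus(self, coarse_lesion_scene):
        scene = coarse_lesion_scene
        env = detect_envelope(scene.frame)
        windows = place_windows(env.values.shape, env.pixel_mm, 1.0, 0.5)
        pmap = build_parametric_map(env, windows, "NAK")
        labels = synth.region_label_map(
            scene.spec, env.values.shape, (env.pixel_mm, env.pixel_mm)
        )
        centers = labels[np.ix_(windows.centers_ax, windows.centers_lat)]
        interior = pmap.values[(centers == 1) & pmap.valid].mean()
        background = pmap.values[(centers == 0) & pmap.valid].mean()
        rim = pmap.values[(centers == 2) & pmap.valid].mean()
        assert interior < background < rim

    def test_unknown_parameter_error(self):
        env = EnvelopeImage(np.ones((20, 20)), 0.1)
        windows = place_windows((20, 20), 0.1, 1.0, 0.0)
        with pytest.raises(ValueError, match="unknown parameter"):
            build_parametric_map(env, windows, "XXX")

    def test_wrong_image_type_error(self):
        env = EnvelopeImage(np.ones((20, 20)), 0.1)
        bmode = BModeImage(np.full((20, 20), 60.0), 0.1)
        windows = place_windows((20, 20), 0.1, 1.0, 0.0)
        with pytest.raises(TypeError):
            build_parametric_map(bmode, windows, "NAK")
        with pytest.raises(TypeError):
            build_parametric_map(env, windows, "CONV")

    def test_bulk_matches_single_parameter_maps(self, coarse_lesion_scene):
        env = detect_envelope(coarse_lesion_scene.frame)
        bmode = log_compress(env)
        windows = place_windows(env.values.shape, env.pixel_mm, 1.5, 0.3)
        bulk = estimate_maps(env, bmode, windows, PARAMETERS)
        for p in PARAMETERS:
            image = env if p in ("NAK", "ENT") else bmode
            single = build_parametric_map(image, windows, p)
            np.testing.assert_array_equal(bulk[p].valid, single.valid)
            np.testing.assert_allclose(
                bulk[p].values[bulk[p].valid], single.values[single.valid]
            )

    def test_correction_applied(self):
        rng = np.random.default_rng(3)
        env = EnvelopeImage(rng.rayleigh(size=(40, 40)), 0.1)
        windows = place_windows((40, 40), 0.1, 1.0, 0.0)
        pmap = build_parametric_map(env, windows, "NAK")
        curve = preprocess.CorrectionCurve(
            "NAK", pmap.depth_mm, np.full(len(pmap.depth_mm), 2.0)
        )
        corrected = build_parametric_map(env, windows, "NAK", correction=curve)
        np.testing.assert_allclose(corrected.values, 2.0 * pmap.values)


class TestROIAverage:
    def _map(self, values):
        values = np.asarray(values, dtype=float)
        from qusrim.features import ParametricMap

        return ParametricMap(
            "NAK", values, np.isfinite(values), np.arange(values.shape[0], dtype=float)
        )

    def test_constant_maps(self):
        m = self._map(np.full((2, 2), 5.0))
        sel = np.ones((2, 2), dtype=bool)
        assert roi_average([m, m], [sel, sel]) == 5.0

    def test_pooled_mean(self):
        a = self._map([[1.0, 3.0]])
        b = self._map([[5.0, 7.0]])
        sel = np.ones((1, 2), dtype=bool)
        assert roi_average([a, b], [sel, sel]) == pytest.approx(4.0)

    def test_empty_roi_missing(self):
        m = self._map(np.ones((2, 2)))
        assert np.isnan(roi_average([m], [np.zeros((2, 2), dtype=bool)]))

    def test_invalid_windows_excluded(self):
        m = self._map([[1.0, np.nan], [3.0, np.nan]])
        sel = np.ones((2, 2), dtype=bool)
        assert roi_average([m], [sel]) == pytest.approx(2.0)


class TestExtractFeatures:
    def test_table_shape_and_columns(self, small_cohort, small_feature_table):
        table = small_feature_table
        assert len(table) == len(small_cohort.lesions)
        assert list(table.columns[:2]) == ["lesion_id", "label"]
        int_cols = [c for c in table.columns if c.endswith("_int")]
        ext_cols = [c for c in table.columns if c.endswith("_ext")]
        assert len(int_cols) == 12 and len(ext_cols) == 12
        assert int_cols == [f"{p}_int" for p in PARAMETERS]
        assert not table.isna().any().any()

    def test_order_invariance(self, small_cohort, small_feature_table):
        reversed_table = extract_features(small_cohort.lesions[::-1], overlap=0.25)
        a = small_feature_table.sort_values("lesion_id").reset_index(drop=True)
        b = reversed_table.sort_values("lesion_id").reset_index(drop=True)
        import pandas.testing as pdt

        pdt.assert_frame_equal(a, b)

    def test_rim_effect_visible_externally(self, small_feature_table):
        table = small_feature_table
        benign = table[table.label == "benign"]
        malignant = table[table.label == "malignant"]
        gap_ext = malignant["NAK_ext"].mean() - benign["NAK_ext"].mean()
        gap_int = abs(malignant["NAK_int"].mean() - benign["NAK_int"].mean())
        assert gap_ext > 0.2
        assert gap_ext > gap_int
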