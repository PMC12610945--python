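"""Image quantification: segmentation, foci, CTCF, morphometry, N/C."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from skimage.draw import disk

import agescore as ag
from agescore import imagequant as iq


def _disk_mask(shape, center, radius, label=1):
    m = np.zeros(shape, dtype=np.int32)
    rr, cc = disk(center, radius, shape=shape)
    m[rr, cc] = label
    return m


class TestSegmentation:
    def test_recovers_planted_interior_nuclei(self):
        eff = ag.MarkerEffectSpec("m", "channel_intensity", 50.0, 50.0)
        scene, gt = ag.generate_scene(
            20, eff, seed=11, geometry=ag.SceneGeometry(shape=(320, 320))
        )
        labels = iq.segment_nuclei(scene.channel("dapi"))
        assert labels.max() == len(gt.labels)

    def test_all_zero_image_yields_empty_mask_with_warning(self):
        with pytest.warns(UserWarning, match="no object"):
            labels = iq.segment_nuclei(np.zeros((64, 64)))
        assert labels.max() == 0

    def test_border_touching_nucleus_excluded(self):
        img = np.zeros((100, 100))
        rr, cc = disk((0, 50), 15, shape=img.shape)  # clipped at the border
        img[rr, cc] = 100.0
        rr, cc = disk((60, 50), 12)
        img[rr, cc] = 100.0
        labels = iq.segment_nuclei(img)
        assert labels.max() == 1
        assert labels[0, 50] == 0


class TestCountFoci:
    def test_planted_counts_recovered_exactly(self, foci_scene):
        scene, gt = foci_scene
        counts = iq.count_foci(scene.channel("gamma_h2ax"), gt.nucleus_masks)
        planted = gt.per_cell_foci_counts["gamma_h2ax"]
        assert [counts[lab] for lab in gt.labels] == planted.tolist()

    def test_uniform_in_window_nucleus_counts_one_component(self):
        mask = _disk_mask((60, 60), (30, 30), 15)
        channel = np.where(mask > 0, 100.0, 0.0)
        assert iq.count_foci(channel, mask) == {1: 1}

    def test_minimum_size_filter(self):
        mask = _disk_mask((40, 40), (20, 20), 12)
        channel = np.zeros((40, 40))
        channel[18:20, 18:20] = 100.0  # 4 px focus
        assert iq.count_foci(channel, mask, min_size_px=5) == {1: 0}
        assert iq.count_foci(channel, mask, min_size_px=4) == {1: 1}

    def test_out_of_window_pixels_ignored(self):
        mask = _disk_mask((40, 40), (20, 20), 12)
        channel = np.zeros((40, 40))
        channel[14:17, 14:17] = 500.0  # saturated: above the window
        assert iq.count_foci(channel, mask) == {1: 0}

    def test_inverted_window_rejected(self):
        mask = _disk_mask((20, 20), (10, 10), 5)
        with pytest.raises(ValueError, match="inverted"):
            iq.count_foci(np.zeros((20, 20)), mask, intensity_window=(200, 20))


class TestCTCF:
    def test_closed_form(self):
        img = np.full((30, 30), 2.0)
        roi = np.zeros((30, 30), dtype=bool)
        roi[5:15, 5:15] = True  # 100 px
        img[roi] = 10.0
        bg = np.zeros_like(roi)
        bg[20:25, 20:25] = True
        assert iq.compute_ctcf(img, roi, bg) == pytest.approx(800.0)

    def test_roi_equal_to_background_gives_zero(self):
        img = np.full((30, 30), 7.0)
        roi = np.zeros((30, 30), dtype=bool)
        roi[2:10, 2:10] = True
        bg = np.zeros_like(roi)
        bg[15:25, 15:25] = True
        assert iq.compute_ctcf(img, roi, bg) == pytest.approx(0.0)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(offset=st.floats(-1e3, 1e3), seed=st.integers(0, 100))
    def test_uniform_offset_invariance(self, offset, seed):
        r = np.random.default_rng(seed)
        img = r.uniform(0, 50, (40, 40))
        roi = np.zeros((40, 40), dtype=bool)
        roi[5:15, 8:20] = True
        bg = np.zeros_like(roi)
        bg[25:35, 25:35] = True
        base = iq.compute_ctcf(img, roi, bg)
        shifted = iq.compute_ctcf(img + offset, roi, bg)
        assert shifted == pytest.approx(base, abs=1e-6 * max(1, abs(base)))

    def test_overlapping_roi_and_background_rejected(self):
        img = np.ones((40, 40))
        bg = np.zeros((40, 40), dtype=bool)
        bg[25:35, 25:35] = True
        with pytest.raises(ValueError, match="overlap"):
            iq.compute_ctcf(img, bg, bg)

    def test_empty_background_rejected(self):
        img = np.zeros((10, 10))
        roi = np.ones((10, 10), dtype=bool)
        with pytest.raises(ValueError, match="background"):
            iq.compute_ctcf(img, roi, np.zeros((10, 10), dtype=bool))


class TestMorphometrics:
    def test_square_is_convex(self):
        m = np.zeros((40, 40), dtype=np.int32)
        m[5:25, 5:25] = 1
        row = iq.nucleus_morphometrics(m).iloc[0]
        assert row.solidity == pytest.approx(1.0)
        assert row.nucleus_area_px == 400

    def test_digital_disk_form_factor_near_one(self):
        m = _disk_mask((80, 80), (40, 40), 30)
        row = iq.nucleus_morphometrics(m).iloc[0]
        assert row.form_factor == pytest.approx(1.0, abs=0.05)

    def test_concave_mask_solidity_below_one(self):
        m = np.zeros((60, 60), dtype=np.int32)
        m[10:50, 25:35] = 1
        m[25:35, 10:50] = 1  # plus sign: concave
        row = iq.nucleus_morphometrics(m).iloc[0]
        assert row.solidity < 1.0
        assert 0 < row.form_factor <= 1.05

    def test_tiny_label_flagged(self):
        m = np.zeros((20, 20), dtype=np.int32)
        m[5:7, 5:8] = 1  # 6 px < 8
        row = iq.nucleus_morphometrics(m).iloc[0]
        assert not row.shape_ok
        assert np.isnan(row.solidity)


class TestNCRatio:
    def test_uniform_image_ratio_one(self):
        nuc = _disk_mask((60, 60), (30, 30), 10)
        cyt = iq.derive_cytoplasm(nuc)
        out = iq.nc_ratio(np.full((60, 60), 13.0), nuc, cyt)
        assert out.nc_ratio.iloc[0] == pytest.approx(1.0)

    def test_planted_ratio(self):
        nuc = _disk_mask((60, 60), (30, 30), 10)
        cyt = iq.derive_cytoplasm(nuc)
        img = np.zeros((60, 60))
        img[nuc > 0] = 8.0
        img[cyt > 0] = 2.0
        assert iq.nc_ratio(img, nuc, cyt).nc_ratio.iloc[0] == pytest.approx(4.0)

    def test_planted_generator_ratio_recovered(self):
        eff = ag.MarkerEffectSpec("rep", "nc_shift", 4.0, 4.0, dispersion=0.01)
        geom = ag.SceneGeometry(noise_sigma=1e-12, background_level=0.0)
        scene, gt = ag.generate_scene(20, eff, seed=8, geometry=geom)
        out = iq.nc_ratio(scene.channel("rep"), gt.nucleus_masks, gt.cytoplasm_masks)
        np.testing.assert_allclose(
            out.sort_values("cell_id").nc_ratio.values,
            gt.per_cell_nc_ratio["rep"],
            rtol=1e-6,
        )

    def test_empty_cytoplasm_is_missing_not_error(self):
        nuc = _disk_mask((60, 60), (30, 30), 10)
        cyt = np.zeros_like(nuc)
        out = iq.nc_ratio(np.ones((60, 60)), nuc, cyt)
        assert np.isnan(out.nc_ratio.iloc[0])


class TestMeanIntensity:
    def test_uniform(self):
        m = _disk_mask((30, 30), (15, 15), 8)
        assert iq.mean_intensity_in_mask(np.full((30, 30), 5.0), m) == {1: 5.0}

    def test_empty_mask(self):
        assert iq.mean_intensity_in_mask(np.ones((10, 10)), np.zeros((10, 10), int)) == {}


class TestPhagocytosis:
    def test_no_spots_fraction_zero(self):
        cells = _disk_mask((60, 60), (30, 30), 12)
        f1, f2, per = iq.phagocytosis_fraction(np.zeros((60, 60)), cells)
        assert f1 == 0.0 and f2 == 0.0
        assert not per.phagocytic.any()

    def test_every_cell_with_spot_fraction_one(self):
        cells = _disk_mask((60, 60), (30, 30), 12)
        ch = np.zeros((60, 60))
        ch[28:31, 28:31] = 100.0
        f1, _, _ = iq.phagocytosis_fraction(ch, cells)
        assert f1 == 1.0

    def test_zero_cells_is_error(self):
        with pytest.raises(ValueError, match="no cells"):
            iq.phagocytosis_fraction(np.zeros((20, 20)), np.zeros((20, 20), int))

    def test_planted_bernoulli_fraction_recovered(self):
        eff = ag.MarkerEffectSpec("phago", "spot_probability", 0.4, 0.4,
                                  dispersion=0.01)
        geom = ag.SceneGeometry(shape=(1000, 1000))
        scene, gt = ag.generate_scene(200, eff, seed=9, geometry=geom)
        whole = np.where(gt.nucleus_masks > 0, gt.nucleus_masks, gt.cytoplasm_masks)
        f1, f2, per = iq.phagocytosis_fraction(scene.channel("phago"), whole)
        planted = gt.per_cell_phagocytic["phago"]
        assert f1 == pytest.approx(planted.mean())  # exact per-cell recovery
        se = np.sqrt(0.4 * 0.6 / 200)
        assert abs(f1 - 0.4) < 3 * se
        assert f2 <= f1


class TestPuncta:
    def test_planted_puncta_recovered(self):
        eff = ag.MarkerEffectSpec("sg", "puncta_rate", 2.0, 2.0, dispersion=0.01)
        scene, gt = ag.generate_scene(20, eff, seed=6)
        counts = iq.count_puncta(scene.channel("sg"), gt.cytoplasm_masks)
        assert [counts[lab] for lab in gt.labels] == gt.per_cell_puncta_counts[
            "sg"
        ].tolist()

    def test_empty_channel_zero_everywhere(self):
        cyt = iq.derive_cytoplasm(_disk_mask((60, 60), (30, 30), 10))
        assert iq.count_puncta(np.zeros((60, 60)), cyt) == {1: 0}

    def test_nuclear_puncta_do_not_count(self):
        nuc = _disk_mask((60, 60), (30, 30), 10)
        cyt = iq.derive_cytoplasm(nuc)
        ch = np.zeros((60, 60))
        ch[28:31, 28:31] = 100.0  # inside the nucleus
        assert iq.count_puncta(ch, cyt) == {1: 0}


def test_background_roi_is_cell_free_and_similar_size(foci_scene):
    scene, gt = foci_scene
    bg = iq.select_background_roi(gt.nucleus_masks)
    assert not np.any(bg & (gt.nucleus_masks > 0))
    mean_area = (gt.nucleus_masks > 0).sum() / len(gt.labels)
    assert bg.sum() >= 0.5 * mean_area
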