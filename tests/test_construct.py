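"""Graphical-construct pipeline: mask, extraction, panel, frame, resize."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import spiroqc as s
from spiroqc.construct import (
    ConstructConfig,
    NormalizationSpec,
    compose_panel,
    extract_curve_regions,
    finalize,
    frame_grays,
    mask_post_bd_colors,
)
from spiroqc.errors import InvalidParameterError, NoCurvesFoundError, StageError
from spiroqc.ingest import ReportPage
from tests.oracles import flood_fill_components


def _page_with_blobs(blobs, shape=(400, 600)):
    """White page whose bottom half carries solid black rectangles.

    ``blobs`` are (top, left, height, width) in bottom-half coordinates.
    """
    h, w = shape
    px = np.full((h, w, 3), 255, dtype=np.uint8)
    for top, left, bh, bw in blobs:
        px[h // 2 + top : h // 2 + top + bh, left : left + bw] = 0
    return ReportPage(px)


class TestColorMask:
    def test_tone_rules(self):
        px = np.full((200, 200, 3), 255, np.uint8)
        px[0, 0] = (0, 0, 255)      # blue: untouched
        px[0, 1] = (255, 0, 0)      # red: whitened
        px[0, 2] = (128, 0, 0)      # maroon: whitened
        px[0, 3] = (255, 192, 203)  # pink: whitened
        px[0, 4] = (0, 0, 0)        # black text: untouched
        px[0, 5] = (0, 255, 0)      # green: untouched
        out = mask_post_bd_colors(ReportPage(px)).pixels
        assert tuple(out[0, 0]) == (0, 0, 255)
        assert tuple(out[0, 1]) == (255, 255, 255)
        assert tuple(out[0, 2]) == (255, 255, 255)
        assert tuple(out[0, 3]) == (255, 255, 255)
        assert tuple(out[0, 4]) == (0, 0, 0)
        assert tuple(out[0, 5]) == (0, 255, 0)

    def test_noop_without_red_family(self, rng):
        px = np.full((210, 210, 3), 255, np.uint8)
        px[150:180, 20:60] = (0, 0, 200)
        out = mask_post_bd_colors(ReportPage(px)).pixels
        assert np.array_equal(out, px)


class TestRegionExtraction:
    def test_area_filter_discards_small_regions(self):
        # 100x80=8000, 100x50=5000 survive; 30x30=900 is noise
        page = _page_with_blobs(
            [(10, 10, 100, 80), (10, 200, 100, 50), (150, 400, 30, 30)]
        )
        (b1, _), (b2, _) = extract_curve_regions(page)
        assert sorted([b1.area, b2.area]) == [5000, 8000]

    def test_area_exactly_1000_is_retained(self):
        # the filter is strictly "< 1000": a 20x50 = 1000 px blob survives
        page = _page_with_blobs([(10, 10, 100, 80), (50, 300, 20, 50)])
        (b1, _), (b2, _) = extract_curve_regions(page)
        assert sorted([b1.area, b2.area]) == [1000, 8000]

    def test_area_999_is_discarded(self):
        page = _page_with_blobs(
            [(10, 10, 100, 80), (10, 200, 100, 50), (50, 400, 27, 37)]
        )
        (b1, _), (b2, _) = extract_curve_regions(page)
        assert sorted([b1.area, b2.area]) == [5000, 8000]

    def test_blank_bottom_half_raises(self):
        with pytest.raises((NoCurvesFoundError, StageError)):
            extract_curve_regions(_page_with_blobs([]))

    def test_single_region_raises(self):
        with pytest.raises(NoCurvesFoundError):
            extract_curve_regions(_page_with_blobs([(10, 10, 100, 80)]))

    def test_matches_flood_fill_oracle(self):
        """Surviving regions and boxes equal a brute-force CC oracle.

        Blob geometry is chosen so the closing operator is the identity
        (solid rectangles, > 5 px apart), making the oracle exact.
        """
        blobs = [(5, 5, 40, 40), (60, 100, 35, 40), (120, 30, 10, 12),
                 (5, 200, 33, 41)]
        page = _page_with_blobs(blobs)
        config = ConstructConfig(min_area=400)  # exercise the filter path
        (vt_box, vt_crop), (fv_box, fv_crop) = extract_curve_regions(page, config)

        binary = np.zeros((200, 600), bool)
        for top, left, bh, bw in blobs:
            binary[top : top + bh, left : left + bw] = True
        comps = [c for c in flood_fill_components(binary) if c["area"] >= 400]
        comps.sort(key=lambda c: -c["area"])
        expected = {(c["area"], c["bbox"]) for c in comps[:2]}
        got = {
            (b.area, (b.top, b.left, b.bottom, b.right))
            for b in (vt_box, fv_box)
        }
        assert got == expected
        # crops carry exactly the region's own pixels
        assert vt_crop.sum() == vt_box.area
        assert fv_crop.sum() == fv_box.area


class TestPanel:
    def test_dimensions_and_placement(self, rng):
        vt = rng.random((200, 300)) > 0.5
        fv = rng.random((120, 80)) > 0.5
        panel = compose_panel(vt, fv)
        assert panel.image.shape == (700, 500)
        assert set(np.unique(panel.image)) <= {0, 255}
        rows = np.nonzero(panel.image.any(axis=1))[0]
        vt_rows, fv_rows = rows[rows < 350], rows[rows >= 350]
        assert vt_rows.mean() < 350 <= fv_rows.mean()

    def test_oversized_crop_downscaled_without_clipping(self):
        crop = np.ones((900, 1200), bool)  # larger than the 350x500 sub-panel
        panel = compose_panel(crop, crop)
        fg_rows = np.nonzero(panel.image[:350].any(axis=1))[0]
        fg_cols = np.nonzero(panel.image[:350].any(axis=0))[0]
        assert fg_rows.min() >= 0 and fg_rows.max() < 350
        assert fg_cols.min() >= 0 and fg_cols.max() < 500

    def test_empty_crop_rejected(self):
        with pytest.raises(InvalidParameterError):
            compose_panel(np.zeros((10, 10), bool), np.ones((10, 10), bool))


class TestDemographicFrame:
    def test_worked_example_grays(self, clean_construct):
        # woman -> 255; age 45 in [10, 84] -> 121; BMI 18.1 in [15, 54] -> 20
        assert clean_construct.frame_grays == (255, 121, 20)
        framed = clean_construct.framed
        assert framed.shape == (700, 700)
        assert np.all(framed[0:234, 500:] == 255)
        assert np.all(framed[234:467, 500:] == 121)
        assert np.all(framed[467:700, 500:] == 20)

    def test_man_encodes_to_black_section(self):
        grays = frame_grays(s.Demographics("man", 47, 34.5), NormalizationSpec())
        assert grays[0] == 0
        assert grays[1] == 128  # (47-10)/74 = 0.5 exactly
        assert grays[2] == 128  # (34.5-15)/39 = 0.5 exactly

    def test_out_of_range_values_clamped(self):
        grays = frame_grays(s.Demographics("man", 99, 5), NormalizationSpec())
        assert grays[1] == 255 and grays[2] == 0

    @settings(max_examples=50, deadline=None)
    @given(
        a1=st.floats(10, 84), a2=st.floats(10, 84),
        b=st.floats(15, 54),
    )
    def test_gray_monotone_in_age(self, a1, a2, b):
        spec = NormalizationSpec()
        g1 = frame_grays(s.Demographics("man", a1, b), spec)
        g2 = frame_grays(s.Demographics("man", a2, b), spec)
        if a1 <= a2:
            assert g1[1] <= g2[1]
        else:
            assert g1[1] >= g2[1]
        assert g1[2] == g2[2]


class TestFinalize:
    def test_output_contract(self, clean_construct):
        x = clean_construct.network_input
        assert x.shape == (224, 224, 3)
        assert x.dtype == np.uint8
        assert np.array_equal(x[..., 0], x[..., 1])
        assert np.array_equal(x[..., 0], x[..., 2])

    def test_constant_image_preserved(self):
        out = finalize(np.full((700, 700), 137, np.uint8))
        assert np.all(out == 137)


class TestFullPipeline:
    def test_deterministic(self, clean_report):
        a = s.build_construct(clean_report.page, clean_report.demographics)
        b = s.build_construct(clean_report.page, clean_report.demographics)
        assert np.array_equal(a.network_input, b.network_input)
        assert np.array_equal(a.framed, b.framed)

    def test_post_bd_overlay_removed_by_mask(self, clean_maneuver,
                                             case_demographics):
        """Paired renders with/without the red overlay give near-identical
        constructs (≤ 1% of foreground pixels may differ via closing fill)."""
        r0 = s.render_report(clean_maneuver, case_demographics,
                             include_post_bd=False)
        r1 = s.render_report(clean_maneuver, case_demographics,
                             include_post_bd=True)
        g0 = s.build_construct(r0.page, case_demographics)
        g1 = s.build_construct(r1.page, case_demographics)
        panel0, panel1 = g0.framed[:, :500], g1.framed[:, :500]
        fg = ((panel0 > 0) | (panel1 > 0)).sum()
        assert (panel0 != panel1).sum() <= 0.01 * fg

    def test_stage_error_names_failing_stage(self):
        blank = ReportPage(np.full((400, 600, 3), 255, np.uint8))
        with pytest.raises(StageError) as exc:
            s.build_construct(blank, s.Demographics("man", 40, 25))
        assert exc.value.stage == "extract"

    def test_annotation_maps_into_input_coordinates(self, clean_maneuver):
        p = s.ManeuverParams(artifact="cough",
                             artifact_params={"onset": 4.5, "width": 0.1,
                                              "amplitude": 5.0})
        cough = s.inject_artifact(clean_maneuver, p)
        r = s.render_report(cough, s.Demographics("man", 40, 25))
        gc = s.build_construct(r.page, r.demographics)
        box = gc.map_page_box(r.artifact_annotation)
        assert box is not None
        t, l, b, rr = box
        assert 0 <= t < b <= 224 and 0 <= l < rr <= 224
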