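"""Bubble segmentation, ellipse fitting and equivalent spherical diameter."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from microbcr.bubbles import (
    BubbleMeasurement,
    bubble_population_stats,
    equivalent_sphere_diameter,
    fit_ellipse_axes,
    measure_bubbles,
    segment_bubbles,
)
from microbcr.frames import FrameSequence
from microbcr.synthetic import SyntheticConfig, make_bubble_frames


def _blank_seq(value=220, shape=(64, 64)):
    frames = np.full((1, *shape), value, dtype=np.uint8)
    return FrameSequence(frames, [0.0], fps=50.0, pixel_scale_mm=0.02)


def _meas(d_sb, i=0):
    return BubbleMeasurement(i, (0.0, 0.0), d_sb, d_sb, d_sb, 100)


class TestEquivalentSphereDiameter:
    @pytest.mark.parametrize(
        "dmaj, dmin, expected",
        [
            (2.0, 2.0, 2.0),                  # sphere identity
            (4.0, 2.0, np.cbrt(32.0)),        # = 3.1748...
            (3.0, 2.0, np.cbrt(18.0)),        # = 2.6207...
        ],
    )
    def test_rotation_ellipsoid_volume_equivalent(self, dmaj, dmin, expected):
        assert equivalent_sphere_diameter(dmaj, dmin) == pytest.approx(expected)

    def test_sphere_identity_over_diameter_grid(self):
        for d in np.arange(0.1, 5.01, 0.1):
            assert equivalent_sphere_diameter(d, d) == pytest.approx(d, rel=1e-12)

    @given(dmaj=st.floats(0.5, 5.0), dmin=st.floats(0.5, 5.0))
    def test_between_minor_and_major(self, dmaj, dmin):
        dmaj, dmin = max(dmaj, dmin), min(dmaj, dmin)
        d = equivalent_sphere_diameter(dmaj, dmin)
        assert dmin - 1e-12 <= d <= dmaj + 1e-12

    def test_nonpositive_axis_rejected(self):
        with pytest.raises(ValueError):
            equivalent_sphere_diameter(2.0, 0.0)


class TestSegmentation:
    def test_blank_frame_yields_no_components(self):
        assert segment_bubbles(_blank_seq()) == [[]]

    def test_three_disjoint_ellipses_found(self, noiseless_cfg):
        seq = make_bubble_frames(
            noiseless_cfg,
            bubbles=[
                ((0.6, 0.6), 0.5, 0.4, 0.0),
                ((1.8, 0.8), 0.7, 0.5, 0.5),
                ((1.2, 1.9), 0.6, 0.6, 0.0),
            ],
        )
        (regions,) = segment_bubbles(seq)
        assert len(regions) == 3

    def test_speck_below_min_area_filtered(self):
        seq = _blank_seq()
        seq.frames[0, 30, 30] = 10  # single dark pixel
        (regions,) = segment_bubbles(seq, min_area_px=5, threshold=100.0)
        assert regions == []

    def test_component_touching_roi_border_excluded(self, noiseless_cfg):
        seq = make_bubble_frames(noiseless_cfg, [((1.28, 1.28), 1.0, 1.0, 0.0)])
        # restrict the ROI so the bubble crosses its edge
        seq.roi = (0, 64, 0, 128)
        (regions,) = segment_bubbles(seq)
        assert regions == []

    def test_deterministic_and_idempotent(self, noiseless_cfg):
        seq = make_bubble_frames(noiseless_cfg, [((1.0, 1.0), 0.8, 0.6, 0.2)])
        a = segment_bubbles(seq)
        b = segment_bubbles(seq)
        assert [[r.bbox for r in f] for f in a] == [[r.bbox for r in f] for f in b]

    def test_empty_roi_rejected(self):
        seq = _blank_seq()
        with pytest.raises(ValueError):
            FrameSequence(seq.frames, seq.timestamps, seq.fps, seq.pixel_scale_mm,
                          roi=(10, 10, 0, 64))


class TestEllipseFit:
    @pytest.mark.parametrize("theta", [0.0, 0.4, np.pi / 2])
    def test_rendered_ellipse_axes_recovered(self, theta, noiseless_cfg):
        seq = make_bubble_frames(noiseless_cfg, [((1.28, 1.28), 1.0, 0.6, theta)])
        (regions,) = segment_bubbles(seq)
        dmaj, dmin, _ = fit_ellipse_axes(regions[0], seq.pixel_scale_mm)
        px = seq.pixel_scale_mm
        assert dmaj == pytest.approx(1.0, abs=px)
        assert dmin == pytest.approx(0.6, abs=px)

    def test_circle_recovered(self, noiseless_cfg):
        seq = make_bubble_frames(noiseless_cfg, [((1.28, 1.28), 2.0, 2.0, 0.0)])
        (regions,) = segment_bubbles(seq)
        dmaj, dmin, _ = fit_ellipse_axes(regions[0], seq.pixel_scale_mm)
        assert dmaj == pytest.approx(2.0, abs=seq.pixel_scale_mm)
        assert dmin == pytest.approx(2.0, abs=seq.pixel_scale_mm)

    def test_rotation_by_quarter_turn_preserves_axis_order(self, noiseless_cfg):
        a = make_bubble_frames(noiseless_cfg, [((1.28, 1.28), 1.2, 0.8, 0.0)])
        b = make_bubble_frames(noiseless_cfg, [((1.28, 1.28), 1.2, 0.8, np.pi / 2)])
        ma, mb = measure_bubbles(a)[0], measure_bubbles(b)[0]
        assert ma.d_major_mm == pytest.approx(mb.d_major_mm, rel=0.01)
        assert ma.d_minor_mm == pytest.approx(mb.d_minor_mm, rel=0.01)


class TestFullRoundTrip:
    @pytest.mark.parametrize(
        "dmaj, dmin", [(0.5, 0.4), (1.0, 0.8), (2.0, 1.2), (3.42, 2.801)]
    )
    def test_render_segment_fit_recovers_ground_truth(self, dmaj, dmin):
        """End to end: bubbles >= 10 px across, mild noise, 2 % accuracy."""
        cfg = SyntheticConfig(seed=3, pixel_scale_mm=0.02, image_shape=(256, 256),
                              noise_sd=5.0)
        seq = make_bubble_frames(cfg, [((2.56, 2.56), dmaj, dmin, 0.3)])
        truth = seq.ground_truth["bubbles"][0]["d_sb_mm"]
        (m,) = measure_bubbles(seq)
        assert m.d_sb_mm == pytest.approx(truth, rel=0.02)

    def test_out_of_frame_bubble_refused(self, noiseless_cfg):
        with pytest.raises(ValueError):
            make_bubble_frames(noiseless_cfg, [((0.1, 0.1), 1.0, 1.0, 0.0)])

    def test_clip_mode_renders_truncated(self, noiseless_cfg):
        seq = make_bubble_frames(
            noiseless_cfg, [((0.1, 0.1), 1.0, 1.0, 0.0)], clip_mode="clip"
        )
        assert seq.frames.min() < 100  # some dark pixels rendered


class TestPopulationStats:
    def test_single_measurement(self):
        s = bubble_population_stats([_meas(2.5)])
        assert (s.n, s.mean_mm, s.sd_mm, s.max_mm) == (1, 2.5, 0.0, 2.5)

    def test_cap_at_max_n(self):
        s = bubble_population_stats([_meas(1.0, i) for i in range(500)], max_n=400)
        assert s.n == 400

    def test_empty_input(self):
        s = bubble_population_stats([])
        assert s.n == 0 and np.isnan(s.mean_mm)

    def test_known_population_recovered_within_standard_error(self):
        rng = np.random.default_rng(42)
        true_mean, true_sd, n = 2.0, 0.3, 400
        d = rng.normal(true_mean, true_sd, n)
        s = bubble_population_stats([_meas(v, i) for i, v in enumerate(d)])
        assert s.mean_mm == pytest.approx(true_mean, abs=3 * true_sd / np.sqrt(n))
        assert s.sd_mm == pytest.approx(true_sd, rel=0.15)
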