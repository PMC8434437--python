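"""Lumen detection: preprocessing, gradient CHT, darkest election, consensus."""

import numpy as np
import pytest

import carodop as cd
from carodop.segmentation import SegmentationParams

from conftest import disk_frame

SPACING = (0.1, 0.3)


class TestPreprocess:
    def test_constant_image_unchanged(self):
        f = np.full((100, 60), 37.0)
        out = cd.preprocess_frame(f, SPACING)
        assert np.allclose(out, 37.0)

    def test_noise_variance_strongly_reduced(self):
        rng = np.random.default_rng(0)
        frame, _ = disk_frame(0.0, 23.0, 3.0)
        noisy = frame.astype(float).copy()
        idx = rng.random(noisy.shape) < 0.05
        noisy[idx] = rng.choice([0.0, 255.0], size=idx.sum())
        out = cd.preprocess_frame(noisy, SPACING)
        bg = np.s_[20:80, 5:40]  # background patch away from the disk
        assert np.var(noisy[bg]) / max(np.var(out[bg]), 1e-12) >= 10.0

    def test_contrast_not_decreased_on_phantom(self, phantom_sequence):
        seq, truth = phantom_sequence
        raw = seq.frames[0].astype(float)
        pre = cd.preprocess_frame(raw, seq.pixel_spacing)
        ys = np.arange(raw.shape[0]) * SPACING[0]
        xs = seq.lateral_origin + np.arange(raw.shape[1]) * SPACING[1]
        d2 = (ys[:, None] - truth.center_y) ** 2 + (xs[None, :] - truth.center_x) ** 2
        inside = d2 <= (0.7 * truth.radius) ** 2
        outside = d2 >= (2 * truth.radius) ** 2
        raw_contrast = raw[outside].mean() - raw[inside].mean()
        pre_contrast = pre[outside].mean() - pre[inside].mean()
        assert pre_contrast >= raw_contrast

    def test_affine_intensity_rescale_invariance(self):
        """Detection is unchanged under global affine rescaling of intensities."""
        frame, origin = disk_frame(1.0, 23.0, 3.0)
        scaled = (frame.astype(float) * 0.31 + 40.0)
        a = cd.preprocess_frame(frame, SPACING)
        b = cd.preprocess_frame(scaled, SPACING)
        ca = cd.detect_dark_circles(a, SPACING, origin)
        cb = cd.detect_dark_circles(b, SPACING, origin)
        assert [(c.x, c.y, c.r) for c in ca] == [(c.x, c.y, c.r) for c in cb]


class TestDetectDarkCircles:
    @pytest.mark.parametrize("radius", [2.2, 3.0, 3.9])
    def test_noise_free_disk_recovered(self, radius):
        frame, origin = disk_frame(1.0, 23.0, radius)
        pre = cd.preprocess_frame(frame, SPACING)
        cands = cd.detect_dark_circles(pre, SPACING, origin)
        best = cd.select_darkest(pre, cands, SPACING, origin)
        iso = SegmentationParams().iso_spacing_mm
        assert abs(best.x - 1.0) <= iso and abs(best.y - 23.0) <= iso
        assert abs(best.r - radius) <= iso  # within one radius bin

    def test_uniform_image_gives_no_candidates(self):
        assert cd.detect_dark_circles(np.full((400, 128), 100.0), SPACING) == []

    def test_oversized_disk_not_matched(self):
        """A 5 mm-radius disk lies outside the configured 2.1-4.0 mm range and
        must not appear among the candidates."""
        frame, origin = disk_frame(0.0, 23.0, 5.0)
        pre = cd.preprocess_frame(frame, SPACING)
        cands = cd.detect_dark_circles(pre, SPACING, origin)
        iso = SegmentationParams().iso_spacing_mm
        assert all(c.r <= 4.0 + 1e-9 for c in cands)
        assert not any(abs(c.r - 5.0) <= iso for c in cands)

    def test_tiny_radius_range_rejected(self):
        with pytest.raises(ValueError):
            cd.detect_dark_circles(np.zeros((50, 50)), SPACING,
                                   params=SegmentationParams(r_min_mm=0.05, r_max_mm=0.2))

    def test_translation_equivariance(self):
        """Shifting the image shifts the detection by the same amount."""
        f1, origin = disk_frame(1.0, 22.0, 3.0)
        f2, _ = disk_frame(1.0 + 1.5, 22.0 + 1.5, 3.0)
        b1 = cd.select_darkest(f1, cd.detect_dark_circles(f1, SPACING, origin), SPACING, origin)
        b2 = cd.select_darkest(f2, cd.detect_dark_circles(f2, SPACING, origin), SPACING, origin)
        iso = SegmentationParams().iso_spacing_mm
        assert b2.x - b1.x == pytest.approx(1.5, abs=iso)
        assert b2.y - b1.y == pytest.approx(1.5, abs=iso)


class TestSelectDarkest:
    def _two_candidates(self):
        return [
            cd.CircleCandidate(x=-6.0, y=15.0, r=3.0),
            cd.CircleCandidate(x=6.0, y=28.0, r=3.0),
        ]

    def test_darkest_interior_wins(self):
        frame = np.full((400, 128), 200.0)
        ys = np.arange(400) * 0.1
        xs = -19.05 + np.arange(128) * 0.3
        frame[(ys[:, None] - 28.0) ** 2 + (xs[None, :] - 6.0) ** 2 <= 9.0] = 10.0
        frame[(ys[:, None] - 15.0) ** 2 + (xs[None, :] + 6.0) ** 2 <= 9.0] = 50.0
        best = cd.select_darkest(frame, self._two_candidates(), SPACING, -19.05)
        assert (best.x, best.y) == (6.0, 28.0)
        assert best.darkness == pytest.approx(10.0, abs=1.0)

    def test_single_candidate_returned(self):
        frame = np.full((400, 128), 100.0)
        only = [cd.CircleCandidate(x=0.0, y=20.0, r=3.0)]
        assert cd.select_darkest(frame, only, SPACING, -19.05) is only[0]

    def test_empty_list_gives_none(self):
        assert cd.select_darkest(np.zeros((10, 10)), [], SPACING) is None


class TestConsensus:
    def _cand(self, x, y, r, dark=10.0, frame=0):
        return cd.CircleCandidate(x=x, y=y, r=r, darkness=dark, frame_index=frame)

    def test_unanimous_triads(self):
        cands = [self._cand(1.2, 20.1, 3.0, frame=i) for i in range(15)]
        det = cd.consensus(cands)
        assert det.status == "ok"
        assert det.n_supporting_frames == 15
        assert (det.xc, det.yc, det.rc) == pytest.approx((1.2, 20.1, 3.0), abs=0.08)

    def test_majority_wins(self):
        a = [self._cand(1.2, 20.1, 3.0, frame=i) for i in range(8)]
        b = [self._cand(-5.0, 25.0, 2.4, frame=8 + i) for i in range(7)]
        det = cd.consensus(a + b)
        assert det.xc == pytest.approx(1.2, abs=0.08)
        assert det.n_supporting_frames == 8

    def test_all_frames_empty_fails(self):
        det = cd.consensus([None] * 15)
        assert det.status == "failed"

    def test_below_min_support_fails(self):
        det = cd.consensus([self._cand(0, 20, 3)] + [None] * 14)
        assert det.status == "failed"


class TestSegmentSequence:
    def test_phantom_centre_recovered(self, phantom_sequence):
        seq, truth = phantom_sequence
        det = cd.segment_sequence(seq)
        assert det.status == "ok"
        err = cd.distance_error((det.xc, det.yc), (truth.center_x, truth.center_y))
        assert err <= 0.43

    def test_vessel_free_sequence_fails(self):
        rng = np.random.default_rng(3)
        frames = rng.integers(80, 120, size=(15, 400, 128), dtype=np.uint8)
        seq = cd.BModeSequence(frames, SPACING, lateral_origin=-19.05)
        det = cd.segment_sequence(seq)
        assert det.status == "failed" or cd.distance_error(
            (det.xc, det.yc), (0.0, 23.0)) > 2.0

    def test_tilted_elliptical_lumen_still_found(self):
        """A 15 deg tilt makes the section mildly elliptical; detection must
        stay within 1 mm of the true centre."""
        truth = cd.PhantomTruth(center_x=-1.0, center_y=22.0, radius=3.0,
                                seed=7, lateral_stretch=1.0 / np.cos(np.radians(15.0)))
        seq = cd.make_phantom_sequence(truth)
        det = cd.segment_sequence(seq)
        assert det.status == "ok"
        assert cd.distance_error((det.xc, det.yc), (-1.0, 22.0)) <= 1.0
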