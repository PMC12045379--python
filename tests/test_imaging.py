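"""Fluctuation-map detection, trace extraction and colocalization."""

import itertools

import numpy as np
import pytest

import kinefp as kf
from kinefp.containers import MovieStack
from kinefp.exceptions import ConfigError
from kinefp.imaging import ROI, FluctuationMap
from kinefp.simulate import _gaussian_patch


def _movie(data, exposure=0.1, channel="ch0"):
    return MovieStack(data=np.asarray(data, dtype=float), exposure=exposure,
                      channel=channel)


class TestFluctuationMap:
    def test_constant_movie_zero(self):
        movie = _movie(np.full((50, 8, 8), 123.0))
        assert np.all(kf.compute_fluctuation_map(movie).data == 0)

    def test_single_alternating_pixel(self):
        data = np.zeros((40, 9, 9))
        data[::2, 4, 4] = 4000.0
        fmap = kf.compute_fluctuation_map(_movie(data)).data
        assert fmap[4, 4] == pytest.approx(4000.0)
        fmap[4, 4] = 0.0
        assert np.all(fmap == 0)

    def test_single_frame_rejected(self):
        with pytest.raises(ConfigError):
            kf.compute_fluctuation_map(_movie(np.zeros((1, 8, 8))))

    def test_depends_only_on_successive_differences(self, snr10_movie):
        movie, _ = snr10_movie
        fmap1 = kf.compute_fluctuation_map(movie).data
        # adding a constant offset per frame pair-preserving the diffs
        shifted = MovieStack(data=movie.data + 7.0, exposure=movie.exposure)
        np.testing.assert_allclose(
            kf.compute_fluctuation_map(shifted).data, fmap1, rtol=1e-5
        )

    def test_spot_centers_are_local_maxima(self, snr10_movie):
        movie, spots = snr10_movie
        fmap = kf.compute_fluctuation_map(movie).data
        for s in spots:
            ri, ci = round(s.row), round(s.col)
            patch = fmap[ri - 2 : ri + 3, ci - 2 : ci + 3]
            peak = np.unravel_index(np.argmax(patch), patch.shape)
            assert abs(peak[0] - 2) <= 1 and abs(peak[1] - 2) <= 1


class TestDetectRois:
    def test_zero_map_empty(self):
        fmap = FluctuationMap(data=np.zeros((16, 16)), exposure=0.1)
        assert kf.detect_rois(fmap, threshold=0.0) == []

    def test_nonmax_suppression_keeps_brighter(self):
        m = np.zeros((16, 16))
        m[8, 8] = 10.0
        m[8, 9] = 8.0
        fmap = FluctuationMap(data=m, exposure=0.1)
        rois = kf.detect_rois(fmap, min_separation=2.0, threshold=1.0)
        assert [(r.row, r.col) for r in rois] == [(8, 8)]

    def test_deterministic_ordering(self):
        m = np.zeros((16, 16))
        m[3, 3] = 5.0
        m[10, 10] = 9.0
        m[12, 4] = 5.0
        fmap = FluctuationMap(data=m, exposure=0.1)
        rois = kf.detect_rois(fmap, min_separation=2.0, threshold=1.0)
        assert [(r.row, r.col) for r in rois] == [(10, 10), (3, 3), (12, 4)]

    def test_translation_equivariance(self, snr10_movie):
        movie, _ = snr10_movie
        sub = movie.data[:300]
        rolled = np.roll(np.roll(sub, 2, axis=1), 3, axis=2)
        f1 = kf.compute_fluctuation_map(_movie(sub))
        f2 = kf.compute_fluctuation_map(_movie(rolled))
        thr = max(f1.data.mean(), f2.data.mean()) * 1.5
        r1 = {(r.row, r.col) for r in kf.detect_rois(f1, threshold=thr)}
        r2 = {(r.row, r.col) for r in kf.detect_rois(f2, threshold=thr)}
        shifted = {((a + 2) % 64, (b + 3) % 64) for a, b in r1}
        interior = {
            (a, b) for a, b in shifted if 2 <= a < 62 and 2 <= b < 62
        }
        assert interior <= r2

    def test_recall_and_precision_on_snr10_movie(self, snr10_movie):
        movie, spots = snr10_movie
        rois = kf.detect_rois(kf.compute_fluctuation_map(movie))
        det = [(r.row, r.col) for r in rois]
        true = [(round(s.row), round(s.col)) for s in spots]

        def near(a, b):
            return abs(a[0] - b[0]) <= 1 and abs(a[1] - b[1]) <= 1

        recall = np.mean([any(near(t, d) for d in det) for t in true])
        precision = np.mean([any(near(t, d) for t in true) for d in det])
        assert recall >= 0.95
        assert precision >= 0.95


class TestExtractTrace:
    def test_constant_window_and_ring(self):
        data = np.full((20, 9, 9), 5.0)   # ring level b = 5
        data[:, 3:6, 3:6] = 12.0          # window level c = 12
        trace = kf.extract_trace(_movie(data), ROI(row=4, col=4))
        np.testing.assert_allclose(trace.intensity, 9 * (12 - 5))

    def test_border_roi_rejected(self):
        movie = _movie(np.zeros((5, 8, 8)))
        with pytest.raises(ConfigError):
            kf.extract_trace(movie, ROI(row=1, col=4))

    def test_channel_mismatch_rejected(self):
        movie = _movie(np.zeros((5, 8, 8)), channel="Cy5")
        with pytest.raises(ConfigError):
            kf.extract_trace(movie, ROI(row=4, col=4, channel="Cy3"))

    def test_linearity_under_scaling(self, snr10_movie):
        movie, _ = snr10_movie
        sub = MovieStack(data=movie.data[:100], exposure=movie.exposure)
        doubled = MovieStack(data=2.0 * movie.data[:100],
                             exposure=movie.exposure)
        roi = ROI(row=20, col=20)
        t1 = kf.extract_trace(sub, roi).intensity
        t2 = kf.extract_trace(doubled, roi).intensity
        np.testing.assert_allclose(t2, 2.0 * t1, rtol=1e-6, atol=1e-6)

    def test_background_roi_statistics(self):
        rng = np.random.default_rng(0)
        sigma = 106.0
        data = 200.0 + rng.normal(0, sigma, size=(4000, 12, 12))
        trace = kf.extract_trace(_movie(data), ROI(row=6, col=6))
        assert abs(trace.intensity.mean()) < 0.2 * sigma
        # window sum contributes 3*sigma; the 9x scaled ring median adds
        # 9 * sigma * sqrt(pi/(2*16)) in quadrature
        expected_sd = sigma * np.sqrt(9 + 81 * np.pi / 32)
        assert trace.intensity.std() == pytest.approx(expected_sd, rel=0.1)

    def test_amplitude_matches_noise_aware_psf_oracle(self, snr10_movie):
        """Bound-minus-unbound amplitude equals the 3x3 PSF flux minus nine
        times the expected median of the noisy ring pixels."""
        movie, spots = snr10_movie
        rng = np.random.default_rng(1)
        for s in spots:
            ri, ci = round(s.row), round(s.col)
            rows, cols, w = _gaussian_patch(1.0, s.row, s.col, (64, 64))
            W = np.zeros((64, 64))
            W[rows, cols] = w
            block = 4000.0 * W[ri - 2 : ri + 3, ci - 2 : ci + 3]
            win = block[1:4, 1:4].sum()
            ring = np.delete(block.reshape(25),
                             [6, 7, 8, 11, 12, 13, 16, 17, 18])
            # expected ring median under per-pixel read noise (Monte Carlo)
            noisy = ring[None, :] + rng.normal(0, 106.0, size=(4000, 16))
            med = np.median(noisy, axis=1).mean()
            expected = win - 9.0 * med
            st = s.truth.states.astype(bool)
            if st.sum() < 50 or (~st).sum() < 50:
                continue
            trace = kf.extract_trace(movie, ROI(row=ri, col=ci))
            amp = trace.intensity[st].mean() - trace.intensity[~st].mean()
            assert amp == pytest.approx(expected, rel=0.05)


class TestColocalize:
    def test_identical_lists_radius_zero(self):
        rois = [ROI(row=r, col=c) for r, c in [(5, 5), (9, 3), (12, 12)]]
        matches, ua, ub = kf.colocalize_rois(rois, list(rois), radius=0.0)
        assert len(matches) == 3 and ua == [] and ub == []

    def test_empty_second_list(self):
        rois = [ROI(row=5, col=5)]
        matches, ua, ub = kf.colocalize_rois(rois, [], radius=2.0)
        assert matches == [] and ua == [0] and ub == []

    def test_negative_radius_rejected(self):
        with pytest.raises(ConfigError):
            kf.colocalize_rois([ROI(row=3, col=3)], [ROI(row=3, col=3)], -1.0)

    def test_jittered_copies_match(self):
        rng = np.random.default_rng(2)
        pts = rng.uniform(10, 90, size=(200, 2))
        # enforce mutual separation so the assignment is unambiguous
        keep = []
        for p in pts:
            if all(np.hypot(*(p - q)) > 6 for q in keep):
                keep.append(p)
        a = [ROI(row=int(round(p[0])), col=int(round(p[1]))) for p in keep]
        b = [
            ROI(row=r.row + int(round(rng.normal(0, 0.5))),
                col=r.col + int(round(rng.normal(0, 0.5))))
            for r in a
        ]
        matches, ua, ub = kf.colocalize_rois(a, b, radius=2.0)
        correct = sum(1 for i, j, _ in matches if i == j)
        assert correct / len(keep) >= 0.99

    def test_matches_brute_force_on_small_instances(self):
        # greedy closest-first matching equals exhaustive greedy ordering
        rng = np.random.default_rng(3)
        for _ in range(20):
            a = [ROI(row=int(r), col=int(c))
                 for r, c in rng.integers(0, 20, size=(5, 2))]
            b = [ROI(row=int(r), col=int(c))
                 for r, c in rng.integers(0, 20, size=(5, 2))]
            matches, _, _ = kf.colocalize_rois(a, b, radius=5.0)
            # brute force: sort all admissible pairs, take greedily
            pairs = sorted(
                (np.hypot(a[i].row - b[j].row, a[i].col - b[j].col), i, j)
                for i, j in itertools.product(range(5), range(5))
                if np.hypot(a[i].row - b[j].row, a[i].col - b[j].col) <= 5.0
            )
            used_a, used_b, expected = set(), set(), []
            for d, i, j in pairs:
                if i not in used_a and j not in used_b:
                    used_a.add(i)
                    used_b.add(j)
                    expected.append((i, j))
            assert [(i, j) for i, j, _ in matches] == expected
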