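"""Stain deconvolution, Otsu segmentation and nuclei QC features."""

import numpy as np
import pytest
from skimage import filters as skfilters

from stainqa.histology import (
    compare_feature_distributions,
    count_merged,
    nuclei_metrics,
    otsu_threshold,
    qc_stain_image,
    segment_nuclei,
    stain_deconvolve,
)
from stainqa.synthetic import (
    EOSIN,
    HAEMATOXYLIN,
    DegradationSpec,
    SceneParams,
    apply_degradation,
    render_pair,
    sample_scene,
)

HE = np.vstack([HAEMATOXYLIN, EOSIN])
RNG = np.random.default_rng(55)


class TestStainDeconvolve:
    def test_white_pixel_has_zero_concentration(self):
        img = np.ones((2, 2, 3))
        conc = stain_deconvolve(img, HE)
        np.testing.assert_allclose(conc, 0.0, atol=1e-12)

    def test_pure_haematoxylin_pixel_recovers_single_stain(self):
        c_true = 0.8
        rgb = np.power(10.0, -c_true * HAEMATOXYLIN)[None, None, :]
        conc = stain_deconvolve(np.broadcast_to(rgb, (3, 3, 3)), HE)
        assert conc[..., 0] == pytest.approx(c_true, abs=1e-9)
        assert np.abs(conc[..., 1]).max() < 1e-6

    def test_parallel_vectors_rejected(self):
        with pytest.raises(ValueError, match="singular"):
            stain_deconvolve(np.ones((2, 2, 3)),
                             np.vstack([HAEMATOXYLIN, HAEMATOXYLIN]))

    def test_negative_concentrations_clipped(self):
        rgb = RNG.random((4, 4, 3))
        conc = stain_deconvolve(rgb, HE)
        assert conc.min() >= 0.0


class TestOtsu:
    def test_separates_two_deltas(self):
        x = np.r_[np.full(50, 0.2), np.full(50, 0.8)]
        thr = otsu_threshold(x.reshape(10, 10))
        assert 0.2 < thr < 0.8

    def test_matches_exhaustive_search(self):
        x = RNG.random((16, 16))
        thr = otsu_threshold(x)
        # brute force: evaluate between-class variance at every bin edge
        counts, edges = np.histogram(x.ravel(), bins=256,
                                     range=(x.min(), x.max()))
        centers = (edges[:-1] + edges[1:]) / 2
        p = counts / counts.sum()
        best_k, best_v = None, -1.0
        for k in range(256):
            w0 = p[:k + 1].sum()
            w1 = 1 - w0
            if w0 == 0 or w1 == 0:
                continue
            m0 = (p[:k + 1] * centers[:k + 1]).sum() / w0
            m1 = (p[k + 1:] * centers[k + 1:]).sum() / w1
            v = w0 * w1 * (m0 - m1) ** 2
            if v > best_v:
                best_k, best_v = k, v
        assert thr == pytest.approx(edges[best_k + 1], abs=1e-12)

    def test_close_to_skimage_reference(self):
        x = RNG.normal(0.3, 0.05, (32, 32))
        x[:10] += 0.4
        ours = otsu_threshold(x)
        ref = skfilters.threshold_otsu(x, nbins=256)
        assert abs(ours - ref) < (x.max() - x.min()) / 128  # within a bin

    def test_shift_invariance(self):
        x = RNG.random((12, 12))
        assert otsu_threshold(x + 5.0) == pytest.approx(
            otsu_threshold(x) + 5.0, abs=1e-9)

    def test_constant_image_rejected(self):
        with pytest.raises(ValueError):
            otsu_threshold(np.ones((4, 4)))


class TestSegmentation:
    def test_blank_channel_yields_no_components(self):
        mask, labels, n = segment_nuclei(np.zeros((16, 16)))
        assert n == 0 and not mask.any()

    def test_planted_disks_recovered(self):
        scene = sample_scene(SceneParams(size=96, n_nuclei=(12, 12),
                                         radius_range=(3, 4)), seed=21)
        pair = render_pair(scene)
        conc = stain_deconvolve(pair.stain, HE)
        _, labels, n = segment_nuclei(conc[..., 0])
        assert n == 12

    def test_merge_diagnostic_flags_adjacent_disks(self):
        # two disks closer than the structuring size merge after dilation
        mask = np.zeros((32, 32), bool)
        rr, cc = np.mgrid[0:32, 0:32]
        centers = [(10.0, 10.0, 4.0), (10.0, 19.0, 4.0)]
        for r0, c0, rad in centers:
            mask |= (rr - r0) ** 2 + (cc - c0) ** 2 <= rad**2
        channel = np.where(mask, 1.0, 0.0)
        # bridge the gap so the components touch
        channel[9:12, 13:17] = 1.0
        _, labels, n = segment_nuclei(channel)
        assert n == 1
        assert count_merged(labels, centers) == 1


class TestNucleiMetrics:
    def test_empty_mask_sentinel(self):
        qc = nuclei_metrics(np.zeros((8, 8), bool))
        assert qc.n_components == 0
        assert qc.normalized_nuclei_count == 0.0
        assert np.isnan(qc.average_nuclei_area)

    def test_single_square_arithmetic(self):
        mask = np.zeros((100, 100), bool)
        mask[10:15, 20:25] = True
        qc = nuclei_metrics(mask)
        assert qc.n_components == 1
        assert qc.normalized_nuclei_count == pytest.approx(1e-4)
        assert qc.average_nuclei_area == pytest.approx(25.0)

    def test_normalized_count_identity_is_exact(self):
        for seed in range(5):
            scene = sample_scene(SceneParams(size=64), seed=600 + seed)
            qc = qc_stain_image(render_pair(scene).stain)
            assert qc.normalized_nuclei_count * qc.nuclei_mask.size == (
                qc.n_components)

    def test_fixture_recovery_within_ten_percent(self):
        rel_errors = []
        for seed in range(50):
            scene = sample_scene(SceneParams(size=64, n_nuclei=(6, 12),
                                             radius_range=(2.5, 4.0)),
                                 seed=700 + seed)
            qc = qc_stain_image(render_pair(scene).stain)
            k = len(scene.nuclei)
            rel_errors.append(abs(qc.n_components - k) / k)
        assert np.mean(rel_errors) <= 0.10


class TestFeatureDistributions:
    def _counts(self, seed, n=200, dropout=0.0):
        rng = np.random.default_rng(seed)
        out = []
        for i in range(n):
            scene = sample_scene(SceneParams(size=48, n_nuclei=(5, 10)),
                                 seed=int(rng.integers(2**31)))
            stain = render_pair(scene).stain
            if dropout:
                stain = apply_degradation(
                    stain, scene,
                    DegradationSpec("nuclei_dropout", dropout, seed=i))
            out.append(qc_stain_image(stain).n_components)
        return np.asarray(out, float)

    def test_identical_sets_have_zero_distance(self):
        a = self._counts(1, n=40)
        res = compare_feature_distributions(a, a.copy())
        assert res["hellinger"] == 0.0
        assert res["g_statistic"] == pytest.approx(0.0, abs=1e-9)

    def test_null_calibration(self):
        """Same-distribution sets test non-significant in >= 90% of replicates."""
        non_sig = 0
        for rep in range(20):
            rng = np.random.default_rng(5000 + rep)
            pooled = rng.poisson(8, 400).astype(float)
            res = compare_feature_distributions(pooled[:200], pooled[200:])
            non_sig += int(not res["significant"])
        assert non_sig >= 18

    def test_dropout_shifts_nuclei_count_distribution(self):
        clean_a = self._counts(11, n=60)
        clean_b = self._counts(12, n=60)
        degraded = self._counts(13, n=60, dropout=0.5)
        base = compare_feature_distributions(clean_a, clean_b)["hellinger"]
        shifted = compare_feature_distributions(clean_a, degraded)["hellinger"]
        assert shifted > base

    def test_order_permutation_invariance(self):
        a = self._counts(21, n=40)
        b = self._counts(22, n=40)
        res1 = compare_feature_distributions(a, b)
        res2 = compare_feature_distributions(
            np.random.default_rng(0).permutation(a), b)
        assert res1["hellinger"] == pytest.approx(res2["hellinger"])
        assert res1["g_statistic"] == pytest.approx(res2["g_statistic"])

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            compare_feature_distributions([], [1.0])
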