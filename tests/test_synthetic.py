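"""Ground-truth scenes, paired rendering and degradation operators."""

import numpy as np
import pytest
from scipy import stats as sps

from stainqa.images import Domain
from stainqa.metrics import mse
from stainqa.synthetic import (
    EOSIN,
    HAEMATOXYLIN,
    DegradationSpec,
    FixtureConfig,
    RenderParams,
    SceneParams,
    apply_degradation,
    build_fixture,
    render_pair,
    sample_scene,
)


class TestSampleScene:
    def test_empty_scene(self):
        scene = sample_scene(SceneParams(size=64, n_nuclei=(0, 0)), seed=1)
        assert scene.nuclei == ()
        assert not scene.nuclei_mask().any()

    def test_determinism_and_seed_sensitivity(self):
        params = SceneParams(size=64, n_nuclei=(8, 8), radius_range=(2, 4))
        s1 = sample_scene(params, seed=7)
        s2 = sample_scene(params, seed=7)
        assert s1.nuclei == s2.nuclei
        np.testing.assert_array_equal(s1.cytoplasm_field, s2.cytoplasm_field)
        s3 = sample_scene(params, seed=8)
        assert s1.nuclei != s3.nuclei

    def test_invariants_hold(self):
        scene = sample_scene(SceneParams(size=64, n_nuclei=(8, 8),
                                         radius_range=(2, 4)), seed=7)
        assert len(scene.nuclei) == 8
        for r0, c0, rad in scene.nuclei:
            assert rad > 0
            assert rad <= r0 <= 64 - rad
            assert rad <= c0 <= 64 - rad
        for i, (r0, c0, ra) in enumerate(scene.nuclei):
            for r1, c1, rb in scene.nuclei[i + 1:]:
                assert np.hypot(r0 - r1, c0 - c1) > ra + rb

    def test_invalid_radius_range_rejected(self):
        with pytest.raises(ValueError):
            SceneParams(size=32, radius_range=(2, 20))
        with pytest.raises(ValueError):
            SceneParams(size=8)

    def test_overfull_scene_records_shortfall(self):
        params = SceneParams(size=16, n_nuclei=(200, 200), radius_range=(2, 3))
        scene = sample_scene(params, seed=0)
        assert scene.n_requested == 200
        assert len(scene.nuclei) < 200


class TestRenderPair:
    def test_empty_scene_zero_cytoplasm_is_white(self):
        scene = sample_scene(SceneParams(size=32, n_nuclei=(0, 0)), seed=3)
        scene = type(scene)(width=32, height=32, nuclei=(),
                            cytoplasm_field=np.zeros((32, 32)), seed=3)
        params = RenderParams(af_background=0.0, af_nuclei_gain=0.0,
                              af_cytoplasm_gain=0.0, af_noise_std=0.01)
        pair = render_pair(scene, params)
        np.testing.assert_allclose(pair.stain.pixels, 1.0)
        assert np.abs(pair.af.pixels).max() < 0.06   # only the noise floor

    def test_mask_pixel_count_matches_disk_areas(self, rng):
        scene = sample_scene(SceneParams(size=64, n_nuclei=(12, 12)), seed=11)
        mask = scene.nuclei_mask()
        total = 0
        rr, cc = np.mgrid[0:64, 0:64]
        for r0, c0, rad in scene.nuclei:
            total += int(((rr - r0) ** 2 + (cc - c0) ** 2 <= rad**2).sum())
        assert mask.sum() == total

    def test_deconvolution_round_trip_recovers_mask(self):
        from stainqa.histology import stain_deconvolve
        scene = sample_scene(SceneParams(size=64, n_nuclei=(10, 10)), seed=5)
        pair = render_pair(scene)
        conc = stain_deconvolve(pair.stain,
                                np.vstack([HAEMATOXYLIN, EOSIN]))
        mask = scene.nuclei_mask().astype(float)
        corr = np.corrcoef(conc[..., 0].ravel(), mask.ravel())[0, 1]
        assert corr > 0.99

    def test_parallel_stain_vectors_rejected(self):
        with pytest.raises(ValueError, match="parallel"):
            RenderParams(stain_vector_e=tuple(HAEMATOXYLIN)).vectors()

    def test_domains_and_shapes(self, small_pair):
        assert small_pair.af.domain is Domain.AF
        assert small_pair.stain.domain is Domain.STAIN
        assert small_pair.af.pixels.shape == (32, 32)
        assert small_pair.stain.pixels.shape == (32, 32, 3)


class TestDegradations:
    @pytest.mark.parametrize("kind", ["nuclei_dropout", "gaussian_blur",
                                      "colour_shift", "additive_noise"])
    def test_zero_severity_is_identity(self, small_pair, kind):
        out = apply_degradation(small_pair.stain, small_pair.scene,
                                DegradationSpec(kind, 0.0, seed=1))
        np.testing.assert_array_equal(out.pixels, small_pair.stain.pixels)

    def test_full_dropout_equals_empty_render(self, small_pair):
        out = apply_degradation(small_pair.stain, small_pair.scene,
                                DegradationSpec("nuclei_dropout", 1.0, seed=1))
        empty = type(small_pair.scene)(
            width=32, height=32, nuclei=(),
            cytoplasm_field=small_pair.scene.cytoplasm_field,
            seed=small_pair.scene.seed)
        np.testing.assert_allclose(out.pixels, render_pair(empty).stain.pixels)

    def test_dropout_requires_scene(self, small_pair):
        with pytest.raises(ValueError, match="scene"):
            apply_degradation(small_pair.stain, None,
                              DegradationSpec("nuclei_dropout", 0.5, seed=1))

    def test_dropout_retention_matches_binomial_oracle(self):
        scene = sample_scene(SceneParams(size=64, n_nuclei=(8, 8)), seed=2)
        pair = render_pair(scene)
        kept = []
        for s in range(200):
            out = apply_degradation(pair.stain, scene,
                                    DegradationSpec("nuclei_dropout", 0.5,
                                                    seed=s))
            from stainqa.histology import qc_stain_image
            kept.append(qc_stain_image(out).n_components)
        # binomial(8, 0.5): mean 4, sd sqrt(2); sem over 200 draws
        sem = np.sqrt(8 * 0.25 / 200)
        assert abs(np.mean(kept) - 4.0) < 3 * sem + 0.3  # + segmentation slack

    def test_severity_validation(self):
        with pytest.raises(ValueError):
            DegradationSpec("nuclei_dropout", 1.5)
        with pytest.raises(ValueError):
            DegradationSpec("unknown_kind", 0.5)
        with pytest.raises(ValueError):
            DegradationSpec("gaussian_blur", -1.0)

    def test_compose_applies_parts_in_order(self, small_pair):
        spec = DegradationSpec("compose", parts=(
            DegradationSpec("gaussian_blur", 1.0, seed=1),
            DegradationSpec("additive_noise", 0.05, seed=2)))
        out = apply_degradation(small_pair.stain, small_pair.scene, spec)
        step1 = apply_degradation(small_pair.stain, small_pair.scene,
                                  spec.parts[0])
        step2 = apply_degradation(step1, small_pair.scene, spec.parts[1])
        np.testing.assert_array_equal(out.pixels, step2.pixels)

    def test_outputs_stay_in_unit_range(self, small_pair):
        for kind, sev in [("gaussian_blur", 3.0), ("colour_shift", 0.3),
                          ("additive_noise", 0.5)]:
            out = apply_degradation(small_pair.stain, small_pair.scene,
                                    DegradationSpec(kind, sev, seed=9))
            assert out.pixels.min() >= 0.0 and out.pixels.max() <= 1.0


def test_degradation_severity_monotonicity():
    """Mean degraded-vs-clean m.s.e. rises with severity (Spearman > 0.9)."""
    severities = [0.1, 0.5, 1.0, 2.0]
    mean_errs = []
    for sev in severities:
        errs = []
        for i in range(50):
            scene = sample_scene(SceneParams(size=32), seed=3000 + i)
            pair = render_pair(scene)
            out = apply_degradation(pair.stain, scene,
                                    DegradationSpec("gaussian_blur", sev,
                                                    seed=i))
            errs.append(mse(out.pixels, pair.stain.pixels))
        mean_errs.append(np.mean(errs))
    rho = sps.spearmanr(severities, mean_errs).statistic
    assert rho > 0.9


def test_paired_geometry_af_and_stain_masks_agree():
    """Nuclei masks segmented from AF and stain views overlap (IoU > 0.9)."""
    from stainqa.histology import qc_stain_image, segment_nuclei
    ious = []
    for i in range(10):
        scene = sample_scene(SceneParams(size=64, n_nuclei=(8, 12)),
                             seed=4000 + i)
        pair = render_pair(scene)
        af_mask, _, _ = segment_nuclei(pair.af.pixels)
        stain_mask = qc_stain_image(pair.stain).nuclei_mask
        inter = np.logical_and(af_mask, stain_mask).sum()
        union = np.logical_or(af_mask, stain_mask).sum()
        ious.append(inter / union)
    assert np.mean(ious) > 0.9


class TestBuildFixture:
    def test_manifest_counts_and_determinism(self, tmp_path):
        cfg = FixtureConfig(n_train=9, n_val=1, n_test=5, seed=3)
        m1 = build_fixture(cfg, tmp_path / "a")
        m2 = build_fixture(cfg, tmp_path / "b")
        import pandas as pd
        df = pd.read_csv(m1)
        assert len(df) == 15
        assert df.split.value_counts().to_dict() == {
            "train": 9, "test": 5, "val": 1}
        assert m1.read_bytes() == m2.read_bytes()

    def test_unwritable_path_raises(self, tmp_path):
        blocker = tmp_path / "not_a_dir"
        blocker.write_text("occupied")
        with pytest.raises(OSError):
            build_fixture(FixtureConfig(), blocker / "sub")
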