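"""Temporal voting heads, soft voting, thresholding and the ensemble."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stainqa.classifier import (
    ClassifierEnsemble,
    classify,
    extract_features,
    gradcam_sequence,
    head_forward,
    select_threshold_alpha,
    train_heads,
    vote,
)
from stainqa.cycle import CycleMode, CycleSequence
from stainqa.images import Domain, ImageFOV
from stainqa.nn import ConvBackbone, TemporalHead

RNG = np.random.default_rng(404)


def _make_sequence(T=2, size=32, seed=0):
    rng = np.random.default_rng(seed)
    frames = []
    for _ in range(T):
        frames.append(ImageFOV(rng.random((size, size)), Domain.AF))
        frames.append(ImageFOV(rng.random((size, size, 3)), Domain.STAIN))
    return CycleSequence(mode=CycleMode.VS_START, T=T, frames=frames)


class TestVote:
    def test_mean_and_identity(self):
        assert vote([0.2, 0.4, 0.9]) == pytest.approx(0.5)
        assert vote([0.73]) == 0.73
        with pytest.raises(ValueError):
            vote([])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=10))
    def test_matches_arithmetic_mean_and_bounds(self, scores):
        v = vote(scores)
        assert v == pytest.approx(sum(scores) / len(scores))
        assert min(scores) - 1e-12 <= v <= max(scores) + 1e-12


class TestExtractFeatures:
    def test_shape_contract_and_determinism(self):
        seq = _make_sequence(T=5)
        bb = ConvBackbone(c_feat=64, seed=1)
        f1 = extract_features(seq, bb)
        f2 = extract_features(seq, bb)
        assert f1.shape == (10, bb.feature_dim)
        assert bb.feature_dim == 128   # mean + sd per conv channel
        np.testing.assert_array_equal(f1, f2)

    def test_identical_frames_give_identical_rows(self):
        seq = _make_sequence(T=2, seed=3)
        seq.frames[1] = ImageFOV(seq.frames[3].pixels.copy(), Domain.STAIN)
        f = extract_features(seq, ConvBackbone(seed=1))
        np.testing.assert_array_equal(f[1], f[3])

    def test_permuting_frames_permutes_rows_only(self):
        seq = _make_sequence(T=3, seed=4)
        bb = ConvBackbone(seed=2)
        base = extract_features(seq, bb)
        swapped = CycleSequence(
            mode=seq.mode, T=seq.T,
            frames=[seq.frames[i] for i in (2, 1, 0, 3, 4, 5)])
        perm = extract_features(swapped, bb)
        np.testing.assert_array_equal(perm[0], base[2])
        np.testing.assert_array_equal(perm[2], base[0])
        np.testing.assert_array_equal(perm[3:], base[3:])


class TestHeadForward:
    def test_zero_parameters_give_symmetric_score(self):
        head = TemporalHead(4, 16, seed=0)
        for p in head.parameters():
            p.data = np.zeros_like(p.data)
        logits, s = head_forward(np.zeros((4, 16)), head)
        np.testing.assert_allclose(logits, 0.0)
        assert s == pytest.approx(0.5)

    def test_score_normalization_and_determinism(self):
        head = TemporalHead(4, 16, seed=1)
        feats = RNG.normal(size=(4, 16))
        logits, s = head_forward(feats, head)
        ex = np.exp(logits - logits.max())
        assert s + ex[0] / ex.sum() == pytest.approx(1.0, abs=1e-12)
        assert head_forward(feats, head)[1] == s

    def test_shape_validation(self):
        head = TemporalHead(4, 16, seed=1)
        with pytest.raises(ValueError):
            head_forward(np.zeros((6, 16)), head)


class TestAlphaSelection:
    def test_separated_case(self):
        alpha = select_threshold_alpha([0.7, 0.9, 0.1, 0.6], [1, 1, 0, 0])
        assert alpha == 0.7

    def test_overlap_case_keeps_sensitivity(self):
        alpha = select_threshold_alpha([0.5, 0.6], [1, 0])
        assert alpha == 0.5   # specificity 0, no error

    def test_self_consistency_sensitivity_is_one(self):
        for trial in range(20):
            rng = np.random.default_rng(trial)
            scores = rng.random(30)
            labels = rng.integers(0, 2, 30)
            if labels.sum() == 0:
                labels[0] = 1
            alpha = select_threshold_alpha(scores, labels)
            pred_pos = scores >= alpha
            assert np.all(pred_pos[labels == 1])

    def test_no_positives_rejected(self):
        with pytest.raises(ValueError):
            select_threshold_alpha([0.4], [0])


def _separable_features(n, two_t=4, c_feat=16, seed=0):
    """Synthetic feature matrices whose temporal drift encodes the label."""
    rng = np.random.default_rng(seed)
    feats, labels = [], []
    for i in range(n):
        label = i % 2
        base = rng.normal(size=c_feat)
        drift = (1.5 if label else 0.1) * np.arange(two_t)[:, None]
        noise = 0.3 * rng.normal(size=(two_t, c_feat))
        feats.append(base[None] + drift * rng.normal(size=c_feat) + noise)
        labels.append(label)
    return feats, np.array(labels)


class TestTrainHeads:
    def test_learns_separable_features_and_reduces_to_single(self):
        f_train, y_train = _separable_features(60, seed=1)
        f_val, y_val = _separable_features(20, seed=2)
        ens = train_heads(f_train, y_train, f_val, y_val, C=1, epochs=15)
        assert ens.n_heads == 1
        majority = max(y_val.mean(), 1 - y_val.mean())
        assert ens.history["heads"][0]["best_val_acc"] > majority

    def test_equal_seeds_give_identical_heads(self):
        f_train, y_train = _separable_features(30, seed=3)
        f_val, y_val = _separable_features(10, seed=4)
        ens = train_heads(f_train, y_train, f_val, y_val, C=2,
                          seeds=(7, 7), epochs=5)
        s1 = ens.heads[0].state_dict()
        s2 = ens.heads[1].state_dict()
        for k in s1:
            np.testing.assert_array_equal(s1[k], s2[k])

    def test_single_class_split_rejected(self):
        f, _ = _separable_features(10)
        with pytest.raises(ValueError, match="both classes"):
            train_heads(f, np.zeros(10, int), f, np.ones(10, int), C=1)

    def test_alpha_set_with_full_validation_sensitivity(self):
        f_train, y_train = _separable_features(40, seed=5)
        f_val, y_val = _separable_features(16, seed=6)
        ens = train_heads(f_train, y_train, f_val, y_val, C=2, epochs=10)
        voted = ens.history["val_voted_scores"]
        pos_scores = np.asarray(voted)[y_val == 1]
        assert np.all(pos_scores >= ens.alpha)


class TestClassifyAndArchive:
    def _tiny_trained_ensemble(self):
        rng = np.random.default_rng(9)
        T, size = 2, 32

        def seqs(n, seed):
            out, labels = [], []
            r = np.random.default_rng(seed)
            for i in range(n):
                label = i % 2
                frames = []
                for t in range(T):
                    sharp = r.random((size, size))
                    blur = sharp if not label else np.full_like(
                        sharp, sharp.mean()) + 0.02 * (t + 1) * r.random(
                            (size, size))
                    frames.append(ImageFOV(np.clip(sharp, 0, 1), Domain.AF))
                    frames.append(ImageFOV(
                        np.clip(np.repeat(blur[..., None], 3, -1), 0, 1),
                        Domain.STAIN))
                out.append(CycleSequence(CycleMode.VS_START, T, frames))
                labels.append(label)
            return out, np.array(labels)

        tr, y_tr = seqs(40, 1)
        va, y_va = seqs(16, 2)
        bb = ConvBackbone(seed=3)
        return train_heads(tr, y_tr, va, y_va, C=2, epochs=8, T=T,
                           backbone=bb), seqs(6, 3)

    def test_report_invariants_and_archive_round_trip(self, tmp_path):
        ens, (test_seqs, _) = self._tiny_trained_ensemble()
        rep = classify(test_seqs[0], ens)
        assert min(rep.per_head_scores) - 1e-12 <= rep.voted_score
        assert rep.voted_score <= max(rep.per_head_scores) + 1e-12
        assert rep.decision in ("positive", "negative")

        ens.save(tmp_path / "arch")
        back = ClassifierEnsemble.load(tmp_path / "arch")
        rep2 = classify(test_seqs[0], back)
        assert rep2.voted_score == pytest.approx(rep.voted_score, abs=1e-12)
        assert back.alpha == ens.alpha

    def test_untrained_ensemble_rejected(self):
        ens = ClassifierEnsemble(backbone=ConvBackbone(seed=0),
                                 heads=[TemporalHead(4, 64, seed=0)],
                                 head_seeds=[0], T=2, alpha=None)
        with pytest.raises(ValueError, match="threshold"):
            classify(_make_sequence(T=2), ens)


class TestGradcam:
    def test_shapes_and_nonnegativity(self):
        ens, (test_seqs, _) = (
            TestClassifyAndArchive()._tiny_trained_ensemble())
        seq = test_seqs[0]
        out = gradcam_sequence(seq, ens)
        assert out["maps"].shape == (2 * seq.T, seq.frames[0].height,
                                     seq.frames[0].width)
        assert out["time_averaged"].shape == (seq.frames[0].height,
                                              seq.frames[0].width)
        assert out["maps"].min() >= 0.0
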