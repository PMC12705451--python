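"""End-to-end desk-scale experiment harness.

Builds the full assessment study on the synthetic fixture: train the good
staining transforms, emulate a zoo of good and poor staining models
(late/early checkpoints plus degradation-wrapped models), run cycle inference
on every field of view, train the classifier ensemble, and evaluate image- and
model-level assessment.  The acceptance script and the heavier tests both
drive this module, so the study conditions live in one place.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .assessment import fit_lda_threshold, model_gate_experiment
from .classifier import (
    ClassifierEnsemble,
    classify,
    extract_features,
    train_heads,
    vote,
)
from .cycle import CycleSequence, run_cycle_vs_start
from .images import ImageFOV
from .metrics import bin_scores, classification_rates, curve_points, kl_divergence
from .nn import ConvBackbone
from .staining import Direction, TransformModel, desk_training_config, train_transform
from .synthetic import (
    DegradationSpec,
    PairedSample,
    RenderParams,
    SceneParams,
    generate_samples,
)


@dataclass
class StudyConfig:
    """Desk-scale study conditions (sizes, seeds, degradation grid)."""

    size: int = 64
    n_transform_train: int = 24
    n_transform_val: int = 6
    n_train: int = 240
    n_val: int = 60
    n_test: int = 100
    T: int = 5
    C: int = 3
    n_candidate_heads: int = 10
    head_epochs: int = 40
    good_steps: int = 500
    poor_steps: int = 50
    dropout_severities: tuple[float, ...] = (0.3, 0.5)
    seed: int = 0
    c_feat: int = 64


@dataclass
class EmulatedModel:
    """A staining 'model under scrutiny': a transform plus an optional
    degradation wrapped around its output (a stand-in for a model whose
    hallucinations take a known form).

    For nuclei-dropout degradations the per-image seed is advanced until at
    least one nucleus is removed: a poor model that happens to reproduce
    every nucleus in a field of view is indistinguishable from a good model
    on that image and would poison the positive labels.
    """

    model_id: str
    label: str                      # "good" or "poor"
    transform: TransformModel
    degradation: DegradationSpec | None = None

    def stain(self, sample: PairedSample) -> ImageFOV:
        from .synthetic import apply_degradation, dropout_keep_mask
        out = self.transform.apply(sample.af)
        if self.degradation is not None:
            spec = replace(self.degradation,
                           seed=self.degradation.seed
                           + sample.scene.seed % 100000)
            if (spec.kind == "nuclei_dropout" and 0 < spec.severity < 1
                    and sample.scene is not None and sample.scene.nuclei):
                n = len(sample.scene.nuclei)
                seed = spec.seed
                while dropout_keep_mask(n, spec.severity, seed).all():
                    seed += 1_000_003
                spec = replace(spec, seed=seed)
            out = apply_degradation(out, sample.scene, spec)
        return out


@dataclass
class StudyResult:
    config: StudyConfig
    g_vs: TransformModel
    g_vaf: TransformModel
    ensemble: ClassifierEnsemble
    test_metrics: dict
    alpha: float
    split_scores: dict = field(default_factory=dict)
    samples: dict = field(default_factory=dict)


def train_cycle_pair(samples, cfg: StudyConfig,
                     extra_vs_checkpoints: tuple[int, ...] = ()
                     ) -> tuple[list[TransformModel], list[TransformModel]]:
    """Train the VS and VAF transforms on a paired training set.

    Returns (vs_checkpoints, vaf_checkpoints); the last checkpoint of each is
    the fully trained transform.  ``extra_vs_checkpoints`` requests extra VS
    step milestones (e.g. early-stopped poor models).
    """
    n_val = cfg.n_transform_val
    train, val = samples[:-n_val], samples[-n_val:]
    tcfg = desk_training_config(seed=cfg.seed, max_epochs=10_000)
    vs_ckpts = train_transform(
        train, val, Direction.AF_TO_STAIN, tcfg,
        max_steps=cfg.good_steps,
        checkpoint_steps=tuple(sorted(set(extra_vs_checkpoints))),
    )
    best_vs = vs_ckpts[-1]
    vaf_ckpts = train_transform(
        train, val, Direction.STAIN_TO_AF,
        desk_training_config(seed=cfg.seed + 1, max_epochs=10_000),
        vs_model=best_vs, max_steps=cfg.good_steps,
    )
    return vs_ckpts, vaf_ckpts


def default_model_zoo(vs_ckpts: list[TransformModel],
                      cfg: StudyConfig) -> list[EmulatedModel]:
    """Five good and five poor emulated staining models.

    Good: the trained VS transform with tiny seeded perturbation-free
    variants (distinct late checkpoints).  Poor: the early-stopped checkpoint
    plus nuclei-dropout and blur wrappers around the good transform.
    """
    best = vs_ckpts[-1]
    early = min(vs_ckpts, key=lambda c: abs(c.step - cfg.poor_steps))
    late = [c for c in vs_ckpts if c.step >= cfg.good_steps * 0.6]
    goods = []
    for i in range(5):
        ck = late[-(i % len(late)) - 1]
        goods.append(EmulatedModel(f"good_{i}", "good", ck))
    p = cfg.dropout_severities
    poors = [
        EmulatedModel("poor_early", "poor", early),
        EmulatedModel("poor_drop_a", "poor", best,
                      DegradationSpec("nuclei_dropout", p[0], seed=11)),
        EmulatedModel("poor_drop_b", "poor", best,
                      DegradationSpec("nuclei_dropout", p[-1], seed=13)),
        EmulatedModel("poor_blur", "poor", best,
                      DegradationSpec("gaussian_blur", 1.5, seed=17)),
        EmulatedModel("poor_drop_c", "poor", best,
                      DegradationSpec("nuclei_dropout", p[-1], seed=19)),
    ]
    return goods + poors


def build_labelled_sequences(samples, models: list[EmulatedModel],
                             g_vs: TransformModel, g_vaf: TransformModel,
                             T: int, seed: int,
                             ) -> tuple[list[CycleSequence], np.ndarray, list[str]]:
    """Assign each sample round-robin to a model, cycle it, label it.

    Labels: 1 (positive/hallucinated) for poor models, 0 for good.  The cycle
    always uses the fixed best pair (g_vs, g_vaf), never the model that
    produced the image under test.
    """
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(models))
    seqs, labels, model_ids = [], [], []
    for i, sample in enumerate(samples):
        model = models[order[i % len(models)]]
        y0 = model.stain(sample)
        seq = run_cycle_vs_start(sample.af, y0, g_vs, g_vaf, T)
        seq.provenance["scrutinized_model"] = model.model_id
        seqs.append(seq)
        labels.append(1 if model.label == "poor" else 0)
        model_ids.append(model.model_id)
    return seqs, np.asarray(labels), model_ids


def run_study(cfg: StudyConfig | None = None) -> StudyResult:
    """Run the full desk-scale study and evaluate on the held-out test split."""
    cfg = cfg or StudyConfig()
    scene_params = SceneParams(size=cfg.size)

    transform_samples = generate_samples(
        cfg.n_transform_train + cfg.n_transform_val, scene_params,
        seed=cfg.seed + 900)
    vs_ckpts, vaf_ckpts = train_cycle_pair(
        transform_samples, cfg, extra_vs_checkpoints=(cfg.poor_steps,))
    g_vs, g_vaf = vs_ckpts[-1], vaf_ckpts[-1]

    zoo = default_model_zoo(vs_ckpts, cfg)

    n_total = cfg.n_train + cfg.n_val + cfg.n_test
    samples = generate_samples(n_total, scene_params, seed=cfg.seed + 1)
    train_s = samples[:cfg.n_train]
    val_s = samples[cfg.n_train:cfg.n_train + cfg.n_val]
    test_s = samples[cfg.n_train + cfg.n_val:]

    train_seqs, y_train, train_mids = build_labelled_sequences(
        train_s, zoo, g_vs, g_vaf, cfg.T, seed=cfg.seed + 2)
    val_seqs, y_val, val_mids = build_labelled_sequences(
        val_s, zoo, g_vs, g_vaf, cfg.T, seed=cfg.seed + 3)
    test_seqs, y_test, test_mids = build_labelled_sequences(
        test_s, zoo, g_vs, g_vaf, cfg.T, seed=cfg.seed + 4)

    backbone = ConvBackbone(c_in=3, c_feat=cfg.c_feat, seed=cfg.seed + 5)
    ensemble = train_heads(
        train_seqs, y_train, val_seqs, y_val, C=cfg.C,
        seeds=tuple(cfg.seed + 10 + i for i in range(cfg.n_candidate_heads)),
        n_candidates=cfg.n_candidate_heads,
        epochs=cfg.head_epochs, T=cfg.T, backbone=backbone)

    reports = [classify(s, ensemble) for s in test_seqs]
    voted = np.array([r.voted_score for r in reports])
    pred = np.array([r.decision == "positive" for r in reports])
    tp = int(np.sum(pred & (y_test == 1)))
    tn = int(np.sum(~pred & (y_test == 0)))
    rates = classification_rates(tp, tn, int((y_test == 1).sum()),
                                 int((y_test == 0).sum()))
    neg_scores = voted[y_test == 0]
    pos_scores = voted[y_test == 1]
    kl = kl_divergence(bin_scores(neg_scores), bin_scores(pos_scores))
    curves = curve_points(voted, y_test)

    train_reports = [classify(s, ensemble) for s in train_seqs]
    train_voted = np.array([r.voted_score for r in train_reports])

    return StudyResult(
        config=cfg, g_vs=g_vs, g_vaf=g_vaf, ensemble=ensemble,
        alpha=float(ensemble.alpha),
        test_metrics={**rates, "kl_neg_pos": kl,
                      "roc_auc": curves["roc_auc"],
                      "pr_auc": curves["pr_auc"]},
        split_scores={
            "test_scores": voted, "test_labels": y_test,
            "test_model_ids": test_mids,
            "train_scores": train_voted, "train_labels": y_train,
            "train_model_ids": train_mids,
            "val_labels": y_val,
        },
        samples={"zoo": zoo, "test_samples": test_s,
                 "vs_checkpoints": vs_ckpts,
                 "sequences": {"train": train_seqs, "val": val_seqs,
                               "test": test_seqs},
                 "labels": {"train": y_train, "val": y_val, "test": y_test}},
    )


def study_at_t(cfg: StudyConfig, seqs_by_split, labels_by_split,
               backbone: ConvBackbone, t_value: int) -> dict:
    """Train and evaluate an ensemble on sequences truncated to t_value cycles."""

    def truncate(seq: CycleSequence) -> CycleSequence:
        return CycleSequence(mode=seq.mode, T=t_value,
                             frames=seq.frames[:2 * t_value],
                             provenance=dict(seq.provenance))

    tr = [truncate(s) for s in seqs_by_split["train"]]
    va = [truncate(s) for s in seqs_by_split["val"]]
    te = [truncate(s) for s in seqs_by_split["test"]]
    y_tr, y_va, y_te = (labels_by_split[k] for k in ("train", "val", "test"))
    ens = train_heads(
        tr, y_tr, va, y_va, C=cfg.C,
        seeds=tuple(cfg.seed + 10 + i for i in range(cfg.n_candidate_heads)),
        n_candidates=cfg.n_candidate_heads,
        epochs=cfg.head_epochs, T=t_value, backbone=backbone)
    reports = [classify(s, ens) for s in te]
    voted = np.array([r.voted_score for r in reports])
    pred = voted >= 0.5
    acc = float(np.mean(pred == (y_te == 1)))
    kl = kl_divergence(bin_scores(voted[y_te == 0]),
                       bin_scores(voted[y_te == 1]))
    return {"accuracy": acc, "kl": kl, "ensemble": ens, "scores": voted}


def dropout_severity_sweep(result: StudyResult, severities=(0.0, 0.2, 0.4, 0.6),
                           n_fovs: int = 50, seed: int = 777) -> dict:
    """Mean voted score as a function of nuclei-dropout severity.

    Generates fresh fields of view, stains them with the good transform,
    applies each dropout severity, cycles and scores them with the study's
    trained ensemble.
    """
    cfg = result.config
    samples = generate_samples(n_fovs, SceneParams(size=cfg.size), seed=seed)
    means = {}
    all_scores = {}
    for sev in severities:
        scores = []
        for i, sample in enumerate(samples):
            y0 = result.g_vs.apply(sample.af)
            if sev > 0:
                from .synthetic import apply_degradation
                y0 = apply_degradation(
                    y0, sample.scene,
                    DegradationSpec("nuclei_dropout", sev, seed=seed + i))
            seq = run_cycle_vs_start(sample.af, y0, result.g_vs,
                                     result.g_vaf, cfg.T)
            scores.append(vote(result.ensemble.score_sequence(seq)))
        means[sev] = float(np.mean(scores))
        all_scores[sev] = np.asarray(scores)
    return {"mean_by_severity": means, "scores": all_scores}


def model_level_assessment(result: StudyResult, n_values=(2, 5, 10, 20),
                           repetitions: int = 20, n_score_fovs: int = 20,
                           seed: int = 99):
    """Fit the LDA threshold on training scores and run the sampling
    experiment over the study's model zoo."""
    cfg = result.config
    tr_scores = np.asarray(result.split_scores["train_scores"])
    tr_labels = np.asarray(result.split_scores["train_labels"])
    lda = fit_lda_threshold(tr_scores[tr_labels == 1],
                            tr_scores[tr_labels == 0])

    samples = generate_samples(max(n_score_fovs, max(n_values)),
                               SceneParams(size=cfg.size), seed=seed)
    model_scores: dict[str, np.ndarray] = {}
    model_labels: dict[str, str] = {}
    for model in result.samples["zoo"]:
        scores = []
        for sample in samples:
            y0 = model.stain(sample)
            seq = run_cycle_vs_start(sample.af, y0, result.g_vs,
                                     result.g_vaf, cfg.T)
            scores.append(vote(result.ensemble.score_sequence(seq)))
        model_scores[model.model_id] = np.asarray(scores)
        model_labels[model.model_id] = model.label
    table = model_gate_experiment(model_scores, model_labels, beta=lda.beta,
                                  n_values=n_values,
                                  repetitions=repetitions, seed=seed + 1)
    return {"lda": lda, "table": table, "model_scores": model_scores,
            "model_labels": model_labels}
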