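"""Ensemble temporal classifier over cycle-inference sequences.

A frozen convolutional backbone embeds each of the 2T frames of a cycle
sequence into a feature vector; C independently seeded temporal voting heads
(two temporal 1x1 convolutions collapsing the time axis, then two dense
layers) each emit a confidence score in [0, 1] — higher means the starting
image is more likely hallucinated.  Soft voting averages the C scores, and a
100%-sensitivity threshold alpha fitted on the validation set turns the voted
score into an accept/reject decision.

Optionally, class-activation (Grad-CAM style) heat maps localize the image
content driving a positive decision, per time step and time-averaged.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .cycle import CycleSequence
from .images import Domain
from .nn import Adam, ConvBackbone, TemporalHead, Tensor
from .staining import bce_loss


# ---------------------------------------------------------------------------
# feature extraction
# ---------------------------------------------------------------------------

def _frame_to_chw(frame, n_channels: int) -> np.ndarray:
    """Channels-first frame array, replicating 1-channel AF frames as needed."""
    px = frame.pixels
    if px.ndim == 2:
        chw = np.repeat(px[None], n_channels, axis=0)
    else:
        chw = np.moveaxis(px, -1, 0)
        if chw.shape[0] != n_channels:
            raise ValueError(f"frame has {chw.shape[0]} channels, "
                             f"backbone expects {n_channels}")
    return chw


def extract_features(seq: CycleSequence, backbone: ConvBackbone) -> np.ndarray:
    """Embed each frame independently; returns a (2T, C_f) feature matrix."""
    batch = np.stack([_frame_to_chw(f, backbone.in_channels)
                      for f in seq.frames])
    return backbone(Tensor(batch)).data


def vote(per_head_scores) -> float:
    """Soft voting: the arithmetic mean of the per-head confidence scores."""
    scores = list(per_head_scores)
    if not scores:
        raise ValueError("cannot vote over an empty score list")
    return float(np.mean(scores))


def _softmax_positive(logits: Tensor) -> Tensor:
    """(B, 2) logits -> probability of the positive class (index 1)."""
    shifted = logits - logits.data.max(axis=-1, keepdims=True)
    ex = shifted.exp()
    return ex[..., 1] / ex.sum(axis=-1)


def head_forward(features: np.ndarray, head: TemporalHead
                 ) -> tuple[np.ndarray, float]:
    """Run one head on a (2T, C_f) feature matrix.

    Returns the two class logits and the positive-class softmax probability.
    """
    f = np.asarray(features, float)
    if f.ndim != 2 or f.shape[0] != head.two_t:
        raise ValueError(f"expected ({head.two_t}, C_f) features, got {f.shape}")
    logits = head(Tensor(f[None]))
    score = float(_softmax_positive(logits).data[0])
    return logits.data[0], score


# ---------------------------------------------------------------------------
# ensemble container
# ---------------------------------------------------------------------------

@dataclass
class ConfidenceReport:
    """Per-head and voted confidence scores with the threshold decision."""

    per_head_scores: list[float]
    voted_score: float
    logit: float                      # logit-transform of the voted score
    decision: str                     # "positive" (reject) / "negative" (accept)
    alpha: float
    provenance: dict = field(default_factory=dict)


@dataclass
class ClassifierEnsemble:
    """Frozen backbone + C trained temporal heads + decision threshold."""

    backbone: ConvBackbone
    heads: list[TemporalHead]
    head_seeds: list[int]
    T: int
    alpha: float | None = None
    feature_stats: tuple[np.ndarray, np.ndarray] | None = None
    history: dict = field(default_factory=dict)

    @property
    def n_heads(self) -> int:
        return len(self.heads)

    def _standardize(self, feats: np.ndarray) -> np.ndarray:
        if self.feature_stats is None:
            return feats
        mu, sd = self.feature_stats
        return (feats - mu) / sd

    def scores_from_features(self, feats: np.ndarray) -> list[float]:
        z = self._standardize(feats)
        return [head_forward(z, h)[1] for h in self.heads]

    def score_sequence(self, seq: CycleSequence) -> list[float]:
        if len(seq.frames) != 2 * self.T:
            raise ValueError(f"sequence has {len(seq.frames)} frames, "
                             f"ensemble expects {2 * self.T}")
        return self.scores_from_features(extract_features(seq, self.backbone))

    # -- archive -----------------------------------------------------------
    def save(self, out_dir: str | Path) -> Path:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        meta = {
            "c_feat": self.backbone.c_feat,
            "in_channels": self.backbone.in_channels,
            "backbone_seed": self.history.get("backbone_seed", 0),
            "head_seeds": self.head_seeds,
            "T": self.T,
            "alpha": self.alpha,
            "has_feature_stats": self.feature_stats is not None,
        }
        (out_dir / "ensemble.json").write_text(json.dumps(meta, indent=2))
        np.savez(out_dir / "backbone.npz", **self.backbone.state_dict())
        for i, head in enumerate(self.heads):
            np.savez(out_dir / f"head_{i}.npz", **head.state_dict())
        if self.feature_stats is not None:
            np.savez(out_dir / "feature_stats.npz",
                     mu=self.feature_stats[0], sd=self.feature_stats[1])
        return out_dir

    @classmethod
    def load(cls, out_dir: str | Path) -> "ClassifierEnsemble":
        out_dir = Path(out_dir)
        meta = json.loads((out_dir / "ensemble.json").read_text())
        backbone = ConvBackbone(meta["in_channels"], meta["c_feat"],
                                seed=meta["backbone_seed"])
        with np.load(out_dir / "backbone.npz") as data:
            backbone.load_state_dict({k: data[k] for k in data.files})
        backbone.freeze()
        heads = []
        for i, seed in enumerate(meta["head_seeds"]):
            head = TemporalHead(2 * meta["T"], backbone.feature_dim, seed=seed)
            with np.load(out_dir / f"head_{i}.npz") as data:
                head.load_state_dict({k: data[k] for k in data.files})
            heads.append(head)
        stats = None
        if meta["has_feature_stats"]:
            with np.load(out_dir / "feature_stats.npz") as data:
                stats = (data["mu"], data["sd"])
        return cls(backbone=backbone, heads=heads,
                   head_seeds=list(meta["head_seeds"]), T=meta["T"],
                   alpha=meta["alpha"], feature_stats=stats,
                   history={"backbone_seed": meta["backbone_seed"]})


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _features_for(sequences, backbone: ConvBackbone) -> np.ndarray:
    return np.stack([extract_features(s, backbone) for s in sequences])


def _batch_scores(head: TemporalHead, feats: np.ndarray) -> Tensor:
    logits = head(Tensor(feats))
    return _softmax_positive(logits)


def train_heads(train_sequences, train_labels, val_sequences, val_labels,
                C: int = 3, seeds: tuple[int, ...] | None = None,
                epochs: int = 40, T: int | None = None,
                backbone: ConvBackbone | None = None,
                learning_rate: float = 1e-3, batch_size: int = 32,
                n_candidates: int | None = None,
                ) -> ClassifierEnsemble:
    """Train independently seeded voting heads and assemble the ensemble.

    Each head minimizes the base-10 BCE between its positive-class softmax
    probability and the 0/1 label; the checkpoint with the best validation
    accuracy (at threshold 0.5) is kept per head.  The backbone stays frozen;
    frame features are computed once and standardized with training-set
    statistics.

    When ``n_candidates`` exceeds ``C``, that many candidate heads are
    trained and the ensemble is the best C-subset by voted validation
    accuracy (exhaustive search; ties broken by lower mean validation BCE of
    the voted score, then lexicographic seed order).  After selection,
    ``alpha`` is set to the 100%-sensitivity threshold on the validation
    voted scores.

    ``train_sequences`` may be :class:`CycleSequence` objects or precomputed
    (2T, C_f) feature matrices.
    """
    y_train = np.asarray(train_labels, int)
    y_val = np.asarray(val_labels, int)
    for name, y in (("training", y_train), ("validation", y_val)):
        if len(np.unique(y)) < 2:
            raise ValueError(f"{name} split must contain both classes")

    if isinstance(train_sequences[0], CycleSequence):
        if T is None:
            T = train_sequences[0].T
        if backbone is None:
            backbone = ConvBackbone(seed=0)
        f_train = _features_for(train_sequences, backbone)
        f_val = _features_for(val_sequences, backbone)
    else:
        f_train = np.stack([np.asarray(f, float) for f in train_sequences])
        f_val = np.stack([np.asarray(f, float) for f in val_sequences])
        if T is None:
            T = f_train.shape[1] // 2
        if backbone is None:
            backbone = ConvBackbone(seed=0)

    mu = f_train.mean(axis=(0, 1), keepdims=False)
    sd = f_train.std(axis=(0, 1), keepdims=False)
    sd = np.where(sd > 0, sd, 1.0)
    z_train = (f_train - mu) / sd
    z_val = (f_val - mu) / sd

    n_candidates = C if n_candidates is None else n_candidates
    if n_candidates < C:
        raise ValueError("n_candidates must be >= C")
    if seeds is None:
        seeds = tuple(range(n_candidates))
    if len(seeds) != n_candidates:
        raise ValueError("need one seed per candidate head")

    two_t = z_train.shape[1]
    c_feat = z_train.shape[2]
    heads: list[TemporalHead] = []
    histories = []
    for seed in seeds:
        head = TemporalHead(two_t, c_feat, seed=seed)
        opt = Adam(head.parameters(), lr=learning_rate)
        rng = np.random.default_rng(seed)
        best_acc, best_state, best_loss = -1.0, head.state_dict(), np.inf
        n = len(z_train)
        for _epoch in range(epochs):
            order = rng.permutation(n)
            for b0 in range(0, n, batch_size):
                idx = order[b0:b0 + batch_size]
                scores = _batch_scores(head, z_train[idx])
                loss = bce_loss(scores, y_train[idx].astype(float))
                opt.zero_grad()
                loss.backward()
                opt.step()
            val_scores = _batch_scores(head, z_val).data
            val_acc = float(np.mean((val_scores >= 0.5) == (y_val == 1)))
            val_loss = bce_loss(val_scores, y_val.astype(float))
            if val_acc > best_acc or (val_acc == best_acc
                                      and val_loss < best_loss):
                best_acc, best_loss = val_acc, val_loss
                best_state = head.state_dict()
        head.load_state_dict(best_state)
        head.freeze()
        heads.append(head)
        histories.append({"seed": int(seed), "best_val_acc": best_acc,
                          "best_val_loss": float(best_loss)})

    # per-candidate validation scores for subset selection and voting
    val_scores = np.stack([_batch_scores(h, z_val).data for h in heads])

    if n_candidates > C:
        import itertools

        def subset_key(combo):
            voted = val_scores[list(combo)].mean(axis=0)
            acc = float(np.mean((voted >= 0.5) == (y_val == 1)))
            loss = bce_loss(voted, y_val.astype(float))
            return (-acc, loss, tuple(seeds[i] for i in combo))

        best_combo = min(itertools.combinations(range(n_candidates), C),
                         key=subset_key)
    else:
        best_combo = tuple(range(C))
    chosen_heads = [heads[i] for i in best_combo]
    chosen_seeds = [int(seeds[i]) for i in best_combo]

    ensemble = ClassifierEnsemble(
        backbone=backbone, heads=chosen_heads, head_seeds=chosen_seeds, T=T,
        feature_stats=(mu, sd),
        history={"heads": [histories[i] for i in best_combo],
                 "candidate_heads": histories,
                 "backbone_seed": getattr(backbone, "seed", 0)},
    )
    voted = list(val_scores[list(best_combo)].mean(axis=0))
    ensemble.alpha = select_threshold_alpha(voted, y_val)
    ensemble.history["val_voted_scores"] = voted
    return ensemble


def select_threshold_alpha(val_voted_scores, val_labels) -> float:
    """Largest threshold with validation sensitivity 1.0.

    With the decision rule ``positive iff score >= alpha``, that threshold is
    the minimum voted score among validation positives; it maximizes
    specificity subject to perfect sensitivity on the validation set.
    """
    scores = np.asarray(val_voted_scores, float)
    labels = np.asarray(val_labels, int)
    pos = scores[labels == 1]
    if pos.size == 0:
        raise ValueError("no positive examples in the validation set")
    return float(pos.min())


def classify(seq: CycleSequence, ensemble: ClassifierEnsemble
             ) -> ConfidenceReport:
    """Score a sequence with every head, vote, and threshold at alpha."""
    if ensemble.alpha is None:
        raise ValueError("ensemble has no decision threshold; train it first")
    per_head = ensemble.score_sequence(seq)
    voted = vote(per_head)
    clamped = min(max(voted, 1e-7), 1 - 1e-7)
    logit = float(np.log(clamped / (1 - clamped)))
    decision = "positive" if voted >= ensemble.alpha else "negative"
    return ConfidenceReport(
        per_head_scores=per_head, voted_score=voted, logit=logit,
        decision=decision, alpha=ensemble.alpha,
        provenance=dict(seq.provenance),
    )


# ---------------------------------------------------------------------------
# class-activation maps
# ---------------------------------------------------------------------------

def gradcam_sequence(seq: CycleSequence, ensemble: ClassifierEnsemble
                     ) -> dict[str, np.ndarray]:
    """Per-time-step positive-class activation maps, averaged over heads.

    For each head, the gradient of the positive logit with respect to the
    backbone's last convolutional activation weights the activation channels
    (spatially averaged gradients); the rectified weighted sum is upsampled
    to frame resolution.  Returns ``{"maps": (2T, H, W), "time_averaged":
    (H, W)}``; maps are non-negative.
    """
    if not hasattr(ensemble.backbone, "c3"):
        raise NotImplementedError(
            "backbone does not expose an internal activation layer")
    backbone = ensemble.backbone
    frames = np.stack([_frame_to_chw(f, backbone.in_channels)
                       for f in seq.frames])
    h_img, w_img = frames.shape[2], frames.shape[3]

    x = Tensor(frames, requires_grad=True)
    feat, act = backbone(x, return_activation=True)     # act: (2T, C, h, w)
    if ensemble.feature_stats is not None:
        mu, sd = ensemble.feature_stats
        feat = (feat - mu) / sd

    accumulated = np.zeros((frames.shape[0], act.shape[2], act.shape[3]))
    for head in ensemble.heads:
        logits = head(feat.reshape(1, *feat.shape))
        act.grad = None
        # clear any grads left from the previous head
        logits_pos = logits[0, 1]
        for p in backbone.parameters():
            p.grad = None
        logits_pos.backward()
        g = act.grad                                    # (2T, C, h, w)
        weights = g.mean(axis=(2, 3), keepdims=True)    # (2T, C, 1, 1)
        cam = np.maximum((weights * act.data).sum(axis=1), 0.0)
        accumulated += cam
        x.grad = None
    accumulated /= ensemble.n_heads
    zoom = (1, h_img / accumulated.shape[1], w_img / accumulated.shape[2])
    maps = ndimage.zoom(accumulated, zoom, order=1)
    maps = np.maximum(maps, 0.0)
    return {"maps": maps, "time_averaged": maps.mean(axis=0)}
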