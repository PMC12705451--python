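"""Model-level acceptance: LDA threshold on score logits and the sampling
experiment harness.

A whole staining model is accepted or rejected from the voted confidence
scores of N of its images: class-conditional Gaussians are fitted to the
logit-transformed scores of positive (hallucinated) and negative (clean)
training images, the discriminant threshold ``beta`` is the equal-density
point between the two class means, and a model is rejected when the mean raw
score of its N images reaches ``beta`` (mapped back to score space).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .metrics import bin_scores, kl_divergence

_CLAMP = 1e-7


class AmbiguousThresholdError(ValueError):
    """No equal-density root lies between the two class means."""

    def __init__(self, roots):
        self.roots = tuple(roots)
        super().__init__(f"no discriminant root between the class means; "
                         f"roots: {self.roots}")


def _logit(s: np.ndarray) -> np.ndarray:
    s = np.clip(np.asarray(s, float), _CLAMP, 1 - _CLAMP)
    return np.log(s / (1 - s))


def _inv_logit(t: float) -> float:
    return float(1.0 / (1.0 + np.exp(-t)))


@dataclass(frozen=True)
class LdaThreshold:
    """Two fitted logit-space Gaussians and their equal-density point."""

    mu1: float        # positive (hallucinated) class
    sigma1: float
    mu2: float        # negative (clean) class
    sigma2: float
    beta_logit: float
    beta: float       # beta_logit mapped back to score space

    def residual(self, t: float | None = None) -> float:
        """Equal-density condition residual at ``t`` (default: the root)."""
        t = self.beta_logit if t is None else t
        lhs = np.log(self.sigma1) + (t - self.mu1) ** 2 / (2 * self.sigma1**2)
        rhs = np.log(self.sigma2) + (t - self.mu2) ** 2 / (2 * self.sigma2**2)
        return float(lhs - rhs)


def solve_equal_density(mu1: float, sigma1: float, mu2: float, sigma2: float
                        ) -> float:
    """Root of the equal-density condition between the two means.

    ``log(s1) + (b-mu1)^2/(2 s1^2) = log(s2) + (b-mu2)^2/(2 s2^2)``.
    Equal variances give the midpoint; otherwise the quadratic has two roots
    and the decision boundary is the one between the means (the other is a
    spurious far-tail crossing).
    """
    if sigma1 <= 0 or sigma2 <= 0:
        raise ValueError("sigmas must be positive")
    if np.isclose(sigma1, sigma2):
        return 0.5 * (mu1 + mu2)
    a = 1.0 / (2 * sigma1**2) - 1.0 / (2 * sigma2**2)
    b = -(mu1 / sigma1**2 - mu2 / sigma2**2)
    c = (mu1**2 / (2 * sigma1**2) - mu2**2 / (2 * sigma2**2)
         + np.log(sigma1 / sigma2))
    disc = b * b - 4 * a * c
    if disc < 0:
        raise AmbiguousThresholdError(())
    roots = sorted([(-b - np.sqrt(disc)) / (2 * a),
                    (-b + np.sqrt(disc)) / (2 * a)])
    lo, hi = sorted((mu1, mu2))
    between = [r for r in roots if lo <= r <= hi]
    if not between:
        raise AmbiguousThresholdError(roots)
    return float(between[0])


def fit_lda_threshold(pos_scores, neg_scores) -> LdaThreshold:
    """Fit class-conditional Gaussians to score logits and solve for beta.

    Gaussian parameters are the sample mean and unbiased sample variance of
    the logit-transformed scores (scores clamped away from exactly 0/1).
    """
    pos = np.asarray(pos_scores, float).ravel()
    neg = np.asarray(neg_scores, float).ravel()
    if len(pos) < 2 or len(neg) < 2:
        raise ValueError("need at least two scores per class")
    t1, t2 = _logit(pos), _logit(neg)
    mu1, mu2 = float(t1.mean()), float(t2.mean())
    s1, s2 = float(t1.std(ddof=1)), float(t2.std(ddof=1))
    if s1 == 0 or s2 == 0:
        raise ValueError("a class has zero logit variance")
    beta_logit = solve_equal_density(mu1, s1, mu2, s2)
    return LdaThreshold(mu1=mu1, sigma1=s1, mu2=mu2, sigma2=s2,
                        beta_logit=beta_logit, beta=_inv_logit(beta_logit))


@dataclass(frozen=True)
class ModelVerdict:
    """Accept/reject decision for one staining model from N image scores."""

    model_id: str
    n: int
    scores: tuple[float, ...]
    s_bar: float
    beta: float
    decision: str                     # "reject" iff s_bar >= beta

    def __post_init__(self):
        if self.decision not in ("accept", "reject"):
            raise ValueError("decision must be accept or reject")


def assess_model(scores, beta: float, model_id: str = "") -> ModelVerdict:
    """Compare the mean voted score over N images with the threshold beta.

    Higher scores mean more hallucinated, so the model is rejected when the
    mean reaches ``beta``; the boundary case is assigned to rejection
    (conservative).
    """
    s = np.asarray(scores, float).ravel()
    if s.size == 0:
        raise ValueError("empty score list")
    if np.any(s < 0) or np.any(s > 1):
        raise ValueError("scores must lie in [0, 1]")
    s_bar = float(s.mean())
    decision = "reject" if s_bar >= beta else "accept"
    return ModelVerdict(model_id=model_id, n=int(s.size),
                        scores=tuple(float(v) for v in s), s_bar=s_bar,
                        beta=float(beta), decision=decision)


def model_gate_experiment(model_scores: dict[str, np.ndarray],
                          model_labels: dict[str, str],
                          beta: float,
                          n_values=(2, 5, 10, 20),
                          repetitions: int = 20,
                          seed: int = 0) -> pd.DataFrame:
    """Sampling experiment over a zoo of scored models.

    ``model_scores`` maps model id -> per-image voted scores;
    ``model_labels`` maps model id -> "good" or "poor".  For every model and
    every N, N scores are sampled without replacement R times; the table
    reports mean/std of the mean score s_bar, the per-repetition decision
    accuracy at ``beta``, and (as frame-level context) the KL divergence
    between the pooled good-group and poor-group s_bar distributions at each
    N is attached in ``DataFrame.attrs["kl_by_n"]``.
    """
    rng = np.random.default_rng(seed)
    max_n = max(n_values)
    for mid, scores in model_scores.items():
        if len(scores) < max_n:
            raise ValueError(f"model {mid} has {len(scores)} scores; "
                             f"need at least {max_n}")
    rows = []
    sbar_pool: dict[tuple[int, str], list[float]] = {}
    for mid, scores in model_scores.items():
        scores = np.asarray(scores, float)
        label = model_labels[mid]
        for n in n_values:
            sbars = []
            correct = 0
            for _ in range(repetitions):
                pick = rng.choice(scores, size=n, replace=False)
                verdict = assess_model(pick, beta, model_id=mid)
                sbars.append(verdict.s_bar)
                want = "reject" if label == "poor" else "accept"
                correct += int(verdict.decision == want)
            sbar_pool.setdefault((n, label), []).extend(sbars)
            rows.append({
                "model_id": mid, "label": label, "N": n, "R": repetitions,
                "mean_sbar": float(np.mean(sbars)),
                "std_sbar": float(np.std(sbars, ddof=0)),
                "decision_accuracy": correct / repetitions,
            })
    table = pd.DataFrame(rows)
    kl_by_n = {}
    for n in n_values:
        good = sbar_pool.get((n, "good"), [])
        poor = sbar_pool.get((n, "poor"), [])
        if good and poor:
            kl_by_n[n] = kl_divergence(bin_scores(good), bin_scores(poor))
    table.attrs["kl_by_n"] = kl_by_n
    table.attrs["overall_accuracy"] = float(table["decision_accuracy"].mean())
    return table
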