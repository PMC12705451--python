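"""Scalar image-quality metrics, distribution divergences and classification
rates used throughout the assessment pipeline.

Image metrics (m.s.e., PCC, PSNR) follow the 8-bit convention: images stored
in [0, 1] are scaled by 255 inside the metric, not in storage.  Score
distributions are binned on [0, 1] with 0.01-wide bins (100 bins) and compared
with a smoothed KL divergence (natural logarithm, per-bin probability mass,
smoothing epsilon 0.001).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.metrics import precision_recall_curve, roc_curve

PSNR_INF = float("inf")


@dataclass(frozen=True)
class SeparationStats:
    """Pooled-variance two-sample t statistic plus bookkeeping."""

    t_statistic: float
    n1: int
    n2: int
    pooled_sd: float
    kl_divergence: float | None = None


@dataclass(frozen=True)
class BinnedDistribution:
    """Probability mass on a uniform bin grid over [0, 1]."""

    edges: np.ndarray      # length n_bins + 1
    mass: np.ndarray       # length n_bins, sums to 1

    @property
    def n_bins(self) -> int:
        return len(self.mass)


def _check_shapes(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    return x, y


def mse(x: np.ndarray, y: np.ndarray, scale: float = 255.0) -> float:
    """Mean squared error on the 8-bit intensity scale (inputs in [0, 1])."""
    x, y = _check_shapes(x, y)
    d = (x - y) * scale
    return float(np.mean(d * d))


def pcc(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation coefficient over all pixels (and channels)."""
    x, y = _check_shapes(x, y)
    xc = x.ravel() - x.mean()
    yc = y.ravel() - y.mean()
    denom = np.sqrt((xc * xc).sum() * (yc * yc).sum())
    if denom == 0.0:
        raise ValueError("correlation undefined for a constant image")
    return float((xc * yc).sum() / denom)


def psnr(x: np.ndarray, y: np.ndarray) -> float:
    """Peak signal-to-noise ratio in dB; +inf when the images are identical."""
    m = mse(x, y)
    if m == 0.0:
        return PSNR_INF
    return float(20.0 * np.log10(255.0 / np.sqrt(m)))


def pooled_t(sample1, sample2) -> SeparationStats:
    """Two-sample t statistic with pooled standard deviation.

    ``t = (mu1 - mu2) / (s_p * sqrt(1/n1 + 1/n2))`` with
    ``s_p^2 = ((n1-1) s1^2 + (n2-1) s2^2) / (n1 + n2 - 2)`` and unbiased
    per-group variances.
    """
    a = np.asarray(sample1, dtype=np.float64).ravel()
    b = np.asarray(sample2, dtype=np.float64).ravel()
    n1, n2 = len(a), len(b)
    if n1 < 2 or n2 < 2:
        raise ValueError("both samples need at least two observations")
    s1, s2 = a.var(ddof=1), b.var(ddof=1)
    sp2 = ((n1 - 1) * s1 + (n2 - 1) * s2) / (n1 + n2 - 2)
    if sp2 == 0.0:
        raise ValueError("pooled variance is zero")
    sp = np.sqrt(sp2)
    t = (a.mean() - b.mean()) / (sp * np.sqrt(1.0 / n1 + 1.0 / n2))
    return SeparationStats(t_statistic=float(t), n1=n1, n2=n2, pooled_sd=float(sp))


def bin_scores(scores, n_bins: int = 100) -> BinnedDistribution:
    """Bin scores in [0, 1] into uniform half-open bins; the last bin is closed."""
    s = np.asarray(scores, dtype=np.float64).ravel()
    if s.size == 0:
        raise ValueError("empty score list")
    if np.any(s < 0) or np.any(s > 1):
        raise ValueError("scores must lie in [0, 1]")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    counts, _ = np.histogram(s, bins=edges)   # numpy closes the last bin
    return BinnedDistribution(edges=edges, mass=counts / counts.sum())


def kl_divergence(p_neg: BinnedDistribution, p_pos: BinnedDistribution,
                  epsilon: float = 0.001) -> float:
    """Smoothed KL divergence D(p_neg || p_pos) over a shared bin grid.

    Natural logarithm on per-bin probability mass, with ``epsilon`` added to
    both arguments of the ratio to avoid infinities on empty bins.
    """
    if p_neg.n_bins != p_pos.n_bins or not np.allclose(p_neg.edges, p_pos.edges):
        raise ValueError("bin grids do not match")
    pn, pp = p_neg.mass, p_pos.mass
    return float(np.sum(np.log((pn + epsilon) / (pp + epsilon)) * pn))


def classification_rates(tp: int, tn: int, p: int, n: int) -> dict[str, float]:
    """Accuracy, sensitivity, specificity, TPR/FPR, precision and recall.

    ``p``/``n`` are the numbers of actual positives/negatives; an empty class
    yields NaN for the rates it alone defines.
    """
    if not (0 <= tp <= p) or not (0 <= tn <= n):
        raise ValueError("need 0 <= tp <= p and 0 <= tn <= n")
    fp = n - tn
    nan = float("nan")
    sens = tp / p if p > 0 else nan
    spec = tn / n if n > 0 else nan
    acc = (tp + tn) / (p + n) if (p + n) > 0 else nan
    prec = tp / (tp + fp) if (tp + fp) > 0 else nan
    return {
        "accuracy": acc,
        "sensitivity": sens,
        "specificity": spec,
        "tpr": sens,
        "fpr": 1.0 - spec if n > 0 else nan,
        "precision": prec,
        "recall": sens,
    }


def curve_points(scores, labels) -> dict:
    """ROC and precision-recall points at every distinct score threshold.

    Returns arrays of (fpr, tpr, roc_thresholds), (precision, recall,
    pr_thresholds) and trapezoid-rule areas under both curves.
    """
    s = np.asarray(scores, dtype=np.float64).ravel()
    y = np.asarray(labels).ravel().astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    fpr, tpr, roc_thr = roc_curve(y, s, drop_intermediate=False)
    prec, rec, pr_thr = precision_recall_curve(y, s)
    roc_auc = float(np.trapezoid(tpr, fpr))
    # recall is decreasing in sklearn's output; integrate on the sorted axis
    order = np.argsort(rec)
    pr_auc = float(np.trapezoid(np.asarray(prec)[order], np.asarray(rec)[order]))
    return {
        "fpr": fpr, "tpr": tpr, "roc_thresholds": roc_thr, "roc_auc": roc_auc,
        "precision": prec, "recall": rec, "pr_thresholds": pr_thr,
        "pr_auc": pr_auc,
    }


def hellinger(p, q) -> float:
    """Hellinger distance between two discrete distributions on a shared grid."""
    p = np.asarray(p, dtype=np.float64).ravel()
    q = np.asarray(q, dtype=np.float64).ravel()
    if p.shape != q.shape:
        raise ValueError("distributions must have the same number of bins")
    for name, v in (("p", p), ("q", q)):
        if not np.isclose(v.sum(), 1.0, atol=1e-8):
            raise ValueError(f"{name} is not normalized (sum={v.sum()})")
    inner = np.sum(np.sqrt(p * q))
    return float(np.sqrt(max(0.0, 1.0 - inner)))


def g_test(observed, expected) -> dict[str, float]:
    """Log-likelihood-ratio goodness-of-fit test.

    ``G = 2 sum O_i ln(O_i / E_i)`` with the ``0 ln 0 = 0`` convention and a
    chi-square tail p-value on ``n_bins - 1`` degrees of freedom.
    """
    o = np.asarray(observed, dtype=np.float64).ravel()
    e = np.asarray(expected, dtype=np.float64).ravel()
    if o.shape != e.shape:
        raise ValueError("observed and expected must have the same length")
    if np.any((o > 0) & (e <= 0)):
        raise ValueError("expected must be positive wherever observed is positive")
    mask = o > 0
    g = 2.0 * np.sum(o[mask] * np.log(o[mask] / e[mask]))
    dof = len(o) - 1
    p_value = float(stats.chi2.sf(g, dof)) if dof > 0 else float("nan")
    return {"G": float(g), "dof": dof, "p_value": p_value}


def g_test_two_sample(counts_a, counts_b) -> dict[str, float]:
    """Two-sample G-test of homogeneity on binned counts (2 x k contingency).

    Bins empty in both samples are dropped before forming the table.
    """
    a = np.asarray(counts_a, dtype=np.float64).ravel()
    b = np.asarray(counts_b, dtype=np.float64).ravel()
    if a.shape != b.shape:
        raise ValueError("count vectors must have the same length")
    keep = (a + b) > 0
    table = np.vstack([a[keep], b[keep]])
    if table.shape[1] < 2:
        return {"G": 0.0, "dof": 0, "p_value": 1.0}
    res = stats.chi2_contingency(table, correction=False,
                                 lambda_="log-likelihood")
    return {"G": float(res.statistic), "dof": int(res.dof),
            "p_value": float(res.pvalue)}
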