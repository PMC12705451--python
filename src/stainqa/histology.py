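"""Hand-crafted histochemical-stain quality metrics.

Colour deconvolution separates an H&E-like RGB image into per-stain
concentration channels through optical densities (``OD = -log10(rgb)``)
projected onto the stain-vector basis; Otsu thresholding plus a morphological
opening segments the nuclei channel; connected components give the two
analytical features — normalized nuclei count (components per pixel) and
average nuclei area — which can be compared between two image sets with
Hellinger distances and G-tests on shared-edge histograms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .images import Domain, ImageFOV
from .metrics import g_test_two_sample, hellinger

OD_FLOOR = 1.0 / 255.0   # transmission floor before the log (black pixels)

# 8-connectivity for component labelling
_STRUCTURE_8 = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class QCMetrics:
    """Per-image nuclei statistics from the segmentation pipeline."""

    normalized_nuclei_count: float   # components per pixel (px^-2)
    average_nuclei_area: float       # px^2; NaN when no components
    n_components: int
    nuclei_mask: np.ndarray


def _disk(radius: int) -> np.ndarray:
    if radius < 1:
        return np.ones((1, 1), dtype=bool)
    rr, cc = np.mgrid[-radius:radius + 1, -radius:radius + 1]
    return rr**2 + cc**2 <= radius**2


def stain_deconvolve(rgb: ImageFOV | np.ndarray,
                     stain_vectors: np.ndarray) -> np.ndarray:
    """Project optical densities onto 2-3 unit stain vectors.

    Returns an (H, W, n_stains) concentration array (base-10 OD units);
    negative concentrations are clipped to zero.
    """
    pixels = rgb.pixels if isinstance(rgb, ImageFOV) else np.asarray(rgb, float)
    if pixels.ndim != 3 or pixels.shape[2] != 3:
        raise ValueError("expected an (H, W, 3) RGB image")
    vectors = np.atleast_2d(np.asarray(stain_vectors, float))
    if vectors.shape[0] not in (2, 3) or vectors.shape[1] != 3:
        raise ValueError("stain_vectors must be 2-3 RGB optical-density rows")
    norms = np.linalg.norm(vectors, axis=1, keepdims=True)
    vectors = vectors / norms
    if np.linalg.matrix_rank(vectors, tol=1e-8) < vectors.shape[0]:
        raise ValueError("singular stain matrix: vectors are linearly dependent")
    od = -np.log10(np.maximum(pixels, OD_FLOOR))
    flat = od.reshape(-1, 3)
    conc, *_ = np.linalg.lstsq(vectors.T, flat.T, rcond=None)
    conc = np.clip(conc.T, 0.0, None)
    return conc.reshape(pixels.shape[0], pixels.shape[1], vectors.shape[0])


def otsu_threshold(channel: np.ndarray, n_levels: int = 256) -> float:
    """Threshold maximizing between-class variance over an n-level histogram.

    The search is exhaustive over all candidate bin boundaries; the returned
    value is the upper edge of the best bin, mapped back to the channel's
    value range.
    """
    x = np.asarray(channel, float).ravel()
    lo, hi = float(x.min()), float(x.max())
    if lo == hi:
        raise ValueError("Otsu threshold undefined for a constant image")
    counts, edges = np.histogram(x, bins=n_levels, range=(lo, hi))
    p = counts.astype(float) / counts.sum()
    centers = (edges[:-1] + edges[1:]) / 2
    w0 = np.cumsum(p)
    w1 = 1.0 - w0
    m = np.cumsum(p * centers)
    m_total = m[-1]
    valid = (w0 > 0) & (w1 > 0)
    between = np.zeros(n_levels)
    between[valid] = ((m_total * w0[valid] - m[valid]) ** 2
                      / (w0[valid] * w1[valid]))
    k = int(np.argmax(between))
    return float(edges[k + 1])


def segment_nuclei(nuclei_channel: np.ndarray, opening_radius: int = 1
                   ) -> tuple[np.ndarray, np.ndarray, int]:
    """Binarize the nuclei channel and clean it up morphologically.

    Otsu threshold, then binary erosion followed by dilation (an opening)
    with a disk structuring element, then 8-connected component labelling.
    Returns (mask, labels, n_components); an empty mask is allowed.
    """
    ch = np.asarray(nuclei_channel, float)
    if ch.min() == ch.max():
        return (np.zeros(ch.shape, bool), np.zeros(ch.shape, int), 0)
    thr = otsu_threshold(ch)
    mask = ch > thr
    selem = _disk(opening_radius)
    mask = ndimage.binary_erosion(mask, structure=selem)
    mask = ndimage.binary_dilation(mask, structure=selem)
    labels, n = ndimage.label(mask, structure=_STRUCTURE_8)
    return mask, labels, int(n)


def count_merged(labels: np.ndarray, nuclei_centers) -> int:
    """Diagnostic: planted nuclei whose centres fall in a shared component.

    Returns the number of extra centres beyond one per occupied component —
    0 when every detected component holds at most one planted nucleus.
    """
    counts: dict[int, int] = {}
    for r0, c0, *_ in nuclei_centers:
        r, c = int(round(r0)), int(round(c0))
        if 0 <= r < labels.shape[0] and 0 <= c < labels.shape[1]:
            lab = int(labels[r, c])
            if lab > 0:
                counts[lab] = counts.get(lab, 0) + 1
    return sum(v - 1 for v in counts.values() if v > 1)


def nuclei_metrics(mask: np.ndarray) -> QCMetrics:
    """Exact component count and area statistics from a binary mask."""
    mask = np.asarray(mask, bool)
    labels, n = ndimage.label(mask, structure=_STRUCTURE_8)
    total_px = mask.size
    if n == 0:
        return QCMetrics(0.0, float("nan"), 0, mask)
    areas = np.bincount(labels.ravel())[1:]
    return QCMetrics(
        normalized_nuclei_count=n / total_px,
        average_nuclei_area=float(areas.mean()),
        n_components=int(n),
        nuclei_mask=mask,
    )


def qc_stain_image(fov: ImageFOV, stain_vectors: np.ndarray | None = None,
                   opening_radius: int = 1) -> QCMetrics:
    """Full pipeline: deconvolve, segment the nuclei channel, measure."""
    from .synthetic import EOSIN, HAEMATOXYLIN
    if fov.domain is not Domain.STAIN:
        raise ValueError("QC applies to STAIN-domain images")
    if stain_vectors is None:
        stain_vectors = np.vstack([HAEMATOXYLIN, EOSIN])
    conc = stain_deconvolve(fov, stain_vectors)
    mask, _labels, _n = segment_nuclei(conc[..., 0], opening_radius)
    return nuclei_metrics(mask)


def compare_feature_distributions(set_a, set_b, n_bins: int = 7,
                                  alpha: float = 0.05) -> dict:
    """Compare one scalar feature between two image sets.

    Histograms share edges computed from the pooled min/max of both sets
    (``n_bins`` uniform bins; 7 is the preset for per-image nuclei counts,
    6 for average areas).  Returns the Hellinger distance between the two
    normalized histograms and a two-sample G-test on the binned counts at
    significance ``alpha``.
    """
    a = np.asarray(set_a, float).ravel()
    b = np.asarray(set_b, float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("both sets must be non-empty")
    lo = min(a.min(), b.min())
    hi = max(a.max(), b.max())
    if lo == hi:
        hi = lo + 1.0
    edges = np.linspace(lo, hi, n_bins + 1)
    ca, _ = np.histogram(a, bins=edges)
    cb, _ = np.histogram(b, bins=edges)
    dist = hellinger(ca / ca.sum(), cb / cb.sum())
    gres = g_test_two_sample(ca, cb)
    return {
        "hellinger": dist,
        "g_statistic": gres["G"],
        "dof": gres["dof"],
        "p_value": gres["p_value"],
        "significant": bool(gres["p_value"] < alpha),
        "edges": edges,
    }
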