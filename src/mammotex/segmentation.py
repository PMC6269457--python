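"""Anatomical component segmentation: air-breast boundary, pectoralis, density.

This reproduces, functionally, the three LIBRA-style anatomical components:
global-threshold breast silhouette, Hough-transform pectoral muscle boundary,
and fuzzy c-means density clusters aggregated into a dense-tissue mask.
Equivalence to the original software is functional (phantom Dice), not
bitwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage import filters, morphology, transform


class SegmentationError(RuntimeError):
    pass


@dataclass
class PectoralLine:
    """Straight pectoral boundary: col*cos(t) + row*sin(t) = dist.

    ``angle_deg`` is the Hough angle t in degrees; t = 0 is a vertical line,
    positive t leans the line so that its column decreases with row (the
    usual chest-wall-left MLO geometry).
    """

    angle_deg: float
    dist: float

    def signed_distance(self, row: float, col: float) -> float:
        """Perpendicular distance in pixels; positive on the breast side (right)."""
        t = np.deg2rad(self.angle_deg)
        return col * np.cos(t) + row * np.sin(t) - self.dist

    def col_at_row(self, row):
        t = np.deg2rad(self.angle_deg)
        return (self.dist - np.asarray(row) * np.sin(t)) / np.cos(t)

    def mirrored(self, width: int) -> "PectoralLine":
        t = np.deg2rad(self.angle_deg)
        return PectoralLine(angle_deg=-self.angle_deg,
                            dist=(width - 1) * np.cos(t) - self.dist)


@dataclass
class BreastSegmentation:
    """Breast/pectoralis/density-cluster masks for one image.

    ``breast_mask`` is the parenchymal region (foreground silhouette with the
    pectoralis removed); ``foreground_mask`` keeps the full silhouette.
    Density cluster labels are 0 outside the parenchyma and 1..K ordered by
    ascending mean intensity.
    """

    breast_mask: np.ndarray
    pectoralis_mask: np.ndarray
    pectoral_line: PectoralLine | None
    density_cluster_labels: np.ndarray
    dense_mask: np.ndarray
    K: int
    foreground_mask: np.ndarray | None = None


def segment_breast(image) -> np.ndarray:
    """Breast silhouette by Otsu thresholding + closing, largest component.

    Thresholding runs on log intensities: the air-tissue split then dominates
    the between-class variance even when bright muscle makes the raw
    histogram trimodal.
    """
    px = image.pixels
    if px.max() <= px.min():
        raise SegmentationError("image has no intensity contrast; empty foreground")
    t = filters.threshold_otsu(np.log1p(px))
    fg = np.log1p(px) > t
    if not fg.any():
        raise SegmentationError("empty foreground after thresholding")
    fg = morphology.closing(fg, morphology.disk(2))
    lab, n = ndi.label(fg)
    if n == 0:
        raise SegmentationError("no connected foreground component")
    sizes = ndi.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    mask = lab == (1 + int(np.argmax(sizes)))
    return mask


def _chest_side(breast_mask: np.ndarray) -> str:
    left = breast_mask[:, 0].sum()
    right = breast_mask[:, -1].sum()
    return "left" if left >= right else "right"


def segment_pectoralis(
    image,
    breast_mask: np.ndarray,
    angle_range_deg: tuple[float, float] = (20.0, 80.0),
    min_votes_frac: float = 0.25,
) -> tuple[np.ndarray, PectoralLine | None]:
    """Pectoral muscle wedge via a straight-line Hough transform.

    The search runs over intensity edges strictly inside the breast (the
    air-breast boundary is excluded) within the upper chest-wall corner, with
    candidate angles 20-80 degrees from vertical.  When no line reaches the
    accumulator threshold the muscle is reported absent (empty mask, line
    None) - a valid outcome on wedge-free images.
    """
    if not breast_mask.any():
        raise SegmentationError("empty breast mask")
    px = image.pixels
    H, W = px.shape
    flipped = _chest_side(breast_mask) == "right"
    if flipped:
        px = px[:, ::-1]
        breast_mask = breast_mask[:, ::-1]

    interior = ndi.binary_erosion(breast_mask, iterations=3)
    grad = ndi.sobel(px, axis=0) ** 2 + ndi.sobel(px, axis=1) ** 2
    grad = np.sqrt(grad) * interior
    window = np.zeros_like(breast_mask)
    window[: int(0.8 * H), : int(0.6 * W)] = True
    grad *= window
    if grad.max() <= 0:
        return _pect_result(None, (H, W), breast_mask, flipped)
    edges = grad > 0.5 * grad.max()

    lo, hi = np.deg2rad(angle_range_deg)
    thetas = np.linspace(lo, hi, int((angle_range_deg[1] - angle_range_deg[0]) * 2) + 1)
    acc, angles, dists = transform.hough_line(edges, theta=thetas)
    min_votes = max(20, int(min_votes_frac * H))
    _, peak_angles, peak_dists = transform.hough_line_peaks(
        acc, angles, dists, num_peaks=1, threshold=min_votes)
    if len(peak_angles) == 0:
        return _pect_result(None, (H, W), breast_mask, flipped)
    line = PectoralLine(angle_deg=float(np.rad2deg(peak_angles[0])), dist=float(peak_dists[0]))
    return _pect_result(line, (H, W), breast_mask, flipped)


def _pect_result(line, shape, breast_mask, flipped):
    H, W = shape
    if line is None:
        mask = np.zeros((H, W), bool)
    else:
        rr, cc = np.mgrid[0:H, 0:W]
        t = np.deg2rad(line.angle_deg)
        mask = (cc * np.cos(t) + rr * np.sin(t) < line.dist) & breast_mask
    if flipped:
        mask = mask[:, ::-1].copy()
        line = line.mirrored(W) if line is not None else None
    return mask, line


# ---------------------------------------------------------------------------
# Fuzzy c-means density clustering


def fuzzy_cmeans_1d(
    values: np.ndarray,
    weights: np.ndarray,
    K: int,
    m: float = 2.0,
    tol: float = 1e-5,
    max_iter: int = 200,
) -> tuple[np.ndarray, np.ndarray]:
    """Weighted 1D fuzzy c-means with deterministic quantile initialization.

    Returns (centroids ascending, memberships of shape (len(values), K)).
    Memberships sum to 1 per sample.
    """
    values = np.asarray(values, float)
    weights = np.asarray(weights, float)
    order = np.argsort(values)
    cw = np.cumsum(weights[order])
    total = cw[-1]
    qs = (np.arange(K) + 0.5) / K
    centroids = values[order][np.searchsorted(cw, qs * total)].astype(float)
    centroids = np.unique(centroids)
    while len(centroids) < K:  # duplicated quantiles on discrete data
        centroids = np.sort(np.concatenate([centroids, [centroids.max() + 1e-6 * (1 + abs(centroids.max()))]]))
    rng_scale = max(values.max() - values.min(), 1e-12)
    expo = 2.0 / (m - 1.0)
    for _ in range(max_iter):
        d = np.abs(values[:, None] - centroids[None, :])
        d = np.maximum(d, 1e-12 * rng_scale)
        inv = d ** (-expo)
        u = inv / inv.sum(axis=1, keepdims=True)
        um = (u**m) * weights[:, None]
        new_c = (um * values[:, None]).sum(axis=0) / um.sum(axis=0)
        shift = np.max(np.abs(new_c - centroids)) / rng_scale
        centroids = new_c
        if shift < tol:
            break
    order = np.argsort(centroids)
    return centroids[order], u[:, order]


def segment_density(
    image,
    breast_mask: np.ndarray,
    pectoralis_mask: np.ndarray,
    K: int = 4,
) -> tuple[np.ndarray, np.ndarray]:
    """Density clusters by fuzzy c-means on within-breast intensities.

    Pixels are hard-assigned to their maximum-membership cluster; labels are
    1..K in ascending centroid order.  The dense mask aggregates clusters
    whose centroid exceeds the midpoint of the lowest and highest centroids.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    paren = breast_mask & ~pectoralis_mask
    if not paren.any():
        raise SegmentationError("breast minus pectoralis is empty")
    px = image.pixels
    vals = px[paren]
    # cluster on the (weighted) set of distinct values: exact for discrete
    # images and fast for continuous ones
    uniq, counts = np.unique(vals, return_counts=True)
    if len(uniq) > 1024:
        edges = np.linspace(uniq[0], uniq[-1], 1025)
        idx = np.clip(np.searchsorted(edges, vals, side="right") - 1, 0, 1023)
        counts = np.bincount(idx, minlength=1024).astype(float)
        keep = counts > 0
        sums = np.bincount(idx, weights=vals, minlength=1024)
        uniq = (sums[keep] / counts[keep])
        counts = counts[keep]
        bin_of_val = idx
        remap = np.cumsum(keep) - 1
        sample_bin = remap[bin_of_val]
    else:
        sample_bin = np.searchsorted(uniq, vals)

    k_eff = min(K, len(uniq))
    if k_eff < K:
        warnings.warn(f"only {len(uniq)} distinct intensities; using K={k_eff}")
    labels = np.zeros(px.shape, dtype=np.int32)
    if k_eff == 1:
        labels[paren] = 1
        dense = np.zeros(px.shape, bool)
        warnings.warn("single density cluster; dense mask empty")
        return labels, dense
    centroids, u = fuzzy_cmeans_1d(uniq, counts.astype(float), k_eff)
    hard = np.argmax(u, axis=1)  # per distinct value / bin
    labels[paren] = hard[sample_bin] + 1
    # enforce strictly increasing observed cluster means by construction:
    # hard assignment of 1D values to ascending centroids is monotone in value
    cutoff = 0.5 * (centroids[0] + centroids[-1])
    dense_clusters = np.nonzero(centroids > cutoff)[0] + 1
    dense = np.isin(labels, dense_clusters) & paren
    return labels, dense


def segment_all(image, K: int = 4) -> BreastSegmentation:
    """Full LIBRA-style segmentation of one image."""
    fg = segment_breast(image)
    pect, line = segment_pectoralis(image, fg)
    labels, dense = segment_density(image, fg, pect, K=K)
    observed_k = int(labels.max())
    return BreastSegmentation(
        breast_mask=fg & ~pect,
        pectoralis_mask=pect,
        pectoral_line=line,
        density_cluster_labels=labels,
        dense_mask=dense,
        K=observed_k,
        foreground_mask=fg,
    )
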