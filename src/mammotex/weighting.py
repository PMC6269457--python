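"""Anatomical weight maps and the 68-element texture signature.

Each polar-grid region receives a weight W = c*S + (1-c)*T in [0, 1]:

* S codes anatomical position: a linear blend of normalized distances to the
  CBA and UOA centroids, S = a*(1 - d_cba) + (1-a)*(1 - d_uoa), where each
  distance is divided by its maximum over retained regions.  Parameter ``a``
  tunes the central (CBA) versus upper-outer (UOA) emphasis.
* T codes tissue composition from the density clusters: with c_hat the
  region's mean cluster label rescaled to [0, 1] (0 = most fatty, 1 = most
  dense), T = b*c_hat + (1-b)*(1 - c_hat).  ``b`` selects dense- versus
  fatty-tissue emphasis.
* ``c`` balances position against tissue composition.

The weighted feature maps are summarized into a 68-element signature: the
mean and the standard deviation of each weighted feature over regions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .texture import FEATURE_NAMES, FeatureMaps

SIGNATURE_LABELS: tuple[str, ...] = tuple(
    [f"{fid}_mean" for fid in FEATURE_NAMES] + [f"{fid}_std" for fid in FEATURE_NAMES]
)


class WeightingError(RuntimeError):
    pass


@dataclass
class WeightMap:
    S: np.ndarray
    T: np.ndarray
    W: np.ndarray
    a: float
    b: float
    c: float


@dataclass
class TextureSignature:
    values: np.ndarray                       # 68 reals
    labels: tuple[str, ...] = SIGNATURE_LABELS
    subject_id: str = ""
    side_label: str = ""
    sampler: str = "anatomy"

    def as_dict(self) -> dict:
        return dict(zip(self.labels, self.values))


def _mask_centroid(mask: np.ndarray) -> np.ndarray:
    rr, cc = np.nonzero(mask)
    return np.array([rr.mean(), cc.mean()])


def position_weights(grid, cba_mask: np.ndarray, uoa_mask: np.ndarray, a: float) -> np.ndarray:
    """Per-region S in [0, 1]; an empty UOA drops its term (a treated as 1)."""
    if not (0.0 <= a <= 1.0):
        raise ValueError("a must lie in [0, 1]")
    if cba_mask is None or not cba_mask.any():
        raise WeightingError("empty CBA")
    cents = np.asarray(grid.centroids)
    c_cba = _mask_centroid(cba_mask)
    d_cba = np.hypot(cents[:, 0] - c_cba[0], cents[:, 1] - c_cba[1])
    d_cba = d_cba / max(d_cba.max(), 1e-12)
    if uoa_mask is None or not uoa_mask.any():
        warnings.warn("empty UOA; S uses the CBA term only")
        return 1.0 - d_cba
    c_uoa = _mask_centroid(uoa_mask)
    d_uoa = np.hypot(cents[:, 0] - c_uoa[0], cents[:, 1] - c_uoa[1])
    d_uoa = d_uoa / max(d_uoa.max(), 1e-12)
    return a * (1.0 - d_cba) + (1.0 - a) * (1.0 - d_uoa)


def tissue_weights(grid, cluster_labels: np.ndarray, b: float) -> np.ndarray:
    """Per-region T in [0, 1] from the mean density-cluster label."""
    if not (0.0 <= b <= 1.0):
        raise ValueError("b must lie in [0, 1]")
    n = grid.n_regions
    sel = grid.label_map >= 0
    lab = grid.label_map[sel]
    clu = cluster_labels[sel].astype(np.float64)
    if np.any(clu < 1):
        raise WeightingError("cluster labels must cover all retained-region pixels")
    K = int(cluster_labels.max())
    cnt = np.bincount(lab, minlength=n).astype(np.float64)
    mean_lab = np.bincount(lab, weights=clu, minlength=n) / cnt
    if K <= 1:
        warnings.warn("single density cluster; T = 0.5 everywhere")
        return np.full(n, 0.5)
    c_hat = (mean_lab - 1.0) / (K - 1.0)
    return b * c_hat + (1.0 - b) * (1.0 - c_hat)


def combine_weights(S: np.ndarray, T: np.ndarray, c: float) -> np.ndarray:
    if not (0.0 <= c <= 1.0):
        raise ValueError("c must lie in [0, 1]")
    S, T = np.asarray(S, float), np.asarray(T, float)
    if S.shape != T.shape:
        raise WeightingError("S and T must have the same length")
    return c * S + (1.0 - c) * T


def build_weight_map(grid, anatomy, cluster_labels, a: float, b: float, c: float) -> WeightMap:
    S = position_weights(grid, anatomy.cba_mask, anatomy.uoa_mask, a)
    T = tissue_weights(grid, cluster_labels, b)
    return WeightMap(S=S, T=T, W=combine_weights(S, T, c), a=a, b=b, c=c)


def apply_weights(maps: FeatureMaps, W: np.ndarray) -> FeatureMaps:
    """Region-wise multiply every feature map by the weight map."""
    W = np.asarray(W, float)
    if W.shape[0] != maps.n_regions:
        raise WeightingError("weight map not aligned with the region list")
    return FeatureMaps(values=maps.values * W[:, None],
                       orientation_mode=maps.orientation_mode,
                       ring_index=maps.ring_index, sector_index=maps.sector_index,
                       centroids=maps.centroids, weights=W)


def summarize_signature(weighted: FeatureMaps, subject_id: str = "",
                        side_label: str = "", sampler: str = "anatomy") -> TextureSignature:
    """Mean and standard deviation of each weighted map over regions."""
    if weighted.n_regions < 2:
        raise WeightingError("need >= 2 regions to summarize a signature")
    means = weighted.values.mean(axis=0)
    stds = weighted.values.std(axis=0)    # population SD across regions
    return TextureSignature(values=np.concatenate([means, stds]),
                            subject_id=subject_id, side_label=side_label,
                            sampler=sampler)
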