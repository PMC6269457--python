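"""End-to-end per-breast analysis and cohort feature assembly.

``analyze_breast`` runs segmentation -> orientation standardization ->
nipple/quadrants -> polar grid -> 34 feature maps -> weight map -> the
68-element signature for one image.  ``RegionCache`` captures everything the
weight/signature stages need so the (a, b, c, f) weight parameters can be
re-applied without re-running segmentation or texture extraction (texture
depends only on the grid step D).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import anatomy as anat
from . import segmentation as segm
from . import texture as tex
from . import weighting as wgt
from .io_formats import MammogramImage, RunConfig


@dataclass
class BreastResult:
    anatomy: anat.BreastAnatomy
    grid: anat.PolarGrid
    maps: tex.FeatureMaps
    weight_map: wgt.WeightMap
    weighted_maps: tex.FeatureMaps
    signature: wgt.TextureSignature


@dataclass
class RegionCache:
    """Per-breast region-level data sufficient to rebuild signatures for any
    weight parameters (a, b, c) and CBA/UOA split f."""

    features: np.ndarray         # (n_regions, 34), unweighted
    centroids: np.ndarray        # (n_regions, 2)
    c_hat: np.ndarray            # (n_regions,) tissue composition in [0, 1]
    paren_coords: np.ndarray     # (n_pixels, 2) parenchyma pixel coordinates
    nipple: tuple[float, float]
    r_p_px: float
    D_mm: float
    subject_id: str = ""
    side_label: str = ""


def analyze_breast(image: MammogramImage, config: RunConfig | None = None,
                   seg: segm.BreastSegmentation | None = None) -> BreastResult:
    config = config or RunConfig()
    if seg is None:
        seg = segm.segment_all(image, K=config.density_clusters)
    anatomy = anat.standardize_orientation(image, seg)
    anatomy = anat.define_quadrants(anatomy, config.f)
    grid = anat.build_polar_grid(anatomy, config.D_mm,
                                 region_min_coverage=config.region_min_coverage,
                                 min_region_pixels=config.min_region_pixels)
    maps = tex.compute_feature_maps(anatomy.standardized_image, grid, config,
                                    orientation_mode="anatomy_aligned")
    wm = wgt.build_weight_map(grid, anatomy, anatomy.segmentation.density_cluster_labels,
                              config.a, config.b, config.c)
    weighted = wgt.apply_weights(maps, wm.W)
    sig = wgt.summarize_signature(weighted, subject_id=image.subject_id,
                                  side_label=image.side_label, sampler="anatomy")
    return BreastResult(anatomy=anatomy, grid=grid, maps=maps, weight_map=wm,
                        weighted_maps=weighted, signature=sig)


def extract_region_cache(image: MammogramImage, config: RunConfig | None = None,
                         seg: segm.BreastSegmentation | None = None) -> RegionCache:
    """Segmentation + anatomy + texture once; weights re-appliable later."""
    config = config or RunConfig()
    if seg is None:
        seg = segm.segment_all(image, K=config.density_clusters)
    anatomy = anat.standardize_orientation(image, seg)
    anatomy = anat.define_quadrants(anatomy, config.f)
    grid = anat.build_polar_grid(anatomy, config.D_mm,
                                 region_min_coverage=config.region_min_coverage,
                                 min_region_pixels=config.min_region_pixels)
    maps = tex.compute_feature_maps(anatomy.standardized_image, grid, config)
    labels = anatomy.segmentation.density_cluster_labels
    K = max(int(labels.max()), 1)
    sel = grid.label_map >= 0
    lab = grid.label_map[sel]
    cnt = np.bincount(lab, minlength=grid.n_regions).astype(float)
    mean_lab = np.bincount(lab, weights=labels[sel].astype(float),
                           minlength=grid.n_regions) / cnt
    c_hat = np.zeros(grid.n_regions) + 0.5 if K <= 1 else (mean_lab - 1.0) / (K - 1.0)
    paren = anatomy.segmentation.breast_mask & ~anatomy.segmentation.pectoralis_mask
    rr, cc = np.nonzero(paren)
    r_p_px = anatomy.r_P_mm / image.pixel_spacing_mm
    return RegionCache(features=maps.values, centroids=np.asarray(grid.centroids),
                       c_hat=c_hat, paren_coords=np.stack([rr, cc], axis=1),
                       nipple=anatomy.nipple, r_p_px=r_p_px, D_mm=config.D_mm,
                       subject_id=image.subject_id, side_label=image.side_label)


def signature_from_cache(cache: RegionCache, a: float, b: float, c: float,
                         f: float) -> np.ndarray:
    """68-element signature for arbitrary weight parameters, from a cache."""
    nr, nc = cache.nipple
    P = cache.paren_coords
    d = np.hypot(P[:, 0] - nr, P[:, 1] - nc)
    cba_sel = d < f * cache.r_p_px
    uoa_sel = (P[:, 0] < nr) & (d > f * cache.r_p_px)
    cents = cache.centroids
    if not cba_sel.any():
        raise wgt.WeightingError("empty CBA")
    c_cba = P[cba_sel].mean(axis=0)
    d_cba = np.hypot(cents[:, 0] - c_cba[0], cents[:, 1] - c_cba[1])
    d_cba = d_cba / max(d_cba.max(), 1e-12)
    if uoa_sel.any():
        c_uoa = P[uoa_sel].mean(axis=0)
        d_uoa = np.hypot(cents[:, 0] - c_uoa[0], cents[:, 1] - c_uoa[1])
        d_uoa = d_uoa / max(d_uoa.max(), 1e-12)
        S = a * (1.0 - d_cba) + (1.0 - a) * (1.0 - d_uoa)
    else:
        S = 1.0 - d_cba
    T = b * cache.c_hat + (1.0 - b) * (1.0 - cache.c_hat)
    W = c * S + (1.0 - c) * T
    vals = cache.features * W[:, None]
    return np.concatenate([vals.mean(axis=0), vals.std(axis=0)])


def cohort_signature_table(women, config: RunConfig | None = None,
                           sampler: str = "anatomy") -> tuple[pd.DataFrame, np.ndarray]:
    """Per-woman bilateral-average signatures for a phantom cohort.

    Returns (X, y): X has one row per woman with the 68 signature labels,
    y is the case/control label vector.
    """
    from .lattice import lattice_signature

    config = config or RunConfig()
    rows, labels = [], []
    for w in women:
        sigs = []
        for side, img in w.images.items():
            if sampler == "anatomy":
                sig = analyze_breast(img, config).signature.values
            else:
                sig = lattice_signature(img, None, config.lattice_spacing_mm,
                                        config.lattice_window_mm, config).values
            sigs.append(sig)
        rows.append(np.mean(sigs, axis=0))
        labels.append(w.label)
    X = pd.DataFrame(rows, columns=list(wgt.SIGNATURE_LABELS),
                     index=[w.subject_id for w in women])
    return X, np.asarray(labels)


def cohort_region_caches(women, config: RunConfig | None = None) -> list[list[RegionCache]]:
    """Per-woman list of per-side region caches (for parameter optimization)."""
    config = config or RunConfig()
    return [[extract_region_cache(img, config) for img in w.images.values()]
            for w in women]


def signatures_from_caches(caches: list[list[RegionCache]], a: float, b: float,
                           c: float, f: float) -> pd.DataFrame:
    rows = [np.mean([signature_from_cache(rc, a, b, c, f) for rc in per_woman], axis=0)
            for per_woman in caches]
    return pd.DataFrame(rows, columns=list(wgt.SIGNATURE_LABELS))
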