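"""Regular-lattice texture sampling: the conventional comparator.

A square lattice is overlaid on the breast; the same 34 texture descriptors
are computed in axis-aligned mode on each square window (clipped to the
breast), all windows contribute equally (no anatomical weighting), and the
signature is the mean and standard deviation of each feature over windows -
structurally identical to the anatomy-driven 68-element signature.

The lattice and anatomy pipelines share the texture code path exactly (one
implementation, two samplers), so downstream performance differences are
attributable to sampling and weighting only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import segmentation as segm
from . import texture as tex
from . import weighting as wgt
from .io_formats import MammogramImage, RunConfig


class LatticeError(RuntimeError):
    pass


@dataclass
class LatticeGrid:
    """Duck-typed sampling grid (same surface the texture stage consumes)."""

    spacing_mm: float
    window_mm: float
    label_map: np.ndarray
    ring_index: np.ndarray      # lattice row index
    sector_index: np.ndarray    # lattice column index
    centroids: np.ndarray
    azimuth_deg: np.ndarray
    coverage: np.ndarray
    pixel_count: np.ndarray
    points: np.ndarray          # (n, 2) lattice centres

    @property
    def n_regions(self) -> int:
        return len(self.pixel_count)


def build_lattice_grid(paren_mask: np.ndarray, pixel_spacing_mm: float,
                       spacing_mm: float, window_mm: float,
                       region_min_coverage: float = 0.5,
                       min_region_pixels: int = 25) -> LatticeGrid:
    if window_mm > spacing_mm:
        raise LatticeError("overlapping windows (window > spacing) are not supported")
    H, W = paren_mask.shape
    s = max(1, int(round(spacing_mm / pixel_spacing_mm)))
    w = max(1, int(round(window_mm / pixel_spacing_mm)))
    label_map = np.full((H, W), -1, dtype=np.int64)
    rows, cols, cents, cov, cnt, pts = [], [], [], [], [], []
    idx = 0
    for gi, r0 in enumerate(range(0, H, s)):
        for gj, c0 in enumerate(range(0, W, s)):
            win = paren_mask[r0:r0 + w, c0:c0 + w]
            m = int(win.sum())
            coverage = m / float(w * w)
            if coverage < region_min_coverage or m < min_region_pixels:
                continue
            rr, cc = np.nonzero(win)
            label_map[r0:r0 + w, c0:c0 + w][win] = idx
            rows.append(gi)
            cols.append(gj)
            cents.append((rr.mean() + r0, cc.mean() + c0))
            cov.append(coverage)
            cnt.append(m)
            pts.append((r0 + (w - 1) / 2.0, c0 + (w - 1) / 2.0))
            idx += 1
    if idx < 2:
        raise LatticeError("fewer than 2 retained lattice windows")
    return LatticeGrid(spacing_mm=spacing_mm, window_mm=window_mm, label_map=label_map,
                       ring_index=np.asarray(rows), sector_index=np.asarray(cols),
                       centroids=np.asarray(cents), azimuth_deg=np.zeros(idx),
                       coverage=np.asarray(cov), pixel_count=np.asarray(cnt),
                       points=np.asarray(pts))


def lattice_signature(image: MammogramImage, seg: segm.BreastSegmentation | None,
                      spacing_mm: float, window_mm: float,
                      config: RunConfig | None = None) -> wgt.TextureSignature:
    """Unweighted axis-aligned 68-element signature on a regular lattice."""
    config = config or RunConfig()
    if seg is None:
        seg = segm.segment_all(image, K=config.density_clusters)
    paren = seg.breast_mask & ~seg.pectoralis_mask
    grid = build_lattice_grid(paren, image.pixel_spacing_mm, spacing_mm, window_mm,
                              region_min_coverage=config.region_min_coverage,
                              min_region_pixels=config.min_region_pixels)
    maps = tex.compute_feature_maps(image, grid, config, orientation_mode="axis_aligned")
    return wgt.summarize_signature(maps, subject_id=image.subject_id,
                                   side_label=image.side_label, sampler="lattice")
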