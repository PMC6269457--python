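"""Breast anatomy parameterization.

Standardizes orientation (pectoral boundary vertical on the left, right
breasts mirrored), locates the nipple, defines the central breast area (CBA)
and upper-outer area (UOA) from the nipple-to-pectoralis distance r_P, and
builds the nipple-centred polar grid used as the texture sampling lattice.

Coordinate convention: row-major, 0-based, origin top-left.  Angles around
the nipple are measured counterclockwise from the leftward direction (from
the nipple toward the chest wall), with "up" (decreasing row) at +90 deg.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from .io_formats import MammogramImage
from .segmentation import BreastSegmentation, PectoralLine


class AnatomyError(RuntimeError):
    pass


@dataclass
class StandardTransform:
    """Horizontal flip (right breasts) followed by a rotation about the centre."""

    flipped: bool
    angle_deg: float          # content rotation that makes the pectoral line vertical
    shape: tuple[int, int]

    def _rot(self, sign: float) -> np.ndarray:
        t = np.deg2rad(sign * self.angle_deg)
        return np.array([[np.cos(t), -np.sin(t)], [np.sin(t), np.cos(t)]])

    def _centre(self) -> np.ndarray:
        H, W = self.shape
        return np.array([(H - 1) / 2.0, (W - 1) / 2.0])

    def apply_array(self, arr: np.ndarray, order: int = 1) -> np.ndarray:
        out = arr[:, ::-1] if self.flipped else arr
        if self.angle_deg == 0.0:
            return out.copy()
        m = self._centre()
        mat = self._rot(-1.0)
        return ndi.affine_transform(out.astype(float), mat, offset=m - mat @ m,
                                    order=order, mode="constant", cval=0.0)

    def apply_mask(self, mask: np.ndarray) -> np.ndarray:
        return self.apply_array(mask.astype(np.uint8), order=0).astype(bool)

    def apply_labels(self, labels: np.ndarray) -> np.ndarray:
        return self.apply_array(labels.astype(float), order=0).astype(labels.dtype)

    def apply_point(self, row: float, col: float) -> tuple[float, float]:
        H, W = self.shape
        c = W - 1 - col if self.flipped else col
        p = np.array([row, c])
        q = self._rot(+1.0) @ (p - self._centre()) + self._centre()
        return float(q[0]), float(q[1])

    def invert_mask(self, mask: np.ndarray) -> np.ndarray:
        out = mask.astype(np.uint8)
        if self.angle_deg != 0.0:
            m = self._centre()
            mat = self._rot(+1.0)
            out = ndi.affine_transform(out.astype(float), mat, offset=m - mat @ m,
                                       order=0, mode="constant", cval=0.0)
        out = out.astype(bool)
        return out[:, ::-1].copy() if self.flipped else out


@dataclass
class BreastAnatomy:
    """Standardized image plus anatomical landmarks and quadrant masks."""

    standardized_image: MammogramImage
    transform: StandardTransform
    segmentation: BreastSegmentation      # masks in standardized coordinates
    pectoral_col: float | None            # vertical pectoral line column (px)
    nipple: tuple[float, float] | None = None
    r_P_mm: float | None = None
    cba_mask: np.ndarray | None = None
    uoa_mask: np.ndarray | None = None
    f: float | None = None


def standardize_orientation(image: MammogramImage, seg: BreastSegmentation) -> BreastAnatomy:
    """Rotate so the pectoral boundary is vertical; mirror right breasts.

    Without a detected pectoral line the rotation is the identity (flagged)
    and only the laterality flip is applied.
    """
    H, W = image.pixels.shape
    flip = image.laterality == "right"
    line = seg.pectoral_line
    if line is not None and flip:
        line = line.mirrored(W)
    if line is None:
        warnings.warn("no pectoral line; identity rotation")
        angle = 0.0
    else:
        angle = line.angle_deg
    tr = StandardTransform(flipped=flip, angle_deg=angle, shape=(H, W))
    std_px = np.clip(tr.apply_array(image.pixels, order=1), 0, None)
    std_img = MammogramImage(pixels=std_px, pixel_spacing_mm=image.pixel_spacing_mm,
                             laterality=image.laterality, view=image.view,
                             subject_id=image.subject_id, side_label=image.side_label)
    std_seg = BreastSegmentation(
        breast_mask=tr.apply_mask(seg.breast_mask),
        pectoralis_mask=tr.apply_mask(seg.pectoralis_mask),
        pectoral_line=None,
        density_cluster_labels=tr.apply_labels(seg.density_cluster_labels),
        dense_mask=tr.apply_mask(seg.dense_mask),
        K=seg.K,
        foreground_mask=tr.apply_mask(seg.foreground_mask)
        if seg.foreground_mask is not None else None,
    )
    pect_col = None
    if line is not None:
        # after the rotation the line is vertical at this column
        t = np.deg2rad(line.angle_deg)
        pect_col = float(line.dist + (W - 1) / 2.0 * (1 - np.cos(t)) - (H - 1) / 2.0 * np.sin(t))
        std_seg.pectoral_line = PectoralLine(angle_deg=0.0, dist=pect_col)
    return BreastAnatomy(standardized_image=std_img, transform=tr,
                         segmentation=std_seg, pectoral_col=pect_col)


def locate_nipple(breast_mask: np.ndarray, pixel_spacing_mm: float,
                  box_mm: float = 15.0) -> tuple[float, float]:
    """Nipple as the centroid of the rightmost breast region in a 1.5 cm box."""
    if not breast_mask.any():
        raise AnatomyError("empty breast mask")
    cols_any = np.nonzero(breast_mask.any(axis=0))[0]
    c_max = int(cols_any[-1])
    w = max(1, int(round(box_mm / pixel_spacing_mm)))
    rows_at_cmax = np.nonzero(breast_mask[:, c_max])[0]
    rc = float(rows_at_cmax.mean())
    r_lo = max(0, int(round(rc - w / 2)))
    r_hi = min(breast_mask.shape[0], int(round(rc + w / 2)) + 1)
    c_lo = max(0, c_max - w + 1)
    box = np.zeros_like(breast_mask)
    box[r_lo:r_hi, c_lo:c_max + 1] = True
    sel = breast_mask & box
    rr, cc = np.nonzero(sel)
    return float(rr.mean()), float(cc.mean())


def define_quadrants(anatomy: BreastAnatomy, f: float) -> BreastAnatomy:
    """CBA = breast within f*r_P of the nipple; UOA = above the nipple, beyond.

    r_P is the perpendicular distance from the pectoral boundary to the
    nipple; with no detected pectoralis the distance to the left image edge
    is used (flagged).
    """
    if not (0.5 <= f <= 1.0):
        raise ValueError("f must lie in [0.5, 1]")
    seg = anatomy.segmentation
    paren = seg.breast_mask & ~seg.pectoralis_mask
    sp = anatomy.standardized_image.pixel_spacing_mm
    if anatomy.nipple is None:
        anatomy.nipple = locate_nipple(paren, sp)
    nr, nc = anatomy.nipple
    if anatomy.pectoral_col is not None:
        r_p_px = abs(nc - anatomy.pectoral_col)
    else:
        warnings.warn("no pectoral line; r_P from left image edge")
        r_p_px = nc
    if r_p_px <= 0:
        raise AnatomyError("nipple lies on the pectoral line; degenerate r_P")
    H, W = paren.shape
    rr, cc = np.mgrid[0:H, 0:W]
    d = np.hypot(rr - nr, cc - nc)
    cba = paren & (d < f * r_p_px)
    uoa = paren & (rr < nr) & (d > f * r_p_px)
    anatomy.r_P_mm = float(r_p_px * sp)
    anatomy.cba_mask = cba
    anatomy.uoa_mask = uoa
    anatomy.f = f
    return anatomy


# ---------------------------------------------------------------------------
# Polar grid


@dataclass
class PolarRegion:
    ring_index: int
    sector_index: int
    mask: np.ndarray
    centroid: tuple[float, float]
    azimuth_deg: float
    coverage: float


@dataclass
class PolarGrid:
    """Nipple-centred ring x sector partition of the parenchyma.

    ``label_map`` assigns each retained-region pixel its region index
    (0..n-1) and -1 elsewhere; per-region attributes are parallel arrays.
    """

    D_mm: float
    nipple: tuple[float, float]
    n_sectors: int
    label_map: np.ndarray
    ring_index: np.ndarray
    sector_index: np.ndarray
    centroids: np.ndarray        # (n, 2) row, col
    azimuth_deg: np.ndarray
    coverage: np.ndarray
    pixel_count: np.ndarray
    dropped_pixels: int = 0

    @property
    def n_regions(self) -> int:
        return len(self.ring_index)

    @property
    def regions(self) -> list[PolarRegion]:
        return [
            PolarRegion(int(self.ring_index[i]), int(self.sector_index[i]),
                        self.label_map == i, (self.centroids[i, 0], self.centroids[i, 1]),
                        float(self.azimuth_deg[i]), float(self.coverage[i]))
            for i in range(self.n_regions)
        ]


def build_polar_grid(
    anatomy: BreastAnatomy,
    D_mm: float,
    region_min_coverage: float = 0.5,
    min_region_pixels: int = 25,
) -> PolarGrid:
    """Rings are [i*D, (i+1)*D) annuli of nipple distance; sectors are equal
    wedges sized so the arc length at r_P is about D (at least 8), so regions
    near the nipple are smaller - denser retro-areolar sampling.

    A candidate region (ring x sector x parenchyma) is retained when its
    breast coverage and pixel count meet the thresholds.
    """
    if D_mm <= 0:
        raise ValueError("D_mm must be positive")
    if anatomy.nipple is None or anatomy.r_P_mm is None:
        raise AnatomyError("quadrants must be defined before the grid")
    seg = anatomy.segmentation
    paren = seg.breast_mask & ~seg.pectoralis_mask
    sp = anatomy.standardized_image.pixel_spacing_mm
    nr, nc = anatomy.nipple
    H, W = paren.shape
    rr, cc = np.mgrid[0:H, 0:W].astype(np.float64)
    d = np.hypot(rr - nr, cc - nc)
    D_px = D_mm / sp
    r_p_px = anatomy.r_P_mm / sp
    n_sectors = max(8, int(round(np.pi * r_p_px / D_px)))

    ring = np.floor(d / D_px).astype(np.int64)
    phi = np.arctan2(nr - rr, nc - cc)           # 0 = leftward, CCW, up = +90
    sector = np.floor((phi + np.pi) / (2 * np.pi / n_sectors)).astype(np.int64)
    sector = np.clip(sector, 0, n_sectors - 1)
    cell = ring * n_sectors + sector

    n_cells = int(cell.max()) + 1
    full_counts = np.bincount(cell.ravel(), minlength=n_cells)
    breast_counts = np.bincount(cell[paren], minlength=n_cells)
    coverage = np.divide(breast_counts, full_counts, out=np.zeros(n_cells),
                         where=full_counts > 0)
    retained = (coverage >= region_min_coverage) & (breast_counts >= min_region_pixels)
    cell_ids = np.nonzero(retained)[0]
    if len(cell_ids) == 0:
        raise AnatomyError("polar grid retained zero regions")
    # deterministic ordering by (ring, sector)
    order = np.lexsort((cell_ids % n_sectors, cell_ids // n_sectors))
    cell_ids = cell_ids[order]
    lut = np.full(n_cells, -1, dtype=np.int64)
    lut[cell_ids] = np.arange(len(cell_ids))
    label_map = np.full((H, W), -1, dtype=np.int64)
    label_map[paren] = lut[cell[paren]]

    n = len(cell_ids)
    pix = np.bincount(label_map[label_map >= 0], minlength=n)
    cent_r = np.bincount(label_map[label_map >= 0], weights=rr[label_map >= 0], minlength=n) / pix
    cent_c = np.bincount(label_map[label_map >= 0], weights=cc[label_map >= 0], minlength=n) / pix
    ring_idx = cell_ids // n_sectors
    sec_idx = cell_ids % n_sectors
    azim = np.rad2deg((sec_idx + 0.5) * (2 * np.pi / n_sectors) - np.pi)
    dropped = int(paren.sum() - pix.sum())
    return PolarGrid(D_mm=D_mm, nipple=(nr, nc), n_sectors=n_sectors,
                     label_map=label_map, ring_index=ring_idx, sector_index=sec_idx,
                     centroids=np.stack([cent_r, cent_c], axis=1),
                     azimuth_deg=azim, coverage=coverage[cell_ids],
                     pixel_count=pix, dropped_pixels=dropped)
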