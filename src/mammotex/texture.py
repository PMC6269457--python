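"""The 34 parenchymal texture descriptors, computed per sampling region.

Feature families (ids are fixed; the signature stage depends on this order):

* TF1-TF13   gray-level histogram (first-order) statistics
* TF14-TF20  gray-level co-occurrence (Haralick/Conners formulations)
* TF21-TF31  gray-level run-length (Galloway/Chu/Dasarathy-Holder statistics)
* TF32-TF34  structural: edge-enhancing index, box-counting fractal
             dimension, local-binary-pattern uniformity

Directional features can be *anatomy aligned*: the co-occurrence matrix
accumulates pixel pairs along the region's radial and tangential unit
offsets (rotated by the region's azimuth on the polar grid, rounded to the
nearest integer displacement) and run lengths are measured along the radial
direction.  Axis-aligned mode (horizontal + vertical co-occurrence,
horizontal runs) serves the regular-lattice comparator.

Quantization bounds are taken from the whole-breast intensity range so
levels are comparable across regions of one image.

Degenerate conventions (all keep every feature finite, and are flagged):
zero-variance regions have skewness = kurtosis = co-occurrence correlation
= 0, energy = 1, entropies = 0; regions with a bounding box smaller than
8x8 get fractal dimension 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.feature import local_binary_pattern

FEATURE_NAMES: tuple[str, ...] = (
    "TF1", "TF2", "TF3", "TF4", "TF5", "TF6", "TF7", "TF8", "TF9", "TF10",
    "TF11", "TF12", "TF13",
    "TF14", "TF15", "TF16", "TF17", "TF18", "TF19", "TF20",
    "TF21", "TF22", "TF23", "TF24", "TF25", "TF26", "TF27", "TF28", "TF29",
    "TF30", "TF31",
    "TF32", "TF33", "TF34",
)

FEATURE_DESCRIPTIONS: dict[str, str] = {
    "TF1": "5th Percentile", "TF2": "5th Mean", "TF3": "95th Percentile",
    "TF4": "95th Mean", "TF5": "Entropy", "TF6": "Kurtosis", "TF7": "Max",
    "TF8": "Mean", "TF9": "Min", "TF10": "Sigma", "TF11": "Skewness",
    "TF12": "Sum", "TF13": "Median",
    "TF14": "Contrast", "TF15": "Correlation", "TF16": "Homogeneity",
    "TF17": "Energy", "TF18": "Entropy", "TF19": "Inverse Difference Moment",
    "TF20": "Cluster Shade",
    "TF21": "Short Run Emphasis", "TF22": "Long Run Emphasis",
    "TF23": "Gray Level Non-uniformity", "TF24": "Run Length Non-uniformity",
    "TF25": "Run Percentage", "TF26": "Low Gray Level Run Emphasis",
    "TF27": "High Gray Level Run Emphasis",
    "TF28": "Short Run Low Gray Level Emphasis",
    "TF29": "Short Run High Gray Level Emphasis",
    "TF30": "Long Run Low Gray Level Emphasis",
    "TF31": "Long Run High Gray Level Emphasis",
    "TF32": "Edge-enhancing index", "TF33": "Box-Counting Fractal Dimension",
    "TF34": "Local Binary Pattern",
}

N_FEATURES = 34
_EPS = 1e-12

# the four undirected integer unit directions (king moves up to sign)
DIRECTIONS: tuple[tuple[int, int], ...] = ((0, 1), (1, 0), (1, 1), (1, -1))


# ---------------------------------------------------------------------------
# Quantization


def quantize(values: np.ndarray, vmin: float, vmax: float, G: int) -> np.ndarray:
    """Uniformly bin [vmin, vmax] into G levels 1..G (constant range -> 1)."""
    if G < 2:
        raise ValueError("G must be >= 2")
    values = np.asarray(values, float)
    if vmax <= vmin:
        return np.ones(values.shape, dtype=np.int32)
    lvl = 1 + np.floor((values - vmin) / (vmax - vmin) * G)
    return np.clip(lvl, 1, G).astype(np.int32)


@dataclass
class QuantizedRegion:
    """Quantized levels on a bounding-box patch with a region mask."""

    levels: np.ndarray     # 2D int, valid where mask
    mask: np.ndarray       # 2D bool
    G: int

    @property
    def pixel_count(self) -> int:
        return int(self.mask.sum())


# ---------------------------------------------------------------------------
# Single-region reference implementations (also used by unit tests)


def histogram_features(values: np.ndarray, levels: np.ndarray | None = None,
                       G: int = 128) -> np.ndarray:
    """TF1-TF13 for one region.

    ``levels`` are the whole-breast-range quantized levels used for the
    entropy (TF5); when omitted the region's own range is used.
    """
    v = np.asarray(values, float).ravel()
    if v.size == 0:
        raise ValueError("empty region")
    if levels is None:
        levels = quantize(v, v.min(), v.max(), G)
    lv = np.asarray(levels).ravel()
    q5, q95 = np.percentile(v, [5, 95])
    mean5 = v[v <= q5].mean()
    mean95 = v[v >= q95].mean()
    counts = np.bincount(lv - 1, minlength=G).astype(float)
    p = counts[counts > 0] / v.size
    entropy = float(-(p * np.log2(p)).sum())
    n = v.size
    mean = v.mean()
    m2 = ((v - mean) ** 2).mean()
    if m2 <= _EPS * max(1.0, mean**2):
        skew = kurt = 0.0
        sigma = 0.0
    else:
        sigma = np.sqrt(m2)
        skew = ((v - mean) ** 3).mean() / sigma**3
        kurt = ((v - mean) ** 4).mean() / m2**2 - 3.0
    return np.array([q5, mean5, q95, mean95, entropy, kurt, v.max(), mean,
                     v.min(), sigma, skew, v.sum(), np.median(v)])


def glcm_matrix(q: QuantizedRegion, offsets) -> np.ndarray:
    """Symmetric normalized G x G co-occurrence matrix over the offsets."""
    G = q.G
    M = np.zeros((G, G))
    lev = q.levels
    msk = q.mask
    H, W = msk.shape
    for dr, dc in offsets:
        r0, r1 = max(0, -dr), min(H, H - dr)
        c0, c1 = max(0, -dc), min(W, W - dc)
        a = msk[r0:r1, c0:c1] & msk[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
        i = lev[r0:r1, c0:c1][a] - 1
        j = lev[r0 + dr:r1 + dr, c0 + dc:c1 + dc][a] - 1
        np.add.at(M, (i, j), 1.0)
        np.add.at(M, (j, i), 1.0)
    s = M.sum()
    return M / s if s > 0 else M


def glcm_features(q: QuantizedRegion, offsets) -> np.ndarray:
    """TF14-TF20 from the symmetric co-occurrence matrix."""
    P = glcm_matrix(q, offsets)
    if P.sum() == 0:  # no valid pairs: degenerate conventions
        return np.array([0.0, 0.0, 1.0, 1.0, 0.0, 1.0, 0.0])
    G = q.G
    i, j = np.mgrid[1:G + 1, 1:G + 1]
    contrast = float((P * (i - j) ** 2).sum())
    homog = float((P / (1.0 + np.abs(i - j))).sum())
    idm = float((P / (1.0 + (i - j) ** 2)).sum())
    energy = float((P**2).sum())
    nz = P[P > 0]
    entropy = float(-(nz * np.log2(nz)).sum())
    mu = float((P * i).sum())
    var = float((P * (i - mu) ** 2).sum())
    if var <= _EPS:
        corr = 0.0
    else:
        corr = float((P * (i - mu) * (j - mu)).sum() / var)
    shade = float((P * (i + j - 2 * mu) ** 3).sum())
    return np.array([contrast, corr, homog, energy, entropy, idm, shade])


def run_lengths(q: QuantizedRegion, direction: tuple[int, int]):
    """Maximal constant-level runs along the direction, broken at the region
    boundary; returns (levels, lengths) arrays."""
    dr, dc = direction
    msk, lev = q.mask, q.levels
    H, W = msk.shape
    levels, lengths = [], []
    starts = [
        (r, c) for r in range(H) for c in range(W)
        if msk[r, c] and not (0 <= r - dr < H and 0 <= c - dc < W and msk[r - dr, c - dc])
    ]
    for r0, c0 in starts:
        r, c = r0, c0
        cur = lev[r, c]
        length = 0
        while 0 <= r < H and 0 <= c < W and msk[r, c]:
            if lev[r, c] != cur:
                levels.append(cur)
                lengths.append(length)
                cur = lev[r, c]
                length = 0
            length += 1
            r, c = r + dr, c + dc
        levels.append(cur)
        lengths.append(length)
    return np.asarray(levels, float), np.asarray(lengths, float)


def runlength_stats(levels: np.ndarray, lengths: np.ndarray, n_pixels: int,
                    G: int) -> np.ndarray:
    """The 11 run-length statistics TF21-TF31 from a run list."""
    n_runs = len(lengths)
    if n_runs == 0:
        return np.zeros(11)
    g, l = levels, lengths
    nr = float(n_runs)
    sre = float((1.0 / l**2).sum() / nr)
    lre = float((l**2).sum() / nr)
    gln = float(sum(c**2 for c in np.bincount(g.astype(int))) / nr)
    rln = float(sum(c**2 for c in np.bincount(l.astype(int))) / nr)
    rp = nr / float(n_pixels)
    lgl = float((1.0 / g**2).sum() / nr)
    hgl = float((g**2).sum() / nr)
    srlgl = float((1.0 / (g**2 * l**2)).sum() / nr)
    srhgl = float((g**2 / l**2).sum() / nr)
    lrlgl = float((l**2 / g**2).sum() / nr)
    lrhgl = float((g**2 * l**2).sum() / nr)
    return np.array([sre, lre, gln, rln, rp, lgl, hgl, srlgl, srhgl, lrlgl, lrhgl])


def runlength_features(q: QuantizedRegion, direction: tuple[int, int]) -> np.ndarray:
    lev, lng = run_lengths(q, direction)
    return runlength_stats(lev, lng, q.pixel_count, q.G)


def fractal_dimension(binary: np.ndarray, mask: np.ndarray | None = None) -> float:
    """Box-counting dimension of a binary pattern; 0 when the bounding box is
    smaller than 8x8 or the pattern is empty (flagged fallback)."""
    pat = np.asarray(binary, bool)
    if mask is not None:
        pat = pat & mask
    if min(pat.shape) < 8 or not pat.any():
        return 0.0
    sizes = []
    s = 1
    while s <= min(pat.shape) // 2:
        sizes.append(s)
        s *= 2
    if len(sizes) < 3:
        return 0.0
    counts = []
    for s in sizes:
        H, W = pat.shape
        hh, ww = -(-H // s), -(-W // s)
        padded = np.zeros((hh * s, ww * s), bool)
        padded[:H, :W] = pat
        boxes = padded.reshape(hh, s, ww, s).any(axis=(1, 3))
        counts.append(boxes.sum())
    slope = np.polyfit(np.log(sizes), np.log(counts), 1)[0]
    return float(-slope)


def structural_features(values_patch: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """TF32-TF34 for one region given its bounding-box patch.

    Gradients and LBP codes here use only the patch (boundary effects at the
    bbox edge); the image-level pipeline computes both on the full image.
    """
    gx = ndi.sobel(values_patch, axis=1)
    gy = ndi.sobel(values_patch, axis=0)
    grad = np.hypot(gx, gy)
    mean_int = values_patch[mask].mean()
    tf32 = float(grad[mask].mean() / mean_int) if abs(mean_int) > _EPS else 0.0
    med = np.median(values_patch[mask])
    tf33 = fractal_dimension(values_patch > med, mask)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        codes = local_binary_pattern(values_patch, P=8, R=1, method="uniform")
    tf34 = float((codes[mask] != 9).mean())
    return np.array([tf32, tf33, tf34])


# ---------------------------------------------------------------------------
# Vectorized per-image extraction over a region label map


@dataclass
class FeatureMaps:
    """34 features per retained region, aligned to the grid's region order."""

    values: np.ndarray                 # (n_regions, 34)
    feature_ids: tuple[str, ...] = FEATURE_NAMES
    orientation_mode: str = "anatomy_aligned"
    ring_index: np.ndarray | None = None
    sector_index: np.ndarray | None = None
    centroids: np.ndarray | None = None
    weights: np.ndarray | None = None
    flags: list = field(default_factory=list)

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]

    def feature(self, fid: str) -> np.ndarray:
        return self.values[:, self.feature_ids.index(fid)]

    def to_frame(self) -> pd.DataFrame:
        n = self.n_regions
        df = pd.DataFrame({
            "region_id": np.arange(n),
            "ring": self.ring_index if self.ring_index is not None else np.zeros(n, int),
            "sector": self.sector_index if self.sector_index is not None else np.zeros(n, int),
            "centroid_row": self.centroids[:, 0] if self.centroids is not None else np.zeros(n),
            "centroid_col": self.centroids[:, 1] if self.centroids is not None else np.zeros(n),
            "weight": self.weights if self.weights is not None else np.ones(n),
        })
        for k, fid in enumerate(self.feature_ids):
            df[fid] = self.values[:, k]
        return df


def _canon(dr: int, dc: int) -> tuple[int, int]:
    if dr < 0 or (dr == 0 and dc < 0):
        dr, dc = -dr, -dc
    return dr, dc


def round_direction(vec: tuple[float, float]) -> tuple[int, int]:
    """Nearest integer (king-move) displacement to a unit vector, canonical sign."""
    dr = int(np.rint(vec[0]))
    dc = int(np.rint(vec[1]))
    if dr == 0 and dc == 0:
        if abs(vec[0]) >= abs(vec[1]):
            dr = 1 if vec[0] > 0 else -1
        else:
            dc = 1 if vec[1] > 0 else -1
    return _canon(dr, dc)


def region_directions(azimuth_deg: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-region radial and tangential direction indices into DIRECTIONS."""
    lut = {d: k for k, d in enumerate(DIRECTIONS)}
    rad = np.empty(len(azimuth_deg), np.int64)
    tan = np.empty(len(azimuth_deg), np.int64)
    for k, az in enumerate(np.deg2rad(azimuth_deg)):
        rad[k] = lut[round_direction((-np.sin(az), -np.cos(az)))]
        tan[k] = lut[round_direction((-np.cos(az), np.sin(az)))]
    return rad, tan


_TRAVERSAL_CACHE: dict = {}


def _traversal(shape: tuple[int, int], d: tuple[int, int]):
    """Pixel ordering that walks the image along direction d, line by line."""
    key = (shape, d)
    if key in _TRAVERSAL_CACHE:
        return _TRAVERSAL_CACHE[key]
    H, W = shape
    rr, cc = np.mgrid[0:H, 0:W]
    if d == (0, 1):
        line, prog = rr, cc
    elif d == (1, 0):
        line, prog = cc, rr
    elif d == (1, 1):
        line, prog = cc - rr, rr
    elif d == (1, -1):
        line, prog = cc + rr, rr
    else:  # pragma: no cover
        raise ValueError(f"unsupported direction {d}")
    order = np.lexsort((prog.ravel(), line.ravel()))
    lines = line.ravel()[order]
    _TRAVERSAL_CACHE[key] = (order, lines)
    return order, lines


def _hist_block(values, label_map, n, levels, G):
    """TF1-TF13 for all regions at once."""
    sel = label_map >= 0
    lab = label_map[sel]
    v = values[sel]
    lv = levels[sel]
    order = np.lexsort((v, lab))
    sv, sl = v[order], lab[order]
    cnt = np.bincount(lab, minlength=n).astype(np.int64)
    b = np.concatenate([[0], np.cumsum(cnt)])
    csum = np.concatenate([[0.0], np.cumsum(sv)])

    out = np.empty((n, 13))

    def percentile(p):
        pos = b[:-1] + (cnt - 1) * (p / 100.0)
        lo = np.floor(pos).astype(np.int64)
        hi = np.minimum(lo + 1, b[1:] - 1)
        frac = pos - lo
        return sv[lo] * (1 - frac) + sv[hi] * frac

    q5 = percentile(5.0)
    q95 = percentile(95.0)
    q50 = percentile(50.0)
    n_le = np.empty(n, np.int64)
    n_lt95 = np.empty(n, np.int64)
    for k in range(n):
        seg = sv[b[k]:b[k + 1]]
        n_le[k] = np.searchsorted(seg, q5[k], side="right")
        n_lt95[k] = np.searchsorted(seg, q95[k], side="left")
    mean5 = (csum[b[:-1] + n_le] - csum[b[:-1]]) / np.maximum(n_le, 1)
    n_ge = cnt - n_lt95
    mean95 = (csum[b[1:]] - csum[b[:-1] + n_lt95]) / np.maximum(n_ge, 1)

    s1 = np.bincount(lab, weights=v, minlength=n)
    mean = s1 / cnt
    dv = v - mean[lab]
    m2 = np.bincount(lab, weights=dv**2, minlength=n) / cnt
    m3 = np.bincount(lab, weights=dv**3, minlength=n) / cnt
    m4 = np.bincount(lab, weights=dv**4, minlength=n) / cnt
    nz = m2 > _EPS * np.maximum(1.0, mean**2)
    sigma = np.sqrt(np.where(nz, m2, 0.0))
    skew = np.where(nz, m3 / np.where(nz, sigma**3, 1.0), 0.0)
    kurt = np.where(nz, m4 / np.where(nz, m2**2, 1.0) - 3.0, 0.0)

    hcounts = np.bincount(lab * G + (lv - 1), minlength=n * G).reshape(n, G)
    p = hcounts / cnt[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log2(p), 0.0)
    entropy = -plogp.sum(axis=1)

    out[:, 0] = q5
    out[:, 1] = mean5
    out[:, 2] = q95
    out[:, 3] = mean95
    out[:, 4] = entropy
    out[:, 5] = kurt
    out[:, 6] = sv[b[1:] - 1]      # max
    out[:, 7] = mean
    out[:, 8] = sv[b[:-1]]         # min
    out[:, 9] = sigma
    out[:, 10] = skew
    out[:, 11] = s1
    out[:, 12] = q50
    return out


def _glcm_block(levels, label_map, n, G, rdir, tdir):
    """TF14-TF20 for all regions: pairs along each region's two offsets."""
    H, W = label_map.shape
    I_parts, J_parts, R_parts = [], [], []
    for oi, (dr, dc) in enumerate(DIRECTIONS):
        r0, r1 = max(0, -dr), min(H, H - dr)
        c0, c1 = max(0, -dc), min(W, W - dc)
        la = label_map[r0:r1, c0:c1]
        lb = label_map[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
        valid = (la >= 0) & (la == lb)
        if not valid.any():
            continue
        reg = la[valid]
        use = (rdir[reg] == oi) | (tdir[reg] == oi)
        if not use.any():
            continue
        reg = reg[use]
        i = levels[r0:r1, c0:c1][valid][use]
        j = levels[r0 + dr:r1 + dr, c0 + dc:c1 + dc][valid][use]
        I_parts.append(i)
        J_parts.append(j)
        R_parts.append(reg)
    out = np.zeros((n, 7))
    out[:, 3] = 1.0  # energy
    out[:, 2] = 1.0  # homogeneity
    out[:, 5] = 1.0  # IDM
    if not R_parts:
        return out
    i0 = np.concatenate(I_parts).astype(np.float64)
    j0 = np.concatenate(J_parts).astype(np.float64)
    r0_ = np.concatenate(R_parts)
    # symmetrize
    I = np.concatenate([i0, j0])
    J = np.concatenate([j0, i0])
    R = np.concatenate([r0_, r0_])
    N = np.bincount(R, minlength=n).astype(np.float64)
    has = N > 0
    Ns = np.where(has, N, 1.0)

    def E(w):
        return np.bincount(R, weights=w, minlength=n) / Ns

    diff = I - J
    contrast = E(diff**2)
    homog = E(1.0 / (1.0 + np.abs(diff)))
    idm = E(1.0 / (1.0 + diff**2))
    mu = E(I)
    var = E(I**2) - mu**2
    cov = E(I * J) - mu**2
    corr = np.where(var > _EPS, cov / np.where(var > _EPS, var, 1.0), 0.0)
    s = I + J
    shade = (E(s**3) - 6 * mu * E(s**2) + 12 * mu**2 * E(s) - 8 * mu**3)

    key = R.astype(np.int64) * (G * G) + (I.astype(np.int64) - 1) * G + (J.astype(np.int64) - 1)
    uk, counts = np.unique(key, return_counts=True)
    ureg = (uk // (G * G)).astype(np.int64)
    p = counts / Ns[ureg]
    energy = np.bincount(ureg, weights=p**2, minlength=n)
    entropy = -np.bincount(ureg, weights=p * np.log2(p), minlength=n)

    out[has, 0] = contrast[has]
    out[has, 1] = corr[has]
    out[has, 2] = homog[has]
    out[has, 3] = energy[has]
    out[has, 4] = entropy[has]
    out[has, 5] = idm[has]
    out[has, 6] = shade[has]
    return out


def _runlength_block(levels, label_map, n, G, rdir, pixel_count):
    """TF21-TF31 for all regions: runs along each region's radial direction."""
    flat_lab = label_map.ravel()
    flat_lvl = levels.ravel()
    Gs, Ls, Rs = [], [], []
    for oi, d in enumerate(DIRECTIONS):
        if not np.any(rdir == oi):
            continue
        order, lines = _traversal(label_map.shape, d)
        sl = flat_lab[order]
        sv = flat_lvl[order]
        new = np.ones(len(sl), bool)
        new[1:] = (lines[1:] != lines[:-1]) | (sl[1:] != sl[:-1]) | (sv[1:] != sv[:-1])
        starts = np.nonzero(new)[0]
        lens = np.diff(np.append(starts, len(sl)))
        labs = sl[starts]
        keep = labs >= 0
        labs, lens_k, levs = labs[keep], lens[keep], sv[starts][keep]
        keep2 = rdir[labs] == oi
        Gs.append(levs[keep2].astype(np.float64))
        Ls.append(lens_k[keep2].astype(np.float64))
        Rs.append(labs[keep2])
    out = np.zeros((n, 11))
    if not Rs:
        return out
    g = np.concatenate(Gs)
    l = np.concatenate(Ls)
    r = np.concatenate(Rs)
    N = np.bincount(r, minlength=n).astype(np.float64)
    has = N > 0
    Ns = np.where(has, N, 1.0)

    def S(w):
        return np.bincount(r, weights=w, minlength=n) / Ns

    sre, lre = S(1.0 / l**2), S(l**2)
    lgl, hgl = S(1.0 / g**2), S(g**2)
    srlgl = S(1.0 / (g**2 * l**2))
    srhgl = S(g**2 / l**2)
    lrlgl = S(l**2 / g**2)
    lrhgl = S(g**2 * l**2)
    gcnt = np.bincount(r * G + (g.astype(np.int64) - 1), minlength=n * G).reshape(n, G)
    gln = (gcnt.astype(np.float64) ** 2).sum(axis=1) / Ns
    lmax = int(l.max())
    lcnt = np.bincount(r * lmax + (l.astype(np.int64) - 1), minlength=n * lmax).reshape(n, lmax)
    rln = (lcnt.astype(np.float64) ** 2).sum(axis=1) / Ns
    rp = N / np.maximum(pixel_count, 1)
    for col, arr in enumerate([sre, lre, gln, rln, rp, lgl, hgl, srlgl,
                               srhgl, lrlgl, lrhgl]):
        out[has, col] = arr[has]
    return out


def _structural_block(values, label_map, n, levels):
    """TF32-TF34 for all regions; gradients/LBP computed on the full image."""
    gx = ndi.sobel(values, axis=1)
    gy = ndi.sobel(values, axis=0)
    grad = np.hypot(gx, gy)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        codes = local_binary_pattern(levels.astype(np.int32), P=8, R=1, method="uniform")
    sel = label_map >= 0
    lab = label_map[sel]
    cnt = np.bincount(lab, minlength=n).astype(np.float64)
    mean_int = np.bincount(lab, weights=values[sel], minlength=n) / cnt
    mean_grad = np.bincount(lab, weights=grad[sel], minlength=n) / cnt
    tf32 = np.where(np.abs(mean_int) > _EPS, mean_grad / np.where(np.abs(mean_int) > _EPS, mean_int, 1.0), 0.0)
    uni = np.bincount(lab, weights=(codes[sel] != 9).astype(float), minlength=n) / cnt
    tf33 = np.zeros(n)
    slices = ndi.find_objects(label_map + 1)
    for k, sl in enumerate(slices):
        if sl is None:
            continue
        patch = values[sl]
        msk = label_map[sl] == k
        med = np.median(patch[msk])
        tf33[k] = fractal_dimension(patch > med, msk)
    out = np.empty((n, 3))
    out[:, 0] = tf32
    out[:, 1] = tf33
    out[:, 2] = uni
    return out


def compute_feature_maps(
    standardized_image,
    grid,
    config=None,
    orientation_mode: str = "anatomy_aligned",
    gray_levels: int | None = None,
) -> FeatureMaps:
    """All 34 features for every retained region of the polar grid.

    In anatomy-aligned mode the co-occurrence matrix accumulates the radial
    and tangential offsets of each region and run lengths follow the radial
    direction; axis-aligned mode uses horizontal+vertical co-occurrence and
    horizontal runs.
    """
    G = gray_levels or (config.gray_levels if config is not None else 128)
    label_map = grid.label_map
    n = grid.n_regions
    if n == 0:
        raise ValueError("grid has no regions")
    values = standardized_image.pixels
    sel = label_map >= 0
    vmin, vmax = values[sel].min(), values[sel].max()
    levels = quantize(values, vmin, vmax, G)

    if orientation_mode == "anatomy_aligned":
        rdir, tdir = region_directions(grid.azimuth_deg)
    elif orientation_mode == "axis_aligned":
        rdir = np.zeros(n, np.int64)           # (0, 1) horizontal runs
        tdir = np.ones(n, np.int64)            # (1, 0) vertical pairs
    else:
        raise ValueError(f"unknown orientation mode {orientation_mode!r}")

    out = np.empty((n, N_FEATURES))
    out[:, 0:13] = _hist_block(values, label_map, n, levels, G)
    out[:, 13:20] = _glcm_block(levels, label_map, n, G, rdir, tdir)
    out[:, 20:31] = _runlength_block(levels, label_map, n, G, rdir, grid.pixel_count)
    out[:, 31:34] = _structural_block(values, label_map, n, levels)
    return FeatureMaps(values=out, orientation_mode=orientation_mode,
                       ring_index=np.asarray(grid.ring_index),
                       sector_index=np.asarray(grid.sector_index),
                       centroids=np.asarray(grid.centroids))
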