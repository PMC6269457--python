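"""Image and table IO plus the run configuration.

Conventions
-----------
* Images are 2D arrays of non-negative intensities with *higher value =
  denser tissue*.  Raw ("for processing") mammograms from some vendors use
  inverted radiographic contrast; set ``invert_on_load`` in :class:`RunConfig`
  to flip polarity at read time.
* Pixel spacing is isotropic, in millimetres.  Anisotropic DICOM inputs are
  resampled to the smaller spacing on load, because the polar geometry and
  the mm-unit grid step require isotropy.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml


class ConfigurationError(ValueError):
    """Missing or inconsistent run configuration."""


class FormatError(ValueError):
    """Unsupported or malformed image input."""


@dataclass
class MammogramImage:
    """A 2D 'for processing' mammogram-like image with acquisition metadata."""

    pixels: np.ndarray
    pixel_spacing_mm: float
    laterality: str = "left"
    view: str = "MLO"
    subject_id: str = ""
    side_label: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2 or min(self.pixels.shape) < 2:
            raise FormatError("pixels must be a 2D grid with >= 2 rows and columns")
        if not np.all(np.isfinite(self.pixels)) or self.pixels.min() < 0:
            raise FormatError("intensities must be finite and non-negative")
        if not (self.pixel_spacing_mm > 0):
            raise ConfigurationError("pixel_spacing_mm must be positive")
        if self.laterality not in ("left", "right"):
            raise ConfigurationError(f"laterality must be left/right, got {self.laterality!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class RunConfig:
    """All tunables of the pipeline.

    ``D_mm`` is the radial step of the nipple-centred polar grid; ``f`` sets
    the relative size of the central breast area (CBA) versus the upper-outer
    area (UOA); ``a``, ``b``, ``c`` parameterize the anatomical weight map
    W = c*S + (1-c)*T.
    """

    D_mm: float = 6.3
    f: float = 0.6
    a: float = 0.8
    b: float = 1.0
    c: float = 0.4
    gray_levels: int = 128
    correlation_threshold: float = 0.90
    cv_outer_folds: int = 10
    cv_inner_folds: int = 5
    seed: int = 0
    region_min_coverage: float = 0.5
    min_region_pixels: int = 25
    density_clusters: int = 4
    invert_on_load: bool = False
    # lattice comparator settings
    lattice_spacing_mm: float = 6.3
    lattice_window_mm: float = 6.3

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not (0.5 <= self.f <= 1.0):
            raise ConfigurationError("f must lie in [0.5, 1]")
        for name in ("a", "b", "c"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        if self.D_mm <= 0:
            raise ConfigurationError("D_mm must be positive")
        if self.gray_levels < 2:
            raise ConfigurationError("gray_levels must be >= 2")
        if not (0.0 < self.correlation_threshold <= 1.0):
            raise ConfigurationError("correlation_threshold must lie in (0, 1]")
        if self.cv_outer_folds < 2 or self.cv_inner_folds < 2:
            raise ConfigurationError("cross-validation folds must be >= 2")
        if not (0.0 < self.region_min_coverage <= 1.0):
            raise ConfigurationError("region_min_coverage must lie in (0, 1]")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def config_hash(self) -> str:
        import hashlib

        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _laterality_from_name(path: Path) -> str | None:
    stem = path.stem.upper()
    for token, side in (("_L", "left"), ("-L", "left"), ("_R", "right"), ("-R", "right")):
        if stem.endswith(token) or f"{token}_" in stem or f"{token}-" in stem:
            return side
    if "LEFT" in stem:
        return "left"
    if "RIGHT" in stem:
        return "right"
    return None


def read_image(
    path: str | Path,
    spacing_override: float | None = None,
    laterality: str | None = None,
    invert: bool = False,
) -> MammogramImage:
    """Read a DICOM / PNG / TIFF mammogram.

    Spacing is taken from DICOM metadata when present, else from
    ``spacing_override``; a missing spacing is a configuration error.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    suffix = path.suffix.lower()
    spacing = spacing_override
    meta_side = None
    if suffix in (".dcm", ".dicom", ""):
        import pydicom

        ds = pydicom.dcmread(str(path))
        arr = ds.pixel_array.astype(np.float64)
        sp = getattr(ds, "PixelSpacing", None) or getattr(ds, "ImagerPixelSpacing", None)
        if sp is not None:
            sr, sc = float(sp[0]), float(sp[1])
            spacing = min(sr, sc)
            if abs(sr - sc) > 1e-9:
                arr = _resample_isotropic(arr, sr, sc, spacing)
        side = str(getattr(ds, "ImageLaterality", "") or getattr(ds, "Laterality", "")).upper()
        meta_side = {"L": "left", "R": "right"}.get(side)
    elif suffix in (".png",):
        from PIL import Image

        arr = np.asarray(Image.open(path)).astype(np.float64)
    elif suffix in (".tif", ".tiff"):
        import tifffile

        arr = tifffile.imread(str(path)).astype(np.float64)
    else:
        raise FormatError(f"unsupported image format: {suffix}")
    if arr.ndim != 2:
        raise FormatError(f"expected a 2D image, got shape {arr.shape}")
    if spacing is None:
        raise ConfigurationError(f"{path.name}: no pixel spacing in metadata and no override given")
    if invert:
        arr = arr.max() - arr
    side = laterality or meta_side or _laterality_from_name(path) or "left"
    return MammogramImage(pixels=arr, pixel_spacing_mm=float(spacing), laterality=side,
                          subject_id=path.stem, side_label=side)


def _resample_isotropic(arr: np.ndarray, sr: float, sc: float, target: float) -> np.ndarray:
    from scipy import ndimage as ndi

    return ndi.zoom(arr, (sr / target, sc / target), order=1)


def write_mask_png(mask: np.ndarray, path: str | Path) -> None:
    from PIL import Image

    Image.fromarray((np.asarray(mask, bool) * 255).astype(np.uint8)).save(str(path))


def write_image_png(pixels: np.ndarray, path: str | Path) -> None:
    """16-bit PNG; intensities are rounded to integers."""
    from PIL import Image

    arr = np.clip(np.round(pixels), 0, 65535).astype(np.uint16)
    Image.fromarray(arr).save(str(path))


# ---------------------------------------------------------------------------
# Region feature tables


def write_feature_table(maps, path: str | Path) -> None:
    """Write one row per polar-grid region: ids, centroid, weight, TF1..TF34."""
    df = maps.to_frame()
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_feature_table(path: str | Path) -> pd.DataFrame:
    # round_trip parsing keeps the %.17g-printed values bit-exact
    return pd.read_csv(path, sep="\t", float_precision="round_trip")


def write_json_report(obj: dict, path: str | Path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_default))
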