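"""Seed-controlled MLO mammogram phantoms with ground truth.

The phantom emulates the geometry the pipeline needs: a breast silhouette
attached to a left chest wall, a pectoralis wedge bounded by a straight line,
a nipple bump at the anterior-most point, blob-like dense-tissue clusters,
and spatially correlated parenchymal noise (a Gaussian random field).  A
case/control texture effect is injected by scaling the local noise variance
inside a chosen anatomical locus by ``1 + effect_size``.

The ground truth (masks, nipple point, pectoral line parameters, effect mask)
is the oracle for segmentation, landmark-recovery and parameter-recovery
tests.  Identical spec + seed gives bit-identical output.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .io_formats import MammogramImage
from .segmentation import PectoralLine


class PhantomSpecError(ValueError):
    pass


EFFECT_KINDS = ("none", "cba_dense", "uoa_dense", "fatty", "diffuse")


@dataclass
class PhantomSpec:
    rows: int = 128
    cols: int = 104
    pixel_spacing_mm: float = 0.7
    laterality: str = "left"
    breast_radius_mm: float = 55.0        # nipple-to-chest-wall extent
    breast_vertical_radius_mm: float = 38.0
    pectoral_angle_deg: float | None = 30.0   # from vertical; None = no wedge
    pectoral_top_col_mm: float = 26.0     # where the line crosses the top edge
    nipple_bump_radius_mm: float = 4.0
    n_dense_blobs: int = 4
    blob_radius_mm: tuple[float, float] = (3.0, 6.5)
    blob_contrast: float = 160.0
    fat_intensity: float = 120.0
    pectoral_intensity: float = 420.0
    texture_corr_length_mm: float = 1.2
    texture_std: float = 24.0
    effect: str = "none"
    effect_size: float = 0.0
    effect_f: float = 0.6                 # CBA/UOA split used for the effect locus
    seed: int = 0

    def __post_init__(self) -> None:
        if self.effect not in EFFECT_KINDS:
            raise PhantomSpecError(f"unknown effect {self.effect!r}")
        if self.effect_size < 0:
            raise PhantomSpecError("effect_size must be >= 0")
        if self.blob_radius_mm[1] > self.breast_radius_mm:
            raise PhantomSpecError("blob radius exceeds breast radius")
        if self.laterality not in ("left", "right"):
            raise PhantomSpecError("laterality must be left/right")


@dataclass
class PhantomTruth:
    breast_mask: np.ndarray          # full silhouette incl. pectoral region
    pectoralis_mask: np.ndarray
    dense_mask: np.ndarray
    nipple: tuple[float, float]      # (row, col)
    pectoral_line: PectoralLine | None
    effect_mask: np.ndarray
    dense_fraction: float = 0.0


def _grf(shape: tuple[int, int], corr_px: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance Gaussian random field with the given correlation length."""
    white = rng.standard_normal(shape)
    smooth = ndi.gaussian_filter(white, sigma=corr_px, mode="reflect")
    sd = smooth.std()
    return smooth / sd if sd > 0 else smooth


def generate_phantom(spec: PhantomSpec) -> tuple[MammogramImage, PhantomTruth]:
    """Render one phantom mammogram and its ground truth."""
    rng = np.random.default_rng(spec.seed)
    sp = spec.pixel_spacing_mm
    H, W = spec.rows, spec.cols
    rr, cc = np.mgrid[0:H, 0:W].astype(np.float64)
    yc = (H - 1) / 2.0
    rx = spec.breast_radius_mm / sp
    ry = spec.breast_vertical_radius_mm / sp

    ellipse = (cc / rx) ** 2 + ((rr - yc) / ry) ** 2 <= 1.0
    nb = spec.nipple_bump_radius_mm / sp
    bump = (cc - rx) ** 2 + (rr - yc) ** 2 <= nb**2
    breast = ellipse | bump
    if not breast.any():
        raise PhantomSpecError("breast geometry does not intersect the image")
    nipple = (yc, float(np.max(np.nonzero(breast.any(axis=0))[0])))

    # pectoral wedge: col = col0 - row*tan(theta), pixels left of the line
    pect = np.zeros((H, W), bool)
    line: PectoralLine | None = None
    if spec.pectoral_angle_deg is not None:
        th = np.deg2rad(spec.pectoral_angle_deg)
        col0 = spec.pectoral_top_col_mm / sp
        line = PectoralLine(angle_deg=spec.pectoral_angle_deg,
                            dist=col0 * np.cos(th))
        pect = (cc * np.cos(th) + rr * np.sin(th) < line.dist) & breast

    # dense blobs: fibroglandular tissue concentrates retro-areolarly, so
    # centres are drawn around the nipple-to-chest-wall axis with a central
    # radial bias, outside the pectoral wedge
    dense = np.zeros((H, W), bool)
    blob_field = np.zeros((H, W))
    placed = 0
    attempts = 0
    while placed < spec.n_dense_blobs and attempts < 200:
        attempts += 1
        frac = rng.beta(1.6, 1.6)            # nipple distance as fraction of rx
        t = rng.uniform(-np.pi / 2.4, np.pi / 2.4)  # angle around the leftward axis
        br = nipple[0] - frac * 0.9 * ry * np.sin(t)
        bc = nipple[1] - frac * rx * np.cos(t)
        if not (0 <= int(round(br)) < H and 0 <= int(round(bc)) < W):
            continue
        if pect[int(round(br)), int(round(bc))] or not breast[int(round(br)), int(round(bc))]:
            continue
        rad = rng.uniform(*spec.blob_radius_mm) / sp
        disc = (cc - bc) ** 2 + (rr - br) ** 2 <= rad**2
        disc &= breast
        if not disc.any():
            continue
        dense |= disc
        blob_field = np.maximum(blob_field, disc.astype(float))
        placed += 1
    dense &= ~pect
    blob_field = ndi.gaussian_filter(blob_field, sigma=1.0 / sp * 0.8)

    img = np.zeros((H, W))
    img[breast] = spec.fat_intensity
    img += spec.blob_contrast * blob_field * breast
    img[pect] = spec.pectoral_intensity

    effect_mask = _effect_mask(spec, breast, pect, dense, nipple, line, sp)

    noise = _grf((H, W), spec.texture_corr_length_mm / sp, rng) * spec.texture_std
    gain = np.ones((H, W))
    gain[effect_mask] = np.sqrt(1.0 + spec.effect_size)
    img = img + noise * gain * breast
    img = np.clip(img, 0, None)

    dense_fraction = dense.sum() / max((breast & ~pect).sum(), 1)
    truth = PhantomTruth(breast_mask=breast, pectoralis_mask=pect, dense_mask=dense,
                         nipple=nipple, pectoral_line=line, effect_mask=effect_mask,
                         dense_fraction=float(dense_fraction))

    if spec.laterality == "right":
        img = img[:, ::-1].copy()
        truth = _mirror_truth(truth, W)

    image = MammogramImage(pixels=img, pixel_spacing_mm=sp, laterality=spec.laterality,
                           side_label=spec.laterality)
    return image, truth


def _effect_mask(spec, breast, pect, dense, nipple, line, sp) -> np.ndarray:
    if spec.effect == "none":
        return np.zeros_like(breast)
    H, W = breast.shape
    rr, cc = np.mgrid[0:H, 0:W].astype(np.float64)
    d = np.hypot(rr - nipple[0], cc - nipple[1])
    if line is not None:
        r_p = abs(line.signed_distance(nipple[0], nipple[1]))
    else:
        r_p = nipple[1]
    inner = d < spec.effect_f * r_p
    paren = breast & ~pect
    if spec.effect == "cba_dense":
        return paren & dense & inner
    if spec.effect == "uoa_dense":
        return paren & dense & ~inner & (rr < nipple[0])
    if spec.effect == "fatty":
        return paren & ~dense
    return paren  # diffuse


def _mirror_truth(t: PhantomTruth, W: int) -> PhantomTruth:
    line = None
    if t.pectoral_line is not None:
        line = t.pectoral_line.mirrored(W)
    return PhantomTruth(
        breast_mask=t.breast_mask[:, ::-1].copy(),
        pectoralis_mask=t.pectoralis_mask[:, ::-1].copy(),
        dense_mask=t.dense_mask[:, ::-1].copy(),
        nipple=(t.nipple[0], W - 1 - t.nipple[1]),
        pectoral_line=line,
        effect_mask=t.effect_mask[:, ::-1].copy(),
        dense_fraction=t.dense_fraction,
    )


# ---------------------------------------------------------------------------
# Cohorts


@dataclass
class CovariateModel:
    """Normal models for per-woman covariates with case/control mean shifts."""

    age_mean: float = 57.0
    age_sd: float = 11.5
    age_case_shift: float = 0.0
    bmi_mean: float = 29.6
    bmi_sd: float = 7.0
    bmi_case_shift: float = 0.0
    density_noise_sd: float = 2.0
    density_case_shift: float = 0.0   # added to density (percent) for cases


@dataclass
class Woman:
    subject_id: str
    label: int
    images: dict          # side -> MammogramImage
    truths: dict          # side -> PhantomTruth
    covariates: dict


def generate_cohort(
    n_cases: int,
    n_controls: int,
    template: PhantomSpec | None = None,
    effect_size: float = 0.0,
    effect: str = "cba_dense",
    covariate_model: CovariateModel | None = None,
    seed: int = 0,
) -> list[Woman]:
    """Bilateral phantom cohort with per-woman geometry variation.

    Cases receive the texture effect bilaterally (per-woman signatures are
    bilateral averages downstream).  Controls have effect 'none'.
    """
    if n_cases < 2 or n_controls < 2:
        raise PhantomSpecError("need >= 2 women per class")
    template = template or PhantomSpec()
    cov = covariate_model or CovariateModel()
    rng = np.random.default_rng(seed)
    women: list[Woman] = []
    labels = [1] * n_cases + [0] * n_controls
    for idx, label in enumerate(labels):
        # per-woman anatomy and texture variation (breast size, pectoral
        # angle, amount/contrast of dense tissue, parenchymal noise scale)
        geom = {
            "breast_radius_mm": template.breast_radius_mm * rng.uniform(0.9, 1.1),
            "breast_vertical_radius_mm": template.breast_vertical_radius_mm * rng.uniform(0.9, 1.1),
            "pectoral_angle_deg": (None if template.pectoral_angle_deg is None
                                   else template.pectoral_angle_deg + rng.uniform(-8, 8)),
            "n_dense_blobs": int(rng.integers(max(template.n_dense_blobs - 2, 1),
                                              template.n_dense_blobs + 3)),
            "blob_contrast": template.blob_contrast * rng.uniform(0.8, 1.2),
            "texture_std": template.texture_std * rng.uniform(0.7, 1.3),
            "texture_corr_length_mm": template.texture_corr_length_mm * rng.uniform(0.8, 1.25),
        }
        images, truths = {}, {}
        for side in ("left", "right"):
            spec = dataclasses.replace(
                template,
                laterality=side,
                effect=effect if label == 1 and effect_size > 0 else "none",
                effect_size=effect_size if label == 1 else 0.0,
                seed=int(rng.integers(2**31)),
                **geom,
            )
            img, tr = generate_phantom(spec)
            img.subject_id = f"w{idx:04d}"
            images[side], truths[side] = img, tr
        dense_pct = 100.0 * 0.5 * (truths["left"].dense_fraction + truths["right"].dense_fraction)
        covars = {
            "age": cov.age_mean + label * cov.age_case_shift + rng.normal(0, cov.age_sd),
            "bmi": cov.bmi_mean + label * cov.bmi_case_shift + rng.normal(0, cov.bmi_sd),
            "density": dense_pct + label * cov.density_case_shift + rng.normal(0, cov.density_noise_sd),
        }
        women.append(Woman(subject_id=f"w{idx:04d}", label=label,
                           images=images, truths=truths, covariates=covars))
    return women


def cohort_manifest(women: list[Woman]) -> pd.DataFrame:
    rows = [{"subject_id": w.subject_id, "label": w.label, **w.covariates} for w in women]
    return pd.DataFrame(rows)


def write_cohort(women: list[Woman], out_dir: str | Path) -> Path:
    """PNG images + masks + manifest TSV for CLI use."""
    from .io_formats import write_image_png, write_mask_png

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for w in women:
        for side, img in w.images.items():
            stem = f"{w.subject_id}_{side[0].upper()}"
            write_image_png(img.pixels, out / f"{stem}.png")
            write_mask_png(w.truths[side].breast_mask, out / f"{stem}_breast.png")
            rows.append({"subject_id": w.subject_id, "side": side,
                         "path": f"{stem}.png", "label": w.label,
                         "spacing_mm": img.pixel_spacing_mm, **w.covariates})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.tsv", sep="\t", index=False)
    return out / "manifest.tsv"
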