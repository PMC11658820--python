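"""Paired image/annotation augmentation.

Photometric ops (hue/saturation shift, Gaussian noise, blur, channel
inversion, contrast, additive value) alter pixels only; geometric ops
(rotation about the image centre, horizontal/vertical flips) are applied
with one explicit affine transform to both the pixels and the point
coordinates, so annotations stay consistent by construction.  Points that
land outside the frame are dropped.  Density maps are regenerated from the
transformed points rather than warped as images: image-space interpolation
does not conserve mass, regeneration does.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage import color as skcolor

from .annotations_io import (
    DatasetManifest,
    ImageRecord,
    ManifestRecord,
    PointSet,
    load_image,
    read_point_annotations,
    save_image,
    save_mask,
    write_point_annotations,
)
from .errors import ValidationError

logger = logging.getLogger(__name__)

__all__ = ["AugmentConfig", "augment_pair", "expand_dataset", "split_dataset"]


@dataclass
class AugmentConfig:
    """Augmentation recipe.  40 variants per source image reproduces the
    study's expansion of 120 patch images into 4,800; per-op magnitudes are
    package defaults (the protocol names the ops but not their strengths)."""

    variants_per_image: int = 40
    rotation_range: float = 25.0      # degrees, uniform in +/- range
    p_rotate: float = 0.5
    p_hflip: float = 0.5
    p_vflip: float = 0.5
    p_hue_sat: float = 0.5
    hue_shift: float = 0.1            # fraction of the hue circle
    sat_shift: float = 0.1            # additive, saturation in [0, 1]
    p_noise: float = 0.3
    noise_sigma: float = 10.0         # intensity units (0-255 scale)
    p_blur: float = 0.3
    blur_sigma_max: float = 2.0       # px
    p_invert: float = 0.1
    p_contrast: float = 0.5
    contrast_range: tuple[float, float] = (0.8, 1.2)
    p_additive: float = 0.5
    additive_max: float = 20.0        # intensity units
    seed: int = 0

    def __post_init__(self) -> None:
        if self.variants_per_image < 1:
            raise ValidationError("variants_per_image must be >= 1")
        for name in ("p_rotate", "p_hflip", "p_vflip", "p_hue_sat", "p_noise",
                     "p_blur", "p_invert", "p_contrast", "p_additive"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {p}")


# ---------------------------------------------------------------------------
# photometric ops (pixels only)
# ---------------------------------------------------------------------------

def _photometric(pixels: np.ndarray, cfg: AugmentConfig,
                 rng: np.random.Generator) -> np.ndarray:
    img = pixels.astype(np.float64)
    if rng.random() < cfg.p_hue_sat:
        hsv = skcolor.rgb2hsv(img / 255.0)
        hsv[..., 0] = (hsv[..., 0] + rng.uniform(-cfg.hue_shift, cfg.hue_shift)) % 1.0
        hsv[..., 1] = np.clip(
            hsv[..., 1] + rng.uniform(-cfg.sat_shift, cfg.sat_shift), 0.0, 1.0
        )
        img = skcolor.hsv2rgb(hsv) * 255.0
    if rng.random() < cfg.p_noise:
        img = img + rng.normal(0.0, rng.uniform(0, cfg.noise_sigma), size=img.shape)
    if rng.random() < cfg.p_blur:
        sigma = rng.uniform(0.0, cfg.blur_sigma_max)
        if sigma > 1e-3:
            img = ndimage.gaussian_filter(img, sigma=(sigma, sigma, 0))
    if rng.random() < cfg.p_invert:
        ch = rng.integers(0, 3)
        img[..., ch] = 255.0 - img[..., ch]
    if rng.random() < cfg.p_contrast:
        factor = rng.uniform(*cfg.contrast_range)
        img = (img - img.mean()) * factor + img.mean()
    if rng.random() < cfg.p_additive:
        img = img + rng.uniform(-cfg.additive_max, cfg.additive_max)
    return np.clip(img, 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# geometric ops (pixels + points, one shared transform)
# ---------------------------------------------------------------------------

def _rotate_pair(pixels: np.ndarray, mask: np.ndarray | None, pts: np.ndarray,
                 angle_deg: float) -> tuple[np.ndarray, np.ndarray | None, np.ndarray]:
    """Rotate image (bilinear, zero fill) and points by ``angle_deg``
    counter-clockwise about the image centre."""
    h, w = pixels.shape[:2]
    theta = np.deg2rad(angle_deg)
    c, s = np.cos(theta), np.sin(theta)
    # forward transform of (x, y) points about centre
    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
    rel = pts - np.array([cx, cy])
    fwd = np.stack(
        [c * rel[:, 0] - s * rel[:, 1], s * rel[:, 0] + c * rel[:, 1]], axis=1
    ) + np.array([cx, cy])
    # image resampling needs the inverse map in (row, col) order
    m_rc = np.array([[c, -s], [s, c]])  # inverse rotation acting on (y, x)
    centre = np.array([cy, cx])
    offset = centre - m_rc @ centre
    rot = np.stack(
        [
            ndimage.affine_transform(
                pixels[..., ch].astype(np.float64), m_rc, offset=offset,
                order=1, mode="constant", cval=0.0,
            )
            for ch in range(pixels.shape[2])
        ],
        axis=-1,
    )
    rot = np.clip(rot, 0, 255).astype(np.uint8)
    rmask = None
    if mask is not None:
        rmask = ndimage.affine_transform(
            mask.astype(np.float64), m_rc, offset=offset,
            order=0, mode="constant", cval=0.0,
        ) > 0.5
    return rot, rmask, fwd


def _drop_outside(pts: np.ndarray, width: int, height: int) -> np.ndarray:
    """Keep points whose nearest pixel lies in frame; clip round-off."""
    keep = (
        (pts[:, 0] > -0.5) & (pts[:, 0] < width - 0.5)
        & (pts[:, 1] > -0.5) & (pts[:, 1] < height - 0.5)
    )
    out = pts[keep].copy()
    # a point in (-0.5, 0) still rounds to pixel 0; clamp it into bounds
    np.clip(out, 0.0, None, out=out)
    return out


def augment_pair(img: ImageRecord, ps: PointSet, cfg: AugmentConfig,
                 rng: np.random.Generator) -> tuple[ImageRecord, PointSet]:
    """One random augmented variant of an (image, annotation) pair."""
    if (ps.width, ps.height) != (img.width, img.height):
        raise ValidationError(
            f"annotation size {ps.width}x{ps.height} does not match image "
            f"{img.width}x{img.height}"
        )
    pixels = _photometric(img.pixels, cfg, rng)
    mask = img.mask
    pts = ps.points.copy()
    h, w = pixels.shape[:2]

    if rng.random() < cfg.p_rotate:
        angle = rng.uniform(-cfg.rotation_range, cfg.rotation_range)
        pixels, mask, pts = _rotate_pair(pixels, mask, pts, angle)
    if rng.random() < cfg.p_hflip:
        pixels = pixels[:, ::-1]
        mask = mask[:, ::-1] if mask is not None else None
        pts[:, 0] = (w - 1) - pts[:, 0]
    if rng.random() < cfg.p_vflip:
        pixels = pixels[::-1]
        mask = mask[::-1] if mask is not None else None
        pts[:, 1] = (h - 1) - pts[:, 1]

    pts = _drop_outside(pts, w, h)
    if len(pts) == 0 and ps.n_points > 0:
        logger.warning("augmentation dropped all %d points of %s",
                       ps.n_points, ps.image_id)
    out_img = ImageRecord(image_id=img.image_id, pixels=np.ascontiguousarray(pixels),
                          mask=np.ascontiguousarray(mask) if mask is not None else None)
    out_ps = PointSet(image_id=ps.image_id, width=w, height=h, points=pts)
    return out_img, out_ps


# ---------------------------------------------------------------------------
# dataset-level expansion and splitting
# ---------------------------------------------------------------------------

def expand_dataset(manifest: DatasetManifest, cfg: AugmentConfig,
                   out_dir: str | Path, overwrite: bool = False) -> DatasetManifest:
    """Write ``variants_per_image`` augmented variants of every record
    (originals are not kept: 120 sources at the default 40 variants give
    the study's 4,800 images).  Deterministic given ``cfg.seed``; existing
    output files are reused unless ``overwrite``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    new_records: list[ManifestRecord] = []
    for ridx, rec in enumerate(manifest.records):
        if not rec.annotation:
            raise ValidationError(f"record {rec.image_id} has no annotation")
        img = None
        ps = None
        for v in range(cfg.variants_per_image):
            vid = f"{rec.image_id}_aug{v:03d}"
            img_path = out_dir / f"{vid}.png"
            ann_path = out_dir / f"{vid}.json"
            mask_path = out_dir / f"{vid}_mask.png" if rec.mask else ""
            exists = img_path.exists() and ann_path.exists() and (
                not rec.mask or Path(mask_path).exists()
            )
            if overwrite or not exists:
                if img is None:
                    img = load_image(manifest.path(rec.image),
                                     manifest.path(rec.mask) if rec.mask else None)
                    ps = read_point_annotations(manifest.path(rec.annotation))
                rng = np.random.default_rng(
                    np.random.SeedSequence([cfg.seed, ridx, v])
                )
                aimg, aps = augment_pair(img, ps, cfg, rng)
                save_image(aimg.pixels, img_path)
                if rec.mask:
                    save_mask(aimg.mask, mask_path)
                write_point_annotations(
                    replace_id(aps, vid), ann_path
                )
            new_records.append(
                ManifestRecord(
                    image_id=vid,
                    image=img_path.name,
                    annotation=ann_path.name,
                    mask=Path(mask_path).name if rec.mask else "",
                    side=rec.side,
                    panicle_id=rec.panicle_id,
                    observed_total=rec.observed_total,
                )
            )
    return DatasetManifest(records=new_records, root=out_dir)


def replace_id(ps: PointSet, new_id: str) -> PointSet:
    return PointSet(image_id=new_id, width=ps.width, height=ps.height,
                    points=ps.points.copy())


def _source_of(image_id: str) -> str:
    return image_id.split("_aug")[0]


def split_dataset(manifest: DatasetManifest, fraction: float = 0.8,
                  level: str = "source", seed: int = 0,
                  ) -> tuple[DatasetManifest, DatasetManifest]:
    """Disjoint, exhaustive train/test partition.

    ``level='source'`` keeps all augmented variants of one source image on
    the same side (no augmented-twin leakage); ``level='record'`` shuffles
    individual records, reproducing the study's apparent protocol.
    """
    if not 0.0 < fraction < 1.0:
        raise ValidationError(f"fraction must be in (0, 1), got {fraction}")
    rng = np.random.default_rng(seed)
    if level == "record":
        groups = [[r] for r in manifest.records]
    elif level == "source":
        by_src: dict[str, list[ManifestRecord]] = {}
        for r in manifest.records:
            by_src.setdefault(_source_of(r.image_id), []).append(r)
        groups = [by_src[k] for k in sorted(by_src)]
    else:
        raise ValidationError(f"unknown split level {level!r}")
    if len(groups) < 2:
        raise ValidationError(
            f"need at least 2 groups to split at level={level!r}, got {len(groups)}"
        )
    order = rng.permutation(len(groups))
    n_train = int(round(fraction * len(groups)))
    n_train = min(max(n_train, 1), len(groups) - 1)
    train_idx = set(order[:n_train].tolist())
    train = [r for gi in sorted(train_idx) for r in groups[gi]]
    test = [r for gi in range(len(groups)) if gi not in train_idx for r in groups[gi]]
    return (
        DatasetManifest(records=train, root=manifest.root),
        DatasetManifest(records=test, root=manifest.root),
    )
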