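"""Ground-truth density maps from point annotations.

A density map is a non-negative grid obtained by placing a unit impulse at
each annotated grain centre and convolving with a normalized 2-D Gaussian
(sigma 5 px by default).  Its integral — the plain sum of all pixels — is
the grain count, which is exactly conserved under the reflect boundary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .annotations_io import PointSet
from .errors import ValidationError

__all__ = [
    "DensityMapConfig",
    "DensityMap",
    "rescale_points",
    "build_density_map",
    "count_from_density",
    "save_density",
    "load_density",
]

#: kernel support, in multiples of sigma (the filter's conventional default)
TRUNCATE = 4.0


@dataclass
class DensityMapConfig:
    target_size: tuple[int, int] = (224, 224)  # (H, W)
    sigma: float = 5.0
    boundary_mode: str = "reflect"  # reflect conserves mass; constant may lose it

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValidationError(f"sigma must be > 0, got {self.sigma}")
        h, w = self.target_size
        if h <= 0 or w <= 0:
            raise ValidationError(f"target_size must be positive, got {self.target_size}")
        if self.boundary_mode not in ("reflect", "constant"):
            raise ValidationError("boundary_mode must be 'reflect' or 'constant'")


@dataclass
class DensityMap:
    values: np.ndarray  # (H, W) float64, all >= 0
    source_image_id: str = ""
    n_points: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)


def rescale_points(ps: PointSet, target_size: tuple[int, int]) -> PointSet:
    """Scale point coordinates from the source image grid to ``target_size``
    (H, W), clamping into [0, target-1] so no point falls off the grid."""
    if ps.width <= 0 or ps.height <= 0:
        raise ValidationError(f"cannot rescale from zero-size image {ps.image_id}")
    th, tw = target_size
    sx = tw / ps.width
    sy = th / ps.height
    pts = ps.points.copy()
    pts[:, 0] = np.clip(pts[:, 0] * sx, 0.0, tw - 1.0)
    pts[:, 1] = np.clip(pts[:, 1] * sy, 0.0, th - 1.0)
    return PointSet(image_id=ps.image_id, width=tw, height=th, points=pts)


def build_density_map(ps: PointSet, cfg: DensityMapConfig | None = None) -> DensityMap:
    """Build the ground-truth density map for an already-rescaled point set.

    Each point contributes a unit impulse at its nearest pixel (collisions
    accumulate), smoothed by a Gaussian of ``cfg.sigma``.  Under the reflect
    boundary the integral equals the point count to float precision.
    """
    cfg = cfg or DensityMapConfig()
    h, w = cfg.target_size
    if ps.width != w or ps.height != h:
        raise ValidationError(
            f"point set '{ps.image_id}' has size {ps.width}x{ps.height}; "
            f"rescale_points to {w}x{h} first"
        )
    cols = np.rint(ps.points[:, 0]).astype(np.intp)
    rows = np.rint(ps.points[:, 1]).astype(np.intp)
    bad = np.flatnonzero((cols < -1) | (cols > w) | (rows < -1) | (rows > h))
    if bad.size:
        raise ValidationError(
            f"point(s) round outside the {h}x{w} grid at indices {bad.tolist()[:20]}"
        )
    # a coordinate in (W-1, W) is inside the image and belongs to its last pixel
    cols = np.clip(cols, 0, w - 1)
    rows = np.clip(rows, 0, h - 1)
    impulses = np.zeros((h, w), dtype=np.float64)
    np.add.at(impulses, (rows, cols), 1.0)
    values = gaussian_filter(
        impulses, sigma=cfg.sigma, mode=cfg.boundary_mode, truncate=TRUNCATE
    )
    # smoothing can produce tiny negative round-off; clamp at exact zero
    np.clip(values, 0.0, None, out=values)
    return DensityMap(values=values, source_image_id=ps.image_id, n_points=ps.n_points)


def count_from_density(dm: DensityMap | np.ndarray) -> float:
    """Grain count of a density map: the sum of all pixel values."""
    values = dm.values if isinstance(dm, DensityMap) else np.asarray(dm)
    if not np.all(np.isfinite(values)):
        raise ValidationError("density grid contains NaN or Inf")
    return float(values.sum())


def save_density(dm: DensityMap, path: str | Path, sigma: float | None = None) -> None:
    """Persist a density map as a 32-bit float ``.npy`` plus a sidecar JSON
    with image_id, n_points and sigma."""
    path = Path(path)
    np.save(path, dm.values.astype(np.float32))
    side = {"image_id": dm.source_image_id, "n_points": int(dm.n_points)}
    if sigma is not None:
        side["sigma"] = float(sigma)
    path.with_suffix(".json").write_text(json.dumps(side))


def load_density(path: str | Path) -> DensityMap:
    path = Path(path)
    values = np.load(path).astype(np.float64)
    meta_path = path.with_suffix(".json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    return DensityMap(
        values=values,
        source_image_id=meta.get("image_id", path.stem),
        n_points=int(meta.get("n_points", 0)),
    )
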