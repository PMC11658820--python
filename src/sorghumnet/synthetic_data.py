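"""Synthetic panicle scenes with exactly known grain annotations.

Each scene is a tapered-ellipse panicle silhouette filled with small
(~8 px) anti-aliased grain blobs at Poisson-disk-like positions, on a
cluttered background whose distractor blobs never touch the mask — so the
visible-grain ground truth is exact by construction.  Panicles come in
opposite-side pairs that share a whole-panicle total; totals are drawn from
a truncated normal spanning the observed field range 672-4,156 grains
(mean ~2,363), and the per-side visible count follows a configurable
quadratic visibility relation ``total = a*v^2 + b*v + c`` plus relative
Gaussian noise, with a controllable between-side asymmetry.

The generator feeds every other module, standing in for field data that is
not publicly deposited; it makes no biological claim about the true
visible-to-total relation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from scipy import ndimage
from scipy.stats import truncnorm

from .annotations_io import (
    DatasetManifest,
    ManifestRecord,
    PointSet,
    save_image,
    save_mask,
    write_point_annotations,
)
from .errors import ValidationError

__all__ = [
    "SceneConfig",
    "SyntheticScene",
    "generate_scene",
    "generate_panicle_pair",
    "generate_benchmark",
]


@dataclass
class SceneConfig:
    canvas: tuple[int, int] = (896, 448)        # (H, W) px
    grain_diameter: float = 8.0                 # px
    total_range: tuple[int, int] = (672, 4156)  # whole-panicle grains
    total_mean: float = 2363.0
    total_sigma: float = 700.0
    # visibility relation: total = rel_a*v^2 + rel_b*v + rel_c + noise
    rel_a: float = 1e-4
    rel_b: float = 2.0
    rel_c: float = 0.0
    rel_noise: float = 0.05      # relative sd of the relation noise
    asymmetry: float = 0.05      # relative sd of the between-side spread
    clutter: float = 0.5         # background distractor density, 0..1
    visible_range: Optional[tuple[int, int]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grain_diameter <= 1:
            raise ValidationError("grain_diameter must be > 1 px")
        lo, hi = self.total_range
        if not (0 < lo <= hi):
            raise ValidationError(f"bad total_range {self.total_range}")
        if not lo <= self.total_mean <= hi:
            raise ValidationError("total_mean must lie inside total_range")
        if self.rel_b <= 0:
            raise ValidationError("rel_b must be > 0")
        if self.rel_noise < 0 or self.asymmetry < 0:
            raise ValidationError("noise parameters must be >= 0")

    def inverse_relation(self, total: float) -> float:
        """Mean visible count for a given total (relation inverted on the
        non-negative branch)."""
        a, b, c = self.rel_a, self.rel_b, self.rel_c
        if abs(a) < 1e-12:
            return max((total - c) / b, 0.0)
        disc = b * b + 4.0 * a * (total - c)
        if disc <= 0:
            return 0.0
        return max((-b + np.sqrt(disc)) / (2.0 * a), 0.0)


@dataclass
class SyntheticScene:
    image: np.ndarray            # (H, W, 3) uint8
    mask: np.ndarray             # (H, W) bool
    points: PointSet             # exact grain centres, all inside the mask
    side: str
    panicle_id: str
    true_visible: int
    true_total: int


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def _panicle_mask(h: int, w: int, rng: np.random.Generator) -> np.ndarray:
    """Vertical tapered ellipse with mild random eccentricity."""
    cy, cx = h / 2.0, w / 2.0
    ry = 0.45 * h * rng.uniform(0.92, 1.0)
    rx = 0.36 * w * rng.uniform(0.85, 1.0)
    yy, xx = np.mgrid[0:h, 0:w]
    t = np.clip((yy - (cy - ry)) / (2.0 * ry), 0.0, 1.0)
    width = rx * (1.0 - 0.35 * t)  # narrower toward the bottom
    return ((xx - cx) / width) ** 2 + ((yy - cy) / ry) ** 2 <= 1.0


def _sample_positions(valid: np.ndarray, n: int, min_dist: float,
                      rng: np.random.Generator) -> np.ndarray:
    """Exactly ``n`` (x, y) positions inside ``valid`` with best-effort
    minimum spacing (dart throwing on a hash grid; the spacing is relaxed
    by halving whenever the region cannot host ``n`` points at it)."""
    coords = np.argwhere(valid)  # (m, 2) rows (y, x)
    if n == 0:
        return np.empty((0, 2))
    if len(coords) < n:
        raise ValidationError(
            f"requested {n} grains but only {len(coords)} valid pixels; "
            f"use a larger canvas"
        )
    order = rng.permutation(len(coords))
    accepted: list[np.ndarray] = []
    d = max(min_dist, 1.0)
    pos = 0
    while len(accepted) < n:
        cell = max(d, 1.0)
        grid: dict[tuple[int, int], list[np.ndarray]] = {}
        for p in accepted:
            grid.setdefault((int(p[0] // cell), int(p[1] // cell)), []).append(p)
        while pos < len(order) and len(accepted) < n:
            yx = coords[order[pos]].astype(np.float64)
            pos += 1
            key = (int(yx[0] // cell), int(yx[1] // cell))
            ok = True
            for dy in (-1, 0, 1):
                for dx in (-1, 0, 1):
                    for q in grid.get((key[0] + dy, key[1] + dx), ()):
                        if (yx[0] - q[0]) ** 2 + (yx[1] - q[1]) ** 2 < d * d:
                            ok = False
                            break
                    if not ok:
                        break
                if not ok:
                    break
            if ok:
                accepted.append(yx)
                grid.setdefault(key, []).append(yx)
        if len(accepted) < n:
            if d <= 1.0:
                raise ValidationError(
                    f"cannot place {n} grains even at 1 px spacing; "
                    f"use a larger canvas"
                )
            d = d / 2.0
            pos = 0  # rescan rejected candidates at the relaxed spacing
            order = rng.permutation(len(coords))
    pts = np.array(accepted)  # (n, 2) as (y, x)
    jitter = rng.uniform(-0.45, 0.45, size=pts.shape)
    pts = pts + jitter
    return pts[:, ::-1]  # -> (x, y)


def _stamp_blob(img: np.ndarray, x: float, y: float, rx: float, ry: float,
                angle: float, color: np.ndarray) -> None:
    """Alpha-blend an anti-aliased rotated ellipse onto ``img`` in place."""
    h, w = img.shape[:2]
    r = max(rx, ry) + 1.5
    x0, x1 = int(max(0, np.floor(x - r))), int(min(w, np.ceil(x + r) + 1))
    y0, y1 = int(max(0, np.floor(y - r))), int(min(h, np.ceil(y + r) + 1))
    if x0 >= x1 or y0 >= y1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dx, dy = xx - x, yy - y
    c, s = np.cos(angle), np.sin(angle)
    u = (dx * c + dy * s) / rx
    v = (-dx * s + dy * c) / ry
    rho = np.sqrt(u * u + v * v)
    alpha = np.clip(1.5 * (1.0 - rho), 0.0, 1.0)[..., None]
    region = img[y0:y1, x0:x1].astype(np.float64)
    img[y0:y1, x0:x1] = (region * (1 - alpha) + color * alpha).astype(np.uint8)


# ---------------------------------------------------------------------------
# scene generation
# ---------------------------------------------------------------------------

def generate_scene(cfg: SceneConfig, panicle_id: str, side: str,
                   rng: np.random.Generator, visible_count: int | None = None,
                   total: int | None = None) -> SyntheticScene:
    """Render one panicle side with exactly ``visible_count`` annotated
    grains (drawn from the config's total/visibility model when omitted)."""
    h, w = cfg.canvas
    if total is None:
        total = _draw_total(cfg, rng)
    if visible_count is None:
        visible_count = _draw_visible(cfg, total, rng)
    visible_count = int(visible_count)
    if visible_count < 0:
        raise ValidationError("visible_count must be >= 0")

    mask = _panicle_mask(h, w, rng)
    radius = cfg.grain_diameter / 2.0

    # background: smooth colour field + distractor blobs kept off the mask
    base = np.empty((h, w, 3))
    low = [ndimage.gaussian_filter(rng.normal(0, 1, (h, w)), sigma=25) for _ in range(3)]
    for ch, (mean, amp) in enumerate(((95, 160), (110, 160), (70, 120))):
        base[..., ch] = mean + amp * low[ch]
    img = np.clip(base, 0, 255).astype(np.uint8)

    dist_out = ndimage.distance_transform_edt(~mask)
    clutter_zone = dist_out > (radius * 1.5 + 2.0)
    n_clutter = int(round(cfg.clutter * 150))
    if n_clutter:
        czone = np.argwhere(clutter_zone)
        picks = czone[rng.integers(0, len(czone), size=n_clutter)]
        for cy, cx in picks:
            rr = radius * rng.uniform(0.5, 1.3)
            col = np.array([rng.uniform(60, 190)] * 3) * rng.uniform(0.8, 1.2, 3)
            _stamp_blob(img, float(cx), float(cy), rr, rr * rng.uniform(0.6, 1.0),
                        rng.uniform(0, np.pi), np.clip(col, 0, 255))

    # panicle body: textured reddish-brown fill
    body = np.empty((h, w, 3))
    tex = ndimage.gaussian_filter(rng.normal(0, 1, (h, w)), sigma=4)
    for ch, (mean, amp) in enumerate(((118, 30), (62, 18), (46, 14))):
        body[..., ch] = mean + amp * tex
    img[mask] = np.clip(body, 0, 255).astype(np.uint8)[mask]

    # grains: bright blobs strictly inside the mask
    inner = ndimage.distance_transform_edt(mask) > (radius + 1.0)
    pts = _sample_positions(inner, visible_count, min_dist=0.75 * cfg.grain_diameter,
                            rng=rng)
    grain_base = np.array([205.0, 155.0, 95.0])
    for x, y in pts:
        rr = radius * rng.uniform(0.75, 1.25)
        aspect = rng.uniform(0.7, 1.0)
        col = np.clip(grain_base * rng.uniform(0.8, 1.15) +
                      rng.normal(0, 8, 3), 0, 255)
        _stamp_blob(img, x, y, rr, rr * aspect, rng.uniform(0, np.pi), col)

    points = PointSet(image_id=f"{panicle_id}_{side}", width=w, height=h, points=pts)
    return SyntheticScene(
        image=img, mask=mask, points=points, side=side, panicle_id=panicle_id,
        true_visible=visible_count, true_total=int(total),
    )


def _draw_total(cfg: SceneConfig, rng: np.random.Generator) -> int:
    lo, hi = cfg.total_range
    a = (lo - cfg.total_mean) / cfg.total_sigma
    b = (hi - cfg.total_mean) / cfg.total_sigma
    val = truncnorm.rvs(a, b, loc=cfg.total_mean, scale=cfg.total_sigma,
                        random_state=rng)
    return int(round(val))


def _draw_visible(cfg: SceneConfig, total: int, rng: np.random.Generator) -> int:
    eps = total * rng.normal(0.0, cfg.rel_noise) if cfg.rel_noise > 0 else 0.0
    v = cfg.inverse_relation(total - eps)
    if cfg.visible_range is not None:
        v = float(np.clip(v, *cfg.visible_range))
    return int(np.clip(round(v), 0, total))


def generate_panicle_pair(cfg: SceneConfig, panicle_id: str,
                          rng: np.random.Generator,
                          ) -> tuple[SyntheticScene, SyntheticScene, int]:
    """Two opposite sides of one panicle sharing a whole-panicle total;
    per-side visible counts spread around the visibility relation by the
    configured asymmetry.  Returns (side A, side B, observed total)."""
    total = _draw_total(cfg, rng)
    eps = total * rng.normal(0.0, cfg.rel_noise) if cfg.rel_noise > 0 else 0.0
    v_mean = cfg.inverse_relation(total - eps)
    if cfg.visible_range is not None:
        v_mean = float(np.clip(v_mean, *cfg.visible_range))
    visibles = []
    for _ in range(2):
        v = v_mean * (1.0 + cfg.asymmetry * rng.normal()) if cfg.asymmetry > 0 else v_mean
        visibles.append(int(np.clip(round(v), 0, total)))
    scene_a = generate_scene(cfg, panicle_id, "A", rng,
                             visible_count=visibles[0], total=total)
    scene_b = generate_scene(cfg, panicle_id, "B", rng,
                             visible_count=visibles[1], total=total)
    return scene_a, scene_b, int(total)


def generate_benchmark(cfg: SceneConfig, n_panicles: int, out_dir: str | Path,
                       seed: int | None = None) -> DatasetManifest:
    """Write a complete benchmark (images, masks, annotations, manifest with
    observed totals) of ``n_panicles`` opposite-side pairs; consumable by
    every other module.  Byte-identical for a fixed seed."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    records: list[ManifestRecord] = []
    for i in range(n_panicles):
        pid = f"pan{i:04d}"
        scene_a, scene_b, total = generate_panicle_pair(cfg, pid, rng)
        for scene in (scene_a, scene_b):
            stem = f"{pid}_{scene.side}"
            save_image(scene.image, out_dir / f"{stem}.png")
            save_mask(scene.mask, out_dir / f"{stem}_mask.png")
            write_point_annotations(scene.points, out_dir / f"{stem}.json")
            records.append(
                ManifestRecord(
                    image_id=stem,
                    image=f"{stem}.png",
                    annotation=f"{stem}.json",
                    mask=f"{stem}_mask.png",
                    side=scene.side,
                    panicle_id=pid,
                    observed_total=total,
                )
            )
    manifest = DatasetManifest(records=records, root=out_dir)
    manifest.write_csv(out_dir / "manifest.csv")
    return manifest
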