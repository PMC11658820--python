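"""Whole-panicle grain-number estimation.

A single photo shows only one face of the panicle, so the pipeline is:
mask the background, cut the panicle image into three equal-height patches
(top / middle / bottom), predict a density map per patch and integrate it,
sum the three patch counts into the visible-face count, and map that count
to the machine-counted whole-panicle total with a fitted polynomial.  A
symmetry report compares the visible counts obtained from the two opposite
sides of the same panicle.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from PIL import Image

from .annotations_io import DatasetManifest, ImageRecord, PointSet
from .density_maps import DensityMapConfig, build_density_map, count_from_density, rescale_points
from .errors import ValidationError
from .sorghum_net import NetworkHandle, predict_density
from .training import MetricsReport, evaluate_counts

__all__ = [
    "PatchSet",
    "GrainCountEstimate",
    "PanicleRecord",
    "PolyModel",
    "apply_mask",
    "patch_heights",
    "split_patches",
    "split_point_set",
    "build_patch_dataset",
    "count_panicle_side",
    "fit_panicle_model",
    "predict_total",
    "symmetry_report",
    "write_estimates_csv",
    "read_estimates_csv",
]


@dataclass
class PatchSet:
    """Three patches of one panicle image: raw crops (which tile the source
    exactly) and the same patches resized for the network."""

    resized: tuple[np.ndarray, np.ndarray, np.ndarray]  # each (h, w, 3) uint8
    raw: tuple[np.ndarray, np.ndarray, np.ndarray]
    heights: tuple[int, int, int]


@dataclass
class GrainCountEstimate:
    image_id: str
    side: str
    patch_counts: tuple[float, float, float]
    total_visible: float = field(init=False)

    def __post_init__(self) -> None:
        self.total_visible = float(sum(self.patch_counts))


@dataclass
class PanicleRecord:
    panicle_id: str
    estimate_a: Optional[GrainCountEstimate]
    estimate_b: Optional[GrainCountEstimate]
    observed_total: int

    def __post_init__(self) -> None:
        if self.observed_total <= 0:
            raise ValidationError(
                f"panicle {self.panicle_id}: observed_total must be > 0"
            )


def apply_mask(img: ImageRecord) -> ImageRecord:
    """Zero the background in every channel; foreground pixels untouched."""
    if img.mask is None:
        raise ValidationError(f"image {img.image_id} has no mask")
    pixels = img.pixels * img.mask[:, :, None].astype(np.uint8)
    return ImageRecord(image_id=img.image_id, pixels=pixels, mask=img.mask)


def patch_heights(h: int) -> tuple[int, int, int]:
    """Heights of the top/middle/bottom patches; the remainder of H mod 3
    goes to the bottom patch, and the three always sum to H."""
    if h < 3:
        raise ValidationError(f"image height must be >= 3, got {h}")
    base = h // 3
    return base, base, h - 2 * base


def _resize(patch: np.ndarray, size: tuple[int, int]) -> np.ndarray:
    th, tw = size
    im = Image.fromarray(patch)
    return np.asarray(im.resize((tw, th), Image.BILINEAR), dtype=np.uint8)


def split_patches(img: ImageRecord, target_size: tuple[int, int] = (224, 224)) -> PatchSet:
    """Cut an image into three equal-height patches and resize each to
    ``target_size``; the raw crops reassemble to the source exactly."""
    h1, h2, h3 = patch_heights(img.height)
    px = img.pixels
    raw = (px[:h1], px[h1:h1 + h2], px[h1 + h2:])
    resized = tuple(_resize(p, target_size) for p in raw)
    return PatchSet(resized=resized, raw=raw, heights=(h1, h2, h3))


def split_point_set(ps: PointSet, heights: tuple[int, int, int]) -> list[PointSet]:
    """Partition a point set into the three patches by row, shifting the
    y coordinate into each patch's local frame."""
    offsets = (0, heights[0], heights[0] + heights[1])
    out = []
    for k, (off, h) in enumerate(zip(offsets, heights)):
        sel = (ps.points[:, 1] >= off) & (ps.points[:, 1] < off + h)
        pts = ps.points[sel].copy()
        pts[:, 1] -= off
        out.append(
            PointSet(image_id=f"{ps.image_id}_p{k}", width=ps.width, height=h, points=pts)
        )
    return out


def build_patch_dataset(manifest: DatasetManifest, dm_cfg: DensityMapConfig,
                        masked: bool = True):
    """Patch-level training data from a manifest: masked, cropped and
    resized patch images with their ground-truth density maps.

    Returns ``(images, densities, counts, meta)`` where images are
    (n, H, W, 3) in [0, 1], densities (n, H, W), counts the per-patch
    ground-truth point counts and meta a DataFrame (image_id, patch, side,
    panicle_id, observed_total).
    """
    from .annotations_io import load_image, read_point_annotations

    xs, ys, counts, meta = [], [], [], []
    for rec in manifest.records:
        if not rec.annotation:
            raise ValidationError(f"record {rec.image_id} has no annotation")
        img = load_image(manifest.path(rec.image),
                         manifest.path(rec.mask) if rec.mask else None)
        if masked and img.mask is not None:
            img = apply_mask(img)
        ps = read_point_annotations(manifest.path(rec.annotation))
        patches = split_patches(img, dm_cfg.target_size)
        point_sets = split_point_set(ps, patches.heights)
        for k in range(3):
            pps = rescale_points(point_sets[k], dm_cfg.target_size)
            dm = build_density_map(pps, dm_cfg)
            xs.append(patches.resized[k].astype(np.float64) / 255.0)
            ys.append(dm.values)
            counts.append(pps.n_points)
            meta.append(
                {
                    "image_id": rec.image_id,
                    "patch": k,
                    "side": rec.side,
                    "panicle_id": rec.panicle_id,
                    "observed_total": rec.observed_total,
                }
            )
    return (
        np.stack(xs),
        np.stack(ys),
        np.array(counts, dtype=np.float64),
        pd.DataFrame(meta),
    )


def count_panicle_side(img: ImageRecord, handle: NetworkHandle, side: str = "A",
                       target_size: tuple[int, int] | None = None) -> GrainCountEstimate:
    """Visible-grain estimate for one side: mask -> 3 patches -> density
    prediction per patch -> integral per patch -> sum."""
    if target_size is None:
        target_size = handle.arch.input_size[:2]
    masked = apply_mask(img)
    patches = split_patches(masked, target_size)
    per_patch = []
    for patch in patches.resized:
        pred = predict_density(handle, patch.astype(np.float64) / 255.0)
        per_patch.append(count_from_density(pred))
    return GrainCountEstimate(
        image_id=img.image_id, side=side, patch_counts=tuple(per_patch)
    )


# ---------------------------------------------------------------------------
# one-side -> whole-panicle polynomial model
# ---------------------------------------------------------------------------

@dataclass
class PolyModel:
    """Polynomial mapping one-side visible count to whole-panicle total;
    coefficients in ascending power order."""

    degree: int
    coefficients: np.ndarray
    fit_metrics: Optional[MetricsReport] = None

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=np.float64)
        if len(self.coefficients) != self.degree + 1:
            raise ValidationError(
                f"degree {self.degree} needs {self.degree + 1} coefficients, "
                f"got {len(self.coefficients)}"
            )

    def to_json(self, seed: int | None = None) -> str:
        doc = {"degree": self.degree, "coefficients": self.coefficients.tolist()}
        if self.fit_metrics is not None:
            doc["metrics"] = self.fit_metrics.as_dict()
        if seed is not None:
            doc["split_seed"] = seed
        return json.dumps(doc, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "PolyModel":
        doc = json.loads(text)
        metrics = None
        if "metrics" in doc:
            m = doc["metrics"]
            metrics = MetricsReport(
                n=m["n"], mae=m.get("mae", float("nan")), mse=m["mse"],
                mape=m.get("mape", float("nan")), rmse=m["rmse"], r2=m.get("r2"),
            )
        return cls(degree=doc["degree"], coefficients=np.array(doc["coefficients"]),
                   fit_metrics=metrics)


def calibration_records(estimates: pd.DataFrame, mode: str = "single",
                        ) -> list[tuple[float, float]]:
    """(visible, observed_total) pairs from an estimates table.

    ``mode='single'`` uses every side as its own record (the default: the
    calibration consumes one side only); ``mode='mean'`` averages the two
    sides' visible counts per panicle first.
    """
    df = estimates.dropna(subset=["observed_total"])
    if mode == "single":
        return list(zip(df["total_visible"].astype(float),
                        df["observed_total"].astype(float)))
    if mode == "mean":
        grouped = df.groupby("panicle_id").agg(
            visible=("total_visible", "mean"),
            total=("observed_total", "first"),
        )
        return list(zip(grouped["visible"], grouped["total"]))
    raise ValidationError(f"unknown calibration mode {mode!r}")


def fit_panicle_model(records: Sequence[tuple[float, float]], degree: int = 2,
                      test_fraction: float = 0.3, seed: int = 0) -> PolyModel:
    """Least-squares polynomial fit of observed whole-panicle totals on
    one-side visible counts, with a random 70:30 train:test split; held-out
    metrics (R2, MSE, RMSE, MAPE) attached to the returned model."""
    data = np.asarray(records, dtype=np.float64)
    if data.ndim != 2 or data.shape[1] != 2:
        raise ValidationError("records must be (visible, observed_total) pairs")
    x, y = data[:, 0], data[:, 1]
    if np.ptp(x) == 0:
        raise ValidationError("degenerate design: all visible counts identical")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(x))
    n_test = int(round(test_fraction * len(x)))
    n_train = len(x) - n_test
    if n_train < degree + 2:
        raise ValidationError(
            f"need at least {degree + 2} training points for degree {degree}, "
            f"got {n_train}"
        )
    tr, te = order[:n_train], order[n_train:]
    coeffs = np.polynomial.polynomial.polyfit(x[tr], y[tr], deg=degree)
    metrics = None
    if len(te) > 0:
        pred = np.polynomial.polynomial.polyval(x[te], coeffs)
        metrics = evaluate_counts(y[te], pred, with_mape=bool(np.all(y[te] > 0)))
        ss_res = float(((y[te] - pred) ** 2).sum())
        ss_tot = float(((y[te] - y[te].mean()) ** 2).sum())
        metrics.r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return PolyModel(degree=degree, coefficients=coeffs, fit_metrics=metrics)


def predict_total(model: PolyModel, total_visible) -> np.ndarray | float:
    """Whole-panicle grain number for one-side visible count(s), clipped
    below at zero."""
    val = np.polynomial.polynomial.polyval(np.asarray(total_visible, dtype=np.float64),
                                           model.coefficients)
    out = np.maximum(val, 0.0)
    return float(out) if np.isscalar(total_visible) or np.ndim(total_visible) == 0 else out


def symmetry_report(records: Sequence[PanicleRecord]) -> MetricsReport:
    """Agreement between side-A and side-B visible-count estimates of the
    same panicles (MAE / MSE / RMSE)."""
    a_vals, b_vals = [], []
    for rec in records:
        if rec.estimate_a is None or rec.estimate_b is None:
            raise ValidationError(f"panicle {rec.panicle_id}: missing a side")
        a_vals.append(rec.estimate_a.total_visible)
        b_vals.append(rec.estimate_b.total_visible)
    a = np.asarray(a_vals)
    return evaluate_counts(a_vals, b_vals, with_mape=bool(np.all(a != 0)))


# ---------------------------------------------------------------------------
# CSV plumbing
# ---------------------------------------------------------------------------

ESTIMATE_COLUMNS = (
    "panicle_id", "side", "patch1", "patch2", "patch3",
    "total_visible", "predicted_total", "observed_total",
)


def write_estimates_csv(rows: list[dict], path: str | Path) -> None:
    pd.DataFrame(rows, columns=list(ESTIMATE_COLUMNS)).to_csv(path, index=False)


def read_estimates_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"panicle_id": str, "side": str})
    missing = set(ESTIMATE_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"estimates CSV {path}: missing columns {sorted(missing)}")
    return df
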