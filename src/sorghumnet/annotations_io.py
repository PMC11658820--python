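"""Reading and writing images, point annotations, masks, manifests and run
configuration.

Point annotations use the LabelMe JSON dialect: a ``shapes`` list whose
entries of ``shape_type == "point"`` each carry a single ``[x, y]``
coordinate, plus ``imageWidth`` / ``imageHeight``.  Coordinates are 0-based,
x = column, y = row, origin at the top-left corner (the convention of the
annotation tool itself).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from PIL import Image

from .errors import AnnotationParseError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "PointSet",
    "ImageRecord",
    "ManifestRecord",
    "DatasetManifest",
    "RunConfig",
    "read_point_annotations",
    "write_point_annotations",
    "load_image",
    "load_mask",
    "load_config",
]


@dataclass
class PointSet:
    """Per-image grain point annotations.

    ``points`` is an (n, 2) float array of (x, y) pixel coordinates;
    duplicates are allowed (two grains may round to the same pixel).
    """

    image_id: str
    width: int
    height: int
    points: np.ndarray  # (n, 2) float64, columns (x, y)

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=np.float64).reshape(-1, 2)
        self.points = pts
        self.validate()

    def validate(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValidationError(
                f"PointSet '{self.image_id}': non-positive image size "
                f"{self.width}x{self.height}"
            )
        x, y = self.points[:, 0], self.points[:, 1]
        bad = np.flatnonzero(
            (x < 0) | (x >= self.width) | (y < 0) | (y >= self.height)
        )
        if bad.size:
            raise ValidationError(
                f"PointSet '{self.image_id}': {bad.size} point(s) outside "
                f"{self.width}x{self.height} bounds at indices {bad.tolist()[:20]}"
            )

    @property
    def n_points(self) -> int:
        return int(self.points.shape[0])


@dataclass
class ImageRecord:
    """An RGB image with an optional binary panicle mask (1 = panicle)."""

    image_id: str
    pixels: np.ndarray  # (H, W, 3) uint8
    mask: Optional[np.ndarray] = None  # (H, W) bool

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValidationError(
                f"ImageRecord '{self.image_id}': pixels must be HxWx3, got {px.shape}"
            )
        self.pixels = px
        if self.mask is not None:
            m = np.asarray(self.mask).astype(bool)
            if m.shape != px.shape[:2]:
                raise ValidationError(
                    f"ImageRecord '{self.image_id}': mask shape {m.shape} does not "
                    f"match image {px.shape[:2]}"
                )
            self.mask = m

    @property
    def height(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width(self) -> int:
        return int(self.pixels.shape[1])


@dataclass
class ManifestRecord:
    image_id: str
    image: str
    annotation: str = ""
    mask: str = ""
    side: str = "none"  # A | B | none
    panicle_id: str = ""
    observed_total: Optional[int] = None


@dataclass
class DatasetManifest:
    """Dataset index: one row per image, CSV-backed.

    CSV header: image_id,image,annotation,mask,side,panicle_id,observed_total
    Paths are stored relative to the manifest location (or absolute).
    """

    records: list[ManifestRecord] = field(default_factory=list)
    root: Path = Path(".")

    COLUMNS = (
        "image_id", "image", "annotation", "mask",
        "side", "panicle_id", "observed_total",
    )

    def __post_init__(self) -> None:
        ids = [r.image_id for r in self.records]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate image_id(s) in manifest: {dup[:10]}")

    def path(self, rel: str) -> Path:
        p = Path(rel)
        return p if p.is_absolute() else self.root / p

    def to_frame(self) -> pd.DataFrame:
        rows = [dataclasses.asdict(r) for r in self.records]
        return pd.DataFrame(rows, columns=list(self.COLUMNS))

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path: str | Path, check_paths: bool = True) -> "DatasetManifest":
        path = Path(path)
        df = pd.read_csv(path, dtype={"image_id": str, "panicle_id": str})
        missing = set(cls.COLUMNS) - set(df.columns)
        if missing:
            raise ValidationError(f"manifest {path}: missing columns {sorted(missing)}")
        records = []
        for row in df.itertuples(index=False):
            tot = row.observed_total
            tot = None if pd.isna(tot) else int(tot)
            records.append(
                ManifestRecord(
                    image_id=str(row.image_id),
                    image="" if pd.isna(row.image) else str(row.image),
                    annotation="" if pd.isna(row.annotation) else str(row.annotation),
                    mask="" if pd.isna(row.mask) else str(row.mask),
                    side="none" if pd.isna(row.side) else str(row.side),
                    panicle_id="" if pd.isna(row.panicle_id) else str(row.panicle_id),
                    observed_total=tot,
                )
            )
        man = cls(records=records, root=path.parent)
        if check_paths:
            for r in man.records:
                for rel in (r.image, r.annotation, r.mask):
                    if rel and not man.path(rel).exists():
                        raise ValidationError(
                            f"manifest {path}: referenced path does not exist: {rel}"
                        )
        return man


# ---------------------------------------------------------------------------
# LabelMe-dialect point annotations
# ---------------------------------------------------------------------------

def read_point_annotations(path: str | Path) -> PointSet:
    """Read a LabelMe-dialect JSON file into a :class:`PointSet`.

    Only shapes of type ``point`` are kept; any other shape type is skipped
    with a logged warning.  Image dimensions come from ``imageWidth`` and
    ``imageHeight``.
    """
    path = Path(path)
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except (json.JSONDecodeError, UnicodeDecodeError) as exc:
        raise AnnotationParseError(f"malformed annotation JSON: {path}: {exc}") from exc
    try:
        width = int(doc["imageWidth"])
        height = int(doc["imageHeight"])
        shapes = doc.get("shapes", [])
    except (KeyError, TypeError, ValueError) as exc:
        raise AnnotationParseError(
            f"annotation JSON missing imageWidth/imageHeight: {path}"
        ) from exc
    pts = []
    skipped = 0
    for shape in shapes:
        if shape.get("shape_type") == "point":
            (x, y), = shape["points"]
            pts.append((float(x), float(y)))
        else:
            skipped += 1
    if skipped:
        logger.warning(
            "%s: skipped %d non-point shape(s)", path, skipped
        )
    image_id = str(doc.get("imagePath", path.stem)) or path.stem
    image_id = Path(image_id).stem
    return PointSet(
        image_id=image_id,
        width=width,
        height=height,
        points=np.array(pts, dtype=np.float64).reshape(-1, 2),
    )


def write_point_annotations(ps: PointSet, path: str | Path) -> None:
    """Write a :class:`PointSet` as LabelMe-dialect JSON (readable back by
    :func:`read_point_annotations`)."""
    ps.validate()
    doc = {
        "version": "5.2.1",
        "flags": {},
        "shapes": [
            {
                "label": "grain",
                "points": [[float(x), float(y)]],
                "group_id": None,
                "shape_type": "point",
                "flags": {},
            }
            for x, y in ps.points
        ],
        "imagePath": f"{ps.image_id}.png",
        "imageData": None,
        "imageHeight": int(ps.height),
        "imageWidth": int(ps.width),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


# ---------------------------------------------------------------------------
# Images and masks
# ---------------------------------------------------------------------------

def load_image(path: str | Path, mask_path: str | Path | None = None) -> ImageRecord:
    """Load a JPEG/PNG image as an HxWx3 uint8 record.

    Grayscale inputs are replicated to 3 channels (the network input is
    fixed at 3 channels).
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"image file not found: {path}")
    with Image.open(path) as im:
        arr = np.asarray(im.convert("RGB"), dtype=np.uint8)
    mask = load_mask(mask_path) if mask_path else None
    return ImageRecord(image_id=path.stem, pixels=arr, mask=mask)


def load_mask(path: str | Path) -> np.ndarray:
    """Load a single-channel mask image; any nonzero pixel counts as
    panicle (robust to 0/1 vs 0/255 dialects)."""
    path = Path(path)
    if not path.exists():
        raise IOError(f"mask file not found: {path}")
    with Image.open(path) as im:
        arr = np.asarray(im.convert("L"))
    return arr > 0


def save_image(pixels: np.ndarray, path: str | Path) -> None:
    Image.fromarray(np.asarray(pixels, dtype=np.uint8)).save(path)


def save_mask(mask: np.ndarray, path: str | Path) -> None:
    Image.fromarray((np.asarray(mask, dtype=np.uint8) > 0).astype(np.uint8) * 255).save(path)


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Pipeline-wide configuration; defaults follow the study protocol
    (Gaussian sigma 5 px, 224x224 inputs, Adam, lr 0.001, batch 8,
    200 epochs with patience 20)."""

    sigma: float = 5.0
    target_height: int = 224
    target_width: int = 224
    batch_size: int = 8
    learning_rate: float = 0.001
    max_epochs: int = 200
    patience: int = 20
    degree: int = 2
    variants_per_image: int = 40
    rotation_range: float = 25.0
    split_fraction: float = 0.8
    split_level: str = "source"
    upsample_mode: str = "nearest"
    final_activation: str = "relu"
    width_scale: float = 1.0
    density_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValidationError(f"sigma must be > 0, got {self.sigma}")
        if self.target_height <= 0 or self.target_width <= 0:
            raise ValidationError("target size components must be > 0")
        if self.batch_size < 1:
            raise ValidationError("batch_size must be >= 1")
        if self.learning_rate <= 0:
            raise ValidationError("learning_rate must be > 0")
        if not (0 < self.split_fraction < 1):
            raise ValidationError("split_fraction must be in (0, 1)")
        if self.patience < 1 or self.max_epochs < 1:
            raise ValidationError("patience and max_epochs must be >= 1")
        if self.variants_per_image < 1:
            raise ValidationError("variants_per_image must be >= 1")
        if self.split_level not in ("source", "record"):
            raise ValidationError("split_level must be 'source' or 'record'")
        if self.density_scale <= 0 or self.width_scale <= 0:
            raise ValidationError("density_scale and width_scale must be > 0")
        if self.upsample_mode not in ("nearest", "bilinear"):
            raise ValidationError("upsample_mode must be 'nearest' or 'bilinear'")
        if self.final_activation not in ("relu", "linear"):
            raise ValidationError("final_activation must be 'relu' or 'linear'")


def load_config(path: str | Path) -> RunConfig:
    """Parse a key-value text config file (``key = value`` or ``key: value``
    per line, ``#`` comments).  Unset keys take the defaults above; unknown
    keys raise an error listing the valid ones."""
    path = Path(path)
    if not path.exists():
        raise IOError(f"config file not found: {path}")
    valid = {f.name: f.type for f in dataclasses.fields(RunConfig)}
    overrides: dict = {}
    for lineno, raw in enumerate(path.read_text().splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        for sep in ("=", ":"):
            if sep in line:
                key, _, val = line.partition(sep)
                break
        else:
            raise ValidationError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key, val = key.strip(), val.strip()
        if key not in valid:
            raise ValidationError(
                f"{path}:{lineno}: unknown config key {key!r}; "
                f"valid keys: {', '.join(sorted(valid))}"
            )
        default = getattr(RunConfig(), key)
        if isinstance(default, bool):
            overrides[key] = val.lower() in ("1", "true", "yes")
        elif isinstance(default, int):
            overrides[key] = int(val)
        elif isinstance(default, float):
            overrides[key] = float(val)
        else:
            overrides[key] = val
    return RunConfig(**overrides)
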