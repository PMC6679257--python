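"""Bounding-box data model and LabelImg/Pascal-VOC annotation I/O.

Internal coordinates are 0-based and half-open: a box occupies the pixel
set ``[x_min, x_max) x [y_min, y_max)``, so ``width = x_max - x_min`` and
areas are exact pixel counts.  The on-disk VOC/LabelImg dialect is 1-based
inclusive; :func:`read_voc_xml` / :func:`write_voc_xml` convert between the
two conventions bijectively.
"""

from __future__ import annotations

import logging
import os
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from PIL import Image

logger = logging.getLogger(__name__)

__all__ = [
    "BoundingBox",
    "AnnotatedImage",
    "DatasetManifest",
    "read_voc_xml",
    "write_voc_xml",
    "load_image",
    "save_image",
    "load_annotated_image",
    "boxes_to_array",
    "array_to_boxes",
]


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned rectangle in 0-based half-open pixel coordinates."""

    x_min: float
    y_min: float
    x_max: float
    y_max: float

    def __post_init__(self) -> None:
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise ValueError(
                f"degenerate box: ({self.x_min}, {self.y_min}, "
                f"{self.x_max}, {self.y_max}) must have positive area"
            )

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    @property
    def area(self) -> float:
        return self.width * self.height

    def clip(self, image_size: tuple[int, int]) -> "BoundingBox | None":
        """Clip to an (H, W) image; returns None if nothing remains."""
        h, w = image_size
        x0, y0 = max(self.x_min, 0.0), max(self.y_min, 0.0)
        x1, y1 = min(self.x_max, float(w)), min(self.y_max, float(h))
        if x0 >= x1 or y0 >= y1:
            return None
        return BoundingBox(x0, y0, x1, y1)

    def round(self) -> "BoundingBox":
        """Round coordinates half-away-from-zero to integers."""
        r = lambda v: float(np.floor(v + 0.5)) if v >= 0 else float(-np.floor(-v + 0.5))
        return BoundingBox(r(self.x_min), r(self.y_min), r(self.x_max), r(self.y_max))

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.x_min, self.y_min, self.x_max, self.y_max)


def boxes_to_array(boxes: Sequence[BoundingBox]) -> np.ndarray:
    """Stack boxes into an (N, 4) float array [x_min, y_min, x_max, y_max]."""
    if not boxes:
        return np.zeros((0, 4), dtype=np.float64)
    return np.array([b.as_tuple() for b in boxes], dtype=np.float64)


def array_to_boxes(arr: np.ndarray) -> list[BoundingBox]:
    return [BoundingBox(*row) for row in np.asarray(arr, dtype=np.float64)]


@dataclass
class AnnotatedImage:
    """An RGB raster plus its ground-truth panicle boxes."""

    image_id: str
    pixels: np.ndarray  # (H, W, 3) uint8
    boxes: list[BoundingBox] = field(default_factory=list)
    source: str = "real"  # "real" | "synthetic"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("pixels must be an (H, W, 3) raster")
        if self.pixels.dtype != np.uint8:
            raise ValueError("pixels must be 8-bit per channel")
        if self.source not in ("real", "synthetic"):
            raise ValueError(f"unknown source {self.source!r}")
        h, w = self.size
        for b in self.boxes:
            if b.x_min < 0 or b.y_min < 0 or b.x_max > w or b.y_max > h:
                raise ValueError(f"box {b.as_tuple()} outside {h}x{w} image")

    @property
    def size(self) -> tuple[int, int]:
        """(H, W)."""
        return self.pixels.shape[0], self.pixels.shape[1]

    def with_(self, **kwargs) -> "AnnotatedImage":
        return replace(self, **kwargs)


@dataclass
class DatasetManifest:
    """Ordered list of (image path, annotation path) pairs.

    Ordering is lexicographic by image path so that seeded splits are
    reproducible across runs and file systems.
    """

    entries: list[tuple[Path, Path]]
    split_tag: str | None = None  # "train" | "test" | None

    def __post_init__(self) -> None:
        self.entries = [(Path(i), Path(a)) for i, a in self.entries]

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def sorted(self) -> "DatasetManifest":
        return DatasetManifest(
            sorted(self.entries, key=lambda e: str(e[0])), self.split_tag
        )

    def validate(self) -> None:
        for img, ann in self.entries:
            if not img.exists():
                raise FileNotFoundError(f"manifest image missing: {img}")
            if not ann.exists():
                raise FileNotFoundError(f"manifest annotation missing: {ann}")

    def save(self, path: str | Path) -> None:
        """Two-column TSV; paths are stored relative to the manifest file
        so a dataset directory can be moved or compared byte-for-byte."""
        path = Path(path)
        base = path.parent.resolve()

        def rel(p: Path) -> str:
            try:
                return os.path.relpath(p.resolve(), base)
            except ValueError:  # different drive on some platforms
                return str(p)

        lines = [f"{rel(img)}\t{rel(ann)}" for img, ann in self.entries]
        path.write_text("\n".join(lines) + ("\n" if lines else ""))

    @classmethod
    def load(cls, path: str | Path, split_tag: str | None = None) -> "DatasetManifest":
        path = Path(path)
        base = path.parent
        entries = []
        for ln in path.read_text().splitlines():
            ln = ln.strip()
            if not ln:
                continue
            img, ann = ln.split("\t")
            entries.append(
                (
                    Path(img) if Path(img).is_absolute() else base / img,
                    Path(ann) if Path(ann).is_absolute() else base / ann,
                )
            )
        return cls(entries, split_tag)

    def load_images(self) -> list[AnnotatedImage]:
        return [load_annotated_image(img, ann) for img, ann in self.entries]


# ---------------------------------------------------------------------------
# VOC / LabelImg XML
# ---------------------------------------------------------------------------

def read_voc_xml(
    path: str | Path,
    image_size: tuple[int, int],
    clip: bool = True,
) -> list[BoundingBox]:
    """Read LabelImg-dialect VOC boxes, converting to internal coordinates.

    The file stores 1-based inclusive pixel coordinates; the returned boxes
    are 0-based half-open: ``(xmin, ymin, xmax, ymax)`` on disk becomes
    ``(xmin-1, ymin-1, xmax, ymax)`` internally.

    Parameters
    ----------
    path : annotation file.
    image_size : (H, W) of the parent image; boxes are clipped to it.
    clip : when False, out-of-bounds boxes are kept verbatim (for datasets
        where truncated objects at plot edges were annotated beyond the
        frame); when True (default) boxes are clipped and boxes left with
        zero area are dropped with a warning.
    """
    path = Path(path)
    try:
        root = ET.parse(path).getroot()
    except ET.ParseError as exc:
        raise ValueError(f"malformed annotation XML {path}: {exc}") from exc

    boxes: list[BoundingBox] = []
    for obj in root.iter("object"):
        bnd = obj.find("bndbox")
        if bnd is None:
            continue
        xmin = float(bnd.findtext("xmin"))
        ymin = float(bnd.findtext("ymin"))
        xmax = float(bnd.findtext("xmax"))
        ymax = float(bnd.findtext("ymax"))
        # on-disk coordinates are 1-based inclusive, so xmin == xmax is a
        # valid 1-pixel-wide box; only inverted coordinates are degenerate
        if xmin > xmax or ymin > ymax:
            logger.warning(
                "%s: rejected degenerate box (%s, %s, %s, %s)",
                path.name, xmin, ymin, xmax, ymax,
            )
            continue
        box = BoundingBox(xmin - 1.0, ymin - 1.0, xmax, ymax)
        if clip:
            clipped = box.clip(image_size)
            if clipped is None:
                logger.warning(
                    "%s: dropped box %s fully outside %sx%s image",
                    path.name, box.as_tuple(), *image_size,
                )
                continue
            box = clipped
        boxes.append(box)
    return boxes


def write_voc_xml(
    boxes: Iterable[BoundingBox],
    image_meta: AnnotatedImage | dict,
    path: str | Path,
    object_name: str = "panicle",
) -> None:
    """Write boxes as a LabelImg-compatible VOC annotation file.

    Inverse of :func:`read_voc_xml`: internal half-open boxes are written
    back as 1-based inclusive coordinates, so write-then-read is the
    identity on valid box lists.
    """
    if isinstance(image_meta, AnnotatedImage):
        h, w = image_meta.size
        filename = image_meta.meta.get("filename", image_meta.image_id + ".png")
        source = image_meta.source
    else:
        h, w = image_meta["height"], image_meta["width"]
        filename = image_meta.get("filename", "image.png")
        source = image_meta.get("source", "real")

    root = ET.Element("annotation")
    ET.SubElement(root, "folder").text = str(Path(path).parent.name)
    ET.SubElement(root, "filename").text = str(filename)
    src = ET.SubElement(root, "source")
    ET.SubElement(src, "database").text = source
    size = ET.SubElement(root, "size")
    ET.SubElement(size, "width").text = str(w)
    ET.SubElement(size, "height").text = str(h)
    ET.SubElement(size, "depth").text = "3"
    ET.SubElement(root, "segmented").text = "0"
    for b in boxes:
        obj = ET.SubElement(root, "object")
        ET.SubElement(obj, "name").text = object_name
        ET.SubElement(obj, "pose").text = "Unspecified"
        ET.SubElement(obj, "truncated").text = "0"
        ET.SubElement(obj, "difficult").text = "0"
        bnd = ET.SubElement(obj, "bndbox")
        ET.SubElement(bnd, "xmin").text = _fmt(b.x_min + 1.0)
        ET.SubElement(bnd, "ymin").text = _fmt(b.y_min + 1.0)
        ET.SubElement(bnd, "xmax").text = _fmt(b.x_max)
        ET.SubElement(bnd, "ymax").text = _fmt(b.y_max)
    ET.indent(root)
    ET.ElementTree(root).write(path, encoding="unicode", xml_declaration=False)


def _fmt(v: float) -> str:
    return str(int(v)) if float(v).is_integer() else repr(float(v))


# ---------------------------------------------------------------------------
# Raster I/O
# ---------------------------------------------------------------------------

def load_image(path: str | Path) -> np.ndarray:
    """Load a JPEG/PNG raster as (H, W, 3) uint8."""
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"))


def save_image(pixels: np.ndarray, path: str | Path) -> None:
    Image.fromarray(np.asarray(pixels, dtype=np.uint8), mode="RGB").save(path)


def load_annotated_image(
    image_path: str | Path, annotation_path: str | Path, **kwargs
) -> AnnotatedImage:
    pixels = load_image(image_path)
    boxes = read_voc_xml(annotation_path, pixels.shape[:2], **kwargs)
    return AnnotatedImage(
        image_id=Path(image_path).stem,
        pixels=pixels,
        boxes=boxes,
        meta={"filename": Path(image_path).name},
    )
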