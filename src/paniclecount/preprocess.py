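"""Photometric enhancement, label-preserving augmentation, resizing, splits.

The enhancement step produces eight photometric variants per image —
enhancement and attenuation of brightness, chroma, contrast and sharpness —
using the standard enhancement-factor semantics (linear blend toward black,
the gray mean, grayscale, or a smoothed copy respectively; factor 1 is the
identity).  Default factors: brightness/chroma/contrast 1.20 and 0.60,
sharpness 2.00 and 0.10.  Photometric variants never move boxes.

Geometric augmentation produces a horizontal mirror, a 90° rotation and a
180° rotation with boxes mapped by the same transform.  Augmentation is
meant for the training side only: variants carry their source image id in
``meta['source_id']`` and the splitter keeps all variants of one source on
the same side.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from PIL import Image, ImageEnhance

from .annotations_io import AnnotatedImage, BoundingBox, DatasetManifest

logger = logging.getLogger(__name__)

__all__ = [
    "EnhancementParams",
    "SplitSpec",
    "enhance",
    "augment",
    "resize_with_boxes",
    "split_dataset",
    "source_id",
]

PAPER_SPLIT_FRACTIONS = (0.8, 0.6, 0.5, 0.4, 0.2)


@dataclass(frozen=True)
class EnhancementParams:
    brightness_enh: float = 1.20
    brightness_att: float = 0.60
    chroma_enh: float = 1.20
    chroma_att: float = 0.60
    contrast_enh: float = 1.20
    contrast_att: float = 0.60
    sharpness_enh: float = 2.00
    sharpness_att: float = 0.10

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.__dict__.values()):
            raise ValueError("all enhancement factors must be positive")


_ENHANCERS = {
    "brightness": ImageEnhance.Brightness,
    "chroma": ImageEnhance.Color,
    "contrast": ImageEnhance.Contrast,
    "sharpness": ImageEnhance.Sharpness,
}


def source_id(image_id: str) -> str:
    """Source image id of a (possibly derived) image id.

    Variant ids are formed as ``<source>__<tag>``; nested derivation keeps
    the original source prefix.
    """
    return image_id.split("__", 1)[0]


def enhance(
    image: AnnotatedImage, params: EnhancementParams = EnhancementParams()
) -> list[AnnotatedImage]:
    """Eight photometric variants (4 properties x enhance/attenuate).

    Boxes are returned unchanged: photometric operators do not move
    objects.  Outputs are clipped to the 8-bit range by the operators
    themselves.
    """
    pil = Image.fromarray(image.pixels, mode="RGB")
    out = []
    for prop, enhancer in _ENHANCERS.items():
        for kind in ("enh", "att"):
            factor = getattr(params, f"{prop}_{kind}")
            pixels = np.asarray(enhancer(pil).enhance(factor))
            out.append(
                image.with_(
                    image_id=f"{source_id(image.image_id)}__{prop}_{kind}",
                    pixels=pixels,
                    boxes=list(image.boxes),
                    meta={**image.meta, "source_id": source_id(image.image_id)},
                )
            )
    return out


def _flip_h(box: BoundingBox, w: int) -> BoundingBox:
    return BoundingBox(w - box.x_max, box.y_min, w - box.x_min, box.y_max)


def _rot180(box: BoundingBox, h: int, w: int) -> BoundingBox:
    return BoundingBox(w - box.x_max, h - box.y_max, w - box.x_min, h - box.y_min)


def _rot90_ccw(box: BoundingBox, w: int) -> BoundingBox:
    # pixel (x, y) of an HxW image maps to (y, W - 1 - x) of the WxH image;
    # in half-open coords a box [x0,x1)x[y0,y1) maps to [y0,y1)x[W-x1,W-x0)
    return BoundingBox(box.y_min, w - box.x_max, box.y_max, w - box.x_min)


def augment(image: AnnotatedImage) -> list[AnnotatedImage]:
    """Mirror, 90° and 180° rotation variants with transformed boxes."""
    h, w = image.size
    src = source_id(image.image_id)
    meta = {**image.meta, "source_id": src}
    mirror = image.with_(
        image_id=f"{src}__mirror",
        pixels=np.ascontiguousarray(image.pixels[:, ::-1]),
        boxes=[_flip_h(b, w) for b in image.boxes],
        meta=dict(meta),
    )
    r90 = image.with_(
        image_id=f"{src}__rot90",
        pixels=np.ascontiguousarray(np.rot90(image.pixels, k=1)),
        boxes=[_rot90_ccw(b, w) for b in image.boxes],
        meta=dict(meta),
    )
    r180 = image.with_(
        image_id=f"{src}__rot180",
        pixels=np.ascontiguousarray(image.pixels[::-1, ::-1]),
        boxes=[_rot180(b, h, w) for b in image.boxes],
        meta=dict(meta),
    )
    return [mirror, r90, r180]


def resize_with_boxes(
    image: AnnotatedImage, target: tuple[int, int] = (256, 256)
) -> AnnotatedImage:
    """Bilinear resize to (H, W) with boxes scaled by the same factors.

    Scaled box coordinates are rounded half-away-from-zero and re-clipped;
    boxes that collapse to zero area are dropped with a warning.
    """
    th, tw = target
    if th < 1 or tw < 1:
        raise ValueError("target dimensions must be >= 1")
    h, w = image.size
    if (h, w) == (th, tw):
        return image
    pil = Image.fromarray(image.pixels, mode="RGB")
    pixels = np.asarray(pil.resize((tw, th), Image.BILINEAR))
    sy, sx = th / h, tw / w
    boxes = []
    for b in image.boxes:
        scaled = BoundingBox(
            _round_half_away(b.x_min * sx),
            _round_half_away(b.y_min * sy),
            max(_round_half_away(b.x_max * sx), _round_half_away(b.x_min * sx)),
            max(_round_half_away(b.y_max * sy), _round_half_away(b.y_min * sy)),
        ) if _has_area(b, sx, sy) else None
        if scaled is None:
            logger.warning("%s: box %s collapsed under resize, dropped",
                           image.image_id, b.as_tuple())
            continue
        clipped = scaled.clip((th, tw))
        if clipped is None:
            logger.warning("%s: box %s collapsed under resize, dropped",
                           image.image_id, b.as_tuple())
            continue
        boxes.append(clipped)
    return image.with_(pixels=pixels, boxes=boxes)


def _round_half_away(v: float) -> float:
    return math.floor(v + 0.5) if v >= 0 else -math.floor(-v + 0.5)


def _has_area(b: BoundingBox, sx: float, sy: float) -> bool:
    return (
        _round_half_away(b.x_max * sx) > _round_half_away(b.x_min * sx)
        and _round_half_away(b.y_max * sy) > _round_half_away(b.y_min * sy)
    )


@dataclass(frozen=True)
class SplitSpec:
    """Seeded train/test partition at one of the study's five proportions."""

    train_fraction: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError("train fraction must lie strictly inside (0, 1)")


def split_dataset(
    manifest: DatasetManifest, spec: SplitSpec
) -> tuple[DatasetManifest, DatasetManifest]:
    """Seeded shuffle-then-partition with |train| = round(fraction * N).

    All derived variants of one source image (shared ``source_id`` prefix)
    land on the same side, so augmentation can never leak test content
    into training.  With only unaugmented sources the train size is exactly
    ``round(fraction * N)``.
    """
    if len(manifest) == 0:
        raise ValueError("cannot split an empty manifest")
    entries = manifest.sorted().entries
    groups: dict[str, list[tuple]] = {}
    for e in entries:
        groups.setdefault(source_id(e[0].stem), []).append(e)
    keys = sorted(groups)
    rng = np.random.default_rng(spec.seed)
    order = [keys[i] for i in rng.permutation(len(keys))]
    target = _round_half_away(spec.train_fraction * len(entries))
    train: list[tuple] = []
    test: list[tuple] = []
    for k in order:
        side = train if len(train) < target else test
        side.extend(groups[k])
    return (
        DatasetManifest(train, "train").sorted(),
        DatasetManifest(test, "test").sorted(),
    )
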