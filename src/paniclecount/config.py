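"""YAML run configuration with strict validation.

One file drives the whole pipeline: scene generation, preprocessing,
train/test splitting, detector hyper-parameters, NMS, evaluation and
counting thresholds.  Defaults equal the published study configuration
(Table-style factors and thresholds are documented on the dataclasses they
configure).  Unknown keys are rejected with the line in the file where
they appear, so typos never silently fall back to defaults.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .counting import CountingConfig
from .detector import HyperParams
from .evaluation import DEFAULT_IOU_THRESHOLD
from .nms import NmsConfig
from .preprocess import EnhancementParams, SplitSpec
from .synthetic_field import SceneConfig, preset

__all__ = ["RunConfig", "PreprocessConfig", "EvaluationConfig", "load_config"]


@dataclass(frozen=True)
class PreprocessConfig:
    resize: tuple[int, int] = (256, 256)
    enhance: bool = True  # emit the 8 photometric variants
    augment_train: bool = True  # mirror/90/180 on the training side
    clip_boxes: bool = True  # clip annotation boxes at image borders
    enhancement: EnhancementParams = field(default_factory=EnhancementParams)


@dataclass(frozen=True)
class EvaluationConfig:
    iou_threshold: float = DEFAULT_IOU_THRESHOLD  # strict > rule


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    out_dir: Path = Path("runs/out")
    scene: SceneConfig = field(default_factory=lambda: preset("standard"))
    n_images: int = 235
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    split: SplitSpec = field(default_factory=SplitSpec)
    train: HyperParams = field(default_factory=HyperParams)
    nms: NmsConfig = field(default_factory=NmsConfig)
    evaluation: EvaluationConfig = field(default_factory=EvaluationConfig)
    counting: CountingConfig = field(default_factory=CountingConfig)


_BLOCKS = {
    "scene": SceneConfig,
    "preprocess": PreprocessConfig,
    "split": SplitSpec,
    "train": HyperParams,
    "nms": NmsConfig,
    "evaluation": EvaluationConfig,
    "counting": CountingConfig,
}
_TOP_KEYS = {"seed", "out_dir", "n_images", *_BLOCKS}


def _find_line(text: str, key: str) -> int | None:
    for i, line in enumerate(text.splitlines(), start=1):
        stripped = line.split("#", 1)[0]
        if stripped.strip().startswith(f"{key}:"):
            return i
    return None


def _reject_unknown(given: dict, allowed: set, path: Path, text: str, where: str):
    for key in given:
        if key not in allowed:
            line = _find_line(text, key)
            loc = f"{path}:{line}" if line else str(path)
            raise ValueError(f"{loc}: unknown key {key!r} in {where}")


def _tupleize(cls, kwargs: dict) -> dict:
    out = {}
    for f in dataclasses.fields(cls):
        if f.name in kwargs:
            v = kwargs[f.name]
            out[f.name] = tuple(v) if isinstance(v, list) else v
    return out


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a pipeline configuration file."""
    path = Path(path)
    text = path.read_text()
    raw = yaml.safe_load(text) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: top level must be a mapping")
    _reject_unknown(raw, _TOP_KEYS, path, text, "top level")

    kwargs: dict = {}
    if "seed" in raw:
        kwargs["seed"] = int(raw["seed"])
    if "out_dir" in raw:
        kwargs["out_dir"] = Path(raw["out_dir"])
    if "n_images" in raw:
        kwargs["n_images"] = int(raw["n_images"])

    for block, cls in _BLOCKS.items():
        if block not in raw:
            continue
        sub = dict(raw[block] or {})
        if block == "scene" and "preset" in sub:
            base = preset(sub.pop("preset"))
        else:
            base = None
        allowed = {f.name for f in dataclasses.fields(cls)}
        if block == "preprocess":
            sub_enh = sub.pop("enhancement", None)
            _reject_unknown(sub, allowed, path, text, f"'{block}' block")
            sub = _tupleize(cls, sub)
            if sub_enh is not None:
                enh_allowed = {f.name for f in dataclasses.fields(EnhancementParams)}
                _reject_unknown(sub_enh, enh_allowed, path, text, "'enhancement' block")
                sub["enhancement"] = EnhancementParams(**sub_enh)
            kwargs[block] = cls(**sub)
            continue
        _reject_unknown(sub, allowed, path, text, f"'{block}' block")
        sub = _tupleize(cls, sub)
        if base is not None:
            kwargs[block] = base.with_(**sub)
        else:
            kwargs[block] = cls(**sub)
    return RunConfig(**kwargs)
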