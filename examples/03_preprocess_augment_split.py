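"""Photometric enhancement, geometric augmentation, and leakage-safe splits.

One source image yields 8 photometric variants (boxes unchanged) and 3
geometric variants (boxes transformed).  The splitter keeps all variants
of a source image on one side, so augmentation cannot leak test content
into training.
"""

from pathlib import Path

from paniclecount import SplitSpec, augment, enhance, split_dataset
from paniclecount.annotations_io import DatasetManifest
from paniclecount.preprocess import source_id
from paniclecount.synthetic_field import preset, render_scene

scene = render_scene(preset("easy").with_(rng_seed=3))
image = scene.image

variants = enhance(image)
print(f"enhance: {len(variants)} photometric variants:",
      ", ".join(v.image_id.split('__')[1] for v in variants))
print("boxes unchanged by photometric ops:",
      all(v.boxes == image.boxes for v in variants))

geo = augment(image)
print(f"augment: {len(geo)} geometric variants; box areas preserved:",
      all(v.boxes[0].area == image.boxes[0].area for v in geo))

# split a synthetic manifest of 235 sources at the 80-20 proportion
entries = [(Path(f"img_{i:03d}.png"), Path(f"img_{i:03d}.xml")) for i in range(235)]
train, test = split_dataset(DatasetManifest(entries), SplitSpec(0.8, seed=1))
print(f"80-20 split of 235 images: {len(train)} train / {len(test)} test "
      "(round(0.8 x 235) = 188)")
leak = {source_id(e[0].stem) for e in train} & {source_id(e[0].stem) for e in test}
print("source ids on both sides:", len(leak))
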