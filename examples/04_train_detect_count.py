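"""Train the small detector on easy scenes, then detect and count.

A deliberately short schedule (a few hundred iterations on a handful of
96x96 scenes) so the script finishes in under a minute; expect rough
detections.  The bundled configs/paper.yaml carries the study-scale
schedule.
"""

import numpy as np

from paniclecount import (
    CountingConfig,
    HyperParams,
    count_panicles,
    match_detections,
    compute_metrics,
    predict,
    train,
)
from paniclecount.synthetic_field import preset, render_scenes

cfg = preset("easy").with_(image_size=(96, 96), panicle_count_range=(4, 9),
                           rng_seed=11)
scenes = render_scenes(cfg, 24)
train_imgs = [s.image for s in scenes[:20]]
held_out = scenes[20:]

hp = HyperParams(seed=0, iteration_budget=400, verification_period=200, ohem_k=64)
state = train(train_imgs, hp)
print(f"trained {state.iteration} iterations; "
      f"loss {state.loss_curve[0]:.3f} -> {np.mean(state.loss_curve[-20:]):.3f}")
for h in state.history:
    print(f"  iter {h['iteration']}: val loss {h['val_loss']:.3f}, "
          f"region error {h['val_error']:.3f}")

tp = fp = fn = 0
for s in held_out:
    det = predict(s.image, state, confidence_threshold=0.5)
    m = match_detections(det, s.truth)
    tp, fp, fn = tp + m.tp, fp + m.fp, fn + m.fn
r = compute_metrics(type(m)(tp, fp, fn, [(None, None, 0.5)] * tp))
print(f"held-out: TP {tp} FP {fp} FN {fn} -> "
      f"precision {r.precision:.2f}, recall {r.recall:.2f} "
      "(IoU > 0.2 counts as a hit)")

rec = count_panicles(held_out[0].image, state,
                     CountingConfig(confidence_threshold=0.5))
print(f"count on one scene: {rec.automated_count} detected vs "
      f"{len(held_out[0].truth)} true panicles")
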