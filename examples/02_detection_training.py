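"""Train the heatmap-regression detector and evaluate on held-out patches.

Point annotations become Gaussian target maps (peak 1 per nucleus, sigma
6 px); a per-pixel regressor is trained with squared loss and Adam, and
the epoch with the best validation F-measure is kept. Evaluation pairs
detections with ground truth one-to-one within a 20 px radius.
"""

from viadens.detect import DetectorConfig, train_detector
from viadens.evalmetrics import MatchResult, match_points, metric_set
from viadens.synthdata import PatchSpec, render_patch


def render_set(n, seed0):
    return [render_patch(PatchSpec(seed=seed0 + i)) for i in range(n)]


train, val, test = render_set(16, 0), render_set(6, 1000), render_set(8, 2000)
config = DetectorConfig(epochs=6, seed=7)
model = train_detector(train, val, config)

print("validation F per epoch:",
      " ".join(f"{f:.3f}" for f in model.selection_record))
print(f"adopted weights from epoch {model.selected_epoch} "
      f"(best validation F = {max(model.selection_record):.3f})")

tp = fp = fn = 0
for patch in test:
    m = match_points(model.detect(patch.image), patch.viable_points, radius=20)
    tp, fp, fn = tp + m.tp, fp + m.fp, fn + m.fn
ms = metric_set(MatchResult(tp, fp, fn, ()))
print(f"held-out: precision={ms.precision:.3f} recall={ms.recall:.3f} "
      f"F={ms.f_measure:.3f}  (tp={tp}, fp={fp}, fn={fn})")
print("-> F near 1 on this easy synthetic task confirms the training, "
      "selection and peak-calling loop is wired correctly")
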