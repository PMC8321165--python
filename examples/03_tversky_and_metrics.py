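"""The Tversky index, its Dice limit, and the six volumetric metrics."""

import numpy as np

from fibroseg import MaskVolume, TverskyParams, compute_metrics, tversky_index, tversky_loss

p = np.array([[1, 1], [1, 0]])
g = np.array([[0, 1], [0, 0]])
print("2x2 example (TP=1, FP=2, FN=0):")
print(f"  S(alpha=0.3, beta=0.7) = {tversky_index(p, g, TverskyParams(0.3, 0.7)):.3f}"
      "  (false positives penalized mildly)")
print(f"  S(alpha=0.5, beta=0.5) = {tversky_index(p, g, TverskyParams(0.5, 0.5)):.3f}"
      "  (= Dice = 2/4)")

p0 = np.array([0.8, 0.4, 0.1])
g0 = np.array([1.0, 1.0, 0.0])
print(f"soft Tversky loss of probabilities {p0} vs labels {g0}: "
      f"{tversky_loss(p0, g0, TverskyParams(0.3, 0.7), smooth=0.0):.4f}")

rng = np.random.default_rng(0)
truth = np.zeros((12, 12, 6), np.uint8)
truth[3:9, 3:9, 1:5] = 1
pred = truth.copy()
pred[2, 3:9, 1:5] = 1  # one-voxel over-segmentation along one face
rep = compute_metrics(MaskVolume(pred, (1, 1, 1)), MaskVolume(truth, (1, 1, 1)))
print("cube truth vs one-face over-segmentation:")
for k, v in rep.as_dict().items():
    unit = "mm" if k == "assd" else "%"
    print(f"  {k:>12}: {v:7.2f} {unit}")
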