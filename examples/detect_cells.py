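"""Train the sliding-window SVM detector and score its detections.

Trains on one phantom's hand-labelled centres (here: ground truth),
scans a held-out phantom at multiple scales, and reports average
precision under the 1.5 um matching rule. Runs in a couple of minutes.
"""

import voxcyto as vc
from voxcyto.detect import DetectorConfig, scan_detect, train_detector
from voxcyto.evaluate import average_precision, match_detections

train_ph = vc.generate_phantom(vc.PhantomSpec(seed=21))
test_ph = vc.generate_phantom(vc.PhantomSpec(seed=22))

model = train_detector([train_ph.dna], [train_ph.truth.centers_um], DetectorConfig())
print("mining log:", model.log["mining"][-1])

detections = scan_detect(test_ph.dna, model, tau=-2.0)
ap = average_precision(detections, test_ph.truth.centers_um)
res = match_detections(
    detections.coords_um[detections.scores > 0], test_ph.truth.centers_um
)
print(f"{len(detections)} ranked detections on the held-out phantom")
print(f"average precision (area under the PR curve): {ap:.3f}")
print(f"at tau = 0: precision {res.precision:.2f}, recall {res.recall:.2f}")
print("AP near 1 means nearly every nucleus is found within 1.5 um, "
      "with false positives ranked below true cells.")
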