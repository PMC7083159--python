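"""Turn a heatmap into box detections and score them with IoU / AP / mAP.

Detections are 8-connected components of the thresholded heatmap; each
carries confidence = (peak heatmap value in the box) x (classifier's
abnormal probability).  They are scored against ground-truth boxes by
greedy confidence-ordered matching.
"""

import numpy as np

from crmloc import (
    BoundingBox,
    GroundTruthRecord,
    RelevanceMap,
    average_precision,
    extract_boxes,
    iou,
    mean_average_precision,
    mean_image_iou,
    pr_curve,
)

heat = np.zeros((32, 32))
heat[4:12, 5:14] = 0.6      # first hot region
heat[20:27, 18:28] = 0.9    # second hot region
dets = extract_boxes(RelevanceMap(heat), classification_score=0.8,
                     image_id="img0")
for d in dets:
    print(f"detection {d.box} confidence={d.confidence:.2f}")

truth = [GroundTruthRecord("img0", (BoundingBox(5, 4, 14, 12),
                                    BoundingBox(17, 20, 28, 27)))]
print("IoU of first pair:",
      round(iou(dets[-1].box, truth[0].boxes[0]), 3))
curve = pr_curve(dets, truth, iou_threshold=0.5)
print("PR points:", curve.points)
print("AP@0.5:", average_precision(curve))
print("mAP@[0.1,0.6]:", round(mean_average_precision(dets, truth), 3))
print("mean image IoU:", round(mean_image_iou(dets, truth), 3))
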