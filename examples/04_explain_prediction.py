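"""Classify a cough case and visualize why with Grad-CAM.

A strong cough near the end of exhalation shows up as a spike on the
flow-volume curve; the heatmap should concentrate there. Loads the
checkpoint written by 03_train_and_evaluate.py (run that first).
"""

import numpy as np
from PIL import Image

from spiroqc import (
    Demographics,
    ManeuverParams,
    build_construct,
    grad_cam,
    inject_artifact,
    overlay,
    render_report,
    simulate_maneuver,
)
from spiroqc.model import load_checkpoint

clf = load_checkpoint("scratch/cough_model.npz")

params = ManeuverParams(
    fvc=3.1, pef=6.2, artifact="cough",
    artifact_params={"amplitude_scale": 0.9, "width": 0.12}, seed=7,
)
maneuver = inject_artifact(simulate_maneuver(params), params)
report = render_report(maneuver, Demographics(sex="woman", age=45, bmi=18.1))
gc = build_construct(report.page, report.demographics)

risk = clf.predict_risk(gc)
print(f"risk that the test is unacceptable: {risk:.3f}")

heatmap = grad_cam(clf, gc, target_class="unacceptable")
box = gc.map_page_box(report.artifact_annotation)
inside = np.zeros_like(heatmap.values, bool)
inside[box[0]:box[2], box[1]:box[3]] = True
print(f"mean heatmap value inside the cough region: "
      f"{heatmap.values[inside].mean():.3f}; outside: "
      f"{heatmap.values[~inside].mean():.3f}")

Image.fromarray(overlay(gc, heatmap, alpha=0.4)).save("scratch/gradcam.png")
print("overlay written to scratch/gradcam.png")
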