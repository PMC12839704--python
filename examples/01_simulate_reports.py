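"""Generate a small labeled dataset of synthetic spirometry reports.

Each report is a PNG page: demographics text in the top half, the
volume-time and flow-volume curves (blue, optionally with a red
post-bronchodilator overlay) in the bottom half. The manifest CSV records
the ground-truth label and artifact for every page.
"""

from pathlib import Path

from spiroqc import generate_dataset

out_dir = Path("scratch/example_reports")
manifest = generate_dataset(out_dir, n=20, unacceptable_fraction=0.35, seed=0)

print(manifest.to_string(index=False))
print()
print(f"{(manifest.label == 'unacceptable').sum()} of {len(manifest)} maneuvers "
      "carry an artifact (cough, early termination, submaximal effort or an "
      "extra breath) and are therefore unacceptable; the rest are clean.")
print(f"Report pages and manifest.csv written to {out_dir}/")
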