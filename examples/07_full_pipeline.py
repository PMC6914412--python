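"""The whole pipeline from one config, with seeded reproducibility.

Runs simulate -> de -> enrich -> signalnet -> targets -> build -> validate,
writes every artifact under out/, and records a SHA-256 manifest; a second
run with the same seed reproduces every file bit for bit.
"""

import json
from pathlib import Path

from cernanet.pipeline import PipelineConfig, run_pipeline

out = Path("scratch/example_pipeline")
manifest = run_pipeline(PipelineConfig(out_dir=str(out / "run1"), seed=6))
manifest2 = run_pipeline(PipelineConfig(out_dir=str(out / "run2"), seed=6))

for stage, files in manifest.items():
    print(f"{stage}: {len(files)} file(s)")
recovery = json.loads((out / "run1" / "build" / "recovery.json").read_text())
print(f"\nplanted-triplet recovery on the default simulation: "
      f"precision {recovery['precision']:.2f}, recall {recovery['recall']:.2f}")
print(f"bitwise reproducible across runs: {manifest == manifest2}")
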