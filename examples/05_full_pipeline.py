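"""One-command reproducible run: synth -> train -> evaluate with a manifest.

Executes the orchestrated pipeline on a small cohort and shows what lands
in the output directory, including the SHA-256 manifest that makes reruns
verifiable.
"""

import json
import tempfile
from pathlib import Path

from milsurv.pipeline import RunConfig, run_pipeline

out = Path(tempfile.mkdtemp()) / "run"
manifest = run_pipeline(RunConfig(
    out_dir=str(out), seed=11, n_patients=60, epochs=10, k_folds=5,
))

print("stage timings (s):", manifest.stage_seconds)
metrics = json.loads((out / "cv_metrics.json").read_text())
print(f"mean C-index: {metrics['mean_cindex']:.4f}")
ev = json.loads((out / "evaluation.json").read_text())
print(f"log-rank p: {ev['logrank_p']:.2e}")
print(f"{len(manifest.files)} output files hashed in manifest.json")
print("re-running with the same config reproduces identical hashes")
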