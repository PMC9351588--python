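"""Run the chained four-step pipeline and list what it writes.

Equivalent to `qdnet run --config cfg.yaml`: power fits -> link selection
-> component decomposition -> networks (+ optional clustering and context
comparison), with a manifest of output hashes for reproducibility.
"""

import tempfile
from pathlib import Path

import qdnet

out = Path(tempfile.mkdtemp(prefix="qdnet-example-"))
cfg = qdnet.PipelineConfig(out_dir=str(out), scenario_name="phylum17", seed=0,
                           order=2, compare=False)
run_dir = qdnet.run_pipeline(cfg)

print(f"pipeline outputs in {run_dir}:")
for path in sorted(run_dir.iterdir()):
    print(f"  {path.name:>24}  {path.stat().st_size:6d} bytes")
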