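"""Run the whole pipeline on a named scenario and list its outputs.

Equivalent to the CLI:  lumenstrain run --scenario paper_like_8mice
"""

import tempfile
from pathlib import Path

from lumenstrain.pipeline import RunConfig, run_pipeline

out_dir = Path(tempfile.mkdtemp()) / "demo_run"
config = RunConfig(
    scenario="paper_like_8mice",
    seed=1,
    out_dir=str(out_dir),
    min_cluster=500,   # fixture-scale cluster gate (10^3 at genome scale)
    min_pi_sites=100,  # fixture-scale |G| gate (5 x 10^5 at genome scale)
    n_boot=200,
)
out = run_pipeline(config)

print(f"outputs in {out}:")
for p in sorted(out.iterdir()):
    print(f"  {p.name}")
print("\nrun.log tail:")
print("\n".join((out / "run.log").read_text().splitlines()[-6:]))
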