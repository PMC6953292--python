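"""Run an analysis from delimited text files.

Blocks travel as CSV with a header row of variable IDs and a leading column
of sample IDs; all blocks must share the same samples in the same order.
The fitted results are written back as small variable-id-keyed tables plus a
JSON summary, so a run is reproducible from its own output.
"""

import tempfile
from pathlib import Path

from mspls import (
    PenaltySpec,
    SimulationConfig,
    fit,
    load_dataset,
    save_fit,
    simulate_dataset,
    three_block_connectivity,
)
from mspls.io import save_block

tmp = Path(tempfile.mkdtemp())
sim = simulate_dataset(SimulationConfig(n=30, p=(40, 40, 10), k=(4, 4, 3), seed=5))
paths = []
for block in sim.dataset.blocks:
    p = tmp / f"{block.name}.csv"
    save_block(block, p)
    paths.append(p)

dataset = load_dataset(paths, names=["X1", "X2", "X3"])
model = fit(dataset, three_block_connectivity(), PenaltySpec("ust", lambda1=0.4))
save_fit(model, tmp / "results", dataset=dataset)

print(f"blocks read back from {tmp}: "
      f"{[(b.name, b.values.shape) for b in dataset.blocks]}")
print(f"converged={model.converged}; results bundle written to {tmp/'results'}:")
for f in sorted((tmp / "results").iterdir()):
    print("   ", f.name)
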