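"""Assemble a typed heterogeneous network and summarise it.

Generates a synthetic herb/ingredient/target/disease dataset, writes
it in the package's on-disk formats (per-relation TSVs plus a
STRING-style PPI file), reads it back through the parsers, and prints
the per-relation summary table.
"""

import tempfile
from pathlib import Path

from repowalk import (
    SyntheticConfig,
    generate,
    load_network,
    summarize_network,
    write_fixture,
)

with tempfile.TemporaryDirectory() as tmp:
    net, ppi, truth = generate(SyntheticConfig(seed=0))
    write_fixture(net, ppi, truth, tmp)
    print("fixture files:", sorted(p.name for p in Path(tmp).iterdir()))

    # the PPI layer passes through the confidence filter on the way in
    full = load_network(tmp, min_score=700)

print(f"\nnetwork: {full.n_nodes} nodes, {full.n_edges} edges")
print(summarize_network(full).to_string(index=False))
print(
    "\nEach row mirrors one typed relation: how many distinct nodes of "
    "either class participate, and how many edges join them. The "
    "target-target row is the PPI layer after keeping only interactions "
    "with combined_score >= 700."
)
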