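"""Simulate a multi-batch dataset and run the preprocessing stage.

Generates three batches with a deliberately non-identical cell-type
structure, then normalizes (ln(1 + 10000·count/total)), selects a shared
highly-variable-gene panel and z-scores each gene within its batch — the
representation every later stage works on.
"""

import numpy as np

from ssber import normalize_log, scale_zscore, scenario_fixture, select_hvg

data = scenario_fixture("scenario1_structure").generate(with_reference=False)

for name in sorted(data["batches"]):
    m = data["batches"][name]
    types = sorted(set(data["truth"][name]))
    print(f"{name}: {m.n_cells} cells x {m.n_genes} genes, "
          f"{len(types)} types: {', '.join(types)}")

lognorm = {b: normalize_log(m) for b, m in data["batches"].items()}
hvg = select_hvg(list(lognorm.values()), n_genes=800)
panel = hvg.sorted()
scaled = {b: scale_zscore(m.subset_genes(panel)) for b, m in lognorm.items()}

one = scaled["celseq"]
print(f"\nHVG panel: {len(hvg)} genes shared by all batches")
print(f"scaled layer: per-gene mean {one.dense().mean(axis=0).max():.2e} "
      f"(0 by construction), sd ~1 for variable genes")
# Each batch is now a cells x 800 matrix of z-scores; anchors are found in
# this space and in its CCA projection.
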