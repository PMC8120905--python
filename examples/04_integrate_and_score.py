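"""Full pipeline on a three-batch dataset with partial type overlap.

Annotates each batch with a classifier trained on a labeled reference,
integrates all batches against an automatically chosen reference batch, and
scores the result with the full metric suite (batch mixing: KBET, iLISI,
ASW_batch; biology conservation: ARI, cLISI, ASW_celltype, isolated-label,
HVG conservation).
"""

import numpy as np

from ssber import (compute_report, integrate_batches, normalize_log,
                   predict_types, scenario_fixture, train_classifier)

data = scenario_fixture("scenario1_structure").generate()
model = train_classifier(normalize_log(data["reference"]),
                         data["reference_labels"], n_genes=300)
names = sorted(data["batches"])
anns = {n: predict_types(model, normalize_log(data["batches"][n]),
                         threshold=0.8) for n in names}
res = integrate_batches([data["batches"][n] for n in names], anns, n_hvg=800)
print(f"reference batch: {res.reference}; anchors: {len(res.anchors)} "
      f"across {len({a.type_label for a in res.anchors})} shared types")

labels = np.concatenate([data["truth"][n] for n in names])
before = [normalize_log(data["batches"][n]).subset_genes(res.hvg.sorted())
          for n in names]
report = compute_report(res.merged, labels, before=before)
for key, val in report.as_dict().items():
    if key == "kbet_by_fraction":
        continue
    print(f"  {key:22s} {val: .3f}")
# ARI/cLISI/ASW_celltype near their ideal values say the eight simulated
# types survived integration; the KBET rejection and iLISI reflect how well
# batches mix *within* the types they actually share — with four
# batch-exclusive types present, perfect global mixing is neither possible
# nor desirable.
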