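"""Read out ROI, edge and network importance from trained fold models.

ROI scores come from the aggregation-weighted latent projections, edge
scores from the learned edge-scaling matrices; both are rolled up to the
seven functional networks of the parcellation.
"""

import numpy as np

from neurofuse import (
    EvalConfig,
    FusionDataset,
    build_report,
    cross_validate,
    default_parcellation,
    fast_model_config,
    top_k_edges,
)
from neurofuse.synth import fast_config, gen_connectivity_cohort

cohort = gen_connectivity_cohort(fast_config(seed=0))
dataset = FusionDataset.from_cohort(cohort)
run = cross_validate(dataset, EvalConfig(model=fast_model_config(20)), [0],
                     keep_models=True)[0]

parc = default_parcellation(20)
report = build_report(run.fold_models, parc, provenance={"seed": 0})

planted = set(cohort.ground_truth["planted_rois"])
for mod in ("fmri", "eeg"):
    top10 = np.argsort(report.roi_scores[mod])[::-1][:10]
    hits = len(set(top10) & planted)
    print(f"{mod}: top-10 ROIs by importance {sorted(top10.tolist())} "
          f"({hits}/10 are planted signature ROIs)")

edges = top_k_edges(report.edge_scores["eeg"], k=5)
print("strongest 5 EEG edge scores (signed learned deviations of the scaling matrix):")
for i, j, v in sorted(edges, key=lambda t: -abs(t[2])):
    tag = "planted" if i in planted and j in planted else "other"
    print(f"  ({parc.roi_labels[i]}, {parc.roi_labels[j]}): {v:+.3f}  [{tag}]")

net = report.network_roi_scores["eeg"]
print("network-level ROI importance (mean over member ROIs):")
print("  " + ", ".join(f"{k}={v:.3f}" for k, v in net.items()))
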