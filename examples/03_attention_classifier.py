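"""Train the entropy-driven attention classifier end to end.

Runs the whole pipeline on a synthetic study with one planted driver block:
subnetwork discovery, supervised representations (fitted on the training
split only), attention training, and held-out evaluation. The attention
weights show which subnetworks the master decision relies on.
"""

import numpy as np

from subnet_attn import PipelineConfig, SyntheticConfig, make_dataset, run_on_dataset

dataset = make_dataset(SyntheticConfig(effect_size=2.0, n_samples=200, seed=1))
result = run_on_dataset(dataset, PipelineConfig(seed=1))

print(f"train/test: {len(result.train_ids)}/{len(result.test_ids)} samples")
print("held-out metrics:")
for key in ("accuracy", "mauc", "f1", "sensitivity", "specificity"):
    value = result.metrics_test.get(key)
    if value is not None:
        print(f"  {key}: {value:.4f}")

print("mean attention per subnetwork (the feature importance FI):")
for sid, fi in zip(result.ranking.subnetwork_ids, result.ranking.fi):
    drivers = set(dataset.ground_truth.driver_genes)
    overlap = len(set(result.partition.genes_of(sid)) & drivers)
    print(f"  {sid}: {100 * fi:.1f}%  ({overlap} driver genes)")
# The subnetwork holding the planted driver genes should carry the largest
# attention share — the model both classifies well and explains *why*.
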