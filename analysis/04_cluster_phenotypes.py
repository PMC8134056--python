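"""Partition all CTCs into k=5 phenotypic clusters on 12 standardized
DNA/CK morphology-intensity features, and check that the clusters are not an
artifact of high-count samples (CTC-to-centroid distances, high vs low)."""

import json

import pandas as pd

from common import OUTDIR, config
from ctcpheno.pipeline import run_stage

run_stage(config(), "cluster")
assignments = pd.read_csv(OUTDIR / "assignments.csv")
model = json.loads((OUTDIR / "cluster_model.json").read_text())
print(f"clustered {len(assignments)} CTCs into k={model['k']} clusters "
      f"(inertia {model['inertia']:.1f})")
print("cluster sizes:", assignments.cluster.value_counts().sort_index().to_dict())
comp = pd.read_csv(OUTDIR / "composition.csv")
pos = comp[comp.n_ctc > 0]
for j in range(1, 6):
    print(f"  cluster {j} present in {pos[f'present_cluster_{j}'].mean():.0%} of "
          f"CTC-positive samples")
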