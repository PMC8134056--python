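"""Generate the default synthetic mCRPC cohort (170 patients, ~331
CellSearch-like cartridges) and report its count marginals.

Writes patients/samples/events/truth tables to results/analysis/.
"""

import pandas as pd

from common import OUTDIR, config
from ctcpheno.pipeline import run_stage

manifest = run_stage(config(), "ingest")
samples = pd.read_csv(OUTDIR / "samples.csv")
events = pd.read_csv(OUTDIR / "events.csv")
truth = pd.read_csv(OUTDIR / "truth_objects.csv")

print(f"cohort: {samples.patient_id.nunique()} patients, {len(samples)} cartridges, "
      f"{len(events)} detected objects")
print(samples.timepoint.value_counts().to_string())
print("true class mix:", truth.true_class.value_counts().to_dict())
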