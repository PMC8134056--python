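"""Final cohort report: descriptive summary, manual-vs-automated count
relationship, paired pre/post-treatment count shifts, and figures."""

import json

import pandas as pd

from common import OUTDIR, config
from ctcpheno.pipeline import run_stage

run_stage(config(), "report")
summary = json.loads((OUTDIR / "cohort_summary.json").read_text())
print(f"report written to {OUTDIR / 'report.md'}")
print(f"  {summary['n_samples']} samples / {summary['n_patients']} patients; "
      f"baseline positivity {summary['ctc_positive_percent_display']}%")
shifts = pd.read_csv(OUTDIR / "paired_shifts.csv")
print(shifts.to_string(index=False))
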