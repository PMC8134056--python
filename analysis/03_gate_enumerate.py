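"""Gate every detected object into CTC / tdEV / other, enumerate per
cartridge, dichotomize at the validated prognostic cuts (>=5 CTC, >=105
tdEV per 7.5 mL) and call per-patient CTC dynamics."""

import pandas as pd

from common import OUTDIR, config
from ctcpheno.pipeline import run_stage
from ctcpheno.reporting import cohort_summary

run_stage(config(), "gate")
counts = pd.read_csv(OUTDIR / "sample_counts.csv")
s = cohort_summary(counts)
base = counts[counts.timepoint == "baseline"]
print(f"baseline CTC positivity: {s['n_ctc_positive_baseline']}/{s['n_baseline']} "
      f"({s['ctc_positive_percent_display']}%)")
print(f"median (range) CTC:  {s['ctc_median']:g} ({s['ctc_range'][0]:g}-{s['ctc_range'][1]:g})")
print(f"median (range) tdEV: {s['tdev_median']:g} ({s['tdev_range'][0]:g}-{s['tdev_range'][1]:g})"
      f"  -> {s['tdev_ctc_fold_ratio']:.0f}-fold tdEV excess")
print("unfavorable baseline groups:",
      (base.ctc_group == "unfavorable").sum(), "CTC,",
      (base.tdev_group == "unfavorable").sum(), "tdEV")
dyn = pd.read_csv(OUTDIR / "dynamics.csv")
print("CTC dynamics:", dyn.direction.value_counts().to_dict())
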