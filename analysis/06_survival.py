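"""Survival stratification: Kaplan-Meier and log-rank for the dichotomized
CTC / tdEV / SI groups, uni- and multivariable Cox models over the baseline
covariates, and Harrell C-index comparison of the CTC- vs tdEV-based models."""

import json

import pandas as pd

from common import OUTDIR, config
from ctcpheno.pipeline import run_stage

run_stage(config(), "survival")
tests = pd.read_csv(OUTDIR / "survival_tests.csv")
hr_rows = tests[tests.group == "unfavorable_vs_favorable"]
for _, r in hr_rows.iterrows():
    print(f"{r.endpoint.upper()} {r.stratifier}: HR {r.hr:.2f} "
          f"({r.hr_ci_low:.2f}-{r.hr_ci_high:.2f}), log-rank p={r.logrank_p:.2g}")
cox = pd.read_csv(OUTDIR / "cox_results.csv")
mv = cox[(cox.model == "multivariable") & (cox.endpoint == "pfs")]
print("\nPFS multivariable model:")
for _, r in mv.iterrows():
    print(f"  {r.covariate}: HR {r.hr:.3f} ({r.ci_low:.3f}-{r.ci_high:.3f}) p={r.p:.3g}")
conc = json.loads((OUTDIR / "concordance.json").read_text())
for ep in ("pfs", "os"):
    c_ctc = conc[ep]["n_ctc_model"].get("c_index")
    c_td = conc[ep]["n_tdev_model"].get("c_index")
    print(f"{ep.upper()} C-index: CTC model {c_ctc:.3f} vs tdEV model {c_td:.3f}")
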