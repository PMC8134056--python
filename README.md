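# ctcpheno

Automated enumeration and phenotypic characterization of circulating tumor
cells (CTCs) and tumor-derived extracellular vesicles (tdEVs) in
CellSearch-like immunofluorescence data, with survival prognostication —
built for researchers studying liquid-biopsy biomarkers in metastatic
castration-resistant prostate cancer (mCRPC).

A CellSearch cartridge images EpCAM-enriched objects from 7.5 mL of blood
in three fluorescence channels: DNA (DAPI), cytokeratin (CK) and CD45. From
per-object features the pipeline

1. **gates** each object: CTC (CK⁺, nucleated, CD45⁻, ≥16 µm², DNA/CK
   co-localized), tdEV (CK⁺, CD45⁻, *anucleated*, ≤16 µm²), or other;
2. **enumerates** per cartridge and dichotomizes at the validated
   prognostic cuts (≥5 CTCs, ≥105 tdEVs per 7.5 mL = unfavorable);
3. **phenotypes** all CTCs by k-means (k = 5) on 12 standardized DNA/CK
   morphology-intensity features;
4. quantifies each sample's phenotypic **diversity** by the Shannon index
   over its cluster composition, SI = −Σᵢ pᵢ ln pᵢ (nats; unfavorable at
   SI ≥ 0.68);
5. runs the **survival** analyses: Kaplan–Meier S(t) = Π(1 − dᵢ/nᵢ),
   log-rank tests, uni-/multivariable Cox proportional hazards
   (h(t|x) = h₀(t)·exp(βᵀx), Efron ties, Wald inference) and Harrell's
   C-index comparison of CTC- vs tdEV-based models.

Because no real cohort of this kind is publicly deposited, the package
includes a first-class synthetic-cohort generator
(`ctcpheno.simulate.generate_cohort`) calibrated to the published cohort's
marginals (~69% baseline CTC positivity, median 1 CTC and 16 tdEVs per
7.5 mL with extreme right skew, five phenotype clusters of unequal
prevalence, hazards increasing with chemotherapy pretreatment, PSA, CTC
burden and diversity), with full ground truth for every object and patient.
It can also render cartridges as multichannel TIFFs and reanalyze them from
pixels (segmentation + feature extraction). See `docs/methods.md` for the
models and their assumptions.

## Worked example

```python
from ctcpheno.config import AnalysisConfig
from ctcpheno.pipeline import run_pipeline

manifest = run_pipeline(AnalysisConfig(seed=1, outdir="results/run1"))
print(manifest["counts"])
```

prints (seed 1):

```
{'objects_in': 87643, 'samples': 335, 'patients': 164, 'n_ctc': 1641,
 'n_tdev': 25987, 'n_other': 60015, 'n_clusters_nonempty': 5,
 'samples_with_defined_si': 198, 'baseline_patients': 150}
```

i.e. 335 cartridges from 164 patients were simulated; gating kept 1,641
CTCs and 25,987 tdEVs out of 87,643 detected objects; all five phenotype
clusters were populated; 198 CTC-positive samples have a defined Shannon
index. The run directory then contains `sample_counts.csv`,
`cluster_model.json`, `diversity.csv`, `km_curves.csv`, `cox_results.csv`,
`table1.md`, `cohort_summary.json`, figures, and a `manifest.json` whose
checksums are identical across reruns with the same seed.

The same analysis as a readable sequence of steps lives in `analysis/`
(`01_simulate.py` … `07_report.py`; run them in order from that directory).
For example `03_gate_enumerate.py` prints

```
baseline CTC positivity: 100/150 (67%)
median (range) CTC:  1 (0-166)
median (range) tdEV: 14 (0-3174)  -> 14-fold tdEV excess
```

and `06_survival.py`

```
PFS ctc_group: HR 3.40 (2.30-5.04), log-rank p=1.1e-10
OS ctc_group: HR 5.26 (3.36-8.25), log-rank p=1.9e-15
PFS C-index: CTC model 0.687 vs tdEV model 0.656
```

— patients with ≥5 baseline CTCs progress and die substantially earlier,
and the tdEV-based model carries prognostic information comparable to the
CTC-based one, mirroring the structure of the clinical findings.

A `ctcpheno` CLI wraps the same stages
(`ctcpheno run|simulate|segment|gate|cluster|diversity|survive|report`,
each with `--config/--seed/--outdir`; config in YAML or JSON,
`ctcpheno validate-config` checks one).

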