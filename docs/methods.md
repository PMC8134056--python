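# Methods

`ctcpheno` reimplements, at desk scale, a post-hoc analysis pipeline for
CellSearch immunofluorescence data in metastatic castration-resistant
prostate cancer (mCRPC): automated detection and enumeration of circulating
tumor cells (CTCs) and tumor-derived extracellular vesicles (tdEVs) from
per-object fluorescence features, k-means phenotyping of CTCs, Shannon-index
quantification of per-sample phenotypic diversity, and survival
stratification. Because no patient-level dataset of this kind is publicly
deposited, the package ships a calibrated synthetic-cohort generator that
plays the role of the study data; every downstream stage is exercised and
tested against the generator's ground truth.

## The synthetic cohort generator

The generator (`ctcpheno.simulate`) emulates a cohort of 170 mCRPC patients
contributing ~331 cartridges (7.5 mL blood draws) across three timepoints
(baseline ~84%, 10–12-week follow-up ~67%, progression ~44% of patients),
with one row per detected fluorescent object.

**CTC counts.** Per-sample CTC counts follow a zero-inflated negative
binomial with a per-patient log-normal frailty on the mean:
`n ~ NB(mean = m · exp(σ·z + c·chemo) · τ_t, dispersion r)`, with a
structural-zero probability `π₀` for patients that shed no detectable CTCs.
Defaults (m = 1.7, r = 1.8, σ = 1.35, c = 0.9, π₀ = 0.05; timepoint
multipliers τ = 1 / 0.35 / 1.4 for baseline / follow-up / progression) were
calibrated once against the published cohort marginals — ~69% baseline CTC
positivity, an overall per-sample median of 1 CTC with a range into the
thousands, counts dropping under therapy and rebounding at progression, and
higher counts in chemotherapy-pretreated patients — and verified stable
across ten generator seeds.

**tdEV counts.** tdEVs are a CTC-linked log-normal multiplier (median
e^2.1 ≈ 8 tdEVs per CTC) plus an independent background component sharing
the patient frailty, drawn NB with dispersion 3. This reproduces the strong
CTC–tdEV correlation, the ~16-fold median excess (median ≈ 16 tdEVs per
7.5 mL) and tdEV-positive, CTC-negative samples.

**Phenotype composition.** Each patient's tumor sheds CTCs from a discrete
*support* of the five phenotype clusters: 58/20/13/6/3% of patients carry
1/2/3/4/5 clusters, cluster weights within the support are
Dirichlet(5)-distributed, and clusters enter the support with probability
proportional to the global prevalence (0.16, 0.14, 0.53, 0.12, 0.05 — cluster
3 is the common epithelial phenotype, cluster 5 rare). Two couplings shape
the biology:

* *Clonal dominance*: high-burden patients collapse to a monoclonal support
  with probability `1 − exp(−1.2·max(z,0))`. Without this, the Shannon
  index is mechanically rank-correlated with CTC count (a sample with one
  CTC always has SI = 0, and any large sample reveals a small nonzero SI),
  with an irreducible Spearman floor of ≈0.3–0.5 under any plain
  Dirichlet-multinomial model at median count 1 — we verified the floor by
  an idealized simulation in which SI is independent of count except for
  the n = 1 constraint. Burden-coupled dominance is the standard biological
  reading (aggressive disease is driven by one expanding clone) and brings
  the default-scenario Spearman correlation to ≈0.1–0.25, the "weak
  correlation" regime of the real cohort.
* *Chemotherapy pretreatment* flattens the support-selection weights
  (exponent 0.7) and adds an extra clone with probability 0.35, so
  pretreated patients show both higher counts and higher baseline
  diversity.

Under therapy the composition sharpens (`q ∝ q^2.2` at follow-up — ARSi
suppresses susceptible subclones, lowering diversity) and partially
re-flattens at progression (`q^0.85`), so the SI falls at follow-up and
rises again at resistance.

**Object features.** Every object gets the full 23-feature record (area,
perimeter, eccentricity, mean/max/total/sd intensity per DNA/CK/CD45
channel, DNA–CK overlap, centroid). CTC features are cluster-conditional
normal draws around the five phenotype archetypes (cluster 1: large oval
nuclei; cluster 2: large cells with intense CK; cluster 4: small cells with
a compact bright DAPI signal and attenuated CK; cluster 5: rare very large
cells); tdEVs are small CK-only particles with zero DNA/CD45 features;
leukocytes are DNA+/CD45+ with faint unspecific CK; debris is dim CK junk.
Clipping keeps every class inside generous margins around the default gates,
so classification against truth is exact by construction — passing gating
tests therefore demonstrate the gate logic, not robustness to borderline
objects, which real cartridges do contain.

**Survival.** Event times are exponential with log-hazard
`1.04·chemo + 0.0015·PSA + 0.45·log1p(CTC) + 0.65·SI` (baseline rates
0.055/month for progression, 0.016/month for death) and independent uniform
censoring on 6–40 months. The CTC term acts on the log count: with a raw
per-unit coefficient matched to the published continuous hazard ratio
(≈1.003/CTC), a desk-scale cohort cannot reproduce the strong dichotomized
(<5 vs ≥5) separation, because the synthetic unfavorable group's median
count is tens, not thousands; log-scale burden is the usual biomarker
assumption and yields unfavorable-group hazard ratios of ≈2–4 with
confidence intervals excluding 1, as in the source cohort.

**Determinism.** All randomness flows from one seeded `numpy` generator,
split into per-concern child streams (patients, composition, counts, tdEVs,
survival, sampling, features), so the calibrated count marginals are
invariant to composition-model changes. Identical seed + config gives
byte-identical outputs.

**What the generator does not emulate.** Realistic optics (PSF, chromatic
aberration, illumination gradients), touching/overlapping cells, borderline
gate objects, cartridge geometry, informative censoring, and missing
clinical covariates. Passing tests show the pipeline's logic is correct on
clean data of realistic shape, not that it would match a human reviewer on
real cartridges.

## Imaging

The image path renders objects as hard fluorescent discs on Gaussian noise
(CTC = co-localized DNA+CK, tdEV = small CK-only, leukocyte = DNA+CD45) and
reanalyzes them: per-channel thresholding (triangle method with an absolute
floor, configurable), 8-connected labeling, minimum object size 4 px. The
cytokeratin object anchors each event; DNA/CD45 features are measured on
the most-overlapping object of that channel's own segmentation, or reported
as zero when none overlaps — which is precisely what makes a tdEV
DNA-negative. Areas are in µm² (pixel area × count), eccentricity from
second-order central moments. Coordinates are 0-based, x right / y down.

## Gating

An event is a **CTC** iff CK mean ≥ 30, DNA total ≥ 2000, CD45 mean ≤ 40,
CK area ≥ 16 µm² (~4 µm diameter) and DNA–CK overlap ≥ 0.5; a **tdEV** iff
CK mean ≥ 30, DNA total ≤ 500, CD45 mean ≤ 40 and CK area ≤ 16 µm²;
everything else is **other**. These numeric values are documented
approximations of the previously established open-source gates for
CellSearch data (whose exact values live in that tool's supplement); all are
config-overridable, and validation rejects any configuration in which the
two DNA gates could overlap (so the partition is provably exclusive).
Counts are per cartridge = per 7.5 mL; the prognostic cuts are ≥5 CTCs and
≥105 tdEVs (boundary = unfavorable). CTC dynamics between baseline and
follow-up are increasing/stable/decreasing with "stable" = exact equality
by default (a configurable relative band is provided but off).

## Phenotyping and diversity

CTC features (12 by default: area, perimeter, eccentricity, mean/max/sd
intensity for DNA and CK; CD45 excluded since CTCs are CD45-negative by
gate) are z-scored with the population-sd convention (zero-variance
features dropped with a warning), then partitioned by Lloyd k-means with
k = 5, 10 restarts, best inertia, deterministic given the seed
(scikit-learn backend; the fitted model must satisfy the fixed point
"centroid = mean of assigned points" to 1e-6, which the tests assert).
Assignment is explicit nearest-centroid with lowest-index tie-breaking. All
CTCs from all timepoints are clustered jointly and assigned everywhere; a
silhouette-based k-selection helper exists but the default pipeline fixes
k = 5. A Mann–Whitney U test on CTC-to-centroid distances between high- and
low-count samples (median split by default) checks that clusters are not
driven by the high-count samples.

The Shannon index SI = −Σ pᵢ ln pᵢ is computed in nats over each sample's
cluster composition (0·ln 0 := 0; base configurable and recorded). SI is
defined only for CTC-positive samples: a zero-CTC sample carries SI = NaN
and group "undefined" and is excluded from SI-stratified survival. The
prognostic cut is SI ≥ 0.68 = unfavorable; note ln 2 ≈ 0.693, so a sample
needs a near-balanced 2-cluster mix, or ≥3 clusters, to be unfavorable —
under the default scenario roughly 5–15% of CTC-positive samples are.
Therapy-driven SI shifts are paired Wilcoxon signed-rank tests per
transition (p = 1 when all differences vanish; zero differences dropped).

## Survival analysis

Kaplan–Meier estimation and the log-rank test are delegated to lifelines,
Cox proportional-hazards to statsmodels `PHReg` (Efron ties by default,
Breslow available), Harrell's C to scikit-survival; the test suite checks
each against independent brute-force oracles (hand product-limit, manual
risk-set accumulation, 1e-4 grid search of the explicit partial likelihood,
exhaustive pair enumeration). Conventions: months; events precede
censorings at tied times; KM median = smallest t with S(t) ≤ 0.5 (within
1e-9, guarding the exact-0.5 boundary against float rounding) else the
literal string "not reached"; 95% CI multiplier 1.959964; two-sided normal
Wald p-values. Monotone-likelihood / separated fits are flagged
(`converged = False`, triggered by |β| ≥ 50 or SE ≥ 1000) rather than
silently reported. Covariates with univariable Wald p < 0.05 enter the
multivariable model; the candidate list is age, chemotherapy status, prior
ARSi, metastasis type, PSA, LDH, baseline CTC count and baseline SI, with
counts entering untransformed (configurable). Model comparison uses
Harrell's C of the fitted linear predictor, for a CTC-based and a
tdEV-based model in parallel.

## Reporting and pipeline

Percentages are displayed rounded half away from zero (98/143 → 69%), raw
fractions retained. The manual-vs-automated count relationship is
least-squares slope/intercept plus Spearman correlation, with residual sd
in the lower vs upper half of the count range summarizing the increasing
spread at high counts. The SI-vs-count correlation is reported as Spearman
(the test type behind the published weak correlation is unstated).

The pipeline derives one seed per stage from the run seed via SHA-256
(`"<seed>:<stage>"`, truncated below 2³¹), writes CSV with `%.17g` floats
(lossless round-trip, so feature-table mode reproduces simulate mode
bit-for-bit) and a manifest with the config hash and SHA-256 checksums of
every output. Figures are SVG with a fixed hash salt and no timestamp
metadata, so full runs are byte-reproducible.

## Problem sizes

Default end-to-end runs use the full 170-patient scenario (~330 cartridges,
~80k objects, ~1.5–2.5k CTCs) and complete in well under a minute.
Replicate-based checks (power of the log-rank and paired-shift tests, SI
trajectory direction, null behavior of the centroid-distance test, Cox
coverage) use 100 seeded replicates of reduced cohorts (40–50 patients,
background objects off, n = 200–1000 for two-arm survival), sizes chosen so
each property is measured with adequate Monte-Carlo resolution.

## Known limitations

* Gate values and the 12-feature set are documented approximations; the
  reference tool's exact gates and feature list are not reproduced.
* The generator's class margins make gating trivially exact; there is no
  model of borderline or ambiguous objects.
* No declumping of touching cells, no illumination correction, no
  proportionality diagnostics (Schoenfeld), no time-varying covariates or
  competing risks.
* Published patient-level effect sizes (hazard ratios, median survival,
  C-indices) are not reproduction targets — the underlying clinical data
  are not deposited; the pipeline reproduces the *structure* of those
  results on synthetic data with known truth.
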