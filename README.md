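# diastab

Stable biomarker discovery for multi-site DIA-MS tumor proteomics.

High-grade serous ovarian cancer (HGSC) shows strong anatomical
site-to-site and intra-tumoral variation in protein expression, which
confounds the search for tissue-based predictive biomarkers.  When a
patient's tumor is sampled many times at two sites (ovary/adnexa and
omentum), a useful biomarker candidate must be *stable within* a patient
and *variable between* patients.  `diastab` implements the full analysis
chain for this design, validated end-to-end on a synthetic cohort whose
ground truth is known:

* **Peptide QC and protein quantification** — removal of low-coverage
  runs (< 5000 quantified peptides) and discordant technical replicates
  (peptide-level Pearson r < 0.8), log2 median normalization, and
  MaxLFQ-style summarization: for each run pair the protein log-ratio is
  the median of shared peptide log2 differences, and the per-run protein
  profile is the least-squares solution of the pairwise ratio system.
* **Stable discriminative protein filter** — a six-step cascade:
  exclude samples with < 20 % tumor content; require detection in both
  fresh-frozen (FF) and FFPE matrices; require a coefficient of variation
  CV = σ/μ < 25 % within every assessable patient; drop proteins
  quantified in < 20 % of samples, in the lowest intensity quartile, or
  in 100 % of samples (uniform housekeeping detection).
* **Single-sample GSEA** — the classic rank-based running-sum statistic
  (member steps weighted by rank^τ, τ = 0.25), range-normalized across
  samples (NES).  Bundled signatures: a 20-protein stromal score and the
  dsDNA-sensing/inflammation (**DSI**) score covering interferon-response,
  cGAS-STING and antigen-presentation proteins.
* **Co-expression modules** — unsigned WGCNA-style detection: soft
  threshold adjacency |cor|^β (β = 7), topological overlap matrix,
  average-linkage clustering with minimum module size 30.
* **HR-deficiency genomics** — TAI, HRD-LOH and LST genomic scar counts
  from allele-specific copy-number segments, the HRD-mean score
  (arithmetic mean of the three), and a univariate logistic classifier of
  HR status with stratified fourfold cross-validation.
* **Differential abundance** — empirical-Bayes moderated t-tests
  (variance shrinkage s̃² = (d₀s₀² + ds²)/(d₀+d), cross-checked against
  limma), Benjamini–Hochberg correction, and the conventional p < 0.05 &
  fold-change > 2 selection.
* **Synthetic cohort generator** — a log2-additive model of ~11 patients
  × 2 sites × many small samples with planted stable proteins, a
  co-expressed DSI module elevated in omentum and in HR-deficient
  patients, a stromal signature, intensity-dependent missingness, and
  allele-specific segment profiles with exactly recoverable planted scar
  events.

## Worked example

The numbered scripts under `analysis/` run the whole study on the
synthetic cohort, writing tables under `results/`:

```sh
python analysis/01_simulate_cohort.py
python analysis/02_quant_qc.py
python analysis/03_stable_filter.py
python analysis/04_coexpression_modules.py
python analysis/05_enrichment_site_effects.py
python analysis/06_hrd_classification.py
python analysis/07_differential_abundance.py
```

which prints, step by step:

```
cohort: 300 proteins, 132 FF samples, 66 FFPE samples, 4/11 HR-deficient patients
QC: 300 proteins x 132 samples (0 runs removed)
cascade survivors: 300 -> 269 -> 191 -> 186 -> 140 -> 72
72 stable discriminative proteins (sensitivity 0.96, FDP 0.000)
1 modules of sizes [51]; largest module captures 39/40 planted DSI members
DSI score higher in omentum in 11/11 patients (t test, p <= 0.05)
STROMAL score higher in omentum in 10/11 patients (t test, p <= 0.05)
HRD-mean 4.7 (deficient) vs 2.0 (intact); fourfold CV AUC 0.871, error 0.133
13 of 72 tested proteins dysregulated (p < 0.05, fold > 2); 8 are planted DSI members
```

Reading this: the cascade recovered 96 % of the planted stable proteins
with no false discoveries; module detection found one module that is
essentially the planted DSI module; the DSI and stromal scores were
significantly higher in omentum in almost every patient (so ovary and
omentum samples are not interchangeable for biomarker evaluation); the
scar-based HRD-mean score separates HR-deficient from HR-intact tumors
with cross-validated AUC 0.87; and the HR-status contrast recovers
mostly DSI members — inflammation tracking HR-deficiency.

The same chain is available as one command (`diastab pipeline demo`) or
from a YAML configuration (`diastab pipeline run --config my.yaml`);
individual stages are exposed as `diastab simulate | qc | filter-stable
| score | compare-sites | modules | hrd | diff`.

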