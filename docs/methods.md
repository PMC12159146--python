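# Methods

This note records the models, conventions and numerical choices behind
`diastab`, and what the synthetic validation does and does not show.

## Synthetic cohort model

Protein abundance is log2-additive:

    value(p, s) = μ_p + patient(p, pat(s)) + module effects(p, s) + ε,
    ε ~ N(0, σ_intra,p)

with per-protein baselines μ_p, independent patient effects
(σ_inter = 1.0 log2 units by default, the scale at which inter-individual
differences dominate a tumor proteome), and intra-patient noise
σ_intra = 0.3 log2 units, chosen as a realistic sampling-repeatability
scale for biopsy-sized DIA-MS samples.  Five protein classes give the
stability cascade something real to discriminate:

* **stable discriminative** (default 10 %) — low intra-patient noise,
  full-strength patient effects, present in FFPE, and structurally
  unexpressed in 1–3 random patients each (detection across the cohort is
  non-uniform, as required of a discriminative marker).  The first
  `dsi_module_size` of these form the DSI module.
* **stromal** — the bundled 20-protein signature, co-expressed through a
  per-sample stromal latent factor shifted by `stromal_omentum_shift`
  (default 1.0 log2) in omentum.
* **housekeeping** — uniformly detected, low variance; removed by the
  cascade's uniform-detection step.
* **FFPE-absent** — otherwise well-behaved proteins missing from the
  FFPE matrix (removed at step 2).
* **noisy** — low-abundance proteins whose log2 SD is ≈ 0.3–0.45 of
  their mean, so their per-patient CV exceeds the 25 % threshold; they
  also carry most of the missingness.

The DSI module is co-expressed at two levels: a per-sample latent factor
(carrying the omentum shift, default 1.0 log2, and the HR-deficiency
shift, default 0.75 log2 — the direction is established, the magnitude a
design choice) and a module-wide patient factor carrying 60 % of the
members' inter-patient variance (`dsi_patient_cor`).  The second level is
what makes the module detectable by correlation networks: co-expression
modules in multi-patient cohorts are driven by inter-individual
co-variation, not by within-patient noise.

Missingness is missing-not-at-random: a logistic function of abundance
(slope 3 per log2 unit) whose midpoint is calibrated by bisection so the
mean missing probability equals `missing_rate` (default 0.15).  Peptide
tables are derived from the FF matrix with peptide offsets ~ N(0, 1.5),
two technical replicate runs per sample and replicate noise SD 0.1.
FFPE matrices reuse the same model with 0.3 log2 units of extra noise
and a protein subset mask; the generator treats FFPE as FF signal plus
independent preservation noise because the within-format covariance of
the two preservation formats is not separately identified here.

What the generator does **not** emulate: batch effects and run-order
drift, correlated (block) missingness, peptide-level interference,
non-Gaussian heavy tails, and any genomic linkage between the proteome
and the scar profiles (HR status is the only shared latent).  Passing
tests therefore demonstrate correctness of the analysis logic under the
stated model, not robustness to every artifact of real data.

## Quantification and QC

Pipeline order is fixed: run filter → replicate filter → log2/median
normalization → drop negative normalized peptides → MaxLFQ → replicate
averaging.  Decisions:

* Replicate discordance (r < 0.8 on shared peptides, log2 scale) removes
  the member with fewer quantified peptides; ties drop the higher
  replicate index.  The correlation scale (peptide-level log2) is
  configurable since conventions differ.
* Median normalization targets the global median of run medians — any
  common constant works; this one is scale-stable and idempotent.
* MaxLFQ: pairwise ratios are medians of shared peptide differences;
  pairs without `min_shared` peptides contribute no equation.  The
  least-squares system fixes only differences, so each connected
  component is anchored so its mean equals the mean of its runs' median
  peptide values.  The solution is computed from the anchored normal
  equations (graph Laplacian plus a rank-one mean constraint), which is
  exact and O(runs³).  The original delayed-normalization joint
  optimization is intentionally not reproduced.

## Stability cascade

CV = σ/μ with the sample SD (n−1).  CV is computed on the stored log2
abundances (the matrix the cascade receives is log-scale); a linear-scale
option exists because CV on logs is unconventional.  The "CV < 25 % in
all samples from a patient" rule is read as: required in every patient
with ≥ 3 quantified samples; patients where the protein is not assessable
do not veto (a protein assessable nowhere passes this step and is left to
the detection-fraction steps).  The permissive any-patient reading is
available behind a flag.  Step 5 uses the nearest-rank 25th percentile of
mean abundance over quantified samples; values tied with the percentile
survive.  Steps 4 and 6 use the post-step-1 FF samples as denominator.

## ssGSEA

Per sample, genes are ranked by decreasing abundance (average ranks on
ties; the most abundant of N genes has rank N).  ES is the full running
sum Σ_i [weighted in-set ECDF − uniform out-of-set ECDF], with member
steps weighted rank^τ, τ = 0.25 (the classic single-sample weighting).
NES divides ES by the ES range across the scored matrix's samples, so one
matrix's scores are comparable; the scoring universe is whatever matrix
is supplied and is recorded in the output.  Missing abundances rank last
by default (DIA missingness is abundance-dependent); a drop-and-renormalize
option exists.  The bundled DSI set is explicitly partial (21 of the 52
module members are public); printed symbols are kept verbatim with an
alias map (PSM8→PSMB8, PSM9→PSMB9) that is never applied silently.

## Co-expression modules

Unsigned adjacency |cor|^β with β = 7 and pairwise-complete correlations
(pairs with < 3 shared observations get adjacency 0, flagged).  TOM is
the standard unsigned topological overlap.  Module detection clusters
1 − TOM by average linkage and cuts statically at 0.99 of the maximum
merge height; clusters below 30 members are unassigned (label 0) and
modules are numbered by decreasing size.  The static cut replaces the
dynamic hybrid tree cut of full WGCNA — a deliberate fidelity gap: the
downstream use is only module membership, and the planted-block recovery
tests bound what the simplification costs.  The soft-threshold scan
reports the smallest power whose scale-free fit R² (signed by slope)
reaches 0.8, else the argmax.

## Genomic scars and HR classification

Coordinates are 0-based half-open base pairs.  Conventions, declared and
tested: copy-neutral LOH (copyA ≥ 1, copyB = 0) counts as LOH and as
allelic imbalance; homozygous deletion (0,0) counts as neither; TAI has
no minimum size by default (configurable); HRD-LOH requires ≥ 15 Mb and
excludes whole chromosomes; LST smooths segments < 3 Mb (merging equal
states before and after, spanning the gaps), then counts arm-internal
breakpoints with both flanks ≥ 10 Mb.  Chromosome-end tests use segment
coordinates; no ploidy renormalization is applied before counting.  All
counters are invariant to subdividing segments into same-state pieces.

The scar-profile generator places events on disjoint chromosome arms of a
reduced synthetic genome (five chromosomes, 80–200 Mb): telomeric AI
blocks of 3–8 Mb (too short to create an LST), interstitial LOH runs of
15–25 Mb with ≥ 10 Mb balanced flanks, and balanced (2,2) blocks of
12–18 Mb.  An interstitial LOH necessarily induces two large-scale
transitions, so the recorded LST truth is 2·(LST blocks) + 2·(LOH
events); this accounting keeps the generator/counter round trip exact
without sharing code with the counters.  Whole-chromosome LOH appears as
a distractor that correctly scores zero everywhere.

The classifier is a univariate logistic model on HRD-mean fitted by IRLS
with a small ridge penalty (default 1e-4) guarding against complete
separation; standard errors come from the unpenalized Fisher information
and AUC is the rank statistic.  Cross-validation is stratified fourfold
with out-of-fold probabilities pooled for the CV AUC and a 0.5
probability threshold for the error rate (the threshold is a convention;
nothing downstream depends on it).

## Differential abundance

Two modes: Welch t (`prior="none"`) and the empirical-Bayes moderated
pooled t, with (d₀, s₀²) estimated by the method of moments on log
residual variances (scaled-F marginal; trigamma inversion by Newton).
When the observed spread of log variances does not exceed chi-square
sampling noise, d₀ = ∞ and s₀² is the mean variance.  Total df is capped
at the summed residual df.  The d₀ = 0 limit reproduces the pooled t
exactly and the implementation is cross-checked against limma's eBayes
in the test suite.  Fold change is the difference of group-mean log2
values; "fold-change > 2" means |log2FC| > 1.  Proteins with < 2
observations in a group are skipped, not imputed.  All tests are
two-sided.

## Pipeline and problem sizes

The pipeline configuration is a flat YAML document; unknown keys are
errors (typo guard).  All randomness derives from one seed via
`SeedSequence([seed, stage_index])`, so reruns are byte-identical.  The
bundled demo and the validation suite use reduced problem sizes — a
300–1000-protein proteome, 4–10 samples per tissue, a five-chromosome
genome — chosen so the planted effects are estimated with comfortable
Monte-Carlo margins while the full chain stays interactive; all
thresholds and statistical conventions are identical at any scale.

## Known limitations

* The stable-filter cascade's step thresholds interact with the cohort's
  missingness pattern; on data without structural absence the
  uniform-detection step (6) can dominate.
* The static-cut module detector can absorb a few correlated background
  proteins into a planted module and will not resolve nested modules the
  way dynamic tree cutting can.
* The ssGSEA NES range normalization makes scores comparable only within
  one scored matrix.
* The HRD classifier is univariate by design; no multivariate or
  ploidy-adjusted variant is provided.
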