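# Methods

This note documents the models, parameter choices and numerical
conventions behind `ionopls`, and what the synthetic validation does and
does not demonstrate about real data.

## The generative model behind the synthetic data

The generator emulates a two-carbon-source bacterial metal-exposure study.
All structure lives on the natural-log scale; intensities are
exponentiated at the end.

For metabolite *m* in sample *s* (carbon source *c*, treatment *g*, sample
type *v*):

    log A_ms = b_m + C_mc + V_mv + delta_mg + e_ms,    e_ms ~ N(0, sigma_bio^2)

* `b_m ~ N(11.5, 1.5^2)` — base log abundance in arbitrary detector units.
* `C_mc ~ N(0, 1.0^2)` and `V_mv ~ N(0, 0.7^2)` — fixed metabolite-specific
  fingerprints of carbon source and of cells vs spent media. Setting the
  carbon fingerprint larger than the sample-type fingerprint reproduces the
  ordering real profiles show: samples separate first by carbon source,
  then by sample type, in PCA and hierarchical clustering.
* `delta_mg = ±(effect size) * sigma_bio` for the metabolites affected in
  that condition pair; 0 otherwise. Default effect size 2 (in units of the
  replicate SD), 20 affected metabolites per (carbon, metal, sample-type)
  pair, 75% of them drawn from the identified pool — pathway-organized
  perturbations concentrate on canonical, library-identifiable metabolites,
  and this makes the spiked pathway a realistic 15 members.
* `sigma_bio = 0.4` — replicate-to-replicate biological variation (~50%
  CV), typical of bacterial batch cultures.

Quantifier ion *i* of analyte *a(m)* reads this latent abundance through a
fixed response factor `r_i ~ logU(0.2, 1)` with multiplicative measurement
noise `N(0, 0.15^2)`; derivative analytes (2TMS/3TMS forms of the first 20
identified metabolites) add a fixed yield offset `N(0, 0.3^2)` and are
merged back by the pipeline. Whole samples are multiplied by a dilution
factor `logU(0.5, 2)` — the quantity PQN must recover. Blanks carry only a
baseline `exp(N(ln 50, 0.3^2))` plus the eight artifact analytes, which
appear at sample-like levels everywhere.

**Corrupted ions** simulate a co-eluting contaminant mistakenly selected
as a quantifier ion: 40 ions (one per chosen multi-ion analyte, always the
weakest-responding fragment, response scaled by 0.2) whose static
magnitude matches the analyte's base abundance but whose variation
`N(0, 0.6^2)` is independent of the latent profile. The magnitude matching
matters: a contaminant ion is mis-selected precisely because its intensity
is comparable, and an ion that *dominated* its analyte's ion sum would
correlate with the sum through itself — a blind spot of any sum-correlation
filter. Under these defaults every corrupted ion's population correlation
with its ion sum stays below 0.8 while true ions sit near 1, so the filter
has a fact of the matter to recover.

What the generator does **not** emulate: chromatographic peak shape,
retention drift, integration error beyond multiplicative noise, missing
peaks, censoring at detector saturation, or correlations between
metabolites beyond the shared sample-level factors. Passing tests
therefore demonstrate correctness of the inference chain under the stated
measurement model, not robustness to every pathology of real GC-MS data.

## Ion-level QC

Artifact removal drops any analyte whose intensity in *any* blank exceeds
the blank noise floor (default 1e3 detector units, ~5 SD above the
simulated baseline); an explicit blacklist is also accepted, since real
studies often curate artifact lists manually. The ion validity filter
computes Pearson correlations on raw (not log) intensities across
non-blank samples, against the sum of all the analyte's quantified ions
*including the ion itself* — so single-ion analytes pass trivially, which
is the intended behavior (they carry no internal consistency check).
Zero-variance ions fail the filter rather than pass vacuously. Analytes
whose ions all fail are excluded entirely. Kovats retention indices are
linear interpolations on the C10-C30 alkane ladder,
`RI = 100(n + (rt − rt_n)/(rt_{n+1} − rt_n))`; no extrapolation outside
the ladder.

## Preprocessing

* **Noise threshold**: per-metabolite mean over blanks (a single global
  mean is available by configuration); study values strictly below the
  floor are zeroed, ties retained. Applied post-merge.
* **PQN**: reference = per-metabolite median over the control samples of
  the sample's own (carbon source, sample type) stratum, so treatment
  effects never leak into the reference and cells are never normalized
  against media. `control` (pooled) and `median` (all-sample) rules are
  available. Quotients are taken only over metabolites positive in both
  sample and reference; a sample sharing none is an error naming the
  sample. Note the factors are identified only up to the reference's own
  scale: recovery of simulated dilutions is therefore assessed after
  removing each stratum's median ratio (the scale-free median relative
  error is ~3% at study defaults).
* **Log and autoscale**: natural log after adding half the smallest
  nonzero value of the matrix (recorded in provenance); columns
  mean-centered and scaled to unit sample variance (ddof 1). Constant
  columns are dropped with a warning, or kept as all-zero columns when
  several models must share one metabolite universe (the pipeline's
  per-pair models use this so SUS comparisons never face mismatched sets).
* **Outlier trimming**: per experimental class, a 2-component PCA on that
  class alone; samples whose Hotelling T² over the scores exceeds the
  in-model Beta limit `(n−1)²/n · Beta_{1−alpha}(A/2, (n−A−1)/2)` at
  alpha = 0.05 are removed from all downstream analyses. The Beta form is
  used (rather than the out-of-sample F form) because the samples being
  judged were part of the fit; under a homogeneous Gaussian class the flag
  rate is then ~alpha, which the tests verify. Classes smaller than 3 are
  skipped with a warning.

## Multivariate models

PCA is SVD-based on the column-centered matrix; R²X_a = sigma_a²/sum
sigma². Hierarchical clustering is average-linkage on Euclidean distances
(scipy's implementation, deterministic ordering). OPLS-DA follows the
single-response orthogonal-projections scheme (README, "The statistics at
the core"); the predictive weight w is invariant under orthogonal
deflation because t_o'y = 0 by construction, and the model is sign-fixed
so q ≥ 0 — the predictive score points toward the class coded +1 (the
treated class), making p(corr) signs reproducible and interpretable.

Cross-validation is sevenfold with deterministic stratified round-robin
fold assignment (samples taken in order within each class); determinism
was preferred over random folds for testability, and both orthogonal and
predictive components are refit inside every training split. With 5+5
samples and 7 folds, folds 5 and 6 are empty and simply skipped; a fold
whose *training* split lacks a class is an error. Q² uses SS of y around
its overall mean. CV-ANOVA uses model df = C (predictive + orthogonal
components) and residual df = n − C − 1; under permuted labels its
rejection rate at alpha = 0.05 sits inside the exact binomial 95% band in
our null simulations (200 draws at n = 10 + 10, 30 variables). A model
predicting worse than the mean gives F ≤ 0 and p = 1.

VIP is computed over the predictive component only (VIP-pred), matching
the interpretation of VIP as discriminatory importance in a 1 + k model;
with one predictive component the SSY weights cancel and
VIP_j = sqrt(J)|w_j|, so mean VIP² = 1 exactly. A consequence worth
stating plainly: VIP is a *relative* measure. When few variables carry
signal, the remaining null variables must average VIP² ≈ 1 and a
substantial fraction of them necessarily exceeds 0.8 — at 10 samples and
269 metabolites with 20 truly affected, VIP ≥ 0.8 selection is essentially
perfectly sensitive but only ~60% specific, with a ceiling near 65% at any
effect size (the acceptance script recomputes these figures). Hit lists
should therefore be read as enriched, not pure, which is exactly why they
are passed onward to pathway-level testing.

## SUS and enrichment

SUS inclusion uses VIP ≥ 0.8 (the dashed-line convention of the plots);
hit selection for enrichment uses strict VIP > 0.8; both thresholds are
configurable. A p(corr) of exactly 0 counts as "up" (fixed tie-break).
The enrichment background is the set of identified (pathway-mappable)
metabolites quantified in the experiment — explicit and configurable,
since using a full compound universe instead would anti-conservatively
inflate enrichment. The test is one-sided (over-representation only);
pathway exclusion lists (for chronically over-interpreted pathways) are
applied before testing so they do not burn FDR budget. P-values are exact
hypergeometric upper tails; BH adjustment across tested pathways; results
sorted by p with ties broken by pathway id.

## Pipeline conventions

Stage order: artifact removal → ion filter → derivative merge → noise
threshold → PQN → log → global autoscale → per-class trimming → global
PCA + clustering → per-pair autoscale and OPLS-DA (control vs one metal,
within carbon source and sample type; eight models) → VIP/p(corr) → SUS
(biphenyl model on x, succinate on y, per metal and sample type) →
enrichment (cells models). Each pairwise model re-autoscales within its
own ten samples, as chemometrics software does. Every output file carries
the configuration hash (output directory excluded) and seed; equal
configurations rerun byte-identically. Stage failures abort with the
stage named.

## Problem sizes in the tests

The validation suite uses the full study design (65 samples x ~835 ions)
with 50 seeds for recovery rates, 100 seeds for effect-size calibration,
and 200 permutations for the CV-ANOVA null; these sizes give Monte-Carlo
error comfortably below the asserted margins while keeping the whole
suite in the low minutes.

## Known limitations

* Multi-class OPLS-DA, O2PLS and S-plots are out of scope; so are raw
  vendor formats, spectral deconvolution and library matching.
* CV-ANOVA's F reference is approximate; its calibration is verified here
  only under the simulated null.
* The real study's outlier criterion, artifact list and pathway-exclusion
  list were manual; the package exposes rule-based equivalents plus
  explicit list inputs rather than claiming to reproduce those curations.
* Printed model statistics from the original instrument data (R²/Q² per
  condition, specific enrichment p-values) depend on undeposited raw data
  and are not reproduction targets; the validation claims are the
  property-based ones listed above.
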