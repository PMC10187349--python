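# Methods

This note documents the models, estimators and numerical conventions
`tgfbsig` implements, the choices made where the design was open, and what
the synthetic-data generators do and do not emulate.

## Differential expression

### Linear contrasts with empirical-Bayes moderation

Per gene, expression (log2 scale) is regressed on a cell-means design
(one indicator per condition) by ordinary least squares; the effect of
interest is a contrast c'β̂, for the co-culture derivation
c = (+1, −0.2, −0.2, −0.2, −0.2, −0.2) over (co-culture+TGF-β and the five
negative conditions). Contrasts with weights summing to zero are pure
comparisons; the reported log2FC is c'β̂ and the unmoderated t uses the
per-gene residual variance s²_g on d_g = n − rank(X) df.

Moderation follows the classical moment-matching scheme: with
z_g = log s²_g and e_g = z_g − ψ(d_g/2) + log(d_g/2), the prior degrees of
freedom solve ψ′(d₀/2) = Var(e) − mean ψ′(d_g/2) by a Newton inversion of
the trigamma function, and s₀² = exp(mean(e) + ψ(d₀/2) − log(d₀/2)).
When the observed spread of log-variances does not exceed its sampling
component, d₀ = +∞ and every posterior variance equals s₀² (this is the
normal branch for generators that draw homoscedastic noise, not an error).
Posterior variances are the df-weighted blend s̃²_g, the moderated t is
log2FC / (s̃_g √(c'(X'X)⁻¹c)), and P values use d₀ + d_g df. The
implementation is cross-checked against Bioconductor limma on a small
matrix in the test suite (agreement to ~1e-6 relative).

### Benjamini-Hochberg

Adjusted P values are the step-up BH procedure (delegated to
`scipy.stats.false_discovery_control`); tests verify exact agreement with
the definitional brute force q_i = min over eligible cutoffs of
p·m/#{p_k ≤ p}.

### Patient-blocked mixed models

Cohorts with repeated biopsies per patient are analyzed per gene with a
random-intercept model y = β₀ + β₁·outcome + u_patient + ε, u ~ N(0, σ²_u),
ε ~ N(0, σ²_e), fit by REML through `statsmodels MixedLM`. Design choices:

- **Boundary handling.** A fit whose patient variance collapses to the
  zero boundary (σ̂²_u ≤ 1e-8), fails to converge, or a cohort where every
  patient contributed a single biopsy, falls back to OLS on all samples
  (σ̂²_u = 0). With one biopsy per patient the two estimators coincide
  exactly.
- **Inference.** Wald t = β̂₁/se(β̂₁) referred to a t distribution with
  n_patients − 2 df. The outcome is a patient-level covariate, so the
  information about β₁ is between-patient; in the balanced case this
  reference is the exact sampling distribution (the fit then equals the
  patient-mean two-group comparison, which the tests assert), and it keeps
  null P values uniform at small cohort sizes where a normal reference
  would be anticonservative. A likelihood-ratio alternative was not
  implemented; Wald needs a single fit per gene.
- A hand-rolled profiled-REML optimizer was considered and rejected: the
  library optimizer is well exercised, and the boundary/fallback contract
  plus the balanced-case closed form pin down the behavior the package
  promises.

The outcome must be constant within a patient; per-sample labels are
accepted but validated against this.

## Signature derivation and scoring

### Candidate ranking

Genes with BH-adjusted P < 0.1 in the co-culture contrast are ordered by
descending log2 fold-change; ties (exactly equal fold-changes) break by
lexicographic gene ID so runs are deterministic. An empty candidate list
is legal output, not an error.

### ssGSEA

Per sample, genes are ranked by expression with average ranks for ties
(largest value → rank N) and walked in descending rank order, rank ties
again broken by gene ID. The score is

ES = Σ_i [P^w_G(i) − P_NG(i)],  P^w_G(i) = Σ_{g∈G, pos≤i} r_g^τ / Σ_{g∈G} r_g^τ,

with τ = 0.25 by default. The weights are the rank magnitudes r_g^τ — the
GSVA realization of ssGSEA — rather than rank-normalized statistics; the
README flags this divergence risk versus the original ssGSEA publication.
Because the statistic is rank-based it is invariant under any strictly
monotone per-sample transform, |ES| ≤ N − 1, and at τ = 0 swapping the set
with its complement negates the score (all property-tested; a naive
double-loop oracle pins the numerics to 1e-9).

Cohort normalization (division of all scores by max − min over samples) is
on by default, matching the convention of GSVA-based analyses; ROC/AUC
computations are unaffected since the rescaling is a positive affine map.
Single-sample mode disables it and warns that scores are then comparable
only within a run. Missing signature genes are an error by default —
scoring a platform that lacks signature genes is a decision the caller
must make explicitly (`allow_missing` drops them with a warning) — because
silent dropping changes what the signature measures.

### Size selection and locking

For N from 3 up to n_max = min(30, #candidates), the top-N genes are
scored on the discovery cohort and the AUC against outcome is recorded.
The locked size is the smallest N that is a local maximum of the trace
(AUC(N) ≥ both defined neighbors); an exact tie with the right neighbor
resolves to the smaller N (parsimony). A trace still rising at n_max
returns n_max with a warning. The returned signature is a frozen object
(tuple of genes); mutation attempts raise. The full AUC trace and
thresholds travel in the signature's provenance.

In-sample selection is optimistic: on null cohorts (no planted effect)
the selected signature's discovery AUC has a median around 0.5–0.6 over
seeds, which the test suite documents as a property rather than hiding.

## Allele-dosage genomics

Per gene, altered alleles = min(2, copies_lost + oncogenic_mutation_count):
a gene has two alleles, and a mutation on an already-deleted locus cannot
disable a third. Two mutations with no copy loss count as two altered
alleles (compound heterozygosity assumed; phasing is out of scope). The
per-sample count A sums PTEN and TP53 contributions; A ≥ threshold
(default 3) is the high-risk call, and the threshold is a parameter so
sensitivity analyses over 1–4 are scriptable. Only mutations flagged
oncogenic/likely-oncogenic upstream are counted; the flag is the caller's
responsibility and the IO layer filters on it.

Cohort classification is per patient on one designated biopsy: highest
Gleason grade group, then greatest percent of tumor at the highest-grade
pattern, then lexicographically smallest biopsy ID (the residual tie-break
is an artifact convention, chosen for determinism). Specificity is
TN/(TN+FP) among non-recurrent patients.

## Outcome statistics

- **ROC/AUC**: AUC is computed by the Mann-Whitney rank identity (ties
  worth one half), which equals the trapezoid area under the ROC polyline
  (asserted in tests); curve points come from scikit-learn without
  intermediate dropping.
- **Mann-Whitney U**: exact enumeration (scipy's exact method) when the
  pooled sample is ≤ 12 and tie-free, otherwise the normal approximation
  with tie correction. A permutation oracle bounds the asymptotic error in
  tests.
- **Spearman with volumes**: ρ on ranks of x versus ranks of
  log10(volume + pseudocount). The pseudocount (default 0.1 cm³; the value
  is a plotting convention, not a statistical one) cannot change ranks,
  hence not ρ — asserted as a test.
- **Phoenix BCR calling**: the nadir is the running minimum of the PSA
  series; BCR is called at the first time PSA ≥ nadir + 2.0 ng/mL,
  inclusive. Using the running rather than global minimum means later
  declines cannot retroactively un-call a recurrence, matching sequential
  clinical assessment; appending values after the first qualifying rise
  never changes the call.

## Synthetic data: what it emulates, what it does not

All generators expand one seed into independent per-stream child seeds
(`numpy` SeedSequence spawning) so adding a stream never perturbs earlier
draws; identical (config, seed) give byte-identical outputs.

- **Co-culture** (defaults: 200 genes, 3 replicates × 6 conditions,
  6 planted genes at +2 log2 units in the stimulated co-culture only,
  baselines N(8, 2), noise sd 0.5 on the log2 scale). Baselines emulate
  RMA-normalized microarray intensities. The replicate count per condition
  is not documented for the source experiment; 3 is the configurable
  default.
- **Cohort** (defaults: 29 patients, 1–4 biopsies each, BCR fraction 0.17
  → 5 recurrent patients, ~60–90 biopsies; planted signature effect
  1.0 log2 units in BCR samples; σ_u = σ_e = 0.5). The gene universe
  defaults to 500 genes — a desk-scale stand-in for a genome-wide array
  chosen once for runtime; rank-based scores are only weakly sensitive to
  universe size. Outcome is assigned at the patient level and shared by
  all of a patient's biopsies. Lesion volumes are lognormal with a higher
  median for BCR patients (meanlog 1.8 vs 0.7, sdlog 0.8 → medians ≈ 6 vs
  2 cm³, matching a cohort whose overall median tumor burden is ~2.5 cm³);
  post-treatment volumes shrink by a Beta(1.5, 5) factor. Grade groups are
  drawn from an intermediate/high-risk mix.
- **Allele calls**: copies lost ~ categorical over {0,1,2} and mutations
  ~ Binomial(2, p), keyed by outcome. Defaults make A ≥ 3 rare in NED and
  common in BCR samples; equal distributions across outcomes give a null.
  The planted truth records the intended A per sample.
- **PSA**: exponential decline from a lognormal baseline (median
  13.5 ng/mL) to a 0.5 ng/mL nadir at 12 months on the clinical follow-up
  grid, then small positive noise (NED) or a linear rise engineered to
  first reach nadir + 2 exactly at a planted visit (BCR); pre-crossing
  values are clipped below threshold so the planted crossing is the first
  qualifying time even under noise. At zero noise the crossing is exact.

Not emulated: probe-level microarray summarization, RNA-seq counts,
mean-variance trends (generator noise is homoscedastic, hence d₀ = ∞ in
moderation there; heteroscedastic variances are exercised with explicit
inverse-χ² draws in tests), gene-gene correlation, tumor purity, batch
effects, and imaging. Passing tests therefore demonstrate correctness of
the estimators and the pipeline's recovery behavior under its assumed
model — not robustness to the full messiness of FFPE biopsy data.

PlantedTruth records patient random intercepts only for the planted
signature genes (the ones tests inspect), keeping the truth JSON small.

## Problem sizes

Default test and reproduction runs use 200-gene co-cultures, 200–500-gene
cohorts of 20–29 patients, 10–20 simulation seeds per property, 2,000-gene
null matrices for calibration, and 100 random matrices for the scoring
oracle — sizes chosen so the whole suite and the reproduction script each
complete in well under a minute on one CPU while leaving every statistical
check comfortably powered.
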