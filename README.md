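# tgfbsig

Transforming growth factor beta (TGF-β) activity in untreated, localized
prostate cancer marks tumors prone to biochemical recurrence (BCR) after
external beam radiotherapy with androgen deprivation. `tgfbsig` is a tested,
reusable implementation of the computational pipeline behind that kind of
radiogenomic analysis, aimed at computational biologists who want to derive,
score and evaluate a prostate-cancer-specific TGF-β expression signature —
and at anyone who needs its statistical building blocks (single-sample
enrichment scoring, moderated differential expression, patient-blocked mixed
models, allele-dosage genomics) with independent oracles attached.

## What it computes

**Signature derivation.** In a six-condition epithelial/stromal co-culture
experiment (LNCaP epithelial cells with HPS-19I stromal cells, ± TGF-β
stimulation, ± the TGF-β receptor inhibitor SD-208, stroma alone ± TGF-β),
per-gene differential expression is fit by least squares with the contrast

&nbsp;&nbsp;&nbsp;&nbsp;c = (+1) · co-culture+TGF-β − ⅕ · (each of the five negative conditions),

moderated by empirical Bayes: sample variances s²_g with d_g degrees of
freedom are shrunk toward a prior (d₀, s₀²) estimated by moment matching on
log s²_g, giving posterior variances s̃²_g = (d₀s₀² + d_g s²_g)/(d₀ + d_g)
and a moderated t on d₀ + d_g df. Genes with Benjamini-Hochberg adjusted
P < 0.1 are ranked by descending log₂ fold-change.

**Single-sample scoring (ssGSEA).** For a gene set G in a sample with N
genes ranked r_g (average ties, largest expression = N), the enrichment
score is the running sum

&nbsp;&nbsp;&nbsp;&nbsp;ES = Σ_i [ P^w_G(i) − P_NG(i) ],&nbsp;&nbsp;
P^w_G(i) = Σ_{g∈G, pos≤i} r_g^τ / Σ_{g∈G} r_g^τ,&nbsp;&nbsp;
P_NG(i) = #{g∉G, pos≤i}/(N−|G|),

with τ = 0.25 and optional cohort normalization by the score range. The
signature size N is locked at the smallest local maximum of the ROC AUC of
the scores against outcome, searched from N = 3 upward.

**Patient-blocked differential expression.** For cohorts with 1–4 biopsies
per patient, per-gene random-intercept linear mixed models
y = β₀ + β₁·outcome + u_patient + ε (REML) realize patient blocking; the
Wald test for β₁ uses n_patients − 2 df.

**Allele-dosage genomics.** Each of *PTEN* and *TP53* contributes
min(2, copies lost + oncogenic mutations) altered alleles; the total
A ∈ {0..4} with A ≥ 3 defines the high-risk class, evaluated at the patient
level on a representative biopsy (highest Gleason grade group, ties broken
by percent tumor at the highest-grade pattern).

**Outcome evaluation.** ROC/AUC via the Mann-Whitney rank identity,
Mann-Whitney U tests (exact for small tie-free samples), Spearman
correlation against log₁₀(volume + pseudocount), and Phoenix BCR calling
(first PSA ≥ running nadir + 2 ng/mL).

A synthetic-data module generates all inputs with the statistical structure
the analysis assumes — planted co-culture responders, patient random
effects, outcome-conditional allele calls, PSA trajectories with planted
crossing times — so every stage is testable without external data.

## Worked example

```
tgfbsig run-all --seed 3 --outdir demo/
```

runs the whole chain on synthetic data and logs:

```
tgfbsig: simulate: 200 co-culture genes x 18 samples; cohort 500 genes x 77 biopsies (29 patients, 5 BCR)
tgfbsig: derive-signature: 200 genes tested; 6 past FDR<0.1 (d0=72.7, s0^2=0.252)
tgfbsig: select-n: locked N=5 (discovery AUC 1.000) from 6 candidates
tgfbsig: score: 77 samples scored against TGFB_PROSTATE (5 genes, tau=0.25)
tgfbsig: classify-alleles: A>=3 on 29 patients; sens 0.60, spec 1.00
tgfbsig: evaluate: score AUC 1.000; volume MW P 0.0783; Spearman rho 0.124
```

Reading: all six genes planted as TGF-β-responsive in the co-culture pass
the FDR filter; the AUC search over N = 3..6 (trace 0.993, 0.995, 1.000,
0.997) locks a five-gene signature whose per-sample scores separate the
five BCR patients' biopsies from the rest perfectly on this seed; the
three-allele *PTEN*/*TP53* rule is 100% specific (0 of 24 NED patients
called positive) and 60% sensitive; baseline lesion volumes trend larger
in BCR patients (Mann-Whitney P = 0.078 at n = 29). `demo/` holds the
expression/annotation/allele/PSA TSVs, `signature.gmt`, per-sample
`scores.tsv`, the AUC trace and the evaluation JSONs. Same seed, same
bytes: every output is deterministic in `--seed`.

Each stage is also exposed as its own subcommand (`simulate`,
`derive-signature`, `select-n`, `score`, `classify-alleles`, `evaluate`)
and as plain library functions (`tgfbsig.signature.ssgsea`,
`tgfbsig.diffexp.fit_mixed_model`, ...).

A note on conventions: the score weights are the rank magnitudes r_g^τ
(the GSVA realization of ssGSEA), not the rank-normalized statistics of
the original single-sample enrichment publication; scores from the two
conventions differ by a monotone-in-rank reweighting, so set membership
decisions and AUCs computed within one convention are internally
consistent but raw scores are not interchangeable across tools.

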