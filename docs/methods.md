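# Methods

## Model and assumptions

The pipeline treats expression as log2-scale, approximately Gaussian
measurements (RMA-like array summaries). It never exponentiates except in
the fold-change reporting filter (fc = 2^Δ). Inputs are assumed complete:
missing values are rejected rather than imputed, since silent imputation is
a larger risk than a hard error at these scales. Identifiers live in two
disjoint namespaces — miRNAs, and genes/TFs — and a transcription factor
appears in the mRNA matrix under its gene id; a Type I loop therefore
requires the miRNA to target the TF's transcript under that same id. One
row per gene/miRNA is assumed (probe collapsing is upstream of this tool).

### Differential expression

Per feature, OLS on a model matrix (intercept, tumor indicator, optional
surrogate variables or pairing dummies) yields Δ, residual variance s²_g
and residual df d_g. The empirical-Bayes prior (d₀, s₀²) is obtained by
matching the first two moments of log s²_g to a scaled-F model: with
e_g = log s²_g − ψ(d_g/2) + log(d_g/2),

- d₀ = 2·ψ′⁻¹( var(e) − ψ′(d_g/2) ), via Newton inversion of the trigamma,
- s₀² = exp( mean(e) + ψ(d₀/2) − log(d₀/2) ),

falling back to d₀ = ∞ (complete pooling) when the observed spread of
log-variances is no larger than its sampling noise. The moderated t uses
the posterior variance and d_g + d₀ df (normal tail when d₀ = ∞). P values
are floored at 1e-300 before any logarithm and computed on the survival
side. Zero-variance features are dropped with a logged warning. Setting
`prior_df=0` reproduces the ordinary equal-variance t-test exactly, which
is both a limiting-case check and an escape hatch.

Thresholds are inclusive (fdr ≤ 0.05 is significant). Pairing in the
matched miRNA data is ignored by default (two-group comparison); a
`paired` flag adds pairing dummies as fixed covariates.

### Surrogate variables

Residuals after removing the condition effect are decomposed by SVD; the
k-th right singular vector is retained when its variance proportion exceeds
the (1 − α) quantile of the same quantity under row-wise permutations of
the residual matrix (default 100 permutations, α = 0.10, seeded; p-values
made monotone along the spectrum, selection stops at the first failure).
This is a deterministic, desk-scale two-step estimator; the function is a
plain `matrix, design -> covariates` interface so a different estimator can
be substituted. It needs ≥ 3 samples per condition and refuses otherwise.
A caveat inherent to *any* residual-space method: only the component of a
confounder orthogonal to the condition is recoverable; a partially aligned
batch still biases Δ by its aligned component even after adjustment (it
restores detection power but not unbiasedness — see the generator notes).

### Set enrichment

Sets are tested against the mRNA moderated-t vector with a Wilcoxon
rank-sum of members vs. non-members: |t| one-sided toward large values for
undirected ("mixed") tests, signed t one-sided for directed tests. The
mixed alternative operationalizes "enriched for deregulation"; ranking |t|
versus t² is equivalent for rank tests, so the choice is cosmetic. Exact
enumeration is used for universes of ≤ 10 without ties, otherwise the
normal approximation with tie correction. Validated-target miRNA sets are
tested against the miRNA's own direction (a repressor's targets should move
opposite to it) and require ≥ 8 members — small validated sets produce
biased rank tests. BH is applied within each family (TF, miRNA, pathway)
separately, so a family's FDR is not diluted by another's. miRNA sets are
only built for an explicit whitelist of externally supported miRNAs;
the whitelist is an input file, not a built-in.

### Loops, scores, labels

Both regulator nodes (miRNA and TF) must appear in the combined
deregulation lists; the target mRNA need not be differentially expressed
(TF binding may produce sub-threshold transcriptional change, and miRNA
action can be translational). Pathway loops additionally require a
significant pathway, a `direct` interaction flag, and both endpoint genes
measured; edges are unordered with lexicographic canonical order, so each
(miRNA, gene pair) is one loop. No deduplication is performed across loop
types: the same molecule may legitimately serve different roles.

Fisher's T = −2Σln pᵢ uses the **unadjusted** per-node MHT p-values (also
for GSEA-rescued regulators, whose own transcript-level p is what the
statistic needs). Under independence T ~ χ² with 2·3 = 6 df; dependence
among the node tests makes the tail probability optimistic, so the score
is a ranking device only — dependence-aware combination (Brown/Kost) is
deliberately out of scope. Score ties are broken lexicographically on
(miRNA, TF, mRNA) for reproducibility. Node directions are the sign of the
moderated t regardless of significance.

Consistency uses the pairwise rule: (a) the regulator–regulator edge
relation holds (miRNA ⊣ TF anti-correlated for Type I; TF→miRNA
correlated or anti-correlated per its sign for Type II), and (b) the
miRNA ⊣ mRNA pair is anti-correlated. For coherent loops this is provably
equivalent to all three edge relations holding simultaneously (verified by
enumeration in the tests); for incoherent loops the three relations can
never hold at once, so the pairwise rule is the usable definition and
yields the expected non-empty consistent incoherent classes. Exactly 2 of
the 8 direction assignments are consistent for every subtype.

Evidence labels on miRNA-target edges: predicted ∧ validated →
true_positive, validated-only → false_negative (the predictive stage missed
a known interaction), predicted-only → novel.

### Summaries

Attribution denominators are the MHT-differentially-expressed mRNAs, and a
target only counts toward a miRNA's attribution when it is itself DE —
"transcriptome deregulation" is read as deregulated transcripts, not all
measured ones. A miRNA-target interaction is consistent when the two move
anti-correlated. Co-targeting overlaps report all 2^k − 1 exclusive Venn
regions of the per-miRNA FFL target sets.

## Numerical and degenerate-input choices

- Quantile normalization maps each column onto the per-rank across-sample
  means; ties receive the mean reference value over the tied ranks. On
  tie-free data the operation is exactly idempotent and all column
  multisets coincide; with ties the averaging rule slightly perturbs the
  reference on a second pass, so idempotence holds only tie-free.
- BH is the standard step-up with capping at 1, validated against a naive
  O(m²) oracle.
- Empty set families, empty loop tables and empty combined lists flow
  through every downstream stage; fractions over an empty loop set refuse
  with a diagnostic rather than returning NaNs.
- All stochastic steps (SVA permutations, simulation) take explicit seeds;
  pipeline outputs are byte-identical under rerun.

## The synthetic study

`synthetic.SimulationConfig` defaults encode the emulated study: 2000 genes
and 40 miRNAs, 20 samples per condition (miRNA samples as matched pairs),
5% of genes and 30% of miRNAs differentially expressed with |log2 effect|
= 2.0 and noise sd 0.25, two planted loops per FFL subtype (alternating
consistent/inconsistent) plus two pathway loops, and 30 decoy edges among
null features. The gene-scale fractions mirror a strongly deregulated
tumor/normal contrast at desk scale; the miRNA fraction is raised above
what small arrays show so every loop subtype can be planted from distinct
regulators. Effects are additive Gaussian shifts — no count model, probe
effects, or intensity-dependent variance — so passing tests demonstrate
correctness of the statistical machinery and joins, not robustness to
array artifacts.

The hidden-factor experiment uses a per-feature ±`batch_effect` coefficient
applied to carrier samples, with carriers drawn at probability
`batch_alignment` in tumors and its complement in normals. The adjustment
comparison uses magnitude 3.0 at 70% alignment: large enough that the
unadjusted within-group variance (≈ |b|·√(p(1−p)) ≈ 1.4 on top of 0.25
noise) sinks a substantial fraction of true effects, while the adjusted fit
recovers them; the aligned 40%-of-b bias on Δ remains in both fits, as it
must. Consistent planted loops draw their TF and target from DE pools with
the direction pattern the pairwise rule requires; inconsistent ones break
only the miRNA-target anti-correlation, so both label states are exercised.
Decoy regulators are non-DE and are eliminated at the prior-restriction
stage; with decoys disabled the pipeline output equals the planted set
exactly, which the tests assert.

## Problem sizes

Tests and the acceptance script run the full pipeline at the default
2000 × 40 scale (seconds per run) and the adjustment comparison over ten
seeds; null calibrations use 50-seed grids at 200-feature scale and 10⁵
draws for the score-uniformity check. These sizes give stable pass/fail
behavior at interactive runtimes.

## Known limitations

- The score's χ²₆ calibration ignores inter-node dependence; ranks are
  meaningful, absolute tail probabilities are optimistic.
- The consistency rule for incoherent loops is an interpretation (the
  pairwise rule), chosen because the all-edges criterion is unsatisfiable
  there; it reproduces the canonical coherent examples.
- GSEA rescue uses transcript-level statistics of targets; it cannot see
  post-translational TF activity, only its downstream transcriptional echo.
- The generator plants clean additive signals; it does not emulate probe
  saturation, cross-hybridization, or correlated noise between miRNAs and
  their host genes.
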