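# mirloop

`mirloop` detects **deregulated miRNA/TF-mediated regulatory loops** from
two-condition (e.g. tumor vs. normal) mRNA and miRNA expression data
combined with regulatory-prior tables. It is aimed at systems biologists who
have log2-scale expression matrices plus curated TF→gene, TF→miRNA and
miRNA→gene interaction tables, and who want ranked, annotated three-node
regulatory motifs rather than flat lists of differentially expressed
transcripts.

## The method

1. **Differential expression with hidden-factor adjustment.** Each
   transcript is tested for a condition effect Δᵢ = μᵢᵗ − μᵢⁿ with a
   *moderated t-statistic*: per-feature residual variances s²_g from an OLS
   fit are shrunk toward an empirical-Bayes prior, s̃² = (d₀s₀² + d_g s²_g)
   / (d₀ + d_g), with (d₀, s₀²) estimated in closed form from the moments of
   log s²_g, and t referred to d_g + d₀ degrees of freedom. Unmodelled
   structure (molecular subtype, batch) is estimated by *surrogate variable
   analysis*: right singular vectors of the condition-residual matrix,
   retained by a permutation test, enter the model as covariates.
   Benjamini–Hochberg FDR is controlled at 0.05.
2. **Set-enrichment rescue (GSEA).** Regulators missed per-transcript are
   rescued by Wilcoxon rank-sum tests of their target sets against the
   remaining transcripts (|t| for undirected tests; signed t, against the
   miRNA's own direction, for validated miRNA target sets of ≥ 8 members),
   with BH FDR 0.25 within each set family. Pathway membership sets flag
   deregulated pathways the same way.
3. **Loop construction.** Priors are restricted to deregulated regulators
   and measured targets, then joined into **Type I** FFLs (miRNA ⊣ TF, miRNA
   ⊣ mRNA, TF → mRNA), **Type II-A/B** FFLs (TF → miRNA and TF →/⊣ mRNA,
   miRNA ⊣ mRNA) and **Type III** loops (miRNA targeting both ends of a
   direct interaction on a significantly deregulated pathway). Coherence
   compares the sign products of the two regulator→mRNA paths.
4. **Scoring and labeling.** Each FFL combines its three node P values with
   Fisher's statistic **T = −2(ln p₁ + ln p₂ + ln p₃)**, scored by the
   upper tail of χ²₆ (a ranking device, not a formal P value). Loops are
   labeled *consistent* when the observed node directions agree with the
   edge-sign structure, and each miRNA-target edge is labeled
   true-positive / false-negative / novel by its prediction-vs-validation
   evidence. Loops are ranked by ascending score within seven groups
   (I-coherent, I-incoherent, II-A/B-coherent/incoherent, III).

A fully-tested synthetic-study generator (planted differential expression,
a hidden partially condition-aligned subtype factor, and planted loops of
every subtype with known consistency) makes the whole pipeline verifiable
without any external database.

## Worked example

```bash
mirloop simulate --out demo --seed 4          # synthetic study + ground truth
mirloop all --config demo/config.yaml --out demo/results
```

The run logs its per-stage tallies:

```
de: 104/2000 mRNAs and 12/40 miRNAs significant at FDR 0.05 (1 + 0 surrogate variables)
gsea: 30 TF sets, 0 miRNA sets, 2 pathway sets tested; 1 significant pathways; combined lists 104 mRNAs / 12 miRNAs
loops: 14 loops constructed
score: loops per group {'I-coherent': 2, 'I-incoherent': 2, 'II-A-coherent': 2, 'II-A-incoherent': 2, 'II-B-coherent': 2, 'II-B-incoherent': 2, 'III': 2}
```

i.e. 104 of 2000 genes and 12 of 40 miRNAs are called differentially
expressed (the generator planted 100 and 12), and the 14 planted loops —
two per FFL subtype plus two pathway loops — are reconstructed and ranked.
`demo/results/loops.tsv` holds the annotated table; its first rows:

```
loop_type  subtype  coherence   mirna    tf_or_gene1  mrna_or_gene2  dir_mirna  dir_tf  dir_mrna  consistent
I          none     coherent    mir-001  G0070        G0155          1          -1      -1        consistent
I          none     coherent    mir-003  G0054        G0176          -1         1       -1        inconsistent
```

The first loop is a Type I coherent FFL whose up-regulated miRNA faces a
down-regulated TF and mRNA — exactly the direction pattern an intact
miRNA-driven repression circuit predicts, hence `consistent`. Summary
tables (`subtype_fractions.tsv`, `mirna_attribution.tsv`,
`cotargeting.tsv`, `mirna_tf_pairs.tsv`) and a reproducibility manifest are
written alongside.

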