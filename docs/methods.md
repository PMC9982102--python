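# Methods

## Scope and data model

The package starts from called variants (a multi-sample VCF of homozygous
inbred parents), a GFF3 gene annotation, a cross-design table and
plot-level grain yield; upstream read alignment and variant calling are
out of scope, as are phasing, imputation and multiallelic decomposition.
Genotypes are held as a samples × sites matrix of alt-allele dosages
(0/1/2, −1 = missing) with per-call depth and genotype quality.
Coordinates are 1-based inclusive at every file boundary (VCF/GFF3
convention); interval trees store 0-based half-open intervals internally,
with conversion confined to readers/writers.

## SNP quality control

Filtering mirrors standard resequencing-panel practice with two tiers:

| threshold | default | action on failure |
|---|---|---|
| per-call depth | ≥ 3 | call masked to missing |
| per-call genotype quality | ≥ 5 | call masked to missing |
| site QUAL | ≥ 30 | site removed |
| site missing rate (after masking) | ≤ 0.2 | site removed |

The site QUAL field stands in for base quality: per-base qualities do not
survive variant calling, so the only quality attached to a site in a VCF
is its phred-scaled QUAL. Masking precedes the missing-rate test, so a
site can be removed because masking pushed it over the limit. Absent
DP/GQ annotations pass (nothing to test against). Multiallelic and indel
records are skipped at read time, not split: the analysis counts
biallelic SNP differences. Filtering is idempotent by construction.

## PEUS classification

Per transcript: promoter = `promoter_len` (default 1000 bp) 5′ of the
start codon in strand orientation, truncated at position 1; exon = all
exon intervals; UTR = 5′ and 3′ UTRs; stop codon = the final 3 coding
bases in transcript orientation, which may span two CDS intervals when
an intron interrupts the last codon. Anchoring the promoter at the start
codon (not the TSS) means it can overlap the transcript's own 5′UTR;
both categories are then recorded — categories are unioned over
transcripts and genes, and a site is PEUS if any category covers it. A
site carries all its categories in category totals but counts once in
the PEUS total. Transcripts without CDS contribute exon/UTR intervals
only. No single-category precedence scheme is applied; where a consumer
needs one, the per-site category sets are exposed.

## Cross scoring

Over PEUS sites only: both parents homozygous and equal → homozygous;
homozygous and different → heterozygous (the F1 is heterozygous there);
either parent missing *or residually heterozygous* → excluded, because
the F1's zygosity at such a locus is ambiguous for an inbred-by-inbred
cross. The three counts always sum to the PEUS site total.

GD = 1 − IBS uses the full filtered SNP set by default (a genome-wide
kinship measure), with an optional site mask for restricted comparisons;
IBS averages the per-site shared-allele fraction (2 − |dᵃ − dᵇ|)/2 over
pairwise-complete sites. For fully observed homozygous parents, the
heterozygous fraction of PEUS sites equals GD restricted to PEUS sites —
a tested identity linking the two predictors.

## Trial analysis

The line × tester ANOVA treats locations, lines and testers as fixed and
tests every source against the pooled error mean square, appropriate
when lines and testers are deliberately chosen rather than sampled. Sums
of squares use the balanced orthogonal cell-mean decomposition
(sequential SS, which equals marginal SS on balanced data); the error SS
is the remainder of the total, non-negative by orthogonality. Unbalanced
data is rejected with an explicit error rather than silently
approximated — the supported design is the replicated multi-location
factorial. For the default 19 × 5 × 3 × 3 layout the degrees of freedom
are (2, 6, 18, 4, 72, 36, 8, 144, 564).

MPH/BPH use entry means over replications (scope `across` additionally
over locations; scope `per-location` within each); parents are averaged
over the same plot structure as the F1s. Crosses with non-positive
parent means get NaN heterosis and a `defined=False` flag. Checks are
excluded from the ANOVA and parents from the F1 model. Fisher's LSD is
t(1 − α/2, df_error)·√(2·MS_error/n); Kempthorne GCA/SCA come from the
balanced cross-mean table (marginal deviations and the interaction
residual), so grand + GCA_line + GCA_tester + SCA reconstructs every
cross mean exactly.

## Predictor comparison

Pearson r with the exact t-based two-sided p-value; least-squares
regression with R² = r². The method for comparing the two predictors'
correlation strengths is a design choice of this package: a paired
t-test on per-stratum differences of Fisher-z transformed coefficients,
the strata being the location × {MPH, BPH} combinations (6 in the
default trial). The pairing matches the only repeated structure in the
per-location analysis; Fisher's z is the standard variance-stabilising
transform for correlation coefficients. Two-sided by default, one-sided
available. p-values are reported unadjusted throughout. Top-k cross
summaries rank by the chosen response, break ties by stable input order
with a warning, and count each parent's appearances.

## Synthetic data generator

The generator reproduces the structure the analysis assumes, not any
particular dataset:

- **Panel** — 24 fully homozygous inbreds in three heterotic groups
  (8 "Reid" including the 5 testers, 13 "nonReid", 3 "Suwan1"), crossed
  19 × 5 = 95. Group allele frequencies follow a Balding–Nichols model:
  ancestral p ~ U(0.05, 0.95), group frequency ~ Beta(p(1−F)/F,
  (1−p)(1−F)/F) with F = 0.15, a typical divergence between maize
  heterotic pools. Inbreds are dosage 2 with their group's frequency,
  else 0 — no residual heterozygosity, no missingness; depth/GQ/QUAL are
  drawn above the default filter thresholds so QC is a pass-through.
- **Gene models** — deterministic non-overlapping genes in equal slots
  (≥ 1 kb intergenic margin each side so promoters never reach a
  neighbour), alternating strands, every third gene with an intron
  splitting the CDS. Desk-scale default: 150 genes, 3000 SNPs on two
  1.5 Mb chromosomes (~10–15% of SNPs PEUS).
- **Phenotypes** — entry genetic value = Σ over causal loci of
  a·(dosage − 1) + d·1{heterozygous}; an F1's dosage is the mean of its
  parents' (heterozygous iff they differ — no recombination is needed
  because F1s are not selfed). Causal loci are a fraction (default 0.30)
  of PEUS sites, optionally relocated off-PEUS via
  `off_peus_effect_fraction`; a ~ N(0, 0.04) t/ha and d ~ Exp(0.20) t/ha
  — strictly positive dominance is the generative source of heterosis,
  chosen because the predictor under study is a heterozygosity count.
  Plot yield = 6.0 (grand mean) + location N(0, 1.0) + rep-within-
  location N(0, 0.2) + genetic value + G×E N(0, 0.3) + plot noise
  N(0, 0.8), all t/ha, truncated at 0 (logged; rare under defaults).
  These magnitudes give inbred parents ~5–6 t/ha, hybrids ~8–18 t/ha and
  MPH of roughly 70–230% — maize-like — and per-cross predictor
  correlations around r ≈ 0.4–0.6, matching the strongly significant
  correlations the analysis is designed to detect.
- **Random streams** — annotation is deterministic; genotypes, effects
  and trial noise use independent child streams of the seed, so changing
  the phenotype seed leaves genotypes fixed.

What the generator does *not* emulate: linkage disequilibrium and
recombination maps (loci are independent given group frequencies),
epistasis, genotype-calling error, real gene-density heterogeneity, and
selection history. Passing recovery tests therefore show the pipeline
recovers a dominance signal concentrated in PEUS regions under the
assumed architecture — not that PEUS counts will out-predict GD on any
real panel.

## Recovery experiments

One replicate = simulate panel + trial at a seed, score crosses, compute
across-location MPH, and compare r(n_het_peus, MPH) with r(GD, MPH) over
the 95 crosses. With causal loci fully inside PEUS regions the PEUS
count wins in ~90% of seeds (the count contains the causal loci; GD
dilutes them across the genome). With causal loci moved fully off-PEUS
the advantage does not merely vanish but reverses (win fraction
~0.1–0.3): GD still covers the causal loci while the PEUS subset no
longer does, so GD becomes the better proxy. The recovery checks assert
the advantage (≥ 80% wins) and its abolition (≤ 60%), not a symmetric
50/50 null.

## Numerical and degenerate-input choices

- Constant inputs make correlation/regression undefined → explicit
  errors (except constant *response* in regression: slope 0, R² 0).
- All-equal correlation pairs in the paired comparison → t = 0, p = 1
  (the t statistic is 0/0 otherwise).
- No jointly observed site between two samples → GD error, not NaN.
- ANOVA error SS is clipped at 0 against floating-point cancellation;
  F-test p-values come from the F survival function.
- Problem sizes in tests and the acceptance script are desk-scale
  (hundreds to thousands of SNPs, 50-seed recovery runs), chosen so a
  full verification pass completes in well under a minute of compute
  while every assertion operates on the same code paths as a
  genome-scale run.

## Known limitations

Single-trait, biallelic-SNP-only; balanced trials only; fixed-effects
inference (no REML/mixed models, no spatial correction); the ANNOVAR-style
single-category assignment used by some annotation pipelines is not
reproduced (category sets are unioned instead); GD is plain IBS without
LD pruning.
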