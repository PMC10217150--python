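# Methods

## Problem and scope

`trioforge` re-implements, as a tested library and CLI, a trio-exome
rare-variant prioritization procedure for a rare congenital disorder
(Congenital Pouch Colon, CPC) studied in 16 proband–parent families (11
male, 5 female probands; trios plus unaffected siblings, 64 exomes in
all). The pipeline classifies Mendelian segregation per (variant, family),
reduces segregating variants through a staged population-frequency /
depth / deleteriousness cascade, assigns the computable subset of ACMG
evidence codes, scores gene-set enrichment, and reproduces the cohort- and
assay-level summary arithmetic. Read alignment, variant calling, and live
annotation-database queries are out of scope: genotypes and annotations
(population allele frequency, CADD, GERP, SIFT/PolyPhen/MutationTaster
calls, consequence class) are inputs, carried in VCF INFO fields or a
sidecar TSV.

Because the deposited cohort is not required, a synthetic cohort generator
with a recorded truth set stands in for the data; it is first-class,
tested code, not a throwaway fixture.

## Segregation model

Genotypes are diploid categories (hom_ref / het / hom_alt / missing;
missing is never imputed). For each (variant, family) with complete
proband and parent calls the classifier applies a fixed decision table:

- **de novo** — proband het, both parents hom_ref, all genotyped
  unaffected siblings hom_ref. A sibling carrying the allele vetoes the
  label (the pattern is then an unexplained Mendelian violation); a
  missing sibling call flags the record but does not veto — the published
  procedure does not state a missing-data policy, so this is the package's
  own choice, made conservative in the reporting direction (nothing is
  silently dropped).
- **recessive-homozygous** — proband hom_alt with both parents het and no
  hom_alt sibling. Configurations with a hom_alt parent are
  Mendelian-consistent but labelled inherited; `relaxed_recessive` admits
  them.
- **inherited paternal / maternal / ambiguous** — het proband with
  exactly one, or both, parents carrying.
- residual categories: not-in-proband, Mendelian-violation-other,
  unclassifiable-missing.

Labels are total and mutually exclusive; the test suite checks the
classifier against an independently written brute-force lookup over all
27 trio and 81 one-sibling-quad combinations. X-linked (hemizygous) logic
is not modelled in v1; the reference candidates are autosomal.

## Filter cascade

The published filter description mixes three frequency bounds
(screen < 0.05, < 0.01, and "≤ 0.01%"); as a single rule these are
contradictory, so the cascade is tiered: `screened` (< 0.05),
`strict_rare` (< 0.01), `extreme_rare` (≤ `maf_extreme`). The
`maf_extreme` default is 5e-4 rather than the literal 1e-4 because the
reference study labels a 3.156e-4-frequency stop-gain "extremely rare";
1e-4 is one configuration flag away. An absent population frequency is
treated as 0 (absence from the databases is itself evidence of rarity,
the same reading ACMG PM2 uses) and logged in the provenance trail.

Deleteriousness is a k-of-m vote (default 2 of 5) over SIFT, PolyPhen,
MutationTaster, CADD Phred ≥ 20 and GERP ≥ 2, with loss-of-function
consequences (stop gained/lost, frameshift) short-circuiting the vote.
The study's "union of intersection" of predictors is not defined
precisely; k-of-m with an LoF bypass is the most defensible reading and
every piece is configurable.

The depth gate takes "average depth of 250" as the family-mean site depth
(≥ semantics at the boundary); a per-sample-minimum mode is available.
Whether the original filter covered probands only or all members is
unstated — family mean is the stricter, symmetric choice.

A candidate therefore needs: a de novo or recessive-homozygous call in at
least one family, the depth gate passed in such a family, tier
strict_rare or better, and a deleterious consensus. Every variant
entering the cascade gets a provenance trail with an identical stage
sequence; candidates have all-pass trails, and the cascade asserts on
every run that no candidate reaches the table with frequency ≥ 0.01. The
within-cohort carrier fraction is reported next to the population
frequency and deliberately not filtered on: the reference data contain a
variant that is ultra-rare in databases yet carried by most probands, and
the pipeline leaves that tension to the analyst.

## ACMG engine

Six of the 28 guideline codes are computable from the pipeline's inputs:
PVS1 (null consequence), PS2 (trio-confirmed de novo), PM2 (frequency ≤
1e-4), PP3 (predictor votes ≥ 2), BS1 (frequency above the rare-disease
expectation, default > 1e-4), BA1 (≥ 0.05, stand-alone benign). The
PM2/BS1 boundary is deliberately placed so the reference stop-gain record
(frequency 3.156e-4) receives BS1, as published, for an ultra-rare
disorder; all thresholds are configurable under the invariant
`pm2 ≤ bs1 ≤ ba1`. Combination follows the standard table restricted to
these codes; mixed pathogenic and benign evidence resolves to VUS (so
"PVS1 + BS1" is reportable but unclassified, matching how the reference
study treated that record). The published table also assigns PVS1 to a
missense record; that contradicts the code's definition (null variants
only) and is not reproduced. Classification is monotone in population
frequency by construction, and the combining function is total over all
2^6 code subsets (both enumerated in tests).

## Enrichment statistics

Term p-values are exact hypergeometric upper tails (`scipy`'s survival
function; an exhaustive enumeration oracle covers every parameterization
with universe ≤ 12 at 1e-12), with a binomial approximation available.
Multiple testing uses Benjamini–Hochberg — the procedure behind the
published "adjusted p" column is unstated, and the printed adjusted
values are not recoverable from the printed raw p-values alone (the
library size is unknown), so adjusted values are treated as data, not as
a reproduction target. The z-score is the standardized deviation of a
term's observed p-rank from its rank distribution under repeated random
same-size queries (default 100, seeded), and the combined score is
`c = z · ln p`. All 106 reference (p, z, combined) triples shipped with
the package reproduce under this formula within |Δ| ≤ 0.05, the slack
being entirely the 2–3 significant figures of the printed z. Because
hypergeometric p-values are discrete, the null-behaviour test asserts
super-uniformity (P[p ≤ a] ≤ a plus binomial sampling margin) rather than
a continuous-uniformity KS test, which would reject any discrete test by
construction.

## Synthetic cohort generator

The generator emulates the study design, not sequencing physics:

- **Structure**: 16 families, all quads by default (64 samples,
  matching the study), 11 male probands; trio/quad mix, family count and
  sex ratio configurable.
- **Sites**: one cohort-shared site list (joint-VCF style), default
  5,000 sites per exome at desk scale (the study-scale 840,667 is a
  config value, not a default). Consequence classes are drawn from the
  per-proband class proportions implied by the reference cohort summary
  (missense 10,764.5 / 840,667 etc.).
- **Population frequencies**: mixture of a common component
  Uniform(0.05, 0.5) and a rare component log-uniform on [1e-6, 1e-2];
  `rare_fraction` defaults to 0.25 — enough rare background to exercise
  the cascade while keeping most sites common, as in real exomes.
- **Transmission**: parents are Hardy–Weinberg draws at the site
  frequency; each child receives one uniformly chosen allele per parent.
  Sites are independent (no linkage disequilibrium) and there is no
  population structure.
- **Planted events**: per proband, 2 de novo het missense and 2
  recessive-homozygous events by default (small integer counts typical of
  prioritized trio candidates; the study's focus class is de novo
  heterozygous missense), each at its own site, rare (≤ 1e-4), high CADD
  and GERP, unanimous deleterious predictor calls. Recessive siblings are
  drawn conditional on not being hom_alt (hom_ref 1/3, het 2/3).
- **Depth**: negative binomial with mean 250 and dispersion 10
  (overdispersed coverage is standard; the dispersion value is a modelling
  choice, not data-derived).
- **Noise**: an independent per-genotype error process replaces a call
  with a uniformly chosen different category at the configured rate
  (default 0).

**Truth-set semantics.** The generator records a label for every
(variant, family) whose realized pattern is informative, from its own
transmission bookkeeping — including background sites where a common
allele happened to produce the het × het → hom_alt recessive
configuration. This matters for recovery metrics: a recessive-homozygous
call at such a site is a *correct classification of a real pattern*, not
a false discovery, and common-allele recessive configurations are
frequent by elementary Mendelian arithmetic. Sensitivity and FDR for the
segregation stage are therefore measured against these labels, under
which both are exactly 1.0 and 0.0 at zero genotyping error, and degrade
monotonically with the error rate (tested pooled over seeds).

What passing these tests does *not* show about real data: no calling
error structure (the error model is independent and uniform, real
genotyping errors are depth- and allele-balance-correlated), no LD, no
population stratification, no X-linked inheritance, annotations drawn
from simple parametric margins rather than real predictor joint
distributions.

## Worked-example fixture

The packaged reference tables carry the study's printed summary numbers
(cohort class counts for 16 probands / 46 controls, a 12-SNP genotyping
plex over 37 samples, 106 enrichment triples, and the three published
extremely rare candidate variants with their annotations). The
worked-example cohort plants those three variants as de novo events in
their published carrier probands among 1,000 background sites and 50
common decoys, simulating coverage at mean 300: the depth gate threshold
(250) equals the default simulated mean, so a mean-250 cohort would sit
exactly on the knife edge of the family-mean filter, and a fixture meant
to exercise the rarity/consensus logic must sit clearly on one side of
the depth gate. Two fixture completions are synthetic and marked as such:
the missense record with CADD 1.07 carries deleterious SIFT/PolyPhen
calls (the study prioritized it as deleterious but printed no predictor
calls), and its carrier list beyond the nine printed proband ids uses
invented placeholders.

## Numerical and interface choices

- Coordinates are 1-based throughout; chromosome labels are stored
  without the `chr` prefix and both dialects are accepted.
- Multiallelic records are split per alternate allele before any
  analysis; a genotype carrying only another alternate allele is hom_ref
  with respect to the allele under consideration. Dosage conservation
  under splitting is brute-force tested over all diploid genotypes.
- VCF INFO floats travel at single precision; round-trips are exact for
  all non-float fields and ~1e-7 relative for frequencies.
- Machine outputs always keep full precision; display rounding (integer
  means, whole-percent call frequencies) is cosmetic and never feeds back
  into computation.
- All randomness flows from one `numpy` Generator per run, seeded from
  the single configured seed; reruns are byte-identical, and the run
  manifest records configs, seed, input checksums and stage outcomes.

## Problem sizes

Desk-scale defaults (5,000 shared sites, 16 families, ≤ 1,000-site
worked examples) keep the full test suite and the acceptance script in
the seconds-to-a-minute range. Cohort-level discovery counts that depend
on the deposited 64-exome data (hundreds of thousands of shared variants)
are not reproducible at this scale and are not claimed; the reproduction
surface is the summary arithmetic, the printed worked examples, and the
statistical properties of the pipeline on the synthetic cohort.
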