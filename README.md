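# trioforge

Rare-variant prioritization for proband–parent trio/quad exome cohorts.

`trioforge` is for analysts working on rare Mendelian phenotypes — the
motivating design is a 16-family trio/quad whole-exome study of
Congenital Pouch Colon (CPC), a rare anorectal malformation — who need a
reproducible path from a joint multi-sample VCF plus pedigree to a short,
evidence-annotated candidate list. It provides:

- **Segregation classification** — every (variant, family) pair gets
  exactly one label from a fixed Mendelian decision table: de novo
  (proband het, parents and unaffected siblings hom_ref),
  recessive-homozygous (proband hom/alt, parents het), inherited with
  paternal/maternal/ambiguous origin, or a residual category (missing
  calls are reported, never silently dropped).
- **A staged filter cascade** — population-frequency tiers
  (screen < 0.05, strict < 0.01, extreme ≤ 5 × 10⁻⁴), a family-mean
  site-depth gate (≥ 250 by default), and a k-of-m deleteriousness
  consensus over SIFT / PolyPhen / MutationTaster / CADD / GERP with a
  loss-of-function short-circuit. Every variant entering the cascade
  carries a provenance trail recording each stage's decision.
- **ACMG evidence assignment** — the six guideline codes computable from
  these inputs (PVS1, PS2, PM2, PP3, BS1, BA1) combined into the standard
  5-tier classification, with conflicting evidence resolving to VUS.
- **Gene-set enrichment** — exact hypergeometric tails,
  Benjamini–Hochberg adjustment, rank-deviation z-scores, and the
  combined ranking score c = z · ln p.
- **Cohort and assay summaries** — per-group totals/means, pooled
  percentages, genotyping-plex call frequencies.
- **A synthetic cohort generator** — pedigree-structured genotypes under
  Hardy–Weinberg and fair Mendelian transmission, with planted de novo and
  recessive events, annotation injection, a genotyping-error process, and
  a recorded truth set, so the whole pipeline is testable without any
  data download.

See `docs/methods.md` for the model, its assumptions, and the reasoning
behind every default.

## Worked example

The package ships the three extremely rare candidate variants of the
reference CPC cohort (in *MUC5B*, *FRG1* and *TAF1B*, with their
published frequencies and predictor scores). Planting them as de novo
events in a synthetic 16-trio cohort among 1,000 background sites and 50
common decoys, then running segregation → cascade → ACMG:

```python
from trioforge.fixtures import reference_cohort
from trioforge.segregation import segregate_cohort
from trioforge.prioritization import prioritize
from trioforge.acmg import assign_and_classify

cohort, expected = reference_cohort(seed=1)
seg = segregate_cohort(cohort)
candidates, trails = prioritize(cohort, seg)
print(candidates[["rank", "gene", "chrom", "pos", "tier",
                  "af_pop", "cadd_phred", "n_probands", "lof"]].to_string(index=False))
```

```
 rank  gene chrom       pos         tier   af_pop  cadd_phred  n_probands   lof
    1 MUC5B    11   1238987 extreme_rare 0.000020        1.07          15 False
    2 TAF1B     2   9904885 extreme_rare 0.000316        1.31           9  True
    3  FRG1     4 189957414 extreme_rare 0.000019       40.00           2 False
```

Exactly the three planted rare variants survive — the 50 common decoys
segregate perfectly as de novo but fall at the frequency screen. All
three sit in the extreme-rarity tier, so the rank order is the number of
carrier probands. The ACMG engine then reproduces the published evidence
pattern — `{PVS1, BS1}` for the TAF1B stop-gain (a null variant whose
frequency is nonetheless high for an ultra-rare disorder: conflicting
evidence, classified VUS) and `{PM2, PP3}` for the FRG1 missense:

```python
for _, row in candidates.iterrows():
    i = cohort.variant_index((row["chrom"], int(row["pos"]), row["ref"], row["alt"]))
    a = assign_and_classify(cohort.profiles[i], predictor_votes=int(row["votes"]))
    print(row["gene"], sorted(a.criteria), a.classification)
# MUC5B ['PM2', 'PP3'] vus
# TAF1B ['BS1', 'PVS1'] vus
# FRG1  ['PM2', 'PP3'] vus
```

The same pipeline runs from the shell:

```sh
trioforge simulate --seed 7 --out store/
trioforge run --config pipeline.yaml        # ingest/simulate → segregate →
                                            # prioritize → classify → enrich → report
```

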