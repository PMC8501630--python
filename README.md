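# ascopy

Downstream analysis of allele-specific copy number profiles from tumor
cohorts.  `ascopy` consumes the segment tables emitted by allele-specific
copy number callers such as ASCAT — per sample, an ordered list of genomic
segments with integer major/minor allele copy numbers plus estimates of
tumor ploidy and aberrant cell fraction — and provides the analysis layer
that typically follows:

- **Ploidy-relative aberration calling.** Tumor ploidy is the
  length-weighted median total copy number across the genome; segments with
  total copy number above (below) ploidy are called gains (losses), with an
  optional tolerance band δ.
- **Recurrent aberrant regions.** Cohort-wide gain/loss frequency tracks
  over the atomic intervals induced by all samples' breakpoints, and maximal
  regions aberrant in at least a proportion *p* (default 0.30) of samples,
  annotated with overlapping genes and cytobands.
- **Eight-index genomic complexity score.** A profile restricted to a
  region *R* (the genome, or one of 43 chromosome arms) is compressed into
  eight length-normalised indices — *var*, *steep*, *curv*, *dev*, *gain*,
  *loss*, *loh*, *asym* — capturing local variation, narrow shifts,
  oscillation, ploidy deviation and its gain/loss decomposition, loss of
  heterozygosity, and non-LOH allelic skewness.  Arm-wise scoring over the
  default layout yields 8 × 43 = 344 values per tumor.
- **Stratified comparison.** Two-group tests per score (Welch *t*, or
  Wilcoxon rank-sum when Shapiro-Wilk flags strong non-normality),
  optional OLS residualization on ploidy and aberrant cell fraction, and
  Bonferroni correction over the score family.
- **Copy-number/expression integration.** Per gene, the copy number of the
  segment at the gene midpoint is paired with log2 expression; *cis-genes*
  satisfy Pearson r > 0.4 **and** a significant (P < 0.05, uncorrected)
  loss-vs-normal or normal-vs-gain Welch test.  The smaller P is rescaled
  for display to Z = −F⁻¹(P) (so P < 0.05 ⇔ Z > 1.64).  Cis-gene lists are
  tested for gene-set enrichment (GMT input) with one-sided Fisher exact
  tests and Benjamini-Hochberg correction.
- **Synthetic cohorts with truth tables.** A generator emulating
  caller-style output: multimodal ploidy (2 / 3.5 / 5.5 by default),
  arm-level and focal events, oscillating focal-complex clusters, LOH and
  allelic asymmetry at configurable per-group rates, plus matched expression
  with planted cis effects — every injected event and true cis gene is
  recorded.

The core scoring model, for clipped segments *i* = 1..*n* in region *R*
with lengths *Lᵢ*, totals *cᵢ*, alleles *aᵢ* ≥ *bᵢ*, width *W* = Σ*Lᵢ*,
regional weighted median *m*, genome ploidy *P* and width cap *w₀* (3 Mb):

| index | formula |
|---|---|
| var (J1) | (1/W) Σ Lᵢ·\|cᵢ − m\| |
| steep (J2) | (1/W) Σ_adjacent \|c_{j+1} − c_j\|·min(L_j, L_{j+1}, w₀) |
| curv (J3) | (1/W) Σ_interior e_j·min(L_j, w₀), e_j the strict local-extremum magnitude of c_j |
| dev (J4) | (1/W) Σ Lᵢ·\|cᵢ − P\| |
| gain (J5) | (1/W) Σ Lᵢ·max(0, cᵢ − P) |
| loss (J6) | (1/W) Σ Lᵢ·max(0, P − cᵢ) |
| loh (J7) | (1/W) Σ_{bᵢ=0, cᵢ≥1} Lᵢ·(aᵢ − bᵢ) |
| asym (J8) | (1/W) Σ_{bᵢ≥1} Lᵢ·(aᵢ − bᵢ) |

with the identity J4 = J5 + J6.  See `docs/methods.md` for assumptions,
parameter choices and limitations.

## Worked example

Simulate a two-group cohort (a high-burden "TP53-mutated-like" stratum vs a
quieter wildtype-like one, 20 samples each), score every genome, and compare
the groups after adjusting for ploidy and aberrant cell fraction:

```python
from ascopy import (GenomeLayout, demo_specs, generate_cohort,
                    synthetic_gene_annotation, score_genome_wide,
                    scores_to_wide, compare_groups, pvals_to_z)

layout = GenomeLayout.default(include_y=False)
genes = synthetic_gene_annotation(layout, n_genes=300, seed=11)
cohort = generate_cohort(layout, demo_specs(n_per_group=20), genes,
                         cis_fraction=0.2, beta=1.0, noise_sd=0.5, seed=11)
scores = scores_to_wide([score_genome_wide(p) for p in cohort.profiles])
results = compare_groups(scores, cohort.metadata["TP53"],
                         covariates=cohort.metadata[["ploidy", "acf"]].astype(float))
for r in results:
    print(f"{r.score_id:14s} {r.test:8s} p_adj={r.p_adjusted:10.3g} "
          f"{'*' if r.significant else ''} ({r.direction})")
print("Z(0.05) =", round(pvals_to_z(0.05), 2))
```

Output:

```
genome.var     t        p_adj=   0.00146 * (mutated>wildtype)
genome.steep   t        p_adj=  3.56e-06 * (mutated>wildtype)
genome.curv    t        p_adj=   5.4e-06 * (mutated>wildtype)
genome.dev     t        p_adj=   0.00423 * (mutated>wildtype)
genome.gain    t        p_adj=   0.00423 * (mutated>wildtype)
genome.loss    t        p_adj=   0.00423 * (mutated>wildtype)
genome.loh     wilcoxon p_adj=     0.107  (mutated>wildtype)
genome.asym    wilcoxon p_adj=    0.0187 * (mutated>wildtype)
Z(0.05) = 1.64
```

The high-burden group shows significantly higher complexity on seven of the
eight genome-wide indices after Bonferroni correction (m = 8); each line
reports the test chosen by the normality gate, the adjusted P and the
direction of the difference.

The same pipeline runs from the shell:

```bash
ascopy simulate --out cohort --seed 11 --samples-per-group 12 --genes 150
ascopy run-all --segments cohort/segments.tsv \
    --expression cohort/expression.tsv --annotation cohort/annotation.bed \
    --metadata cohort/metadata.tsv --group-by TP53 \
    --covariates ploidy,acf --out results
```

which writes `calls.tsv`, `frequency.tsv`, `regions.tsv`,
`scores_genome.tsv`, `scores_arm.tsv`, `compare_*.tsv`, `cis_genes.tsv`
(and `enrichment.tsv` when a GMT is given) plus a `manifest.json` with the
configuration and per-stage row counts.  Subcommands (`call`, `recurrence`,
`score`, `compare`, `cis`, `enrich`) run each stage standalone.

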