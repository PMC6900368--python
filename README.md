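# kindredscope

Kindred analysis for familial hypercholesterolemia (FH): given annotated
exome variants, family genotypes with lipid phenotypes, a structural-variant
junction, and a multi-population SNP reference panel, determine which
variant configuration explains a family's LDL-C pattern and where a
deletion haplotype came from.

FH is dose-dependent: one deleterious *LDLR* allele produces the
heterozygous phenotype (LDL-C above the age/sex 95th percentile, population
mean ≈ 298 mg/dl), two alleles of the same gene — homozygous or in-trans
compound heterozygous — the severe homozygous phenotype (≈ 625 mg/dl).
`kindredscope` implements the four computational stages of that workup:

1. **Variant prioritization** (`kindredscope.prioritize`) — a filter cascade
   over ANNOVAR-style tables: drop silent/non-coding consequences, weakly
   supported calls (depth < 20), off-panel genes, and common variants
   (MAF > 1% in gnomAD/TOPMED/ExAC) — except variants whose pathogenicity
   predictor consensus is predominantly damaging, retained as flagged
   exceptions; survivors ranked by damaging-call fraction and meta-score.
2. **Cosegregation search** (`kindredscope.segregation`) — enumerate
   dominant, recessive, and same-gene compound-heterozygous models, score
   each pedigree member for consistency (heterozygous carriers under
   recessive/compound models are allowed the intermediate phenotype), and
   rank models by how completely they explain the affected set.  Affection
   is assigned from LDL-C (Friedewald LDL-C = TC − HDL-C − TG/5 where not
   measured directly; default cutoffs 190 mg/dl adult, 160 pediatric).
3. **SV junction & PCR screen** (`kindredscope.junction`) — deletion length
   from retained-base breakpoints, non-templated insert vs microhomology
   from a junction-spanning read, exact-match in-silico multiplex PCR, and
   band-pattern genotyping (wild-type band + breakpoint band → wt/del, etc.)
   with cohort tabulation.
4. **Haplotype ancestry** (`kindredscope.ancestry`) — reference-panel QC
   (drop tri-allelic, sex-chromosome, MAF < 0.05 sites), windowed LD pruning
   (plink `--indep-pairwise`-style), PCA projection of a query sample, and a
   phased-block population-of-origin posterior: per-site independent
   allele-frequency likelihoods with Laplace smoothing,
   P(hap | pop) = ∏ₛ (c + α)/(c_tot + 2α), softmax-normalized across
   populations.

Because patient-level data for such studies are protected, the package
ships a first-class synthetic generator (`kindredscope.simulate`):
Balding–Nichols SNP panels with a single differentiation knob F, Mendelian
pedigrees with a planted compound-heterozygous or consanguineous-homozygous
structure, genotype-dose LDL-C phenotypes, and allele sequences carrying
the junction insert and assay primer sites.  Two published worked-example
kindreds (summary tables only) are bundled under `kindredscope.datasets`.

## Worked example

```bash
python examples/02_cosegregation_search.py
```

```
affected members (LDL-C >= 190 mg/dl): 1-1, 1-2, 1-3, 2-1, 2-2, 2-3, 3-2, 3-3

exome variants only:
  best model: dominant_single(APOB:p.G230V) [APOB]
  explains all affected: False
  unexplained affected: ['1-3', '2-1', '2-2', '3-2']

with the structural deletion:
  best model: compound_heterozygous(LDLR:exon1del+LDLR:p.G592E) [LDLR]
  explains all affected: True
```

With exome variants alone no model covers the affected set — subject 1-3
(LDL-C 232 mg/dl) carries no plausible causal genotype.  Adding the
genotype column for the 2,977 bp promoter/exon-1 deletion (found by
whole-genome sequencing, invisible to the exome) yields a
compound-heterozygous *LDLR* model: the proband carries the missense allele
from her mother and the deletion from her father, and every heterozygous
relative's elevated LDL-C matches a single-allele state.

The other examples cover the filter cascade (8 candidates from the
proband's exome table, 2 of them frequency-rule exceptions), junction
arithmetic and the in-silico PCR screen (insert `TTCG`, bands 481/254 bp →
genotype calls), block-origin inference on a synthetic panel, and a full
seeded end-to-end run.  Each prints what it computes and what the numbers
mean.  A thin CLI (`kindredscope prioritize|segregate|pcr|genotype-bands|run`)
wraps the same entry points.

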