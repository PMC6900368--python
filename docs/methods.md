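# Methods

This note records the models, conventions, and numerical choices behind
`kindredscope`, and what the synthetic experiments do and do not establish.

## Coordinates, formats, and missingness

Genomic positions are 1-based and inclusive, and every breakpoint or variant
carries a genome-build tag (`hg19`/`hg38`); no liftover is performed, so
coordinates from different builds never mix silently.  Deletion breakpoints
are stored as the last retained base on the left and the first retained base
on the right; deletion length is therefore
`right_first_retained − left_last_retained − 1` (a junction insert is *not*
subtracted — it is extra, non-reference sequence).  This is the only
convention under which the worked example's printed breakpoint pair
(11,198,406 / 11,201,384, hg19) and printed length (2,977 bp) agree.

Missing table cells (`—`, `-`, `.`) parse to `None`, never 0.  The
distinction is load-bearing: a variant absent from every frequency database
is *novel* and must pass the frequency filter, while frequency 0 would be a
claim about observed data.  Genotypes are stored as the published tables
print them — unordered allele pairs (`GA`), slash-separated strings for
indels and structural alleles (`AGA/-`, `-/del`, `G/G` for a duplication
homozygote) — and interpreted against each variant's declared ref/alt
symbols, so `-` can denote the deleted allele of a deletion or the
reference allele of an insertion without ambiguity.

## Prioritization cascade

Stages run in fixed order: consequence → depth → gene panel → frequency.
Choices the published description leaves open:

* **Depth boundary**: "low read depth (>20)" is read as *keep* depth ≥ 20
  (the parenthetical describes the retained class); configurable.
* **Frequency aggregation**: the maximum observed frequency across the
  configured databases — the most conservative reading of "common".
  The cutoff itself is exclusive at the keep side (`max AF < 0.01` keeps).
* **Predictor vocabulary**: `D`, `H`, `M` count as damaging; `T`, `B`, `P`,
  `L`, `N` as non-damaging (`P` = possibly damaging deliberately counts
  against, keeping the exception rule strict); `U` (undetermined — LRT's own
  output vocabulary) is an *abstention* and leaves the denominator.  With
  `U` counted as benign, the worked example's LCAT variant (4 damaging of
  9 calls) would miss the 0.5 exception threshold that its published
  retention implies; treating `U` as an abstention (4 of 8) is both truer to
  the predictor's semantics and consistent with the worked example.
* **Unscoreable variants**: a common variant that *no* predictor scores
  (typical for in-frame indels) cannot be dismissed as benign and is
  retained as a flagged exception (`uncalled_is_damaging=True`,
  configurable).  The worked example's SPTY2D1 p.K107del row requires this.
* **Ranking**: damaging-call fraction (descending), then meta-score, then
  genomic coordinate.  Unscored variants rank after scored ones.

The per-stage trace satisfies, and tests verify, a conservation law:
`removed + retained = input` at every stage.

## Cosegregation model semantics

Affection is binary (affected/unaffected/unknown) from LDL-C against a
cutoff rule.  The published age/sex-adjusted 95th-percentile tables are not
reproduced anywhere we can consume, so the default is a fixed 190 mg/dl
adult, 160 mg/dl pediatric cutoff with a pluggable `(age, sex) → cutoff`
table.  The bundled kindred files carry no ages (the source tables print
none), so the adult cutoff applies there throughout.

Per-member consistency:

* **dominant**: carrier ⇔ affected.
* **recessive**: homozygous-alt must be affected; heterozygous carriers are
  unconstrained (FH heterozygotes are phenotypic — the intermediate class);
  affected non-carriers are inconsistent.
* **compound heterozygous** (two distinct variants, one gene): in-trans
  double carriers must be affected; single carriers unconstrained; affected
  carriers of neither are inconsistent.  Trans/cis phase is resolved from
  parental genotypes (a variant is paternal if exactly the father carries
  it); unresolvable pairs are flagged phase-ambiguous and rank below phased
  explanations.  A cis double carrier is treated as a single-allele carrier.

Ranking key: explains-all-affected, then *inhabited causal class* (a
recessive model with no affected homozygote, or a compound model with no
affected double carrier, explains no severe case and ranks below any model
whose causal class is inhabited), then phased before ambiguous, then fewer
inconsistencies, fewer variants, lexical gene order.  Without the
causal-class rule a vacuous recessive model — every member heterozygous,
nobody homozygous — could outrank all dominant models on a pedigree it
explains nothing about; the rule is what makes the exome-only search
correctly report the deletion-carrying brother as unexplained.

Ties that remain (e.g. a family where every member carries at least one
allele, so dominant and recessive fit equally) resolve by enumeration
order; binary affection cannot distinguish them, and the package does not
pretend otherwise.

## Junction characterization and the PCR screen

A junction read must anchor with ≥ 10 exactly matching bases on each flank.
Bases between the anchors belonging to neither flank are the non-templated
insert.  Microhomology — the longest exact overlap between the left flank's
terminus and the right flank's start — is computed from the flanks and
reported only for insert-free junctions; insert and microhomology are
mutually exclusive descriptions of the same junction.

In-silico PCR is exact string matching on both strands (no mismatch
tolerance, no thermodynamics): the screen's logic needs presence/absence of
a priming site, not amplification efficiency.  Product size spans the
forward primer's 5′ start through the reverse primer's 5′ start, inclusive;
products above `max_product_bp` (default 2,000) are suppressed, which is
what keeps the breakpoint-flanking pair silent on the wild-type allele
(its sites sit ~3.2 kb apart there).  Band → genotype calls use a ±10 bp
matching tolerance as a gel-resolution proxy; the default assay constants
(481 bp wild-type band, 254 bp breakpoint band) mirror the published assay.
The real product sizes depend on reference sequence not reproduced here, so
synthetic alleles plant the primer sites at offsets that realize those
sizes exactly.

## Reference panel and block-origin model

Panel QC drops multi-allelic sites, sex-chromosome sites, and sites with
pooled MAF < 0.05 (exactly 0.05 is retained — the published rule discards
strictly below).  LD pruning is windowed pairwise r² on dosages (defaults
1000/5/0.5); when a pair exceeds the ceiling the *later* site in position
order is dropped — a deterministic rule, where the reference tool's internal
choice is unspecified.  Monomorphic sites contribute r² = 0.  PCA centers
dosages at 2p and scales by √(2p(1−p)) with per-site mean imputation of
missing dosages; queries are standardized with the panel's statistics and
projected onto the panel's SNP loadings.

The block-origin model treats pruned sites as independent.  Per population
k, P(hap | k) = ∏ₛ (c + α)/(c_tot + 2α) with allele counts c (or frequency ×
a nominal 100 chromosomes when only frequencies are known) and Laplace
α = 0.5; posteriors are the softmax of log-likelihood + log-prior (uniform
prior by default), computed with max-subtraction.  The *observation* for a
phased block is its genotype — both haplotypes, conditionally independent
given the population — summed in `phased_block_loglik`.  This matters
quantitatively: with 100-site blocks across six populations at F_ST 0.05,
single-haplotype scoring is capped near 81% top-1 recovery even with the
exact generating frequencies (a Bayes-optimality measurement, reproduced in
the test suite's conditions), whereas genotype scoring reaches 92–97%.
The functional form, α, and prior are this package's choices, documented as
such; they are configurable and are not claimed to be the original study's
unpublished model.

## Synthetic generators

The generators reproduce the statistical structure the analysis assumes,
not real genomes:

* **Panel**: Balding–Nichols — ancestral p ~ U(0.05, 0.95), population
  frequency ~ Beta(p(1−F)/F, (1−p)(1−F)/F), genotypes Binomial(2, freq).
  One differentiation knob, no LD, no recombination map, no mutation model.
  Conclusions from it speak to frequency-based discrimination only; real
  panels have LD that pruning only partially removes.
* **Pedigrees**: Mendelian transmission, one allele per parent per locus.
  The `kindred1-like` structure forces the designated proband to be the
  family's single compound heterozygote (deletion paternal, missense
  maternal), with siblings' draws conditioned on that configuration; the
  `kindred2-like` structure forces two homozygous children of two
  heterozygous parents (a consanguineous loop represented by a shared
  founder allele).  These constructions guarantee the planted configuration
  at any seed — they emulate a *given* family, not family sampling.
* **Phenotypes**: LDL-C ~ Normal(mean(dose), sd) truncated at zero, class
  means 130/298/625 mg/dl for 0/1/2 deleterious alleles (the latter two are
  the classic clinical means for heterozygous and homozygous FH; the
  non-carrier mean and sd = 40 mg/dl are this package's choices).  HDL-C and
  TG are drawn from unremarkable ranges and TC is back-computed so the
  Friedewald identity holds exactly.  With sd = 40 a non-carrier exceeds the
  190 mg/dl cutoff with probability ≈ 0.07, so synthetic pedigrees
  occasionally contain a phenocopy — deliberate, and the segregation search
  degrades gracefully (the planted model still ranks first by inconsistency
  count).
* **Sequences**: random-base flanks and deleted interval with primer sites
  planted at offsets realizing the assay's product sizes; the deleted allele
  joins the flanks around the junction insert (default `TTCG`).

All generators are driven by integer seeds through numpy `default_rng`;
fixed seed ⇒ byte-identical output, verified by tests.

## Problem sizes and verification

The test suite and acceptance script run on deliberately small instances:
panels of 300–500 sites and ≤ 6 populations, 200-replicate recovery
experiments, pedigrees of 5–12 members, cohorts of up to 641 synthetic band
patterns.  These sizes make every oracle check exhaustive (all-pairs r²
verification, brute-force re-filtering, full model enumeration) while the
whole suite completes in seconds.  Oracles are independent re-statements of
each postcondition, not calls into the code under test.

## Known limitations

* Binary affection discards the severity signal that distinguishes
  homozygous from heterozygous FH; a two-tier rule would sharpen model
  ranking but the published percentile tables needed to calibrate it are
  not available.
* No formal linkage (LOD) statistics; the search reports consistency
  accounting, not significance.
* The block-origin model ignores residual LD between pruned sites and
  admixture; it ranks candidate source populations, it does not estimate
  admixture proportions.
* In-silico PCR's exact matching will miss primer sites disrupted by
  common SNPs; real assay design should check variant databases.
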