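# Methods

## Scope and design

The package re-creates a population-screening analysis over a
three-ancestry Asian cohort as a library of small, testable stages wired
together by `pipeline.run_pipeline`. Real inputs of this kind (joint
genotypes, VEP annotations, ClinVar evidence, ADMIXTURE/RFMix output,
duphold-annotated SVs, star-allele diplotypes) are access-controlled or
produced by external tools, so the first-class `synthetic_cohort` module
generates all of them from a seeded configuration with planted ground
truth. Everything the tests assert about recovery is therefore a statement
about the pipeline's correctness on data whose answer is known — not about
any real cohort.

## The synthetic cohort

**Cohort structure.** Defaults follow the study conditions: 5502 Chinese
(CH), 1941 Indian (IND) and 1608 Malay (MY) individuals (9051 total),
57.3% female, ages uniform on 0–85. Each individual has a "planted"
ancestry that defines the frequency stratum their genotypes are drawn from.

**Admixture model.** Q vectors (K = 3) come from a two-component mixture.
"Pure" individuals assign 1 − ε to their planted component with
ε ~ Beta(1, c), c = `admixture_concentration` (default 5; redrawn in the
rare case ε ≥ 0.5 so the planted component stays the argmax). Admixed
individuals (fraction `fraction_admixed`, default 0.10) receive a
secondary component ~ U(0.25, 0.5) and a third ~ U(0, 0.15). Admixed
individuals self-report their secondary ancestry with probability 0.3.
These three dials were fixed once so that the emergent summary statistics
echo the published cohort: ~3% of individuals are R/E-mismatched, the
mismatched group's median maxQ is ~0.55–0.58 against ~0.87 for the matched
group, and an admixed tail exists for the lowest-quartile enrichment test.
At `fraction_admixed=0` and high concentration (e.g. 500) every maxQ
exceeds 0.95, which the generator's tests pin down.

**Local ancestry.** One 250-Mb autosome is split into 40 equal blocks per
haplotype; each haplotype's block labels are quota-sampled from the
individual's Q vector (largest-remainder apportionment, then a seeded
shuffle) and merged into msp-style segments. Quota sampling guarantees the
per-genome ancestry dosage matches Q to block resolution (≤ 1/80), well
inside the ±0.05 consistency bound the tests enforce. There is no
recombination map, LD, or chromosome structure — deliberately: the
downstream logic consumes segment labels, not haplotype realism.

**Genotypes.** Each planted gene carries one recurrent variant with
per-ancestry carrier frequency f taken from the study's burden tables.
Genotypes are Hardy–Weinberg within ancestry at allele frequency
p = 1 − √(1 − f), so the probability of carrying ≥1 allele is exactly f
and the at-risk-couple expectation f² is exact rather than approximate.
X-linked genes use carrier probability f for males (hemizygotes written as
homozygous diploid calls; the sample table carries sex) and HWE for
females. Every call gets AD/DP/GQ: DP ~ max(Poisson(32), 10), het alt
reads ~ Binomial(DP, ½), GQ ~ U{60..99}. A 0.5% rate of spurious
heterozygous calls with failing metrics (allele balance 0.08 or GQ 12) is
injected on reference individuals; the recorded carrier truth is computed
*after* applying the same re-qualification rule the pipeline uses, so
truth recovery fails if QC is skipped.

**Planted analysis targets.** Besides the per-gene recurrent variants the
generator plants: ancestry-specific variants placed only on haplotypes
whose local-ancestry block matches (with a configurable number of
discordant carriers drawn from individuals of other assigned ancestries
holding ≥10% of the variant's ancestral component — cryptic admixture);
ClinVar-evidence hotspots (three TwoPlus P/LP anchors in a 25-bp window,
with and without benign majorities, plus resident missense VUS at
controlled REVEL scores); one exemplar of every classifier branch
(conflicting records at 2 and 5 P/LP submissions, a novel SNV reproducing
a known amino-acid change, PVS1- and downstream-anchored LOF variants on
both strands, a TTN truncation, an in-frame frameshift pair, an in-cis
P/LP pair, a benign record, a retention-filter casualty); duphold SV
records crossing each filter threshold; and per-gene pharmacogene allele
frequencies from which diplotypes are drawn independently (HWE), with
analytic phenotype expectations recorded in the truth file.

**Determinism.** All randomness flows through one `numpy` Generator seeded
from the config; identical configs give byte-identical bundles (tested via
SHA-256).

## Statistical choices

- **Fisher exact test**: two-sided p from `scipy.stats.fisher_exact`;
  odds ratio is the conditional MLE with exact CI
  (`scipy.stats.contingency.odds_ratio`). Tests cross-check p against full
  hypergeometric enumeration (1e-10) and the OR against direct
  noncentral-hypergeometric likelihood maximisation.
- **Wilcoxon rank-sum**: exact null for tie-free samples with ≤25 pooled
  observations, otherwise the normal approximation with tie correction
  (`scipy.stats.mannwhitneyu`); validated against exhaustive rank
  enumeration and a 10,000-replicate type-I-error simulation.
- **Benjamini–Hochberg**: `statsmodels` step-up with monotonicity, applied
  per emitted comparison table (the family is whatever one analysis table
  contains, and is recorded alongside the adjusted values). Note that BH
  adjusted p-values are *not* idempotent in general — re-adjusting
  [0, 0.75, 1] gives [0, 1, 1] because the m/i rank weight re-inflates
  interior values; the tests demonstrate this and assert idempotence only
  on fixed-point inputs (m = 1, tied vectors).
- **Rounding**: reported percentages round half-up to the printed
  precision (2 d.p. for carrier frequencies and prevalences, 1 d.p. for
  PGx fractions, whole percent for the panel-gap fraction).

## Rule-engine conventions

Decisions the sources leave open, fixed here and configurable:

- Allele-balance bounds are inclusive ([0.20, 0.80] passes).
- The retention AF threshold is strict (< 0.05), the REVEL and SpliceAI
  thresholds strict (> 0.7, > 0.8), pLI strict (> 0.9), carrier-frequency
  panel-gap threshold strict (> 0.5%).
- Hotspots are computed on genomic coordinates at 1-bp steps from variant
  start positions; ">2" is implemented as ≥3; benign/likely-benign
  counts require TwoPlus review status (configurable).
- "Downstream" for the Tier1B anchor rule means greater transcript-oriented
  coordinate: larger genomic position on "+" genes, smaller on "−".
- Conflicting records with 1–3 P/LP submissions and TTN truncations cannot
  be automated faithfully (the original calls used expert curation and a
  dedicated cardiac classifier); they are emitted as VUS with a
  manual-review flag, and `classify_all` accepts an override table of
  final calls so the pipeline stays total.
- Close-proximity frameshift pairing uses a 30-bp window (the original
  inspection was visual and distance-free).
- Multi-allelic decomposition is assumed done upstream (the generator only
  emits biallelic records); an optional kinship check rejects cohorts
  shipping a related pair (KING ≥ 0.0884).
- Virtual mating is within-ancestry and sex-blind; X-linked genes are
  excluded from the severe-recessive panel. Two exclusion-listed variants
  in the same partner are treated as potentially in trans (conservative).
- Quartile membership for the enrichment test takes the ⌊n/4⌋ lowest maxQ
  individuals within each ancestry (stable ties), pooled into one 2×2;
  a per-ancestry breakdown is emitted alongside.
- The ADMIXTURE `.Q` file is headerless; component order is fixed CH, IND,
  MY end to end.

## PGx rule table

`data/pgx_phenotype_rules.tsv` is a synthetic stand-in modelled on CPIC
function-pair semantics (and editable precisely because CPIC guidance
versions over time): a generic metabolizer map (UM/RM/NM/IM/PM over
increased/normal/decreased/no function) with gene-specific overrides —
CYP2D6 treats normal+decreased as NM (activity-score style), UGT1A1
escalates decreased-function pairs to PM, CYP3A5 inverts actionability
(expressers are the actionable group), SLCO1B1 and VKORC1 use risk
categories. "Actionable" means any phenotype whose flag is set, per gene.

## Problem sizes

The default configuration is the full study scale (9051 individuals,
~70 planted variants), which generates and analyses in a few seconds.
Parameter-recovery tests run at n = 2000 in study proportions with the
ancestry-specific plants scaled down so absolute allele counts do not
distort gene-level frequencies; recovery is asserted within 99% binomial
envelopes (Bonferroni-corrected across cells where many are checked), and
the at-risk-couple f² checks use dedicated one- and two-gene bundles per
the closed-form expectation.

## Limitations

The synthetic severe-recessive panel holds about a dozen genes against the
original 1,300, so the absolute ARC rates it produces (~0.3–1% by
ancestry) are partial sums, comparable in structure but not in value to a
full-panel estimate. No LD, realistic mutation spectra, read-level noise
beyond the injected QC failures, CNV breakpoint realism, or star-allele
calling (diplotypes are consumed as input). Passing truth-recovery tests
demonstrates the pipeline's rules are implemented exactly, not that the
generator reproduces the genetic architecture of any real population.
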