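# Methods

## The genetic model

The pipeline targets autosomal-dominant inheritance of a rare heterozygous
variant in a multiplex family: one founder introduces the variant, every
transmission to a child is an independent fair coin, married-in spouses are
non-carriers (a rare variant has a single origin per family) and there are no
de novo events. Phenotype is conditionally independent of everything else
given carrier status: carriers are affected with probability `penetrance`,
non-carriers with probability `phenocopy_rate`. "Affected" means
histologically confirmed disease; relatives with symptoms but no endoscopy
are recorded as `unknown` and excluded from concordance scoring rather than
treated as unaffected, since they may simply be undiagnosed. Only autosomal
variants are modeled (the genes of interest, *DSP* on chromosome 6 and *PPL*
on chromosome 16, are autosomal); sex is recorded but plays no role in
transmission.

## Variant filtering

Genotype QC reads the thresholds as follows: depth and genotype quality are
exclusive (a call must *exceed* 15 reads and GQ 20), the heterozygote
allele-ratio band 0.30–0.70 is inclusive at both ends, and the homozygote
bounds (< 0.15, > 0.85) are exclusive. A call whose allele ratio falls
outside its called genotype's band is set to missing
(`ratio_genotype_mismatch`) rather than re-called: the QC stage validates the
caller's output, it does not invent genotypes. QC failures are per genotype;
a variant survives as long as one informative call remains.

Rarity requires every *present* European-ancestry reference MAF (1000
Genomes, ESP, ExAC) to be < 0.001 and the internal-cohort MAF, when present,
to be < 0.01. Absent MAFs count as zero — a variant unseen in a reference
population is rare there by construction, and several of the qualifying
variants in this design are absent from ExAC entirely. Deleteriousness is a
consensus over ten categorical prediction calls (SIFT, PolyPhen2-HDIV/HVAR,
LRT, MutationTaster, MutationAssessor, FATHMM, CADD, RadialSVM, LR) consumed
as precomputed annotations: damaging in at least one algorithm qualifies
(configurable), and protein-truncating consequences qualify unconditionally
because missense-oriented predictors do not score them. Conservation flags
(PhyloP, SiPhy, GERP++) are carried as descriptive annotations, not used as a
filter. Per-algorithm score cutoffs are upstream of this package; it consumes
calls, not scores.

## Segregation and concordance

Discovery co-segregation requires every genotyped affected member to carry
the variant. Unaffected carriers do not break co-segregation — under
incomplete penetrance they are expected — but they are counted and reported.

Replication concordance scores first-degree relatives of each proband:

* each genotyped sibling with a known phenotype is one unit, concordant iff
  affected ⇔ carrier;
* the parents collapse into one dyad unit. If only one parent is genotyped,
  the other's carrier status is inferred as the complement (the proband is
  heterozygous and the variant has one origin). With at least one affected
  parent, the dyad is concordant iff carrier status matches affection for
  both parents; with neither parent affected, it is concordant iff exactly
  one parent carries (the unaffected transmitting parent is the only
  carrier — two carriers, or an affected non-carrier, are discordant). The
  dyad rule has no unique canonical form; this one treats "phenotype
  predicts genotype" parent-by-parent and is the package's documented choice.

The chance null gives every unit probability ½ of concordance, so the
reported P is the exact one-sided binomial upper tail; a two-sided option
(doubled smaller tail, capped at 1) is exposed but one-sided is the default
because the hypothesis is directional. The tail is computed with exact
integer binomial coefficients up to n = 1000 and in log space beyond, stable
past n = 10,000.

The replication cohort shipped in `eoefam.datasets` is a **synthetic
reconstruction**: the individual-level genotypes behind the published summary
(78.3% concordance, P = 0.005) are access-restricted, and 18 concordant of
23 units is the unique small-integer pair consistent with both printed
values (78.26% → 78.3%; 0.00531 → 0.005). The shipped families realize
exactly those units through `score_concordance`; they are inputs to the
statistic, not outputs of it.

## Burden tests

All burden tests are 2×2 tables: two-tailed Fisher's exact P under the
probability-mass rule (tables as or less probable than the observed one),
odds ratio (a·d)/(b·c) with the Haldane–Anscombe +0.5 correction when a cell
is zero, and the Pearson chi-square without continuity correction. Fisher and
the chi-square go through scipy; the test suite checks Fisher against an
exhaustive margin-preserving enumeration in exact rational arithmetic.

The allele-level test counts two alleles per subject per gene (het = 1 minor
allele, hom-alt = 2) and treats alleles as independent observations. That is
the published construction and is reproduced as such; it ignores
within-subject dependence and should not be read as a statistical
recommendation. Missing genotypes contribute major alleles with a warning by
default (configurable to drop the subject). Control counts (ExAC allele
counts, UK Biobank carrier counts) are inputs, not recomputed: which control
variants qualify depends on the external database version, so the package
takes the published counts as given. The desmosome gene set (GO:0030057, 25
symbols) ships as an editable list because GO membership is
release-dependent; only the membership of the primary genes affects any
number computed here.

## Phenotype scores and assays

EoEHSS features are totalled as grade + stage (0–6); group ratios divide the
summed totals of the evaluated features in a group by 6 × (number of
evaluated features), so unevaluated features (for example LPF when the biopsy
contains no lamina propria) leave both numerator and denominator. Activity
classes: active ≥ 15 eos/hpf; inactive < 15 with disease history; control
≤ 2 without history; the uncovered region (3–14 without history) is labelled
`indeterminate` explicitly instead of being forced into a class. The EI grade
is mapped from peak eosinophil counts through configurable bin edges
(default 15/30/60). ΔCT = CT(gene) − CT(GAPDH), accepted only when GAPDH
CT < 30; group fold changes are 2^(mean ΔCT_B − mean ΔCT_A). Assay formulas
(wound closure, protein remaining, total protein vs non-variant mean,
corrected total fluorescence) are direct arithmetic on pre-measured inputs;
negative corrected fluorescence is retained with a `low_signal` flag rather
than clipped.

## The simulator

`SimConfig` defaults describe the study conditions the pipeline assumes:
three-generation families, penetrance 0.8 (dominant with carriers who remain
unaffected), phenocopy rate 0.05 (general-population EoE prevalence is far
lower, but relatives in multiplex families share environment and background
risk), mean exome depth 60× with negative-binomial overdispersion
(dispersion 8), heterozygote alternate-read fraction 0.5, sequencing error
0.005 folded into the alternate-read probability, GQ ~ Normal(60, 15)
truncated at zero, and mean 2.2 children per couple. Depth is
negative-binomial because exome coverage is overdispersed relative to
Poisson and one dispersion knob suffices. Families are rejection-sampled to
contain at least two affected members (multiplex ascertainment), capped at
200 attempts so that degenerate configurations (penetrance and phenocopy
both zero) still return; no further ascertainment correction is modeled.
Cohorts are joint-called: every sample receives a call at every family
variant (hom-ref truth outside the variant's own family), which is what
makes the written VCF round-trip the in-memory cohort exactly. Neutral decoy
variants are gene-dropped through the pedigrees (founder allele counts
binomial in the MAF, children inherit one allele per parent), so the entire
truth layer is Mendelian-consistent by construction.

The *unlinked-variant* null used in testing sets penetrance = phenocopy = 0.5
with multiplex conditioning off. Conditioning must be off because requiring
two affected members skews parental phenotype patterns and biases the
parent-dyad null below ½ even when genotype and phenotype are independent;
with conditioning off, every scoring unit is concordant with probability
exactly ½ and the concordance statistic is a calibrated fair coin.

What the simulator does **not** emulate: linkage disequilibrium and
haplotype structure, batch effects and mapping artifacts in coverage,
relatedness-aware joint genotyping errors, non-Mendelian events (de novo
variants, uniparental disomy), X-linked inheritance, and realistic
ascertainment beyond the ≥ 2-affected condition. Passing tests therefore
show the pipeline's logic and statistics are correct under the stated model,
not that the model captures every property of real exome cohorts.

## Numerical and size choices

Fisher P values on the published tables are exact and fast (< 1 s). Property
tests use 1,000 random tables (total ≤ 40) against the enumeration oracle,
the full k ≤ n ≤ 50 grid against the rational binomial oracle (12
significant digits), 1,000 random variants against an independently coded
filter-predicate oracle, ≥ 10,000 transmissions for the fair-coin check and
500 simulated replicates for the null-concordance check — sizes chosen to
keep Monte-Carlo standard errors small (3-SE acceptance bands) while the
whole suite runs in seconds on one CPU.
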