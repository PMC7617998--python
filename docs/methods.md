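# Methods

This note documents the statistical model behind `modyburden`, the default
parameters and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical conventions that matter when
reproducing results.

## Study design being modeled

The framework targets a two-cohort design for a dominant, genetically
heterogeneous disease: a clinically ascertained case cohort sequenced on a
targeted panel (default n = 2,571) compared against a biobank-scale,
genome-sequenced population control cohort (default n = 155,501), with an
aggregate reference database (gnomAD-style per-population AC/AN) supplying
external allele frequencies. Evidence for or against a gene–disease
relationship combines four strands: carrier burden enrichment, pedigree
co-segregation, population-frequency credibility, and design power.

## Quality control

QC operates at three levels with three mode profiles:

| rule | threshold | modes |
|---|---|---|
| FS (strand-bias Phred p) | fail if > 60 | all |
| QD (confidence/depth) | fail if < 2 | all |
| ReadPosRankSum | fail if < −8 | all |
| MQRankSum | fail if < −12.5 | all |
| MQ | fail if < 40 | all |
| AAscore (Graphtyper TP probability) | fail if < 0.5 | wgs |
| low-complexity region flag | fail | wgs, gnomad |
| low-coverage region flag (≤10× in ≤80% of samples) | fail | gnomad |
| excluded regions (e.g. chr12:120994310–120994335) | fail | all |
| genotype depth | fail if < 20 (panel) / < 15 (wgs) | per genotype |
| genotype quality | fail if < 20 | per genotype |
| allelic balance (het) | fail if binomial p < 0.001 | per genotype |
| per-sample missingness | remove if > 2% (strict) | per cohort |
| per-variant call rate | remove if > 2% missing (strict) | per cohort |

Conventions worth stating:

* An absent site metric is non-evaluable: the rule is skipped with a
  warning, never failed. Aggregate-reference records lack caller
  internals, and failing them wholesale would discard the cohort.
* The "missingness > 2%" rule is implemented both per sample and per
  variant; the pipeline applies the per-sample filter first, then the
  per-variant call-rate filter (genotypes removed by genotype-level QC
  count as missing calls for the call-rate).
* Harmonization is symmetric: a variant failing in either cohort is
  removed from both; absence from a cohort is not failure.
* All interval checks are 1-based and closed; BED input is converted on
  read.
* QC is idempotent and its reason lists are sorted, so results are
  independent of evaluation order.

## Variant classes and NMD escape

Classes are disjoint: PTV (stop-gain, frameshift, splice-site), damaging
missense (REVEL strictly greater than 0.7 — a score exactly at the cutoff
does not qualify), synonymous (the calibration class). A missense record
without a REVEL score cannot be assessed and is classed `NONE` with a
warning rather than raising. Consequence terms and REVEL scores are
consumed as annotations, never computed; in particular a record labelled
`splice_site` is trusted as a canonical splice-site PTV as emitted by the
annotator — the package does not re-derive splice positions.

A PTV escapes nonsense-mediated decay when its truncation lies in the last
coding exon, within the final 50 coding bases (inclusive) of the
penultimate coding exon, or anywhere in a single-exon gene. The window is
measured in coding-sequence bases along the transcript (strand-aware), not
genomic bases, because the rule is transcript biology: NMD requires an
exon-junction complex downstream of the stop. Splice-site PTVs, which sit
in introns, take the NMD status of the downstream coding exon they
disrupt; this is a documented convention, and a boundary case (a splice
variant "assigned" to the penultimate exon) is treated as disrupting the
whole exon, i.e. not inside the 50-bp window.

## Burden test

The counting unit is the carrier (an individual with ≥ 1 qualifying
variant counts once), matching the dominant-disease model. The test is the
two-sided Fisher exact test on the 2×2 carrier table; the effect size is
the sample odds ratio with a Woolf log-OR 95% CI, with 0.5 added to every
cell (Haldane–Anscombe) whenever any cell is zero. A table with no
carriers in either cohort is degenerate: p = 1 and the OR is undefined.
Significance uses the printed Bonferroni threshold α = 0.002 (0.05 over
6 genes × 3 classes) rather than the slightly different 0.05/18, to match
the design it reproduces.

The ultra-rare filter keeps variants with frequency strictly below the
threshold (primary 1e-4; sensitivity tiers 5e-5 and 2e-4; PTVs also get a
no-threshold tier, and a MAC = 1 tier restricts to singletons). The
frequency source is configurable: the control cohort, or the external
reference AC/AN carried on each record. The pipeline defaults to the
external reference because a control cohort of n individuals cannot
resolve frequencies below 1/(2n) — at the scaled demo size every
control-observed variant would otherwise exceed the 1e-4 threshold. The
MAC = 1 nesting property (singletons are a subset of every MAF tier) holds
when MAC and MAF are measured on the same cohort, which is how the tests
exercise it.

Region scopes: `in_domain` requires a protein position inside an annotated
domain (closed endpoints); `out_domain` is its exact complement (including
variants without a protein position), so the two scopes partition every
qualifying set and carrier counts add — a conservation law the tests
assert. `nmd_escape_only` inverts the primary NMD policy and keeps exactly
the escape PTVs.

### Calibration of the null

Under the generating null (all odds ratios 1) the suite's rejection
fraction at p < 0.05 is *below* 0.05, not equal to it: with ultra-rare
carrier frequencies the expected case carrier count is of order one, the
2×2 tables are extremely discrete, and the exact Fisher test is
conservative (measured empirical size ≈ 0.01–0.03 under the default
conditions). The meaningful calibration claim — and the one the tests
assert — is one-sided: no inflation above the nominal level. A synonymous
track whose rejection rate *exceeded* nominal would indicate technical
artifact; a rate below nominal is the expected behaviour of the exact test.

For the same reason the Wald power approximation overstates the power of
the exact test by several percentage points at moderate expected counts
(15–60 carriers); the two routes converge (within ~2 points) only when
expected counts reach the hundreds. The simulation route is therefore the
default and the Wald route is an upper-bound approximation used for fast
grid searches (`detectable_or` bisects it by default in the tests).

### Parameter recovery

With a single-exon gene generated at control carrier frequency 1.2e-4 and
odds ratio 21 (2,571 vs 155,501), the Woolf 95% CI covers the generating
truth at nominal rate (measured 95.4% over 500 replicates), and the median
estimated OR falls inside the 8–49 interval such a design prints. The
1.2e-4 default was derived from the design itself: it is the control
carrier frequency at which the expected Woolf interval width under OR 21
matches an 8–49 CI at these cohort sizes.

## Co-segregation evidence

**Eligibility.** A family contributes only if it shows at least four
informative co-segregations and the variant's population frequency is
strictly below 1/1500 — common variants co-segregate by chance and
confound the analysis.

**LOD.** An informative meiosis is a parent→child transmission where the
parent is an *observed* carrier and the child has an observed genotype and
known affection status. Matings with two carrier parents are
phase-ambiguous and skipped; ungenotyped connectors are never imputed as
obligate carriers (conservative: only observed genotypes count). A meiosis
is concordant when genotype matches phenotype. With R concordant and X
discordant meioses the score is the maximized two-point LOD treating the
phenotype as a fully penetrant marker locus:

    LOD = max(0, R·log10(2(1−θ̂)) + X·log10(2θ̂)),  θ̂ = X/(R+X)

reducing to M·log10 2 when all M meioses are concordant, and to 0 when no
meiosis is informative. Scores from independent families add. The test
suite validates this engine against a full transmission-pattern
enumeration oracle (summing over carrier-state assignments of
unknown-genotype members) on fixture pedigrees.

**Binomial tests.** Co-segregation: carriers among affected, genotyped
members against an expected proportion of 0.5. Non-penetrance: carriers
among unaffected, genotyped members aged ≥ 25 against a 10% tolerance
threshold; individuals of unknown age are excluded because the age gate
cannot be certified, and the age filter applies only to the non-penetrance
test. Both use the minimum-likelihood two-sided convention: the p-value
sums the probabilities of all outcomes no more probable than the observed
one (for a 0.1 null this correctly gathers lower-tail outcomes as well).
This convention reproduces, at printed precision, the nine verifiable
published p-values the acceptance suite checks. Two published values
(1.64e-10 for 34/34 and 9.57e-7 for 21/21) do not match exact
recomputation under any standard two-sided convention (exact values
1.16e-10 and 9.54e-7); they are documented exclusions, most plausibly
typographic.

## Frequency credibility and power

The maximum credible allele frequency for a fully monoallelic disease is

    AF_max = prevalence × max_allelic_contribution × max_genetic_contribution / (2 × penetrance)

with prevalence defaulting to 248 per million (MODY) and penetrance to
0.5. The allelic and genetic contributions have no hidden defaults — they
must be supplied, because they are judgments about disease architecture.
With allelic contribution 0.2 the bound is 4.96e-5 per individual, about
seven occurrences among 141,456 reference individuals; this
parameterization reproduces the published "no more than seven times"
bound, but the pairing is a reconstruction (per-individual rather than
per-allele frequency, implied allelic contribution ≈ 0.2) and is
documented rather than asserted. `max_tolerated_ac` offers a `point` mode
(rounded expectation) and a `poisson95` mode (Garwood exact lower-bound
inversion).

Power for the carrier Fisher design: control carrier probability is 2×MAF
by default (heterozygote approximation; configurable to MAF), case odds
are OR × control odds, carrier counts are binomial, and power is the
rejection fraction over n_reps = 10,000 seeded replicates (Fisher p-values
are cached over distinct count pairs, which makes the simulation cheap).
The alpha for the power statements is 0.05, the conventional choice where
the design text leaves it unstated. `detectable_or` bisects the monotone
power curve to an OR resolution of 0.05.

## Synthetic-data generator

The generator is the study's stand-in for real cohorts and defines the
conditions every stochastic test runs under:

* **Gene models** are deterministic given the spec: near-equal exons,
  fixed 500-bp introns, fully coding exons, one contiguous domain placed
  centrally or at the 3' end. The default six-gene set comprises a
  high-penetrance positive control (PTV OR 80), a low-penetrance control
  (PTV OR 6), a single-exon gene (PTV OR 21 at carrier frequency 1.2e-4 —
  the parameter-recovery benchmark), a two-exon gene with a 3' domain
  covering 22% of the protein, and two null genes (all ORs 1). Synonymous
  classes are null everywhere; baseline aggregate carrier frequencies are
  in the 3e-5–4e-4 range typical of ultra-rare class aggregates.
* **Cohorts.** Each class's aggregate frequency is split evenly across its
  variants (default 6). Control carrier counts are Binomial(n, f); case
  counts are Binomial(n, f′) with the class OR applied on the odds scale.
  Within a gene each individual carries at most one variant (the
  multi-variant carrier path is exercised by dedicated unit tests
  instead), so carrier counts add across disjoint variant sets. Site and
  genotype metrics are drawn from fixed benign distributions — only
  threshold-crossing matters to QC — and artifacts are injected at
  configured per-filter rates (defaults: FS 1%, QD 1%, low-complexity 1%;
  genotype DP 1%, GQ 1%, allelic balance 0.5%; missing genotypes 0.2%).
  Reference AC/AN fields are made consistent with the generating
  frequency.
* **Pedigrees.** One founder introduces the variant; each meiosis
  transmits it with probability 0.5; affection is penetrance for carriers
  and the phenocopy rate otherwise (defaults 0.9 and 0.02); ages are
  uniform integers on 1–80 so the ≥ 25 gate is exercised. Ages are not
  generation-consistent — a deliberate simplification, since only the age
  gate consumes them.
* **Determinism.** All randomness flows from one integer seed; identical
  configuration and seed give identical in-memory data and byte-identical
  VCF/PED/TSV outputs.

What the generator does *not* emulate — and what passing tests therefore
do not demonstrate about real data: linkage disequilibrium and haplotype
structure, ancestry stratification, relatedness, sequencing-read-level
error processes, compound heterozygosity, and annotation error
(consequences and REVEL scores are taken as ground truth). The QC stage is
exercised against injected threshold-crossing artifacts, not against
realistic caller error distributions.

## Pipeline and problem sizes

`run-all` executes simulate → write VCF/PED → read back → QC → burden grid
→ co-segregation → frequency screen → power grid, and writes a manifest
(resolved config, seed, input digests, per-stage row counts). Rerunning
with the same config yields byte-identical TSVs (the manifest carries
wall-clock timestamps). The demo configuration uses 600 cases vs 4,000
controls — large enough for the positive-control signal to appear, small
enough that the full run takes seconds; statistical guarantees (power,
calibration, CI coverage) are always evaluated at the full design sizes of
2,571 vs 155,501, which the sparse carrier representation makes cheap. The
test suite's replicate counts (1,000 null suite runs, 500 recovery
replicates, 10,000 power replicates) are the package's chosen Monte-Carlo
sizes: 3 MC standard errors at these sizes are tighter than every
tolerance asserted.

## Known limitations

* No covariate adjustment, kernel/dispersion (SKAT-style) tests, or
  relatedness correction; unrelatedness is assumed upstream.
* The LOD engine is a counting approximation suited to fully genotyped
  published pedigrees; it does not peel large half-genotyped pedigrees and
  never infers obligate carriers.
* One transcript per gene; no transcript selection or variant effect
  prediction.
* The credibility screen implements only the monoallelic formula; no
  recessive or ancestry-specific variants of it.
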