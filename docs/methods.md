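# Methods

This note records the models, parameter choices and numerical conventions
behind `cgpval`, and what the synthetic cohorts do and do not establish.

## The decision layer

### Small-variant reportability

A call is reported when its VAF clears the tier-appropriate cutoff
(`tier1_vaf` = 0.02 for Tier I, `other_vaf` = 0.05 otherwise, both
inclusive ≥) *and* it has at least `min_alt_reads` = 4 unique supporting
reads. Precedence is fixed: blacklist masking first (a blacklisted
position is never reported at any evidence level), then the indel length
limit, then the evidence thresholds. The indel limit is ≤ 25 bp inclusive
(`max_indel_len`), measured as |len(ref) − len(alt)| for pure
insertions/deletions and max(len(ref), len(alt)) for delins; MNVs are
treated as substitutions and are exempt. VAFs are fractions internally and
become percentages only at I/O, rounded half-up to one decimal.

Tier I loci that fail the thresholds in a sample whose locus coverage is
below `tier1_min_coverage` return *indeterminate*, split into
`low_coverage_no_evidence` (zero alt reads) and
`low_coverage_subthreshold_evidence` (some alt reads). The coverage
threshold defaults to the power-derived 400× rather than a separate
constant: 400× is the round depth at which the exact binomial tail
P(X ≥ 4), X ~ Bin(depth, 0.02), reaches 95% (the exact minimum is 386×).
This coupling is a design choice — the indeterminate zone is exactly the
regime where a negative cannot be distinguished from an undersampled
positive at the verified LoD.

RNA events use unique-read floors only: fusions report at ≥ 5 unique
supporting reads, splice variants at ≥ 8 unique junction reads.

### Copy-number fold change

The observed per-gene fold change is modelled as a diploid mixture: a
fraction *p* of cells (tumor purity) carries *c* copies, the rest are
diploid, so FC = (p·c + (1 − p)·2)/2. Two consequences anchor the model:
FC(0.30, 10) = 2.2 and FC(0.50, 0) = 0.5, which are regression-tested.
Classification follows the printed interval notation exactly — gain at
FC ≥ 3.2, gain-indeterminate on [2.2, 3.2), loss at FC ≤ 0.5,
loss-indeterminate on (0.5, 0.7] — with the gain path applied to oncogenes
and the loss path to tumor suppressors (the gene→role map is configuration,
not inference). Inverting the model at a decision cut gives the minimum
detectable purity 2(FC_cut − 1)/(c − 2); values outside (0, 1] are
reported as infinity, i.e. not detectable at any purity. Normal ploidy is
fixed at 2; aneuploid baselines are out of scope and will bias FC for
genuinely non-diploid genomes.

### TMB and MSI

TMB = eligible variants / covered_mb, TMB-High at ≥ 10 mut/Mb.
Eligibility: non-germline, synonymous or nonsynonymous consequence,
VAF ≥ 5%, gene outside HLA-A/B/C. Whether indels count is configurable
(`include_indels`, default True, since coding indels are nonsynonymous
alterations). `covered_mb` ∈ (0, 1.33] is an input — the panel extent
actually sequenced to eligibility in the sample; the synthetic generator
derives it as the fraction of probe positions reaching a depth floor.
Germline status comes from the input germline flag (truth labels in
synthetic data); tumor-only proxy germline filtering from population
databases is explicitly out of scope.

MSI: sites qualify at depth ≥ 60 reads; < 40 qualified sites → Invalid;
otherwise score = unstable/qualified with MSI-High strictly > 0.20. A site
is unstable when its baseline-standardized statistic exceeds the normal
baseline mean by k = 3 SD. The per-site statistic of production callers is
proprietary, so the z-score form here is a documented stand-in; the
sample-level qualification and cutoff logic is the validated part.

### QC and contamination

Blacklist: a position is "consistently" under-covered when its depth is
< 80× in at least 90% of cohort samples (`blacklist_fraction` = 0.9,
configurable; a median-depth mode would be stricter and is not the
default because occasional deep samples should not rescue a dead
position). The contamination score treats each identity SNP independently:
the host genotype is fixed by maximum likelihood under the clean model
(expected VAF ∈ {0, ½, 1}), then the summed log-likelihood ratio of a
binomial mixture over contaminant genotypes (Hardy–Weinberg at allele
frequency 0.5 by default) is maximized over a contamination-fraction grid
α ∈ {0, 0.01, …, 0.5}. Including α = 0 in the grid floors the score at 0,
so clean samples score exactly 0; the cost is that bootstrap null
p-values are conservative (stochastically ≥ uniform) rather than exactly
uniform — the safe direction for a QC flag, and the calibration test
asserts exactly that. Expected VAFs are clipped to [10⁻³, 1 − 10⁻³] so a
single unexpected read never contributes infinite evidence. The p-value is
a parametric bootstrap (default 200 draws) of the score under the clean
model at the observed depths. Analyte gating is independent per class
(small variants/TMB, CNA, MSI, RNA) so one failing metric yields partial
reporting, and a contamination flag routes to manual review rather than
auto-failing.

## Validation statistics

PPA = 100·TP/(TP+FN), NPA = 100·TN/(TN+FP), each with an exact
Clopper–Pearson interval from beta quantiles (low = 0 at zero hits,
high = 1 at full hits). Indeterminate test calls are excluded from 2×2
tables as non-evaluable by default (configurable to count as negative);
aggregation level (variant/gene/sample) is an explicit label. APA/ANA are
means of per-variant positive/negative call rates across replicates of a
condition, requiring ≥ 2 replicates per variant per stratum. TMB %CV uses
the sample standard deviation and is compared against the 12.5% acceptance
bound. Raw fractions are always retained next to rounded percentages so
either rounding convention of a printed table can be checked.

Hit-rate LoD: per-level hit rates with exact CIs; the LoD is the most
dilute level with a 100% hit rate under a monotone-prefix rule — a level
qualifies only if every more concentrated level also qualifies. The rule
for non-monotone series (e.g. 100%, 90%, 100%) is not dictated by the
hit-rate framing alone; the prefix rule was chosen as the worst-scenario
reading and is enforced by exhaustive enumeration tests. `lod_at_95`
applies the same rule at a 95% criterion. Coverage power is the exact
binomial tail (scipy's regularized incomplete beta, no normal
approximation); `min_coverage` finds the exact minimum by doubling plus
bisection, valid because power is monotone in depth.

## The synthetic cohort generator

The generator reproduces the statistical structure the validation assumes,
at the summary level (call tables), not the read level.

* **Depth**: log-normal truncated to integers ≥ 0, parameterized in closed
  form to median 750 and SD 385 (σ² = ln t, t = (1 + √(1 + 4(s/m)²))/2)
  — the right skew matches hybrid-capture coverage profiles.
* **VAF**: expected VAF = purity × cellular fraction × allele dosage
  (default dosage 0.5, clonal heterozygous); germline loci at 50%/100%
  independent of purity; observed alt reads Binomial(depth, expected VAF).
* **Dilution**: level ℓ scales purity (hence every somatic expected VAF)
  by exactly ℓ pre-noise; germline loci are untouched.
* **Error**: decoy loci (default 1,000 per sample) draw false alt reads at
  a post-UMI-collapse substitution rate of 2×10⁻⁴ per base — the order of
  magnitude UMI consensus calling achieves — giving true-negative
  denominators without simulating ~2M positions.
* **MSI**: 130 sites; stable sites N(0, 1), unstable sites N(6, 1); for
  MSI-High truth the truly-unstable fraction is 0.6 × purity, so the 20%
  cutoff is crossed near purity ⅓ and dilution series exercise the MSI
  LoD.
* **Contamination**: expected VAF = (1 − α)·g_a/2 + α·g_b/2 with
  Hardy–Weinberg genotypes, reducing exactly to the pure samples at
  α ∈ {0, 1}.

All randomness flows through one explicitly threaded numpy Generator; a
fixed seed makes every table, report and study byte-reproducible.

What passing tests on these cohorts shows: the decision rules, models and
statistics are implemented exactly as specified, recover their generative
parameters, and degrade with purity the way the mixture models predict.
What they do not show: performance on real FFPE data — the generator has
no deamination artifacts, strand bias, mappability structure, germline
leakage, or correlated coverage, so agreement percentages from synthetic
studies characterize the code, not the assay.

## Study problem sizes

The packaged study configuration uses 8 samples for accuracy (1,000 decoy
loci each), 12 replicates for precision, and a 6-level neat-to-1:32
dilution series with 4 replicates per level for LoD; enumeration-based
checks (rule grids, LoD outcome tables, interval coverage) are exact and
exhaustive at their stated sizes. All are configurable upward through
`RunConfig`/`SimulationConfig`.

## Known limitations

* The fold-change model assumes a diploid normal background and one tumor
  clone; subclonal copy-number and genome doubling are not modelled.
* The per-site MSI statistic and the vendor contamination algorithm are
  proprietary; both components here are documented surrogates that match
  the published description of their inputs and outputs.
* Tier labels are inputs; clinical-significance tiering is out of scope.
* Exact QC cut values beyond the depth blacklist (80×) and RNA read floor
  (9,000,000) are laboratory configuration; the defaults in
  `QcThresholds` are placeholders exposed in one place.
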