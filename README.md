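# cgpval

Decision rules and analytical-validation statistics for tumor-only
comprehensive genomic profiling (CGP) panels.

Clinical laboratories validating a pan-cancer NGS panel face the same
post-variant-calling questions regardless of vendor pipeline: which calls
are reportable, how tumor purity limits copy-number and signature
detection, how to score TMB and MSI, when a sample's QC supports which
variant classes, and how to quantify accuracy, precision and limit of
detection against a non-reference comparator. `cgpval` implements that
decision layer and its statistical framework as a tested Python library,
exercised end to end on synthetic cohorts — no protected specimen data is
required to run, reproduce or extend any analysis.

## What it implements

**Reportability rules** (`cgpval.reportability`) — tier-dependent VAF
cutoffs (2% for Tier I, 5% otherwise), a 4-unique-read minimum, a 25 bp
indel length limit, blacklist masking, unique-read floors for fusions (≥5)
and splice variants (≥8), and the Tier I *indeterminate* logic for loci
whose coverage cannot support the verified limit of detection.

**Copy-number model** (`cgpval.cna`) — the diploid-mixture fold-change
model

    FC = (p·c + (1 − p)·2) / 2

for tumor purity *p* and tumor copy number *c*, with the five-state
classification (gain ≥ 3.2, gain-indeterminate [2.2, 3.2), negative,
loss-indeterminate (0.5, 0.7], loss ≤ 0.5) and its inversion
*p*<sub>min</sub> = 2(FC<sub>cut</sub> − 1)/(c − 2), which shows e.g. that
homozygous deletions need ≥ 50% tumor purity.

**Signatures** (`cgpval.signatures`) — TMB as eligible mutations per
megabase sequenced (TMB-High at ≥ 10 mut/Mb) and MSI as the unstable
fraction of ≥ 40 qualified homopolymer sites (MSI-High above 20%).

**Sample QC** (`cgpval.qc`) — cohort-level low-coverage blacklist
derivation (consistently < 80×), a binomial-mixture log-likelihood
contamination score with bootstrap p-value, and per-analyte gating with
partial-reporting semantics.

**Validation statistics** (`cgpval.stats`, `cgpval.lod`) — PPA/NPA from
2×2 agreement tables with exact Clopper–Pearson intervals, replicate
APA/ANA across conditions, TMB %CV against the 12.5% bound, Pearson R/R²,
the hit-rate limit-of-detection estimator (LoD = most dilute level with a
100% hit rate, worst-scenario prefix rule), and exact binomial coverage
power P(X ≥ 4), X ~ Bin(depth, VAF) — 400× gives 95% power at 2% VAF.

**Synthetic cohorts** (`cgpval.simulate`) — seeded generators for variant
tables (VAF = purity × cellular fraction × allele dosage, binomial read
sampling at log-normal 750×/SD 385 depth), dilution series (neat to 1:32),
130-site MSI panels, and two-sample contamination mixtures.

**Orchestration** (`cgpval.pipeline`, `cgpval` CLI) — a full synthetic
validation study (accuracy → precision → LoD) with provenance-stamped JSON
reports, reproducible from (config, seed) alone.

## Worked example

```python
>>> from cgpval import expected_fold_change, min_purity_for_call, GeneRole
>>> expected_fold_change(0.30, 10)   # 10 copies at 30% purity
2.2
>>> expected_fold_change(0.50, 0)    # homozygous deletion at 50% purity
0.5
>>> min_purity_for_call(0, GeneRole.TSG_LOSS)
0.5
```

Running the full synthetic study (`python examples/run_validation_study.py`)
prints, for seed 1:

```
accuracy (per variant class):
  small_variants  PPA 100.0% (103/103)  NPA 100.0% (8000/8000)
  copy_gain       PPA 100.0% (4/4)  NPA 100.0% (108/108)
  copy_loss       PPA 66.7% (2/3)  NPA 100.0% (29/29)
  msi             PPA 50.0% (1/2)  NPA 100.0% (6/6)
  tmb             PPA 100.0% (3/3)  NPA 100.0% (5/5)

precision: APA 97.5%  ANA 100.0%  TMB CV 3.1% (<=12.5%: True)

LoD: Tier I small variant at VAF 0.05, MSI at tumor purity 0.4
```

The imperfect copy-loss and MSI agreement is the model behaving correctly,
not a defect: the cohort deliberately includes low-purity samples, and
both analytes lose signal as normal DNA dilutes the tumor — losses bottom
out at FC = (2 − 2p + 0)/2 > 0.5 once p < 0.5, and the unstable-site
fraction falls below the 20% cutoff. The dilution-series LoD quantifies
the same effect per analyte.

Each script in `examples/` demonstrates one capability (fold-change model,
reportability rules, TMB/MSI scoring, concordance statistics, LoD and
power, contamination QC, full study) and prints a short interpretation.

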