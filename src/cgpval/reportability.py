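"""Variant reportability rules for a tumor-only hybrid-capture panel.

Small variants (SNVs, MNVs and indels) are reported when they clear a
tier-dependent allele-fraction cutoff — 2% VAF for Tier I variants, 5% for
all others — with at least 4 unique supporting reads, are not at a
blacklisted low-coverage position, and (for indels) alter at most 25 bp of
sequence. Tier I loci that fail the thresholds in a sample whose coverage
at the locus is below the depth needed to support the verified limit of
detection are reported *indeterminate* rather than negative, distinguishing
"no evidence seen but coverage insufficient" from "sub-threshold reads seen
but coverage insufficient". RNA events use unique-read floors: >=5 unique
reads for a gene fusion, >=8 unique junction reads for a splice variant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import pandas as pd

__all__ = [
    "VariantClass",
    "Consequence",
    "Status",
    "Reason",
    "ReportStatus",
    "RuleThresholds",
    "VariantCall",
    "classify_small_variant",
    "classify_fusion",
    "classify_splice",
    "apply_rules_to_table",
]


class VariantClass(str, Enum):
    SUBSTITUTION = "substitution"
    MNV = "MNV"
    INSERTION = "insertion"
    DELETION = "deletion"
    DELINS = "delins"


class Consequence(str, Enum):
    SYNONYMOUS = "synonymous"
    NONSYNONYMOUS = "nonsynonymous"
    OTHER = "other"


class Status(str, Enum):
    REPORTED = "reported"
    NOT_REPORTED = "not_reported"
    INDETERMINATE = "indeterminate"


class Reason(str, Enum):
    PASS = "pass"
    BELOW_VAF = "below_vaf"
    BELOW_READS = "below_reads"
    BLACKLISTED = "blacklisted"
    INDEL_TOO_LONG = "indel_too_long"
    LOW_COVERAGE_NO_EVIDENCE = "low_coverage_no_evidence"
    LOW_COVERAGE_SUBTHRESHOLD_EVIDENCE = "low_coverage_subthreshold_evidence"


_STATUS_FOR_REASON = {
    Reason.PASS: Status.REPORTED,
    Reason.BELOW_VAF: Status.NOT_REPORTED,
    Reason.BELOW_READS: Status.NOT_REPORTED,
    Reason.BLACKLISTED: Status.NOT_REPORTED,
    Reason.INDEL_TOO_LONG: Status.NOT_REPORTED,
    Reason.LOW_COVERAGE_NO_EVIDENCE: Status.INDETERMINATE,
    Reason.LOW_COVERAGE_SUBTHRESHOLD_EVIDENCE: Status.INDETERMINATE,
}


@dataclass(frozen=True)
class ReportStatus:
    status: Status
    reason: Reason

    def __post_init__(self) -> None:
        if _STATUS_FOR_REASON[self.reason] is not self.status:
            raise ValueError(f"reason {self.reason} inconsistent with status {self.status}")


@dataclass(frozen=True)
class RuleThresholds:
    """Reporting thresholds; defaults are the validated assay cutoffs."""

    tier1_vaf: float = 0.02
    other_vaf: float = 0.05
    min_alt_reads: int = 4
    max_indel_len: int = 25  # inclusive: alterations of <=25 bp are evaluable
    min_fusion_reads: int = 5
    min_splice_reads: int = 8
    # depth below which a threshold-failing Tier I locus is indeterminate
    # rather than negative; 400x gives 95% power at 2% VAF with >=4 reads
    tier1_min_coverage: int = 400

    def __post_init__(self) -> None:
        if not self.tier1_vaf <= self.other_vaf:
            raise ValueError("tier1_vaf must not exceed other_vaf")
        for name in ("min_alt_reads", "max_indel_len", "min_fusion_reads",
                     "min_splice_reads", "tier1_min_coverage"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class VariantCall:
    """One small-variant observation from UMI-collapsed calling output."""

    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    variant_class: VariantClass
    vaf: float
    alt_reads: int
    depth: int
    consequence: Consequence
    tier1: bool
    germline: bool
    gene: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.vaf <= 1.0) or not math.isfinite(self.vaf):
            raise ValueError(f"vaf must be in [0, 1], got {self.vaf}")
        if self.alt_reads < 0 or self.depth < 0:
            raise ValueError("read counts must be non-negative")
        if self.alt_reads > self.depth:
            raise ValueError(f"alt_reads ({self.alt_reads}) exceeds depth ({self.depth})")
        if self.pos < 1:
            raise ValueError("pos is 1-based and must be >= 1")

    @property
    def indel_length(self) -> int:
        """Bases of sequence alteration: length difference for pure indels,
        alt length for delins, 0 for substitutions/MNVs."""
        if self.variant_class in (VariantClass.INSERTION, VariantClass.DELETION):
            return abs(len(self.ref) - len(self.alt))
        if self.variant_class is VariantClass.DELINS:
            return max(len(self.ref), len(self.alt))
        return 0


def classify_small_variant(
    call: VariantCall,
    thresholds: RuleThresholds | None = None,
    blacklist: frozenset[tuple[str, int]] | set[tuple[str, int]] | None = None,
) -> ReportStatus:
    """Apply the small-variant reporting rules to one call.

    Precedence: blacklist masking dominates everything; the indel length
    limit comes next; then the VAF and read-support thresholds with the
    Tier I indeterminate fallback at low coverage.
    """
    thresholds = thresholds or RuleThresholds()
    blacklist = blacklist or frozenset()
    if (call.chrom, call.pos) in blacklist:
        return ReportStatus(Status.NOT_REPORTED, Reason.BLACKLISTED)
    if call.indel_length > thresholds.max_indel_len:
        return ReportStatus(Status.NOT_REPORTED, Reason.INDEL_TOO_LONG)

    vaf_cut = thresholds.tier1_vaf if call.tier1 else thresholds.other_vaf
    if call.vaf >= vaf_cut and call.alt_reads >= thresholds.min_alt_reads:
        return ReportStatus(Status.REPORTED, Reason.PASS)

    if call.tier1 and call.depth < thresholds.tier1_min_coverage:
        if call.alt_reads == 0:
            return ReportStatus(Status.INDETERMINATE, Reason.LOW_COVERAGE_NO_EVIDENCE)
        return ReportStatus(Status.INDETERMINATE, Reason.LOW_COVERAGE_SUBTHRESHOLD_EVIDENCE)

    if call.vaf < vaf_cut:
        return ReportStatus(Status.NOT_REPORTED, Reason.BELOW_VAF)
    return ReportStatus(Status.NOT_REPORTED, Reason.BELOW_READS)


def classify_fusion(unique_reads: int, thresholds: RuleThresholds | None = None) -> ReportStatus:
    """A gene fusion is reported at >=5 unique supporting reads."""
    thresholds = thresholds or RuleThresholds()
    if unique_reads < 0:
        raise ValueError("read counts must be non-negative")
    if unique_reads >= thresholds.min_fusion_reads:
        return ReportStatus(Status.REPORTED, Reason.PASS)
    return ReportStatus(Status.NOT_REPORTED, Reason.BELOW_READS)


def classify_splice(
    unique_junction_reads: int, thresholds: RuleThresholds | None = None
) -> ReportStatus:
    """A splice variant is reported at >=8 unique junction reads."""
    thresholds = thresholds or RuleThresholds()
    if unique_junction_reads < 0:
        raise ValueError("read counts must be non-negative")
    if unique_junction_reads >= thresholds.min_splice_reads:
        return ReportStatus(Status.REPORTED, Reason.PASS)
    return ReportStatus(Status.NOT_REPORTED, Reason.BELOW_READS)


VARIANT_TABLE_COLUMNS = [
    "sample_id", "chrom", "pos", "ref", "alt", "variant_class", "vaf",
    "alt_reads", "depth", "consequence", "tier1", "germline", "gene",
]


def _call_from_row(row: pd.Series) -> VariantCall:
    return VariantCall(
        sample_id=str(row["sample_id"]),
        chrom=str(row["chrom"]),
        pos=int(row["pos"]),
        ref=str(row["ref"]),
        alt=str(row["alt"]),
        variant_class=VariantClass(row["variant_class"]),
        vaf=float(row["vaf"]),
        alt_reads=int(row["alt_reads"]),
        depth=int(row["depth"]),
        consequence=Consequence(row["consequence"]),
        tier1=bool(row["tier1"]),
        germline=bool(row["germline"]),
        gene=str(row["gene"]),
    )


def apply_rules_to_table(
    table: pd.DataFrame,
    thresholds: RuleThresholds | None = None,
    blacklist: frozenset[tuple[str, int]] | set[tuple[str, int]] | None = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Annotate every row of a variant table with its report status.

    Returns the annotated table (row order preserved, ``status`` and
    ``reason`` columns appended) and a summary of counts per reason.
    Duplicate (sample, locus, alt) rows are rejected.
    """
    thresholds = thresholds or RuleThresholds()
    summary = {reason.value: 0 for reason in Reason}
    if table.empty:
        annotated = table.copy()
        annotated["status"] = pd.Series(dtype=str)
        annotated["reason"] = pd.Series(dtype=str)
        return annotated, summary

    key_cols = ["sample_id", "chrom", "pos", "alt"]
    dupes = table.duplicated(subset=key_cols)
    if dupes.any():
        first = table.loc[dupes.idxmax(), key_cols].tolist()
        raise ValueError(f"duplicate variant rows (sample, locus, alt): {first}")

    statuses, reasons = [], []
    for _, row in table.iterrows():
        result = classify_small_variant(_call_from_row(row), thresholds, blacklist)
        statuses.append(result.status.value)
        reasons.append(result.reason.value)
        summary[result.reason.value] += 1
    annotated = table.copy()
    annotated["status"] = statuses
    annotated["reason"] = reasons
    return annotated, summary
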