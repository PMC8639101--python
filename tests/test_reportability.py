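"""Small-variant, fusion and splice reportability rules."""

import itertools

import pandas as pd
import pytest

from cgpval.reportability import (
    Consequence,
    Reason,
    RuleThresholds,
    Status,
    VariantCall,
    VariantClass,
    apply_rules_to_table,
    classify_fusion,
    classify_small_variant,
    classify_splice,
)


def call(
    vaf=0.10,
    alt_reads=50,
    depth=500,
    tier1=False,
    variant_class=VariantClass.SUBSTITUTION,
    ref="A",
    alt="T",
    pos=100,
    chrom="chr1",
):
    return VariantCall(
        sample_id="S1",
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        variant_class=variant_class,
        vaf=vaf,
        alt_reads=alt_reads,
        depth=depth,
        consequence=Consequence.NONSYNONYMOUS,
        tier1=tier1,
        germline=False,
        gene="PIK3CA",
    )


def oracle(call, th, blacklisted):
    """Independent re-derivation of the rules, written branch by branch."""
    if blacklisted:
        return (Status.NOT_REPORTED, Reason.BLACKLISTED)
    if call.variant_class in (VariantClass.INSERTION, VariantClass.DELETION):
        if abs(len(call.ref) - len(call.alt)) > th.max_indel_len:
            return (Status.NOT_REPORTED, Reason.INDEL_TOO_LONG)
    if call.variant_class is VariantClass.DELINS:
        if max(len(call.ref), len(call.alt)) > th.max_indel_len:
            return (Status.NOT_REPORTED, Reason.INDEL_TOO_LONG)
    cut = th.tier1_vaf if call.tier1 else th.other_vaf
    if call.vaf >= cut and call.alt_reads >= th.min_alt_reads:
        return (Status.REPORTED, Reason.PASS)
    if call.tier1 and call.depth < th.tier1_min_coverage:
        if call.alt_reads == 0:
            return (Status.INDETERMINATE, Reason.LOW_COVERAGE_NO_EVIDENCE)
        return (Status.INDETERMINATE, Reason.LOW_COVERAGE_SUBTHRESHOLD_EVIDENCE)
    if call.vaf < cut:
        return (Status.NOT_REPORTED, Reason.BELOW_VAF)
    return (Status.NOT_REPORTED, Reason.BELOW_READS)


class TestSmallVariantExamples:
    def test_tier1_substitution_at_5_percent_reported(self):
        result = classify_small_variant(call(vaf=0.05, alt_reads=25, depth=500, tier1=True))
        assert result.status is Status.REPORTED

    def test_non_tier_just_below_5_percent_not_reported(self):
        result = classify_small_variant(call(vaf=0.049, alt_reads=40, depth=1000))
        assert (result.status, result.reason) == (Status.NOT_REPORTED, Reason.BELOW_VAF)

    def test_tier1_no_evidence_low_coverage_is_indeterminate(self):
        result = classify_small_variant(call(vaf=0.0, alt_reads=0, depth=200, tier1=True))
        assert (result.status, result.reason) == (
            Status.INDETERMINATE,
            Reason.LOW_COVERAGE_NO_EVIDENCE,
        )

    def test_tier1_subthreshold_evidence_low_coverage_is_indeterminate(self):
        result = classify_small_variant(call(vaf=0.01, alt_reads=2, depth=200, tier1=True))
        assert (result.status, result.reason) == (
            Status.INDETERMINATE,
            Reason.LOW_COVERAGE_SUBTHRESHOLD_EVIDENCE,
        )

    def test_tier1_failure_at_adequate_coverage_is_negative(self):
        result = classify_small_variant(call(vaf=0.01, alt_reads=5, depth=800, tier1=True))
        assert (result.status, result.reason) == (Status.NOT_REPORTED, Reason.BELOW_VAF)

    def test_tier1_threshold_is_2_percent(self):
        assert classify_small_variant(call(vaf=0.02, tier1=True)).status is Status.REPORTED
        reported_at_2 = classify_small_variant(call(vaf=0.02, tier1=False))
        assert reported_at_2.status is Status.NOT_REPORTED

    def test_minimum_4_unique_reads(self):
        assert classify_small_variant(call(alt_reads=4)).status is Status.REPORTED
        assert (
            classify_small_variant(call(alt_reads=3)).reason is Reason.BELOW_READS
        )

    def test_blacklist_dominates_strong_evidence(self):
        result = classify_small_variant(
            call(vaf=0.9, alt_reads=400), blacklist={("chr1", 100)}
        )
        assert result.reason is Reason.BLACKLISTED

    def test_indel_length_limit_inclusive_at_25(self):
        ok = call(variant_class=VariantClass.DELETION, ref="A" * 26, alt="A")
        too_long = call(variant_class=VariantClass.DELETION, ref="A" * 27, alt="A")
        assert classify_small_variant(ok).status is Status.REPORTED
        assert classify_small_variant(too_long).reason is Reason.INDEL_TOO_LONG

    def test_mnv_exempt_from_indel_limit(self):
        mnv = call(variant_class=VariantClass.MNV, ref="GT" * 20, alt="AC" * 20)
        assert classify_small_variant(mnv).status is Status.REPORTED

    def test_alt_reads_exceeding_depth_rejected(self):
        with pytest.raises(ValueError):
            call(alt_reads=600, depth=500)


class TestRnaRules:
    @pytest.mark.parametrize("reads, reported", [(5, True), (4, False), (0, False), (100, True)])
    def test_fusion_threshold_at_5_reads(self, reads, reported):
        status = classify_fusion(reads).status
        assert (status is Status.REPORTED) == reported

    @pytest.mark.parametrize("reads, reported", [(8, True), (7, False), (0, False)])
    def test_splice_threshold_at_8_reads(self, reads, reported):
        status = classify_splice(reads).status
        assert (status is Status.REPORTED) == reported

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            classify_fusion(-1)
        with pytest.raises(ValueError):
            classify_splice(-1)


class TestExhaustiveGrid:
    def test_rules_match_independent_oracle_over_full_grid(self):
        """Every rule branch: tier x VAF x alt reads x depth x indel length
        x blacklist, checked against a branch-by-branch oracle."""
        th = RuleThresholds()
        vafs = [0.0, 0.019, 0.02, 0.021, 0.049, 0.05, 0.051, 0.3]
        alt_read_opts = [0, 3, 4, 5]
        depths = [200, 399, 400, 1000]
        indel_lens = [0, 24, 25, 26]
        for tier1, vaf, alts, depth, ilen, blk in itertools.product(
            (False, True), vafs, alt_read_opts, depths, indel_lens, (False, True)
        ):
            if alts > depth:
                continue
            if ilen == 0:
                vclass, ref, alt = VariantClass.SUBSTITUTION, "A", "T"
            else:
                vclass, ref, alt = VariantClass.DELETION, "A" * (ilen + 1), "A"
            c = call(
                vaf=vaf, alt_reads=alts, depth=depth, tier1=tier1,
                variant_class=vclass, ref=ref, alt=alt,
            )
            blacklist = {("chr1", 100)} if blk else set()
            got = classify_small_variant(c, th, blacklist)
            want = oracle(c, th, blk)
            assert (got.status, got.reason) == want, (tier1, vaf, alts, depth, ilen, blk)

    def test_monotone_in_evidence(self):
        """More VAF or more alt reads never demotes a call (ranking
        reported > indeterminate > not_reported)."""
        rank = {Status.NOT_REPORTED: 0, Status.INDETERMINATE: 1, Status.REPORTED: 2}
        th = RuleThresholds()
        grid = [(v, a) for v in (0.0, 0.01, 0.02, 0.05, 0.2) for a in (0, 2, 4, 10)]
        for tier1 in (False, True):
            for depth in (200, 500):
                for (v1, a1), (v2, a2) in itertools.product(grid, grid):
                    if v2 >= v1 and a2 >= a1 and a2 <= depth:
                        s1 = classify_small_variant(call(vaf=v1, alt_reads=a1, depth=depth, tier1=tier1), th)
                        s2 = classify_small_variant(call(vaf=v2, alt_reads=a2, depth=depth, tier1=tier1), th)
                        assert rank[s2.status] >= rank[s1.status]


class TestApplyRulesToTable:
    def make_table(self, n=6):
        rows = []
        for i in range(n):
            rows.append(
                {
                    "sample_id": "S1", "chrom": "chr1", "pos": 100 + i, "ref": "A",
                    "alt": "T", "variant_class": "substitution",
                    "vaf": 0.01 * (i + 1), "alt_reads": 2 * i, "depth": 500,
                    "consequence": "nonsynonymous", "tier1": i % 2 == 0,
                    "germline": False, "gene": "TP53",
                }
            )
        return pd.DataFrame(rows)

    def test_empty_table(self):
        annotated, summary = apply_rules_to_table(pd.DataFrame())
        assert annotated.empty
        assert all(v == 0 for v in summary.values())

    def test_no_rows_dropped_and_summary_matches_per_row(self):
        table = self.make_table()
        annotated, summary = apply_rules_to_table(table)
        assert len(annotated) == len(table)
        from collections import Counter

        assert summary == {
            r.value: Counter(annotated["reason"]).get(r.value, 0) for r in Reason
        }

    def test_idempotent_on_annotated_table(self):
        annotated, _ = apply_rules_to_table(self.make_table())
        again, _ = apply_rules_to_table(annotated)
        assert list(again["status"]) == list(annotated["status"])
        assert list(again["reason"]) == list(annotated["reason"])

    def test_duplicate_rows_rejected(self):
        table = pd.concat([self.make_table(2)] * 2, ignore_index=True)
        with pytest.raises(ValueError, match="duplicate"):
            apply_rules_to_table(table)
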