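"""Readers and writers for the tabular formats the pipeline exchanges.

Variant tables travel either as tab-delimited text (the native format of
every module here) or as VCF with the assay-specific annotations carried in
INFO fields (VAF, unique alt/total read counts, consequence, tier and
germline flags). Blacklists are BED intervals (0-based, half-open on disk,
converted to 1-based positions in memory). Configuration files are YAML.
"""

from __future__ import annotations

from pathlib import Path
from typing import Any

import pandas as pd
import pysam
import yaml

from .reportability import VARIANT_TABLE_COLUMNS

__all__ = [
    "read_variant_table",
    "write_variant_table",
    "read_variant_vcf",
    "write_variant_vcf",
    "read_blacklist_bed",
    "write_blacklist_bed",
    "load_config",
    "dump_config",
]

_BOOL_COLUMNS = ("tier1", "germline")


def write_variant_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_variant_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    missing = set(VARIANT_TABLE_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"variant table missing columns: {sorted(missing)}")
    for col in _BOOL_COLUMNS:
        table[col] = table[col].astype(bool)
    return table


_VCF_HEADER_LINES = [
    ('INFO', 'VAF', '1', 'Float', 'Variant allele fraction from unique reads'),
    ('INFO', 'AU', '1', 'Integer', 'Unique alt-supporting read count'),
    ('INFO', 'DPU', '1', 'Integer', 'Unique total read depth at locus'),
    ('INFO', 'CSQ', '1', 'String', 'Consequence: synonymous|nonsynonymous|other'),
    ('INFO', 'VC', '1', 'String', 'Variant class'),
    ('INFO', 'TIER1', '0', 'Flag', 'Tier I clinical significance label'),
    ('INFO', 'GERM', '0', 'Flag', 'Germline-flagged locus'),
    ('INFO', 'GENE', '1', 'String', 'Gene symbol'),
]


def write_variant_vcf(table: pd.DataFrame, path: str | Path) -> None:
    """Write a variant table as an uncompressed VCF."""
    header = pysam.VariantHeader()
    for _, name, number, vtype, desc in _VCF_HEADER_LINES:
        header.info.add(name, number, vtype, desc)
    for chrom in pd.unique(table["chrom"].astype(str)):
        header.contigs.add(chrom)
    samples = pd.unique(table["sample_id"].astype(str))
    if len(samples) != 1:
        raise ValueError("VCF export expects a single-sample table")
    header.add_meta("sample_id", samples[0])
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for _, row in table.iterrows():
            rec = vcf.new_record(
                contig=str(row["chrom"]),
                start=int(row["pos"]) - 1,
                alleles=(str(row["ref"]), str(row["alt"])),
            )
            rec.info["VAF"] = float(row["vaf"])
            rec.info["AU"] = int(row["alt_reads"])
            rec.info["DPU"] = int(row["depth"])
            rec.info["CSQ"] = str(row["consequence"])
            rec.info["VC"] = str(row["variant_class"])
            rec.info["GENE"] = str(row["gene"])
            if bool(row["tier1"]):
                rec.info["TIER1"] = True
            if bool(row["germline"]):
                rec.info["GERM"] = True
            vcf.write(rec)


def read_variant_vcf(path: str | Path) -> pd.DataFrame:
    """Read a VCF written by :func:`write_variant_vcf` back into a table."""
    records = []
    with pysam.VariantFile(str(path)) as vcf:
        sample_id = "unknown"
        for hrec in vcf.header.records:
            if hrec.key == "sample_id":
                sample_id = hrec.value
        for rec in vcf:
            records.append(
                {
                    "sample_id": sample_id,
                    "chrom": rec.contig,
                    "pos": rec.pos,  # pysam exposes 1-based pos
                    "ref": rec.ref,
                    "alt": rec.alts[0],
                    "variant_class": rec.info["VC"],
                    "vaf": float(rec.info["VAF"]),
                    "alt_reads": int(rec.info["AU"]),
                    "depth": int(rec.info["DPU"]),
                    "consequence": rec.info["CSQ"],
                    "tier1": "TIER1" in rec.info,
                    "germline": "GERM" in rec.info,
                    "gene": rec.info["GENE"],
                }
            )
    return pd.DataFrame.from_records(
        records, columns=VARIANT_TABLE_COLUMNS if not records else None
    )


def read_blacklist_bed(path: str | Path) -> frozenset[tuple[str, int]]:
    """Blacklisted positions from BED (0-based half-open) as 1-based (chrom, pos)."""
    bed = pd.read_csv(
        path, sep="\t", header=None, usecols=[0, 1, 2], names=["chrom", "start", "end"]
    )
    positions = set()
    for chrom, start, end in bed.itertuples(index=False):
        if end <= start:
            raise ValueError(f"degenerate BED interval {chrom}:{start}-{end}")
        for pos0 in range(int(start), int(end)):
            positions.add((str(chrom), pos0 + 1))
    return frozenset(positions)


def write_blacklist_bed(
    positions: set[tuple[str, int]] | frozenset[tuple[str, int]], path: str | Path
) -> None:
    """Write 1-based (chrom, pos) singletons as BED intervals."""
    rows = sorted(positions)
    with open(path, "w") as fh:
        for chrom, pos in rows:
            fh.write(f"{chrom}\t{pos - 1}\t{pos}\n")


def load_config(path: str | Path) -> dict[str, Any]:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    return data


def dump_config(config: dict[str, Any], path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)
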