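"""Synthetic tumor-only sequencing cohorts for exercising the validation.

The generator emulates the statistical structure of UMI-collapsed panel
sequencing of FFPE tumor specimens, not the reads themselves:

* per-locus unique depth follows a right-skewed log-normal with median
  750x and SD 385, truncated to non-negative integers;
* a somatic variant carried at cellular fraction ``ccf`` and allele dosage
  ``d`` in a tumor of purity ``p`` has expected VAF = p * ccf * d, and its
  observed alt-read count is Binomial(depth, expected VAF); germline loci
  sit at 50% or 100% VAF independent of purity;
* dilution with normal DNA scales purity — and every somatic expected
  VAF — linearly by the dilution level, leaving germline loci untouched;
* sequencing error plants false alt reads at decoy loci at a small
  per-base substitution probability, providing true-negative denominators;
* 130 microsatellite homopolymer sites carry a baseline-standardized
  instability statistic, N(0,1) in normal tissue and shifted for the
  unstable sites of an MSI-High tumor, whose unstable fraction scales
  with purity;
* cross-individual contamination mixes two germline genotype vectors so
  identity-SNP VAFs deviate from {0, 50, 100}%.

All randomness flows through an explicitly threaded numpy Generator; a
fixed seed reproduces every table byte for byte.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "TruthVariant",
    "TruthSample",
    "SimulationConfig",
    "depth_lognormal_params",
    "draw_depths",
    "simulate_variant_table",
    "simulate_dilution_series",
    "simulate_msi_sites",
    "simulate_contamination",
    "draw_genotypes",
    "simulate_covered_mb",
    "make_truth_sample",
]

# genes used when planting synthetic truth; gain/loss lists follow the
# validated copy-number panels
GAIN_GENES = (
    "CCND1", "CCNE1", "CDK4", "CDK6", "EGFR", "ERBB2", "FGFR1", "FGFR2",
    "KIT", "KRAS", "MET", "MDM2", "MYC", "PIK3CA",
)
LOSS_GENES = ("ATM", "BRCA1", "BRCA2", "PTEN")
FUSION_GENES = ("ALK", "FGFR3", "NTRK1", "NTRK3", "RET", "ROS1")
SPLICE_TARGETS = ("MET_ex14", "EGFR_ex2_7")
_SOMATIC_GENES = (
    "TP53", "KRAS", "PIK3CA", "BRAF", "EGFR", "APC", "PTEN", "RB1",
    "NF1", "ATM", "ARID1A", "SMAD4", "FBXW7", "STK11", "CDKN2A", "KEAP1",
)


@dataclass(frozen=True)
class TruthVariant:
    """Ground-truth small variant planted in a synthetic sample."""

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    variant_class: str = "substitution"
    consequence: str = "nonsynonymous"
    tier1: bool = False
    germline: bool = False
    cellular_fraction: float = 1.0
    allele_dosage: float = 0.5  # fraction of alleles mutated in carrier cells

    def __post_init__(self) -> None:
        if not (0.0 < self.cellular_fraction <= 1.0):
            raise ValueError("cellular_fraction must be in (0, 1]")
        if not (0.0 < self.allele_dosage <= 1.0):
            raise ValueError("allele_dosage must be in (0, 1]")

    def expected_vaf(self, purity: float) -> float:
        """Germline loci are clonal in every cell; somatic VAF dilutes with purity."""
        if self.germline:
            return self.allele_dosage
        return purity * self.cellular_fraction * self.allele_dosage


@dataclass(frozen=True)
class TruthSample:
    """Ground truth for one synthetic specimen."""

    sample_id: str
    purity: float
    tumor_type: str = "unknown"
    tmb_rate: float = 0.0  # true mutations per Mb
    msi_status: str = "MS-Stable"  # MSI-High | MS-Stable
    cn_truth: dict[str, int] = field(default_factory=dict)
    fusion_truth: dict[str, bool] = field(default_factory=dict)
    splice_truth: dict[str, bool] = field(default_factory=dict)
    variants: tuple[TruthVariant, ...] = ()

    def __post_init__(self) -> None:
        if not (0.0 <= self.purity <= 1.0) or not math.isfinite(self.purity):
            raise ValueError(f"purity must be a finite fraction in [0, 1], got {self.purity}")
        if self.tmb_rate < 0 or not math.isfinite(self.tmb_rate):
            raise ValueError("tmb_rate must be a finite non-negative rate")
        if self.msi_status not in ("MSI-High", "MS-Stable"):
            raise ValueError(f"unknown msi_status: {self.msi_status}")
        if any(c < 0 or c != int(c) for c in self.cn_truth.values()):
            raise ValueError("copy numbers must be non-negative integers")


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the generative model; defaults match the validated assay."""

    seed: int = 0
    depth_median: float = 750.0
    depth_sd: float = 385.0
    panel_mb: float = 1.33            # maximum eligible exonic extent
    panel_total_bases: int = 1_975_834
    n_msi_sites: int = 130
    sequencing_error: float = 2e-4    # post-UMI-collapse substitution rate
    n_decoy_loci: int = 1000
    dilution_levels: tuple[float, ...] = (1.0, 0.5, 0.25, 0.125, 0.0625, 0.03125)
    msi_mu_unstable: float = 6.0      # shift of unstable-site statistic, in baseline SDs
    msi_site_fraction_high: float = 0.6  # unstable fraction at purity 1 for MSI-High
    msi_false_site_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.depth_median <= 0 or self.depth_sd < 0:
            raise ValueError("depth_median must be > 0 and depth_sd >= 0")
        if not 0.0 <= self.sequencing_error < 1.0:
            raise ValueError("sequencing_error must be in [0, 1)")
        if any(not 0.0 < lv <= 1.0 for lv in self.dilution_levels):
            raise ValueError("dilution levels must be fractions in (0, 1]")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def depth_lognormal_params(median: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of a log-normal with the given median and standard deviation.

    With t = exp(sigma^2), Var = median^2 * t * (t - 1), so
    t = (1 + sqrt(1 + 4 (sd/median)^2)) / 2 in closed form.
    """
    mu = math.log(median)
    if sd == 0:
        return mu, 0.0
    ratio2 = (sd / median) ** 2
    t = (1.0 + math.sqrt(1.0 + 4.0 * ratio2)) / 2.0
    return mu, math.sqrt(math.log(t))


def draw_depths(n: int, config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Integer unique-read depths from the configured right-skewed model."""
    mu, sigma = depth_lognormal_params(config.depth_median, config.depth_sd)
    if sigma == 0:
        return np.full(n, int(round(config.depth_median)), dtype=np.int64)
    depths = np.rint(rng.lognormal(mean=mu, sigma=sigma, size=n)).astype(np.int64)
    return np.maximum(depths, 0)


def simulate_variant_table(
    truth: TruthSample,
    config: SimulationConfig | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """One sample's small-variant call table.

    Each truth variant is observed at Binomial(depth, expected VAF) alt
    reads; additionally ``n_decoy_loci`` variant-free positions are emitted
    with error-driven alt reads, so downstream agreement statistics have
    true-negative rows. Rows carry the columns the reportability engine
    expects.
    """
    config = config or SimulationConfig()
    rng = rng if rng is not None else config.rng()

    records: list[dict] = []
    n_true = len(truth.variants)
    depths = draw_depths(n_true + config.n_decoy_loci, config, rng)
    for i, tv in enumerate(truth.variants):
        depth = int(depths[i])
        evaf = tv.expected_vaf(truth.purity)
        alt = int(rng.binomial(depth, min(evaf, 1.0))) if depth > 0 else 0
        records.append(
            {
                "sample_id": truth.sample_id,
                "chrom": tv.chrom,
                "pos": tv.pos,
                "ref": tv.ref,
                "alt": tv.alt,
                "variant_class": tv.variant_class,
                "vaf": alt / depth if depth > 0 else 0.0,
                "alt_reads": alt,
                "depth": depth,
                "consequence": tv.consequence,
                "tier1": tv.tier1,
                "germline": tv.germline,
                "gene": tv.gene,
                "truth_positive": not tv.germline,
                "expected_vaf": evaf,
            }
        )
    # decoy loci: no variant present, alt reads arise from sequencing error
    decoy_depths = depths[n_true:]
    decoy_alts = rng.binomial(decoy_depths, config.sequencing_error)
    decoy_bases = ("A", "C", "G", "T")
    for j in range(config.n_decoy_loci):
        depth = int(decoy_depths[j])
        alt = int(decoy_alts[j])
        ref = decoy_bases[j % 4]  # fixed per position so replicates share keys
        alt_base = {"A": "G", "C": "T", "G": "A", "T": "C"}[ref]
        records.append(
            {
                "sample_id": truth.sample_id,
                "chrom": "chrD",
                "pos": 10_000_000 + j,
                "ref": ref,
                "alt": alt_base,
                "variant_class": "substitution",
                "vaf": alt / depth if depth > 0 else 0.0,
                "alt_reads": alt,
                "depth": depth,
                "consequence": "other",
                "tier1": False,
                "germline": False,
                "gene": "NONE",
                "truth_positive": False,
                "expected_vaf": 0.0,
            }
        )
    return pd.DataFrame.from_records(records)


def simulate_dilution_series(
    truth: TruthSample,
    levels: tuple[float, ...] | list[float] | None = None,
    replicates: int = 3,
    config: SimulationConfig | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Replicate variant tables across a dilution series.

    Each level ``l`` (a fraction in (0, 1], sorted descending, neat = 1)
    rescales the tumor content: effective purity = l * neat purity, so
    every somatic expected VAF scales linearly while germline loci are
    untouched. Returns a long table with ``level`` and ``replicate``
    columns prepended to the variant-table columns.
    """
    config = config or SimulationConfig()
    rng = rng if rng is not None else config.rng()
    levels = tuple(levels) if levels is not None else config.dilution_levels
    if any(not 0.0 < lv <= 1.0 for lv in levels):
        raise ValueError("dilution levels must be in (0, 1]")
    if any(b >= a for a, b in zip(levels, levels[1:])):
        raise ValueError("dilution levels must be sorted strictly descending")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")

    frames = []
    for level in levels:
        diluted = replace(truth, purity=truth.purity * level)
        for rep in range(replicates):
            table = simulate_variant_table(diluted, config, rng)
            table.insert(0, "replicate", rep)
            table.insert(0, "level", level)
            frames.append(table)
    return pd.concat(frames, ignore_index=True)


def simulate_msi_sites(
    truth: TruthSample,
    config: SimulationConfig | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Per-site homopolymer instability table for one sample.

    Stable sites draw their baseline-standardized statistic from N(0, 1);
    for an MSI-High tumor a purity-scaled fraction of sites is truly
    unstable and draws from N(mu_unstable, 1). Site depth follows the
    same model as variant loci.
    """
    config = config or SimulationConfig()
    rng = rng if rng is not None else config.rng()
    n = config.n_msi_sites
    depths = draw_depths(n, config, rng)
    if truth.msi_status == "MSI-High":
        frac_unstable = min(1.0, config.msi_site_fraction_high * truth.purity)
    else:
        frac_unstable = config.msi_false_site_rate
    n_unstable = int(round(frac_unstable * n))
    unstable_truth = np.zeros(n, dtype=bool)
    if n_unstable > 0:
        unstable_truth[rng.choice(n, size=n_unstable, replace=False)] = True
    stats = rng.normal(0.0, 1.0, size=n)
    stats[unstable_truth] += config.msi_mu_unstable
    return pd.DataFrame(
        {
            "site_id": [f"MSI_{i:03d}" for i in range(n)],
            "depth": depths,
            "instability_statistic": stats,
            "truth_unstable": unstable_truth,
        }
    )


def draw_genotypes(
    n_snps: int, allele_freq: float, rng: np.random.Generator
) -> np.ndarray:
    """Diploid genotypes (alt-allele counts 0/1/2) under Hardy-Weinberg."""
    if not 0.0 < allele_freq < 1.0:
        raise ValueError("allele_freq must be in (0, 1)")
    return rng.binomial(2, allele_freq, size=n_snps)


def simulate_contamination(
    genotypes_a: np.ndarray,
    genotypes_b: np.ndarray,
    alpha: float,
    config: SimulationConfig | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Identity-SNP VAF table for a two-sample mixture.

    Per SNP the expected VAF is (1-alpha) * g_a/2 + alpha * g_b/2 for
    genotypes g in {0, 1, 2}; observed alt counts are binomial at the
    simulated depth. alpha = 0 reproduces pure sample A, alpha = 1 pure
    sample B.
    """
    config = config or SimulationConfig()
    rng = rng if rng is not None else config.rng()
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be a fraction in [0, 1]")
    ga = np.asarray(genotypes_a)
    gb = np.asarray(genotypes_b)
    if ga.shape != gb.shape:
        raise ValueError("genotype vectors must have equal length")
    if not (np.isin(ga, (0, 1, 2)).all() and np.isin(gb, (0, 1, 2)).all()):
        raise ValueError("genotypes must be alt-allele counts in {0, 1, 2}")
    expected = (1.0 - alpha) * ga / 2.0 + alpha * gb / 2.0
    depths = draw_depths(len(ga), config, rng)
    alts = rng.binomial(depths, expected)
    return pd.DataFrame(
        {
            "snp_id": [f"rsS{i:05d}" for i in range(len(ga))],
            "genotype_a": ga,
            "genotype_b": gb,
            "expected_vaf": expected,
            "depth": depths,
            "alt_reads": alts,
            "vaf": np.where(depths > 0, alts / np.maximum(depths, 1), 0.0),
        }
    )


def simulate_covered_mb(
    config: SimulationConfig,
    rng: np.random.Generator,
    min_depth: int = 150,
    n_probe_positions: int = 2000,
) -> float:
    """Panel extent successfully sequenced in one sample, in megabases.

    Approximated as panel_mb times the fraction of a probe subsample of
    positions reaching ``min_depth`` unique reads.
    """
    depths = draw_depths(n_probe_positions, config, rng)
    return config.panel_mb * float((depths >= min_depth).mean())


def make_truth_sample(
    sample_id: str,
    rng: np.random.Generator,
    *,
    purity: float = 0.6,
    tmb_rate: float = 5.0,
    msi_status: str = "MS-Stable",
    tumor_type: str = "unknown",
    panel_mb: float = 1.33,
    n_tier1: int = 2,
    n_germline: int = 20,
    synonymous_fraction: float = 0.3,
    subclonal_fraction: float = 0.0,
    min_ccf: float = 0.1,
    cn_truth: dict[str, int] | None = None,
    fusion_truth: dict[str, bool] | None = None,
    splice_truth: dict[str, bool] | None = None,
) -> TruthSample:
    """Plant a realistic truth set for one specimen.

    The somatic variant count is Poisson(tmb_rate * panel_mb), split between
    synonymous and nonsynonymous consequences, clonal heterozygous by
    default; a ``subclonal_fraction`` of them instead carries a cellular
    fraction drawn uniformly on [min_ccf, 1), putting some observed VAFs
    near the reporting cutoffs. ``n_tier1`` of them are labelled Tier I.
    Germline loci are planted at 50%/100% VAF in a 2:1 ratio.
    """
    n_somatic = int(rng.poisson(tmb_rate * panel_mb))
    variants: list[TruthVariant] = []
    positions = rng.choice(np.arange(1_000, 60_000_000), size=n_somatic + n_germline, replace=False)
    bases = np.array(["A", "C", "G", "T"])
    for i in range(n_somatic):
        ref = str(rng.choice(bases))
        alt = str(rng.choice([b for b in bases if b != ref]))
        variants.append(
            TruthVariant(
                chrom=f"chr{1 + int(rng.integers(22))}",
                pos=int(positions[i]),
                ref=ref,
                alt=alt,
                gene=str(rng.choice(_SOMATIC_GENES)),
                consequence="synonymous" if rng.random() < synonymous_fraction else "nonsynonymous",
                tier1=i < n_tier1,
                cellular_fraction=1.0
                if rng.random() >= subclonal_fraction
                else float(rng.uniform(min_ccf, 1.0)),
            )
        )
    for j in range(n_germline):
        ref = str(rng.choice(bases))
        alt = str(rng.choice([b for b in bases if b != ref]))
        variants.append(
            TruthVariant(
                chrom=f"chr{1 + int(rng.integers(22))}",
                pos=int(positions[n_somatic + j]),
                ref=ref,
                alt=alt,
                gene=str(rng.choice(_SOMATIC_GENES)),
                consequence="nonsynonymous",
                germline=True,
                allele_dosage=0.5 if rng.random() < 2 / 3 else 1.0,
            )
        )
    return TruthSample(
        sample_id=sample_id,
        purity=purity,
        tumor_type=tumor_type,
        tmb_rate=tmb_rate,
        msi_status=msi_status,
        cn_truth=cn_truth or {},
        fusion_truth=fusion_truth or {},
        splice_truth=splice_truth or {},
        variants=tuple(variants),
    )
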