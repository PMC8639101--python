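"""Tumor mutational burden and microsatellite instability scoring.

TMB is the count of eligible somatic variants — non-germline synonymous and
nonsynonymous calls at >=5% VAF outside the HLA class I genes — divided by
the megabases of panel successfully sequenced (at most 1.33 Mb of exonic
sequence), with TMB-High called at >=10 mutations/Mb. MSI is scored over a
panel of 130 homopolymer sites: a site qualifies when covered by >=60 reads
and is unstable when its baseline-standardized instability statistic
exceeds the normal baseline by k standard deviations; the microsatellite
score is the unstable fraction of qualified sites, MSI-High above 20%, and
the sample is invalid below 40 qualified sites.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "TmbResult",
    "MsiResult",
    "HLA_CLASS_I_GENES",
    "compute_tmb",
    "compute_msi",
    "call_site_instability",
]

HLA_CLASS_I_GENES = frozenset({"HLA-A", "HLA-B", "HLA-C"})

TMB_HIGH_CUTOFF = 10.0          # mutations per Mb
TMB_ELIGIBLE_MIN_VAF = 0.05
MAX_PANEL_MB = 1.33
MSI_HIGH_CUTOFF = 0.20          # MSI-High strictly above


@dataclass(frozen=True)
class TmbResult:
    eligible_count: int
    covered_mb: float
    tmb: float
    classification: str  # TMB-High | TMB-Low


@dataclass(frozen=True)
class MsiResult:
    evaluable_sites: int
    unstable_sites: int
    score: float | None
    classification: str  # MSI-High | MS-Stable | Invalid


def compute_tmb(
    variants: pd.DataFrame,
    covered_mb: float,
    *,
    min_vaf: float = TMB_ELIGIBLE_MIN_VAF,
    high_cutoff: float = TMB_HIGH_CUTOFF,
    max_covered_mb: float = MAX_PANEL_MB,
    include_indels: bool = True,
) -> TmbResult:
    """Mutations per megabase from a sample's variant table.

    Eligibility: non-germline, consequence synonymous or nonsynonymous,
    VAF >= 5%, gene outside HLA-A/B/C. ``covered_mb`` is the panel extent
    actually sequenced to eligibility in this sample. ``include_indels``
    keeps insertion/deletion/delins rows among the eligible counts
    (substitutions and MNVs always count).
    """
    if not 0.0 < covered_mb <= max_covered_mb:
        raise ValueError(
            f"covered_mb must be in (0, {max_covered_mb}], got {covered_mb}"
        )
    if variants.empty:
        eligible = 0
    else:
        mask = (
            ~variants["germline"].astype(bool)
            & variants["consequence"].isin(["synonymous", "nonsynonymous"])
            & (variants["vaf"] >= min_vaf)
            & ~variants["gene"].isin(HLA_CLASS_I_GENES)
        )
        if not include_indels:
            mask &= variants["variant_class"].isin(["substitution", "MNV"])
        eligible = int(mask.sum())
    tmb = eligible / covered_mb
    classification = "TMB-High" if tmb >= high_cutoff else "TMB-Low"
    return TmbResult(eligible, covered_mb, tmb, classification)


def call_site_instability(
    statistic: float,
    baseline_mean: float = 0.0,
    baseline_sd: float = 1.0,
    k: float = 3.0,
) -> bool:
    """A site is unstable when its statistic exceeds baseline mean + k*sd."""
    if baseline_sd <= 0:
        raise ValueError("baseline_sd must be positive")
    return statistic > baseline_mean + k * baseline_sd


def compute_msi(
    sites: pd.DataFrame,
    *,
    min_site_depth: int = 60,
    min_sites: int = 40,
    cutoff: float = MSI_HIGH_CUTOFF,
    baseline_mean: float = 0.0,
    baseline_sd: float = 1.0,
    k: float = 3.0,
) -> MsiResult:
    """Sample-level microsatellite score from a per-site table.

    ``sites`` has columns site_id, depth and either a precomputed boolean
    ``unstable`` column or an ``instability_statistic`` column evaluated
    against the normal baseline. Sites below ``min_site_depth`` reads are
    unqualified and ignored; fewer than ``min_sites`` qualified sites makes
    the sample Invalid; otherwise the score is unstable/qualified with
    MSI-High strictly above the 20% cutoff.
    """
    if min_site_depth < 0 or min_sites < 1:
        raise ValueError("min_site_depth must be >=0 and min_sites >=1")
    qualified = sites[sites["depth"] >= min_site_depth]
    n_eval = len(qualified)
    if n_eval < min_sites:
        return MsiResult(n_eval, 0, None, "Invalid")
    if "unstable" in qualified.columns:
        unstable = qualified["unstable"].astype(bool)
    else:
        unstable = qualified["instability_statistic"].apply(
            call_site_instability, args=(baseline_mean, baseline_sd, k)
        )
    n_unstable = int(unstable.sum())
    score = n_unstable / n_eval
    classification = "MSI-High" if score > cutoff else "MS-Stable"
    return MsiResult(n_eval, n_unstable, score, classification)
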