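"""Hit-rate limit-of-detection estimation and binomial coverage power.

The hit-rate approach evaluates a dilution series (neat down to 1:32) with
replicate testing at each level, builds a percent-detection table with exact
Clopper-Pearson 95% confidence intervals, and reports the LoD as the lowest
(most dilute) level with a 100% hit rate under a worst-scenario reading: a
level only qualifies if every more concentrated level also qualifies.

Coverage power ties read depth to detectability: a variant at allele
fraction ``vaf`` sequenced to ``depth`` unique reads is called when at least
``min_alt`` mutant reads are observed, so detection power is the exact
binomial tail P(X >= min_alt), X ~ Binomial(depth, vaf). Solving for the
smallest depth achieving 95% power at 2% VAF motivates the 400x minimum
coverage used for low-frequency reporting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "DilutionLevel",
    "DilutionSeries",
    "HitRateRow",
    "clopper_pearson",
    "hit_rate_table",
    "hit_rate_lod",
    "lod_at_95",
    "binomial_power",
    "min_coverage",
    "series_from_table",
]


@dataclass(frozen=True)
class DilutionLevel:
    """One dilution level: analyte concentration plus replicate outcomes."""

    level: float  # VAF or tumor-purity fraction
    detected: tuple[bool, ...]

    def __post_init__(self) -> None:
        if len(self.detected) < 1:
            raise ValueError("each level needs at least one replicate")


@dataclass(frozen=True)
class DilutionSeries:
    """Ordered dilution levels for one analyte, most concentrated first."""

    analyte: str
    levels: tuple[DilutionLevel, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not self.levels:
            raise ValueError("dilution series must contain at least one level")
        values = [lv.level for lv in self.levels]
        if any(b >= a for a, b in zip(values, values[1:])):
            raise ValueError("levels must be strictly decreasing in concentration")


@dataclass(frozen=True)
class HitRateRow:
    level: float
    n: int
    hits: int
    hit_rate: float
    ci_low: float
    ci_high: float


def clopper_pearson(hits: int, n: int, confidence: float = 0.95) -> tuple[float, float]:
    """Exact binomial confidence interval from beta quantiles.

    Returns (low, high) with low = 0 when hits = 0 and high = 1 when
    hits = n.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= hits <= n:
        raise ValueError(f"hits must be in [0, n], got hits={hits}, n={n}")
    if not 0 < confidence < 1:
        raise ValueError("confidence must be in (0, 1)")
    alpha = 1.0 - confidence
    low = 0.0 if hits == 0 else float(sps.beta.ppf(alpha / 2, hits, n - hits + 1))
    high = 1.0 if hits == n else float(sps.beta.ppf(1 - alpha / 2, hits + 1, n - hits))
    return low, high


def hit_rate_table(series: DilutionSeries, confidence: float = 0.95) -> pd.DataFrame:
    """Percent-detection table with exact CIs, one row per dilution level."""
    rows = []
    for lv in series.levels:
        n = len(lv.detected)
        hits = int(sum(lv.detected))
        low, high = clopper_pearson(hits, n, confidence)
        rows.append(
            HitRateRow(level=lv.level, n=n, hits=hits, hit_rate=hits / n, ci_low=low, ci_high=high)
        )
    return pd.DataFrame([r.__dict__ for r in rows])


def _lowest_qualifying_level(series: DilutionSeries, min_rate: float) -> float | None:
    # monotone-prefix rule: a level counts only while every more
    # concentrated level also meets the criterion
    lod = None
    for lv in series.levels:
        rate = sum(lv.detected) / len(lv.detected)
        if rate >= min_rate:
            lod = lv.level
        else:
            break
    return lod


def hit_rate_lod(
    series: DilutionSeries, confidence: float = 0.95
) -> tuple[pd.DataFrame, float | None]:
    """LoD as the most dilute level with a 100% hit rate (worst scenario).

    Returns the percent-detection table and the LoD level, or None when no
    level (starting from the most concentrated) achieves 100% detection.
    """
    table = hit_rate_table(series, confidence)
    return table, _lowest_qualifying_level(series, 1.0)


def lod_at_95(series: DilutionSeries) -> float | None:
    """Most dilute level with hit rate >= 95% under the monotone-prefix rule."""
    return _lowest_qualifying_level(series, 0.95)


def binomial_power(depth: int, vaf: float, min_alt: int = 4) -> float:
    """P(at least ``min_alt`` mutant reads), X ~ Binomial(depth, vaf)."""
    if depth < 0:
        raise ValueError("depth must be non-negative")
    if not 0.0 <= vaf <= 1.0:
        raise ValueError(f"vaf must be in [0, 1], got {vaf}")
    if min_alt < 0:
        raise ValueError("min_alt must be non-negative")
    return float(sps.binom.sf(min_alt - 1, depth, vaf))


def min_coverage(vaf: float, target_power: float = 0.95, min_alt: int = 4) -> int:
    """Smallest depth at which ``binomial_power`` reaches ``target_power``.

    Power is monotone non-decreasing in depth, so a bracketing doubling
    search plus bisection finds the exact minimum.
    """
    if not 0.0 < vaf <= 1.0:
        raise ValueError("vaf must be in (0, 1]: a zero-frequency variant is never detectable")
    if not 0.0 < target_power < 1.0:
        raise ValueError("target_power must be in (0, 1)")
    hi = max(min_alt, 1)
    while binomial_power(hi, vaf, min_alt) < target_power:
        hi *= 2
        if hi > 10**9:  # pragma: no cover - unreachable for vaf > 0
            raise RuntimeError("no feasible depth found")
    lo = hi // 2
    while lo < hi:
        mid = (lo + hi) // 2
        if binomial_power(mid, vaf, min_alt) >= target_power:
            hi = mid
        else:
            lo = mid + 1
    return hi


def series_from_table(table: pd.DataFrame, analyte: str | None = None) -> DilutionSeries:
    """Build a DilutionSeries from a long table (analyte, level, detected)."""
    if analyte is not None:
        table = table[table["analyte"] == analyte]
    else:
        analytes = table["analyte"].unique()
        if len(analytes) != 1:
            raise ValueError("table contains multiple analytes; pass analyte=")
        analyte = analytes[0]
    levels = []
    for level, grp in sorted(table.groupby("level"), key=lambda kv: -kv[0]):
        levels.append(DilutionLevel(level=float(level), detected=tuple(grp["detected"].astype(bool))))
    return DilutionSeries(analyte=str(analyte), levels=tuple(levels))
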