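"""Concordance and precision statistics for assay validation.

When a new qualitative test is compared against a non-reference comparator,
sensitivity/specificity analogues are reported as positive and negative
percent agreement from the usual 2x2 table:

    PPA = 100 * TP / (TP + FN)      NPA = 100 * TN / (TN + FP)

with exact Clopper-Pearson 95% intervals. Replicate precision under changed
conditions (run, operator, day, instrument, reagent lot, barcode) is
summarised as average positive/negative agreement — the mean per-variant
positive (negative) call rate across replicates of a condition — and
quantitative TMB precision as the percent coefficient of variation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .lod import clopper_pearson

__all__ = [
    "AgreementTable",
    "Agreement",
    "agreement_from_calls",
    "ppa",
    "npa",
    "apa_ana",
    "tmb_cv",
    "correlation",
]

TMB_CV_ACCEPTANCE = 12.5  # percent; precision bound for replicate TMB scores


@dataclass(frozen=True)
class AgreementTable:
    """2x2 test-vs-comparator counts at a stated aggregation level."""

    tp: int
    fp: int
    fn: int
    tn: int
    level: str = "variant"  # variant | gene | sample

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class Agreement:
    """A percent agreement with its exact 95% confidence interval."""

    percent: float
    numerator: int
    denominator: int
    ci_low: float   # percent
    ci_high: float  # percent


def agreement_from_calls(
    calls: pd.DataFrame,
    *,
    test_col: str = "test_call",
    reference_col: str = "reference_call",
    level: str = "variant",
    indeterminate_as_negative: bool = False,
) -> AgreementTable:
    """Tally a paired-call table into 2x2 counts.

    Calls may be boolean or the strings reported/not_reported/indeterminate.
    Indeterminate test calls are excluded as non-evaluable unless
    ``indeterminate_as_negative`` is set.
    """

    def to_bool(col: pd.Series) -> pd.Series:
        if col.dtype == bool:
            return col
        mapped = col.map(
            {
                "reported": True,
                "not_reported": False,
                True: True,
                False: False,
                "positive": True,
                "negative": False,
            }
        )
        if indeterminate_as_negative:
            mapped = mapped.where(col != "indeterminate", False)
        return mapped

    test = to_bool(calls[test_col])
    ref = to_bool(calls[reference_col])
    keep = test.notna() & ref.notna()
    test, ref = test[keep].astype(bool), ref[keep].astype(bool)
    return AgreementTable(
        tp=int((test & ref).sum()),
        fp=int((test & ~ref).sum()),
        fn=int((~test & ref).sum()),
        tn=int((~test & ~ref).sum()),
        level=level,
    )


def _agreement(numerator: int, denominator: int, confidence: float) -> Agreement:
    low, high = clopper_pearson(numerator, denominator, confidence)
    return Agreement(
        percent=100.0 * numerator / denominator,
        numerator=numerator,
        denominator=denominator,
        ci_low=100.0 * low,
        ci_high=100.0 * high,
    )


def ppa(table: AgreementTable, confidence: float = 0.95) -> Agreement:
    """Positive percent agreement 100*TP/(TP+FN) with exact CI."""
    if table.tp + table.fn == 0:
        raise ValueError("PPA undefined: no comparator-positive calls (tp + fn = 0)")
    return _agreement(table.tp, table.tp + table.fn, confidence)


def npa(table: AgreementTable, confidence: float = 0.95) -> Agreement:
    """Negative percent agreement 100*TN/(TN+FP) with exact CI."""
    if table.tn + table.fp == 0:
        raise ValueError("NPA undefined: no comparator-negative calls (tn + fp = 0)")
    return _agreement(table.tn, table.tn + table.fp, confidence)


def apa_ana(
    replicates: pd.DataFrame,
    condition: str | None = None,
    *,
    key_col: str = "key",
    truth_col: str = "truth_positive",
    detected_col: str = "detected",
) -> pd.DataFrame:
    """Average positive/negative agreement across replicate conditions.

    ``replicates`` is a long table with one row per replicate measurement:
    a variant key, a truth label (is this variant expected positive), the
    per-replicate detection outcome, and optional condition columns. The
    per-variant positive call rate is detected/total replicates; APA is the
    mean rate over truth-positive variants and ANA the mean negative call
    rate over truth-negative variants. With ``condition`` set the result is
    stratified by that column's values; otherwise one pooled row labelled
    "overall" is returned. Percentages are on the 0-100 scale.
    """
    required = {key_col, truth_col, detected_col}
    missing = required - set(replicates.columns)
    if missing:
        raise ValueError(f"replicate table missing columns: {sorted(missing)}")

    def stratum_stats(df: pd.DataFrame, label: str) -> dict:
        if df.empty:
            raise ValueError(f"empty stratum: {label!r}")
        rates = df.groupby(key_col).agg(
            truth=(truth_col, "first"), rate=(detected_col, "mean"), n=(detected_col, "size")
        )
        if (rates["n"] < 2).any():
            under = rates.index[rates["n"] < 2].tolist()
            shown = ", ".join(map(str, under[:5])) + (" ..." if len(under) > 5 else "")
            raise ValueError(
                f"conditions require >=2 replicates per variant; {len(under)} offending keys: {shown}"
            )
        pos = rates[rates["truth"]]
        neg = rates[~rates["truth"]]
        return {
            "condition": label,
            "apa": 100.0 * pos["rate"].mean() if len(pos) else np.nan,
            "ana": 100.0 * (1.0 - neg["rate"]).mean() if len(neg) else np.nan,
            "n_positive_variants": len(pos),
            "n_negative_variants": len(neg),
        }

    if condition is None:
        return pd.DataFrame([stratum_stats(replicates, "overall")])
    if condition not in replicates.columns:
        raise ValueError(f"no such condition column: {condition!r}")
    rows = [stratum_stats(grp, str(label)) for label, grp in replicates.groupby(condition)]
    return pd.DataFrame(rows)


def tmb_cv(values: Sequence[float]) -> float:
    """Percent coefficient of variation of replicate TMB scores.

    100 * sample standard deviation / mean; compared downstream against the
    12.5% acceptance bound (``TMB_CV_ACCEPTANCE``).
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size < 2:
        raise ValueError("CV needs at least two replicate values")
    mean = arr.mean()
    if mean <= 0:
        raise ValueError("CV undefined for non-positive mean")
    return float(100.0 * arr.std(ddof=1) / mean)


def correlation(x: Iterable[float], y: Iterable[float]) -> tuple[float, float]:
    """Pearson R and R^2 for paired quantitative values."""
    xa = np.asarray(list(x), dtype=float)
    ya = np.asarray(list(y), dtype=float)
    if xa.size != ya.size:
        raise ValueError("x and y must be the same length")
    if xa.size < 3:
        raise ValueError("correlation needs at least 3 pairs")
    if np.isclose(xa.std(), 0) or np.isclose(ya.std(), 0):
        raise ValueError("correlation undefined for zero-variance input")
    r = float(np.corrcoef(xa, ya)[0, 1])
    return r, r * r
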