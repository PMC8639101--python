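"""Purity-aware copy-number fold-change model and five-state classification.

A tumor specimen is a mixture of neoplastic cells at purity ``p`` carrying
``c`` copies of a gene and normal diploid cells. The expected normalized
read-depth fold change relative to a diploid baseline is

    FC = (p * c + (1 - p) * 2) / 2

so a tumor with 10 copies at 30% purity yields FC = 2.2 and a homozygous
deletion (0 copies) at 50% purity yields FC = 0.5. Calls are classified per
gene role: oncogenes on the gain path (gain / gain-indeterminate / negative)
and tumor suppressors on the loss path (loss / loss-indeterminate /
negative), with the indeterminate zones signalling sub-threshold evidence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

__all__ = [
    "GeneRole",
    "CnaClass",
    "CnaThresholds",
    "CopyNumberCall",
    "expected_fold_change",
    "classify_copy_number",
    "min_purity_for_call",
]


class GeneRole(str, Enum):
    """Direction of clinically relevant copy-number change for a gene."""

    ONCOGENE_GAIN = "oncogene_gain"
    TSG_LOSS = "tsg_loss"


class CnaClass(str, Enum):
    GAIN = "gain"
    GAIN_INDETERMINATE = "gain_indeterminate"
    NEGATIVE = "negative"
    LOSS_INDETERMINATE = "loss_indeterminate"
    LOSS = "loss"


@dataclass(frozen=True)
class CnaThresholds:
    """Fold-change decision cuts.

    Gain is called at FC >= ``gain_fc`` and gain-indeterminate on
    [``gain_ind_fc``, ``gain_fc``); loss at FC <= ``loss_fc`` and
    loss-indeterminate on (``loss_fc``, ``loss_ind_fc``].
    """

    gain_fc: float = 3.2
    gain_ind_fc: float = 2.2
    loss_fc: float = 0.5
    loss_ind_fc: float = 0.7

    def __post_init__(self) -> None:
        if not (self.loss_fc < self.loss_ind_fc < 1 < self.gain_ind_fc < self.gain_fc):
            raise ValueError(
                "thresholds must satisfy loss_fc < loss_ind_fc < 1 < gain_ind_fc < gain_fc"
            )


@dataclass(frozen=True)
class CopyNumberCall:
    """Per-gene fold-change observation with its five-state classification."""

    sample_id: str
    gene: str
    fc: float
    gene_role: GeneRole
    classification: CnaClass

    def __post_init__(self) -> None:
        if not (self.fc > 0 and math.isfinite(self.fc)):
            raise ValueError(f"fold change must be finite and positive, got {self.fc}")


def expected_fold_change(purity: float, copies: int | float) -> float:
    """Expected fold change for ``copies`` tumor copies at the given purity.

    FC = (purity*copies + (1-purity)*2) / 2; a diploid tumor (copies=2)
    yields 1.0 at any purity.
    """
    if not (0.0 <= purity <= 1.0) or not math.isfinite(purity):
        raise ValueError(f"purity must be in [0, 1], got {purity}")
    if copies < 0 or not math.isfinite(copies):
        raise ValueError(f"copies must be non-negative, got {copies}")
    return (purity * copies + (1.0 - purity) * 2.0) / 2.0


def classify_copy_number(
    fc: float,
    gene_role: GeneRole | str,
    thresholds: CnaThresholds | None = None,
) -> CnaClass:
    """Classify a fold change along the gain or loss path for the gene's role."""
    thresholds = thresholds or CnaThresholds()
    if not (fc > 0 and math.isfinite(fc)):
        raise ValueError(f"fold change must be finite and positive, got {fc}")
    role = GeneRole(gene_role)
    if role is GeneRole.ONCOGENE_GAIN:
        if fc >= thresholds.gain_fc:
            return CnaClass.GAIN
        if fc >= thresholds.gain_ind_fc:
            return CnaClass.GAIN_INDETERMINATE
        return CnaClass.NEGATIVE
    # tumor-suppressor loss path
    if fc <= thresholds.loss_fc:
        return CnaClass.LOSS
    if fc <= thresholds.loss_ind_fc:
        return CnaClass.LOSS_INDETERMINATE
    return CnaClass.NEGATIVE


def min_purity_for_call(
    copies: int,
    gene_role: GeneRole | str,
    thresholds: CnaThresholds | None = None,
    *,
    fc_cut: float | None = None,
) -> float:
    """Minimum tumor purity at which ``copies`` reaches the decision fold change.

    Inverts the mixture model at the decision cut: purity =
    2*(FC_cut - 1)/(copies - 2). By default the cut is the outer edge of
    the detectable zone — the gain-indeterminate bound (2.2) for
    oncogenes and the loss bound (0.5) for tumor suppressors, matching
    the model's two anchor equivalences; pass ``fc_cut`` to invert at any
    other fold change. Returns ``math.inf`` when no purity in (0, 1] can
    reach the cut (the change is not detectable at any purity).
    """
    thresholds = thresholds or CnaThresholds()
    role = GeneRole(gene_role)
    if copies == 2:
        raise ValueError("copies=2 is diploid: FC is 1 at every purity, inversion undefined")
    if copies < 0:
        raise ValueError(f"copies must be non-negative, got {copies}")
    if fc_cut is None:
        fc_cut = (
            thresholds.gain_ind_fc if role is GeneRole.ONCOGENE_GAIN else thresholds.loss_fc
        )
    purity = 2.0 * (fc_cut - 1.0) / (copies - 2.0)
    if not (0.0 < purity <= 1.0):
        return math.inf
    return purity
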