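"""End-to-end synthetic validation study orchestration.

``run_validation_study`` mirrors the structure of an analytical validation:
an accuracy stage (test-vs-truth 2x2 agreement per variant class), a
precision stage (replicate APA/ANA across conditions and TMB %CV), and a
limit-of-detection stage (dilution series, percent-detection tables,
hit-rate LoD). Every stage consumes synthetic cohorts from
:mod:`cgpval.simulate` under one seeded generator, applies the decision
rules exactly as the single-sample modules do, and summarises with
:mod:`cgpval.stats` / :mod:`cgpval.lod`. Reports carry a provenance block
(version, seed, config digest) so a run is reproducible from the config
alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cna import CnaThresholds, GeneRole, classify_copy_number, expected_fold_change
from .lod import DilutionLevel, DilutionSeries, hit_rate_lod
from .qc import QcThresholds
from .reportability import RuleThresholds, apply_rules_to_table, classify_fusion, classify_splice
from .signatures import compute_msi, compute_tmb
from .simulate import (
    GAIN_GENES,
    LOSS_GENES,
    FUSION_GENES,
    SimulationConfig,
    make_truth_sample,
    simulate_msi_sites,
    simulate_variant_table,
)
from .stats import agreement_from_calls, apa_ana, npa, ppa, tmb_cv

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_validation_study", "version_and_provenance"]


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce a study run."""

    seed: int = 0
    n_samples: int = 8
    n_precision_replicates: int = 6
    dilution_levels: tuple[float, ...] = (1.0, 0.5, 0.25, 0.125, 0.0625, 0.03125)
    lod_replicates: int = 4
    fc_noise_sd: float = 0.05  # log-scale SD of observed fold change
    rules: RuleThresholds = field(default_factory=RuleThresholds)
    cna: CnaThresholds = field(default_factory=CnaThresholds)
    qc: QcThresholds = field(default_factory=QcThresholds)
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    rounding: int = 1
    ci_level: float = 0.95

    def digest(self) -> str:
        payload = yaml.safe_dump(asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def version_and_provenance(config: RunConfig) -> dict:
    """Provenance block stamped into every report."""
    return {"tool": "cgpval", "version": __version__, "seed": config.seed,
            "config_digest": config.digest()}


def _agreement_block(table, confidence: float) -> dict:
    out: dict = {"tp": table.tp, "fp": table.fp, "fn": table.fn, "tn": table.tn,
                 "level": table.level}
    if table.tp + table.fn > 0:
        a = ppa(table, confidence)
        out["ppa"] = {"percent": a.percent, "ci": [a.ci_low, a.ci_high],
                      "fraction": f"{a.numerator}/{a.denominator}"}
    if table.tn + table.fp > 0:
        a = npa(table, confidence)
        out["npa"] = {"percent": a.percent, "ci": [a.ci_low, a.ci_high],
                      "fraction": f"{a.numerator}/{a.denominator}"}
    return out


def _simulate_cna_calls(truth, config: RunConfig, rng) -> pd.DataFrame:
    """Observed fold changes with log-normal noise, classified per gene role."""
    rows = []
    for gene in GAIN_GENES + LOSS_GENES:
        copies = truth.cn_truth.get(gene, 2)
        role = GeneRole.ONCOGENE_GAIN if gene in GAIN_GENES else GeneRole.TSG_LOSS
        fc = expected_fold_change(truth.purity, copies) * float(
            rng.lognormal(0.0, config.fc_noise_sd)
        )
        cls = classify_copy_number(fc, role, config.cna)
        positive = (
            cls.value in ("gain", "gain_indeterminate")
            if role is GeneRole.ONCOGENE_GAIN
            else cls.value in ("loss", "loss_indeterminate")
        )
        truth_positive = copies > 2 if role is GeneRole.ONCOGENE_GAIN else copies < 2
        rows.append(
            {"sample_id": truth.sample_id, "gene": gene, "role": role.value, "fc": fc,
             "classification": cls.value, "test_call": positive,
             "reference_call": truth_positive}
        )
    return pd.DataFrame(rows)


def _simulate_rna_reads(truth, rng, mean_positive_reads: float = 60.0) -> pd.DataFrame:
    """Unique supporting read counts for fusion and splice targets."""
    rows = []
    for gene in FUSION_GENES:
        present = truth.fusion_truth.get(gene, False)
        lam = mean_positive_reads * truth.purity if present else 0.05
        reads = int(rng.poisson(lam))
        rows.append({"sample_id": truth.sample_id, "target": gene, "kind": "fusion",
                     "unique_reads": reads, "reference_call": present})
    for target in ("MET_ex14", "EGFR_ex2_7"):
        present = truth.splice_truth.get(target, False)
        lam = mean_positive_reads * truth.purity if present else 0.05
        reads = int(rng.poisson(lam))
        rows.append({"sample_id": truth.sample_id, "target": target, "kind": "splice",
                     "unique_reads": reads, "reference_call": present})
    return pd.DataFrame(rows)


def _make_cohort(config: RunConfig, rng) -> list:
    """Truth samples spanning purity, TMB and MSI conditions."""
    truths = []
    purities = np.linspace(0.3, 0.9, config.n_samples)
    for i in range(config.n_samples):
        msi_high = i % 4 == 0
        tmb_rate = 20.0 if i % 3 == 0 else 4.0
        cn = {}
        if i % 2 == 0:
            cn[GAIN_GENES[i % len(GAIN_GENES)]] = 12
        if i % 3 == 0:
            cn[LOSS_GENES[i % len(LOSS_GENES)]] = 0
        fusions = {FUSION_GENES[i % len(FUSION_GENES)]: i % 2 == 1}
        splices = {"MET_ex14": i % 4 == 1}
        truths.append(
            make_truth_sample(
                f"S{i:03d}",
                rng,
                purity=float(purities[i]),
                tmb_rate=tmb_rate,
                msi_status="MSI-High" if msi_high else "MS-Stable",
                cn_truth=cn,
                fusion_truth=fusions,
                splice_truth=splices,
            )
        )
    return truths


def _accuracy_stage(config: RunConfig, rng) -> dict:
    truths = _make_cohort(config, rng)
    small_frames, cna_frames, rna_frames = [], [], []
    msi_rows, tmb_rows = [], []
    for truth in truths:
        table = simulate_variant_table(truth, config.sim, rng)
        annotated, _ = apply_rules_to_table(table, config.rules)
        somatic = annotated[~annotated["germline"]].copy()
        somatic["test_call"] = somatic["status"].map(
            {"reported": True, "not_reported": False, "indeterminate": None}
        )
        somatic["reference_call"] = somatic["truth_positive"]
        small_frames.append(somatic)

        cna_frames.append(_simulate_cna_calls(truth, config, rng))
        rna_frames.append(_simulate_rna_reads(truth, rng))

        sites = simulate_msi_sites(truth, config.sim, rng)
        msi = compute_msi(sites)
        msi_rows.append({"sample_id": truth.sample_id,
                         "test_call": msi.classification == "MSI-High",
                         "reference_call": truth.msi_status == "MSI-High"})

        tmb = compute_tmb(somatic.drop(columns=["test_call", "reference_call"]),
                          covered_mb=config.sim.panel_mb)
        tmb_rows.append({"sample_id": truth.sample_id, "tmb": tmb.tmb,
                         "test_call": tmb.classification == "TMB-High",
                         "reference_call": truth.tmb_rate >= 10.0})

    small = pd.concat(small_frames, ignore_index=True)
    cna_calls = pd.concat(cna_frames, ignore_index=True)
    rna = pd.concat(rna_frames, ignore_index=True)
    rna["test_call"] = [
        (classify_fusion(r, config.rules).status.value == "reported")
        if k == "fusion"
        else (classify_splice(r, config.rules).status.value == "reported")
        for r, k in zip(rna["unique_reads"], rna["kind"])
    ]

    blocks = {}
    blocks["small_variants"] = _agreement_block(
        agreement_from_calls(small.dropna(subset=["test_call"]), level="variant"),
        config.ci_level,
    )
    for role, label in ((GeneRole.ONCOGENE_GAIN, "copy_gain"), (GeneRole.TSG_LOSS, "copy_loss")):
        sub = cna_calls[cna_calls["role"] == role.value]
        blocks[label] = _agreement_block(agreement_from_calls(sub, level="gene"), config.ci_level)
    for kind in ("fusion", "splice"):
        sub = rna[rna["kind"] == kind]
        blocks[kind + "s"] = _agreement_block(agreement_from_calls(sub, level="gene"), config.ci_level)
    blocks["msi"] = _agreement_block(
        agreement_from_calls(pd.DataFrame(msi_rows), level="sample"), config.ci_level
    )
    blocks["tmb"] = _agreement_block(
        agreement_from_calls(pd.DataFrame(tmb_rows), level="sample"), config.ci_level
    )
    logger.info("accuracy stage: %d samples, %d small-variant rows", len(truths), len(small))
    return blocks


def _precision_stage(config: RunConfig, rng) -> dict:
    # subclonal variants put some expected VAFs near the 5% cutoff so
    # replicate-to-replicate eligibility (hence TMB) actually varies
    truth = make_truth_sample("P000", rng, purity=0.7, tmb_rate=15.0, subclonal_fraction=0.4)
    rows, tmb_values = [], []
    conditions = ["run1", "run2"]
    for cond in conditions:
        for rep in range(config.n_precision_replicates):
            table = simulate_variant_table(truth, config.sim, rng)
            annotated, _ = apply_rules_to_table(table, config.rules)
            somatic = annotated[~annotated["germline"]]
            for _, row in somatic.iterrows():
                rows.append(
                    {"key": f"{row['chrom']}:{row['pos']}:{row['alt']}",
                     "truth_positive": bool(row["truth_positive"]),
                     "detected": row["status"] == "reported",
                     "run": cond, "replicate": rep}
                )
            tmb_values.append(compute_tmb(somatic, covered_mb=config.sim.panel_mb).tmb)
    replicates = pd.DataFrame(rows)
    overall = apa_ana(replicates)
    by_run = apa_ana(replicates, condition="run")
    cv = tmb_cv(tmb_values)
    logger.info("precision stage: %d replicate rows, TMB CV %.2f%%", len(replicates), cv)
    return {
        "apa_ana_overall": overall.to_dict(orient="records"),
        "apa_ana_by_run": by_run.to_dict(orient="records"),
        "tmb_cv_percent": cv,
        "tmb_cv_acceptance": cv <= 12.5,
        "n_replicates": config.n_precision_replicates * len(conditions),
    }


def _lod_stage(config: RunConfig, rng) -> dict:
    truth = make_truth_sample("L000", rng, purity=0.8, tmb_rate=8.0, msi_status="MSI-High",
                              n_tier1=1)
    tier1 = next(tv for tv in truth.variants if tv.tier1)
    out = {}
    # small-variant LoD on the Tier I variant, tracked through the rules
    levels = []
    for level in config.dilution_levels:
        detected = []
        diluted = replace(truth, purity=truth.purity * level)
        for _ in range(config.lod_replicates):
            table = simulate_variant_table(diluted, config.sim, rng)
            annotated, _ = apply_rules_to_table(table, config.rules)
            row = annotated[(annotated["pos"] == tier1.pos) & (annotated["chrom"] == tier1.chrom)]
            detected.append(bool((row["status"] == "reported").all() and len(row) == 1))
        levels.append(DilutionLevel(level=tier1.expected_vaf(diluted.purity), detected=tuple(detected)))
    series = DilutionSeries(analyte="tier1_small_variant", levels=tuple(levels))
    table_sv, lod_sv = hit_rate_lod(series, config.ci_level)
    out["small_variant_vaf"] = {"table": table_sv.to_dict(orient="records"), "lod": lod_sv}

    # MSI LoD on tumor purity
    levels = []
    for level in config.dilution_levels:
        diluted = replace(truth, purity=truth.purity * level)
        detected = []
        for _ in range(config.lod_replicates):
            msi = compute_msi(simulate_msi_sites(diluted, config.sim, rng))
            detected.append(msi.classification == "MSI-High")
        levels.append(DilutionLevel(level=diluted.purity, detected=tuple(detected)))
    series = DilutionSeries(analyte="msi_purity", levels=tuple(levels))
    table_msi, lod_msi = hit_rate_lod(series, config.ci_level)
    out["msi_purity"] = {"table": table_msi.to_dict(orient="records"), "lod": lod_msi}

    logger.info("LoD stage: small-variant LoD %s, MSI LoD %s", lod_sv, lod_msi)
    return out


def run_validation_study(config: RunConfig | None = None, out_dir: str | Path | None = None) -> dict:
    """Run accuracy, precision and LoD stages on synthetic cohorts.

    Returns the report as a dict and, when ``out_dir`` is given, writes
    ``report.json`` there. Deterministic under a fixed config seed.
    """
    config = config or RunConfig()
    rng = np.random.default_rng(config.seed)
    report = {"provenance": version_and_provenance(config)}
    thresholds_in_effect = {
        "rules": asdict(config.rules), "cna": asdict(config.cna), "qc": asdict(config.qc)
    }
    logger.info("thresholds in effect: %s", thresholds_in_effect)
    report["thresholds"] = thresholds_in_effect
    for name, stage in (("accuracy", _accuracy_stage), ("precision", _precision_stage),
                        ("lod", _lod_stage)):
        try:
            report[name] = stage(config, rng)
        except Exception as exc:
            raise RuntimeError(f"validation stage {name!r} failed: {exc}") from exc
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, default=float)
    return report
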