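"""Cohort-level summaries: coverage QC, carrier burden, diagnostic yield."""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .core import (
    CohortSummary,
    DiagnosticStatus,
    FamilyReport,
    GenePanel,
    Reported,
    VariantRecord,
    Zygosity,
)
from .prioritize import PrioritizationConfig, count_positive_predictors


def coverage_summary(depths) -> dict:
    """Median depth and C10/C30 (percent of bases covered >= 10x / 30x)."""
    depths = np.asarray(depths, dtype=float)
    if depths.size == 0:
        raise ValueError("empty coverage target")
    if (depths < 0).any():
        raise ValueError("depths must be >= 0")
    return {
        "median": float(np.median(depths)),
        "C10": float(100.0 * np.mean(depths >= 10)),
        "C30": float(100.0 * np.mean(depths >= 30)),
    }


@dataclass
class CarrierBurden:
    per_patient: dict
    mean_known_het_recessive: float
    mean_rare_predicted_pathogenic: float


def carrier_burden(patient_variants: dict,
                   panel: GenePanel,
                   causative_keys: dict | None = None,
                   config: PrioritizationConfig | None = None) -> CarrierBurden:
    """Per-patient heterozygous carrier burden in panel genes.

    ``patient_variants`` maps patient id to a list of
    ``(VariantRecord, Zygosity)``; ``causative_keys`` maps patient id to
    the set of variant keys of the family's causative genotype, which
    are excluded from the counts.  Two counts per patient: known
    (reported) pathogenic recessive alleles carried het, and unreported
    het alleles predicted damaging by at least two algorithms.
    """
    config = config or PrioritizationConfig()
    causative_keys = causative_keys or {}
    per_patient = {}
    for patient, variants in patient_variants.items():
        excluded = causative_keys.get(patient, set())
        known = 0
        predicted = 0
        for rec, zyg in variants:
            if zyg is not Zygosity.HET or rec.key() in excluded:
                continue
            gene = panel.get(rec.gene)
            if gene is None or "AR" not in gene.inheritance_modes:
                continue
            if rec.reported is Reported.REPORTED_PATHOGENIC:
                known += 1
            elif count_positive_predictors(rec.predictions, config) >= 2:
                predicted += 1
        per_patient[patient] = (known, predicted)
    n = max(len(per_patient), 1)
    return CarrierBurden(
        per_patient=per_patient,
        mean_known_het_recessive=sum(k for k, _ in per_patient.values()) / n,
        mean_rare_predicted_pathogenic=sum(p for _, p in per_patient.values()) / n,
    )


def cohort_yield(reports: list[FamilyReport]) -> CohortSummary:
    """Diagnostic yield over one report per family."""
    ids = [r.family_id for r in reports]
    if len(ids) != len(set(ids)):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate family id(s): {dupes}")
    return CohortSummary(
        n_solved=sum(r.status is DiagnosticStatus.SOLVED for r in reports),
        n_candidate=sum(r.status is DiagnosticStatus.CANDIDATE for r in reports),
        n_unsolved=sum(r.status is DiagnosticStatus.UNSOLVED for r in reports),
    )


def summary_to_dict(summary: CohortSummary) -> dict:
    return {
        "n_families": summary.n_families,
        "n_solved": summary.n_solved,
        "n_candidate": summary.n_candidate,
        "n_unsolved": summary.n_unsolved,
        "frac_solved": summary.frac_solved,
        "frac_candidate": summary.frac_candidate,
        "pct_solved": summary.pct_solved,
        "pct_candidate": summary.pct_candidate,
    }


def write_summary_json(path, summary: CohortSummary):
    with open(path, "w") as fh:
        json.dump(summary_to_dict(summary), fh, indent=2)
        fh.write("\n")


def family_report_dict(report: FamilyReport) -> dict:
    out = {
        "family_id": report.family_id,
        "status": report.status.value,
        "notes": report.notes,
        "modifiers": [v.hgvs or f"{v.chrom}:{v.pos}{v.ref}>{v.alt}"
                      for v in report.modifiers],
    }
    if report.causative is not None:
        cand = report.causative.candidate
        out["causative"] = {
            "gene": cand.gene,
            "model": cand.model.value,
            "cosegregation": cand.cosegregation.value,
            "alleles": [
                {
                    "hgvs": a.variant.hgvs,
                    "class": a.acmg_class.value,
                    "evidence": sorted(a.evidence.codes),
                }
                for a in report.causative.alleles
            ],
        }
    return out
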