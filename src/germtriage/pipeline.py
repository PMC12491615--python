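"""End-to-end orchestration: classify, screen, filter, score, report.

Stages run in the study-workflow order: (1) PPV/POV/PSLF classification
restricted to the DDR/PCa gene universe, (2) cross-cohort gene screen
against non-African cases and healthy aged controls, (3) population-
control MAF screen, (4) per-carrier CHIP VAF filter, then tumor-matched
evidence, the 9-step weighted ranking and prevalence statistics.  Every
excluded variant carries exactly one machine-parseable reason code, and
the run summary's filter funnel conserves counts at every stage.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import pandas as pd

from . import variant_io
from .bundle import InputBundle
from .chip_filter import (
    EXCLUDE_CHIP,
    ChipDecision,
    VariantChipStatus,
    multi_carrier_resolution,
    screen_carrier,
)
from .classification import (
    ClassifiedVariant,
    classify_variant,
    restrict_gene_set,
)
from .config import PipelineConfig
from .cross_cohort import (
    GeneScreenDecision,
    gene_burden,
    gene_exclusion_screen,
    shared_variant_report,
)
from .errors import GermtriageError
from .frequency import CohortFrequency, control_screen, tier_gnomad
from .ranking import (
    CarrierScore,
    GeneSummary,
    VariantScore,
    format_prevalence,
    prevalence,
    rank_genes,
    rank_variant,
    score_carrier,
)
from .tumor_evidence import TumorEvidence, detect_loh, detect_second_hit
from .types import GenotypeCall

log = logging.getLogger(__name__)

REASON_CROSS_COHORT = "cross_cohort_burden"
REASON_CONTROL = "control_maf"
REASON_CHIP = "chip_vaf"
REASON_CHIP_MISSING = "chip_missing_vaf"
REASON_NO_CARRIERS = "no_carriers"

FUNNEL_STAGES = (
    "input",
    "candidates_classified",
    "gene_set_restricted",
    "cross_cohort_screened",
    "control_screened",
    "chip_screened",
)


@dataclass
class PipelineResult:
    classified: list[ClassifiedVariant]
    stage1_classes: dict[str, str]
    gene_screen: dict[str, GeneScreenDecision]
    shared_report: pd.DataFrame
    control_borderline: dict[str, str]
    chip_decisions: list[ChipDecision]
    chip_status: dict[str, VariantChipStatus]
    retained: list[ClassifiedVariant]
    retained_carriers: dict[str, list[GenotypeCall]]
    tumor_evidence: dict[tuple[str, str], TumorEvidence]
    variant_scores: list[VariantScore]
    gene_summaries: list[GeneSummary]
    prevalence_blocks: dict[str, dict]
    funnel: dict
    run_summary: dict
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)


def _cohort_frequencies(
    calls: list[GenotypeCall],
    patients_by_cohort: dict[str, list[str]],
) -> dict[str, dict[str, CohortFrequency]]:
    """key -> cohort -> CohortFrequency for every variant with a carrier."""
    cohort_of = {
        pid: cohort for cohort, pids in patients_by_cohort.items() for pid in pids
    }
    counts: dict[str, dict[str, list[int]]] = {}
    for call in calls:
        if call.missing or call.allele_count == 0:
            continue
        cohort = cohort_of.get(call.patient_id)
        if cohort is None:
            continue
        slot = counts.setdefault(call.key, {}).setdefault(cohort, [0, 0])
        slot[0] += int(call.allele_count == 1)
        slot[1] += int(call.allele_count == 2)
    out: dict[str, dict[str, CohortFrequency]] = {}
    for key, per_cohort in counts.items():
        out[key] = {
            cohort: CohortFrequency(
                cohort, len(patients_by_cohort[cohort]), het, hom
            )
            for cohort, (het, hom) in per_cohort.items()
        }
    return out


def run_pipeline(
    bundle: InputBundle,
    config: PipelineConfig = PipelineConfig(),
    out_dir: Optional[str | Path] = None,
    seed: Optional[int] = None,
) -> PipelineResult:
    """Run all stages on one input bundle; optionally write result tables."""
    sizes = bundle.cohort_sizes()
    patients_by_cohort: dict[str, list[str]] = {}
    patient_map = {p.patient_id: p for p in bundle.patients}
    for p in bundle.patients:
        patients_by_cohort.setdefault(p.cohort, []).append(p.patient_id)
    case_cohorts = [c for c in ("SAPCS", "PPCG") if sizes.get(c)]
    freqs = _cohort_frequencies(bundle.calls, patients_by_cohort)

    def case_freqs(key: str) -> list[CohortFrequency]:
        return [
            f for c, f in sorted(freqs.get(key, {}).items()) if c in case_cohorts
        ]

    # ---- stage 1: classification + gene-set restriction -----------------
    classified = []
    for v in bundle.variants:
        ann = bundle.annotations[v.key]
        tier = tier_gnomad(ann, config.maf_rare, config.maf_low)
        classified.append(
            classify_variant(
                v, ann, tier, case_freqs(v.key),
                pslf_floor=config.pslf_floor,
                require_cgi_driver=config.require_cgi_driver,
                sift_polyphen_mode=config.sift_polyphen_mode,
            )
        )
    n_candidates_classified = sum(cv.is_candidate for cv in classified)
    classified = restrict_gene_set(classified, bundle.gene_lists)
    stage1_classes = {cv.key: cv.cls for cv in classified}
    n_after_gene = sum(cv.is_candidate for cv in classified)

    # drop candidates nobody carries (nothing downstream can use them)
    classified = [
        cv
        if not (cv.is_candidate and not case_freqs(cv.key))
        else replace(cv, cls="excluded", exclusion_reason=REASON_NO_CARRIERS)
        for cv in classified
    ]

    # ---- stage 2: cross-cohort gene screen -------------------------------
    case_calls = [
        c for c in bundle.calls
        if patient_map.get(c.patient_id) and patient_map[c.patient_id].role == "case"
    ]
    african_ppvs = [cv for cv in classified if cv.is_ppv_class]
    african_genes = sorted({(cv.variant.gene or "").upper() for cv in african_ppvs})
    n_cases = sum(sizes.get(c, 0) for c in case_cohorts)
    gene_screen: dict[str, GeneScreenDecision] = {}
    shared_report = pd.DataFrame()
    if bundle.comparison and african_ppvs and n_cases:
        african_burden = gene_burden(
            african_ppvs, case_calls, "AFRICAN", n_cases, genes=african_genes
        )
        comparison_burdens = []
        comparison_freqs: dict[str, dict[str, float]] = {}
        for name, comp in sorted(bundle.comparison.items()):
            comp_classified = []
            for v in comp.variants:
                ann = bundle.annotations.get(v.key)
                if ann is None:
                    continue
                tier = tier_gnomad(ann, config.maf_rare, config.maf_low)
                comp_classified.append(
                    classify_variant(
                        v, ann, tier, [],
                        pslf_floor=config.pslf_floor,
                        require_cgi_driver=config.require_cgi_driver,
                        sift_polyphen_mode=config.sift_polyphen_mode,
                    )
                )
            comp_classified = restrict_gene_set(comp_classified, bundle.gene_lists)
            comparison_burdens.append(
                gene_burden(comp_classified, comp.calls, name, comp.n_patients)
            )
            per_key: dict[str, list[int]] = {}
            for call in comp.calls:
                if call.allele_count > 0:
                    per_key.setdefault(call.key, [0, 0])
                    per_key[call.key][0] += int(call.allele_count == 1)
                    per_key[call.key][1] += int(call.allele_count == 2)
            comparison_freqs[name] = {
                key: (het + 2 * hom) / (2 * comp.n_patients)
                for key, (het, hom) in per_key.items()
            }
        gene_screen = gene_exclusion_screen(
            african_burden, comparison_burdens, config.burden_metric
        )
        shared_report = shared_variant_report(african_ppvs, comparison_freqs)
        excluded_genes = {g for g, d in gene_screen.items() if not d.keep}
        if excluded_genes:
            classified = [
                replace(cv, cls="excluded", exclusion_reason=REASON_CROSS_COHORT)
                if cv.is_candidate and (cv.variant.gene or "").upper() in excluded_genes
                else cv
                for cv in classified
            ]
    n_after_cross = sum(cv.is_candidate for cv in classified)

    # ---- stage 3: population-control MAF screen --------------------------
    control_borderline: dict[str, str] = {}
    screened = []
    for cv in classified:
        if not cv.is_candidate:
            screened.append(cv)
            continue
        decision = control_screen(
            freqs.get(cv.key, {}).get("SAC"),
            freqs.get(cv.key, {}).get("EAC"),
            config.control_exclude,
        )
        if not decision.keep:
            cv = replace(cv, cls="excluded", exclusion_reason=REASON_CONTROL)
        elif decision.borderline:
            control_borderline[cv.key] = decision.detail
        screened.append(cv)
    classified = screened
    n_after_control = sum(cv.is_candidate for cv in classified)

    # ---- stage 4: CHIP VAF filter (per carrier) ---------------------------
    candidate_keys = {cv.key: cv for cv in classified if cv.is_candidate}
    carrier_calls = [
        c for c in case_calls
        if c.key in candidate_keys and c.allele_count > 0 and not c.missing
    ]
    chip_decisions = [
        screen_carrier(
            call,
            candidate_keys[call.key].variant.gene,
            bundle.gene_lists,
            config.chip_vaf_threshold,
        )
        for call in carrier_calls
    ]
    chip_status = multi_carrier_resolution(chip_decisions)
    retained_carriers: dict[str, list[GenotypeCall]] = {}
    call_map = {(c.patient_id, c.key): c for c in carrier_calls}
    final = []
    for cv in classified:
        if not cv.is_candidate:
            final.append(cv)
            continue
        status = chip_status.get(cv.key)
        if status is None or not status.retained:
            reasons = [
                d.decision for d in chip_decisions if d.key == cv.key
            ]
            reason = (
                REASON_CHIP if EXCLUDE_CHIP in reasons else REASON_CHIP_MISSING
            ) if reasons else REASON_NO_CARRIERS
            final.append(replace(cv, cls="excluded", exclusion_reason=reason))
            continue
        retained_carriers[cv.key] = [
            call_map[(pid, cv.key)] for pid in status.retained_carriers
        ]
        final.append(cv)
    classified = final
    retained = [cv for cv in classified if cv.is_candidate]
    n_retained = len(retained)

    # ---- tumor-matched evidence ------------------------------------------
    vaf_map = {(d.patient_id, d.key): d.vaf for d in chip_decisions}
    tumor_evidence: dict[tuple[str, str], TumorEvidence] = {}
    for cv in retained:
        for call in retained_carriers[cv.key]:
            patient = patient_map[call.patient_id]
            profile = bundle.somatic.get(call.patient_id)
            available = patient.tumor_available and profile is not None
            loh = second = False
            if available:
                loh = detect_loh(
                    cv.variant,
                    vaf_map.get((call.patient_id, cv.key)),
                    profile,
                    config.loh_af_threshold,
                    config.loh_af_delta,
                )
                second = detect_second_hit(cv.variant, profile)
            tumor_evidence[(call.patient_id, cv.key)] = TumorEvidence(
                key=cv.key, patient_id=call.patient_id,
                loh=loh, second_hit=second, tumor_available=available,
            )

    # ---- ranking ----------------------------------------------------------
    decision_map = {(d.patient_id, d.key): d for d in chip_decisions}
    variant_scores = []
    for cv in retained:
        sac = freqs.get(cv.key, {}).get("SAC")
        eac = freqs.get(cv.key, {}).get("EAC")
        carrier_scores = [
            score_carrier(
                cv,
                decision_map[(call.patient_id, cv.key)],
                patient_map[call.patient_id],
                tumor_evidence.get((call.patient_id, cv.key)),
                config.weights,
                sac.maf if sac else 0.0,
                eac.maf if eac else 0.0,
            )
            for call in retained_carriers[cv.key]
        ]
        variant_scores.append(rank_variant(cv, carrier_scores, config.recurrence))
    gene_summaries = rank_genes(variant_scores, bundle.gene_lists.known_gt_genes)

    # ---- prevalence -------------------------------------------------------
    class_by_key = {cv.key: cv for cv in retained}
    all_pairs = [
        (pid, class_by_key[key].variant.gene)
        for key, calls in retained_carriers.items()
        for pid in (c.patient_id for c in calls)
    ]
    ppv_pairs = [
        (c.patient_id, class_by_key[key].variant.gene)
        for key, calls in retained_carriers.items()
        if class_by_key[key].is_ppv_class
        for c in calls
    ]
    known_gt = bundle.gene_lists.known_gt_genes
    prevalence_blocks = {}
    case_patients = [p for p in bundle.patients if p.role == "case"]
    if case_patients:
        for name, pairs, floor in (
            ("ppv_known_gt", ppv_pairs, None),
            ("cumulative_known_gt", all_pairs, None),
            ("ppv_known_gt_restricted", ppv_pairs, config.ancestry_floor),
            ("cumulative_known_gt_restricted", all_pairs, config.ancestry_floor),
            ("cumulative_all_genes", all_pairs, None),
        ):
            try:
                n, d, pct = prevalence(
                    pairs, bundle.patients, gene_filter=known_gt if "known_gt" in name else None,
                    ancestry_floor=floor,
                )
            except GermtriageError:
                continue
            prevalence_blocks[name] = {
                "numerator": n, "denominator": d, "percent": round(pct, 2),
            }

    # ---- funnel & conservation -------------------------------------------
    reason_counts: dict[str, int] = {}
    for cv in classified:
        if cv.cls == "excluded":
            reason_counts[cv.exclusion_reason] = reason_counts.get(cv.exclusion_reason, 0) + 1
    funnel = {
        "input": len(bundle.variants),
        "candidates_classified": n_candidates_classified,
        "gene_set_restricted": n_after_gene,
        "cross_cohort_screened": n_after_cross,
        "control_screened": n_after_control,
        "chip_screened": n_retained,
        "excluded_by_reason": dict(sorted(reason_counts.items())),
    }
    retained_path = [funnel[s] for s in FUNNEL_STAGES[1:]]
    if any(a < b for a, b in zip(retained_path, retained_path[1:])):
        raise GermtriageError(f"funnel not non-increasing: {retained_path}")
    if n_retained + sum(reason_counts.values()) != len(bundle.variants):
        raise GermtriageError("funnel conservation violated: retained + excluded != input")

    run_summary = {
        "seed": seed,
        "config": config.to_dict(),
        "cohort_sizes": dict(sorted(sizes.items())),
        "funnel": funnel,
        "prevalence": prevalence_blocks,
        "n_candidate_genes": len({s.gene for s in gene_summaries}),
        "n_retained_variants": n_retained,
        "control_borderline": dict(sorted(control_borderline.items())),
        "gene_screen_excluded": sorted(
            g for g, d in gene_screen.items() if not d.keep
        ),
    }

    result = PipelineResult(
        classified=classified,
        stage1_classes=stage1_classes,
        gene_screen=gene_screen,
        shared_report=shared_report,
        control_borderline=control_borderline,
        chip_decisions=chip_decisions,
        chip_status=chip_status,
        retained=retained,
        retained_carriers=retained_carriers,
        tumor_evidence=tumor_evidence,
        variant_scores=variant_scores,
        gene_summaries=gene_summaries,
        prevalence_blocks=prevalence_blocks,
        funnel=funnel,
        run_summary=run_summary,
    )
    result.tables = _build_tables(result, bundle, freqs)
    if out_dir is not None:
        variant_io.write_results(result.tables, run_summary, out_dir)
    return result


def _build_tables(
    result: PipelineResult,
    bundle: InputBundle,
    freqs: dict[str, dict[str, CohortFrequency]],
) -> dict[str, pd.DataFrame]:
    fm, fv = variant_io.format_maf, variant_io.format_vaf
    vaf_map = {(d.patient_id, d.key): d.vaf for d in result.chip_decisions}
    class_columns = [
        "gene", "key", "rsid", "aa_change", "consequence", "class", "n_carriers",
        "sapcs_carriers", "ppcg_carriers", "maf_sapcs", "maf_ppcg",
        "gnomad_maf_all", "gnomad_maf_afr", "maf_sac", "maf_eac", "vaf_carriers",
        "in_known_gt_panel", "control_borderline",
    ]

    def class_rows(predicate) -> pd.DataFrame:
        rows = []
        for cv in sorted(result.retained, key=lambda c: ((c.variant.gene or ""), c.key)):
            if not predicate(cv):
                continue
            carriers = result.retained_carriers[cv.key]
            per_cohort = freqs.get(cv.key, {})
            ann = bundle.annotations[cv.key]
            sapcs = sum(1 for c in carriers if c.patient_id.startswith("SAPCS"))
            rows.append(
                {
                    "gene": cv.variant.gene,
                    "key": cv.key,
                    "rsid": cv.variant.rsid or "",
                    "aa_change": cv.variant.aa_change or "",
                    "consequence": cv.variant.consequence or "",
                    "class": cv.cls,
                    "n_carriers": len(carriers),
                    "sapcs_carriers": sapcs,
                    "ppcg_carriers": len(carriers) - sapcs,
                    "maf_sapcs": fm(per_cohort["SAPCS"].maf if "SAPCS" in per_cohort else None),
                    "maf_ppcg": fm(per_cohort["PPCG"].maf if "PPCG" in per_cohort else None),
                    "gnomad_maf_all": fm(ann.gnomad_maf_all),
                    "gnomad_maf_afr": fm(ann.gnomad_maf_afr),
                    "maf_sac": fm(per_cohort["SAC"].maf if "SAC" in per_cohort else 0.0),
                    "maf_eac": fm(per_cohort["EAC"].maf if "EAC" in per_cohort else 0.0),
                    "vaf_carriers": ";".join(
                        fv(vaf_map.get((c.patient_id, cv.key))) or "ND" for c in carriers
                    ),
                    "in_known_gt_panel": cv.in_known_gt_panel,
                    "control_borderline": cv.key in result.control_borderline,
                }
            )
        return pd.DataFrame(rows, columns=class_columns)

    excluded_rows = [
        {
            "key": cv.key,
            "gene": cv.variant.gene or "",
            "reason": cv.exclusion_reason,
        }
        for cv in sorted(result.classified, key=lambda c: c.key)
        if cv.cls == "excluded"
    ]
    component_names = sorted(
        {name for vs in result.variant_scores for cs in vs.carrier_scores for name, _ in cs.components}
    )
    ranking_rows = []
    for vs in sorted(
        result.variant_scores, key=lambda v: (-v.variant_rank, v.gene or "", v.key)
    ):
        row = {
            "key": vs.key,
            "gene": vs.gene,
            "class": vs.cls,
            "stratum": vs.stratum,
            "n_carriers": len(vs.carrier_scores),
            "variant_rank": f"{vs.variant_rank:g}",
        }
        for name in component_names:
            row[name] = f"{sum(v for cs in vs.carrier_scores for n, v in cs.components if n == name):g}"
        ranking_rows.append(row)
    gene_rows = [
        {
            "gene": s.gene,
            "stratum": s.stratum,
            "gene_weight": f"{s.gene_weight:g}",
            "n_variants": s.n_variants,
            "n_carriers": s.n_carriers,
            "in_known_gt_panel": s.in_known_gt_panel,
        }
        for s in result.gene_summaries
    ]
    screen_rows = [
        {
            "gene": d.gene,
            "status": "exclude" if not d.keep else ("conserved" if d.conserved_in else "keep"),
            "conserved_in": ",".join(d.conserved_in),
            "excluded_by": d.excluded_by or "",
        }
        for d in sorted(result.gene_screen.values(), key=lambda d: d.gene)
    ]
    return {
        "ppv": class_rows(lambda cv: cv.cls == "PPV"),
        "pov": class_rows(lambda cv: cv.cls == "POV"),
        "pslf": class_rows(lambda cv: cv.cls.startswith("PSLF")),
        "excluded": pd.DataFrame(excluded_rows, columns=["key", "gene", "reason"]),
        "variant_ranking": pd.DataFrame(
            ranking_rows,
            columns=["key", "gene", "class", "stratum", "n_carriers", "variant_rank"]
            + component_names,
        ),
        "gene_ranking": pd.DataFrame(
            gene_rows,
            columns=["gene", "stratum", "gene_weight", "n_variants", "n_carriers",
                     "in_known_gt_panel"],
        ),
        "gene_screen": pd.DataFrame(
            screen_rows, columns=["gene", "status", "conserved_in", "excluded_by"]
        ),
        "shared_variants": (
            result.shared_report
            if len(result.shared_report.columns)
            else pd.DataFrame(columns=["key", "gene", "class"])
        ),
    }


def report_prevalence(result: PipelineResult) -> str:
    """Human-readable prevalence block (numerator/denominator, percent)."""
    labels = {
        "ppv_known_gt": "Reported (PPV, known GT genes)",
        "cumulative_known_gt": "Cumulative predicted (PPV+POV, known GT genes)",
        "ppv_known_gt_restricted": "Reported, African ancestry restricted",
        "cumulative_known_gt_restricted": "Cumulative, African ancestry restricted",
        "cumulative_all_genes": "Cumulative, all candidate genes",
    }
    lines = []
    for name, block in result.prevalence_blocks.items():
        label = labels.get(name, name)
        lines.append(
            f"{label}: "
            + format_prevalence(block["numerator"], block["denominator"], block["percent"])
        )
    return "\n".join(lines)
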