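"""Independent brute-force re-implementations used as test oracles.

These deliberately re-read the scoring rules from scratch (plain
conditionals, no shared code with the package) so that agreement with
the pipeline is a genuine cross-check.
"""
from __future__ import annotations

from typing import Optional


def brute_force_carrier_score(
    cls: str,
    in_chip_gene: bool,
    sac_maf: float,
    eac_maf: float,
    has_plof: bool,
    age: Optional[float],
    cohort_mean: float,
    isup: Optional[int],
    psa: Optional[float],
    fh_prostate: Optional[bool],
    fh_breast_ovarian: Optional[bool],
    tumor_available: bool,
    loh: bool,
    second_hit: bool,
) -> float:
    """Naive re-read of the 9-step weighting."""
    points = 0.0
    if in_chip_gene:
        points -= 0.5
    if sac_maf < 0.01 and eac_maf < 0.01:
        points += 1.0
    if cls in ("PPV", "PSLF_PPV"):
        points += 1.0
    if has_plof:
        points += 1.0
    if age is not None:
        younger = cohort_mean - age
        if younger > 10:
            points += 2.0
        elif younger > 0:
            points += 1.0
    if isup is not None:
        if isup >= 4:
            points += 1.0
        elif isup == 3:
            points += 0.5
    if psa is not None and psa > 60:
        points += 1.0
    if fh_prostate:
        points += 1.0
    if fh_breast_ovarian:
        points += 0.5
    if not tumor_available:
        points += 0.5
    elif loh or second_hit:
        points += 1.0
    return points


def random_carrier_case(rng):
    """One randomized carrier-variant scoring scenario (plain dict)."""
    cohort = "SAPCS" if rng.random() < 0.7 else "PPCG"
    return {
        "cls": ["PPV", "POV", "PSLF_PPV", "PSLF_POV"][rng.integers(4)],
        "in_chip_gene": bool(rng.random() < 0.2),
        "sac_maf": float(rng.choice([0.0, 0.005, 0.0102, 0.02])),
        "eac_maf": float(rng.choice([0.0, 0.0125, 0.009])),
        "has_plof": bool(rng.random() < 0.3),
        "age": None if rng.random() < 0.1 else float(rng.uniform(40, 90)),
        "cohort": cohort,
        "cohort_mean": {"SAPCS": 67.0, "PPCG": 65.0}[cohort],
        "isup": None if rng.random() < 0.1 else int(rng.integers(1, 6)),
        "psa": None if rng.random() < 0.1 else float(rng.uniform(1, 300)),
        "fh_prostate": [None, False, True][rng.integers(3)],
        "fh_breast_ovarian": [None, False, True][rng.integers(3)],
        "tumor_available": bool(rng.random() < 0.7),
        "loh": bool(rng.random() < 0.3),
        "second_hit": bool(rng.random() < 0.2),
    }


def score_case_with_pipeline(case: dict) -> float:
    """Run one scenario through the package scorer."""
    from germtriage.chip_filter import ChipDecision
    from germtriage.classification import ClassifiedVariant
    from germtriage.frequency import FrequencyTier
    from germtriage.ranking import score_carrier
    from germtriage.tumor_evidence import TumorEvidence
    from germtriage.types import GenomicVariant, PatientRecord

    variant = GenomicVariant("chr1", 1000, "A", "G", gene="ATM",
                             consequence="missense")
    cv = ClassifiedVariant(
        variant=variant,
        cls=case["cls"],
        rarity=FrequencyTier("rare"),
        functional_flags=frozenset({"plof"}) if case["has_plof"] else frozenset(),
    )
    chip = ChipDecision(
        key=variant.key, patient_id="P1", vaf=0.5,
        in_chip_gene=case["in_chip_gene"], decision="retain",
        rank_penalty=-0.5 if case["in_chip_gene"] else 0.0,
    )
    patient = PatientRecord(
        patient_id="P1", cohort=case["cohort"], role="case",
        age_years=case["age"], psa_ng_ml=case["psa"], isup_gg=case["isup"],
        fh_prostate=case["fh_prostate"],
        fh_breast_ovarian=case["fh_breast_ovarian"],
        tumor_available=case["tumor_available"],
    )
    tumor = TumorEvidence(
        key=variant.key, patient_id="P1",
        loh=case["loh"] and case["tumor_available"],
        second_hit=case["second_hit"] and case["tumor_available"],
        tumor_available=case["tumor_available"],
    )
    return score_carrier(
        cv, chip, patient, tumor,
        sac_maf=case["sac_maf"], eac_maf=case["eac_maf"],
    ).total


def score_case_with_oracle(case: dict) -> float:
    return brute_force_carrier_score(
        case["cls"], case["in_chip_gene"], case["sac_maf"], case["eac_maf"],
        case["has_plof"], case["age"], case["cohort_mean"], case["isup"],
        case["psa"], case["fh_prostate"], case["fh_breast_ovarian"],
        case["tumor_available"], case["loh"], case["second_hit"],
    )
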