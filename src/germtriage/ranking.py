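"""The 9-step weighted ranking of retained variants and candidate genes.

Each retained carrier-variant pair is scored from variant features
(CHIP-gene penalty, control rarity, PPV-over-POV, pLoF), clinical
presentation (age below the cohort reference mean, ISUP grade group,
PSA, family history) and tumor-matched biallelic inactivation (LOH
and/or second hit, with a half weight when no tumor was available).
Variant rank is the recurrence-weighted sum over carriers; gene weight
sums variant ranks, with rare and population-specific low-frequency
(PSLF) variants ranked in separate strata.  Prevalence counts unique
carriers over the (optionally ancestry-restricted) patient set.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from pydantic import BaseModel, ConfigDict

from .chip_filter import ChipDecision
from .classification import ClassifiedVariant
from .errors import ConfigError, UndefinedFrequencyError
from .tumor_evidence import TumorEvidence
from .types import PatientRecord


class RankingWeights(BaseModel):
    """Weights of the 9-step ranking; defaults are the published scheme."""

    model_config = ConfigDict(frozen=True)

    chip_gene_penalty: float = -0.5
    control_rare_bonus: float = 1.0  # SAC and EAC MAF < control_rare_maf
    control_rare_maf: float = 0.01
    ppv_bonus: float = 1.0
    plof_bonus: float = 1.0
    age_younger_bonus: float = 1.0  # up to 10 y below the cohort mean
    age_much_younger_bonus: float = 2.0  # > 10 y below
    age_window_years: float = 10.0
    isup3_bonus: float = 0.5
    isup4plus_bonus: float = 1.0
    psa_bonus: float = 1.0
    psa_threshold_ng_ml: float = 60.0
    fh_pca_bonus: float = 1.0
    fh_breast_ovarian_bonus: float = 0.5
    tumor_evidence_bonus: float = 1.0  # LOH and/or second hit
    tumor_missing_bonus: float = 0.5  # no matched tumor available
    age_reference_means: dict[str, float] = {"SAPCS": 67.0, "PPCG": 65.0}


DEFAULT_WEIGHTS = RankingWeights()


@dataclass(frozen=True)
class CarrierScore:
    """Score of one retained carrier with its named component breakdown."""

    key: str
    patient_id: str
    components: tuple[tuple[str, float], ...]

    @property
    def total(self) -> float:
        return sum(v for _, v in self.components)


def score_carrier(
    cv: ClassifiedVariant,
    chip: ChipDecision,
    patient: PatientRecord,
    tumor: Optional[TumorEvidence],
    weights: RankingWeights = DEFAULT_WEIGHTS,
    sac_maf: float = 0.0,
    eac_maf: float = 0.0,
) -> CarrierScore:
    """Sum of the applicable weights; missing clinical fields contribute 0."""
    w = weights
    comp: list[tuple[str, float]] = []

    # variant features
    if chip.in_chip_gene:
        comp.append(("chip_gene_penalty", w.chip_gene_penalty))
    if sac_maf < w.control_rare_maf and eac_maf < w.control_rare_maf:
        comp.append(("control_rare_bonus", w.control_rare_bonus))
    if cv.is_ppv_class:
        comp.append(("ppv_bonus", w.ppv_bonus))
    if "plof" in cv.functional_flags:
        comp.append(("plof_bonus", w.plof_bonus))

    # clinical presentation
    if patient.age_years is not None:
        mean = w.age_reference_means.get(patient.cohort)
        if mean is None:
            raise ConfigError(
                f"no age reference mean configured for cohort {patient.cohort!r}"
            )
        younger_by = mean - patient.age_years
        if younger_by > w.age_window_years:
            comp.append(("age_much_younger_bonus", w.age_much_younger_bonus))
        elif younger_by > 0:
            comp.append(("age_younger_bonus", w.age_younger_bonus))
    if patient.isup_gg is not None:
        if patient.isup_gg >= 4:
            comp.append(("isup4plus_bonus", w.isup4plus_bonus))
        elif patient.isup_gg == 3:
            comp.append(("isup3_bonus", w.isup3_bonus))
    if patient.psa_ng_ml is not None and patient.psa_ng_ml > w.psa_threshold_ng_ml:
        comp.append(("psa_bonus", w.psa_bonus))
    if patient.fh_prostate:
        comp.append(("fh_pca_bonus", w.fh_pca_bonus))
    if patient.fh_breast_ovarian:
        comp.append(("fh_breast_ovarian_bonus", w.fh_breast_ovarian_bonus))

    # tumor features
    if not patient.tumor_available:
        comp.append(("tumor_missing_bonus", w.tumor_missing_bonus))
    elif tumor is not None and (tumor.loh or tumor.second_hit):
        comp.append(("tumor_evidence_bonus", w.tumor_evidence_bonus))

    return CarrierScore(key=cv.key, patient_id=patient.patient_id, components=tuple(comp))


@dataclass(frozen=True)
class VariantScore:
    """Recurrence-aggregated rank of one variant with its carrier breakdown."""

    key: str
    gene: Optional[str]
    cls: str
    stratum: str  # rare | PSLF
    carrier_scores: tuple[CarrierScore, ...]
    variant_rank: float


def rank_variant(
    cv: ClassifiedVariant,
    carrier_scores: Sequence[CarrierScore],
    mode: str = "sum",
) -> VariantScore:
    """Aggregate carrier scores: ``sum`` (recurrence-weighted) or ``mean``."""
    if not carrier_scores:
        raise ConfigError(f"variant {cv.key} has no retained carriers to rank")
    totals = [c.total for c in carrier_scores]
    if mode == "sum":
        rank = sum(totals)
    elif mode == "mean":
        rank = sum(totals) / len(totals)
    else:
        raise ConfigError(f"recurrence mode must be sum/mean, got {mode!r}")
    return VariantScore(
        key=cv.key,
        gene=cv.variant.gene,
        cls=cv.cls,
        stratum=cv.stratum,
        carrier_scores=tuple(carrier_scores),
        variant_rank=rank,
    )


@dataclass(frozen=True)
class GeneSummary:
    gene: str
    stratum: str
    gene_weight: float
    n_variants: int
    n_carriers: int
    in_known_gt_panel: bool


def rank_genes(
    variant_scores: Iterable[VariantScore],
    known_gt_genes: frozenset[str] = frozenset(),
) -> list[GeneSummary]:
    """Gene weights per stratum, sorted by weight desc, carriers desc, symbol.

    A gene with both rare and PSLF variants appears once per stratum.
    """
    slots: dict[tuple[str, str], dict] = {}
    for vs in variant_scores:
        gene = (vs.gene or "").upper()
        slot = slots.setdefault(
            (gene, vs.stratum), {"weight": 0.0, "n": 0, "carriers": set()}
        )
        slot["weight"] += vs.variant_rank
        slot["n"] += 1
        slot["carriers"].update(c.patient_id for c in vs.carrier_scores)
    summaries = [
        GeneSummary(
            gene=gene,
            stratum=stratum,
            gene_weight=slot["weight"],
            n_variants=slot["n"],
            n_carriers=len(slot["carriers"]),
            in_known_gt_panel=gene in known_gt_genes,
        )
        for (gene, stratum), slot in slots.items()
    ]
    summaries.sort(key=lambda s: (-s.gene_weight, -s.n_carriers, s.gene, s.stratum))
    return summaries


def prevalence(
    carrier_pairs: Iterable[tuple[str, str]],
    patients: Iterable[PatientRecord],
    gene_filter: Optional[frozenset[str]] = None,
    ancestry_floor: Optional[float] = None,
) -> tuple[int, int, float]:
    """Unique-carrier prevalence: (numerator, denominator, percent).

    ``carrier_pairs`` are (patient_id, gene) pairs of retained
    carrier-variant observations; a patient counts once no matter how
    many qualifying variants they carry.  The denominator is the case
    patients passing the ancestry floor (strict ``>``); percent is
    reported to 2 decimals by the callers.
    """
    eligible = {
        p.patient_id
        for p in patients
        if p.role == "case"
        and (
            ancestry_floor is None
            or (p.african_fraction is not None and p.african_fraction > ancestry_floor)
        )
    }
    if not eligible:
        raise UndefinedFrequencyError("empty prevalence denominator")
    genes = None if gene_filter is None else {g.upper() for g in gene_filter}
    carriers = {
        pid
        for pid, gene in carrier_pairs
        if pid in eligible and (genes is None or (gene or "").upper() in genes)
    }
    n, d = len(carriers), len(eligible)
    return n, d, 100.0 * n / d


def format_prevalence(numerator: int, denominator: int, percent: float) -> str:
    return f"{numerator}/{denominator}, {percent:.2f}%"
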