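"""Allele-frequency mathematics.

Cohort minor allele frequencies from carrier counts (diploid 2n
denominator), gnomAD frequency tiering, the population-control exclusion
screen with its borderline policy, and per-carrier variant allele
fractions from read counts.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Optional

from .errors import ContractViolation, UndefinedFrequencyError
from .types import AnnotationBundle

log = logging.getLogger(__name__)

#: default frequency-tier and control-screen thresholds
MAF_RARE = 0.01
MAF_LOW = 0.05
CONTROL_EXCLUDE = 0.02

TIER_ORDER = {"unknown": 0, "rare": 0, "low_frequency": 1, "common": 2}


@dataclass(frozen=True, slots=True)
class CohortFrequency:
    """Carrier-derived allele frequency of one variant in one cohort."""

    cohort: str
    n_patients: int
    het_carriers: int
    hom_carriers: int

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise UndefinedFrequencyError(
                f"cohort {self.cohort}: frequency undefined for n={self.n_patients}"
            )
        if self.het_carriers < 0 or self.hom_carriers < 0:
            raise ContractViolation("carrier counts must be non-negative")
        if self.het_carriers + self.hom_carriers > self.n_patients:
            raise ContractViolation(
                f"cohort {self.cohort}: carriers exceed cohort size"
            )

    @property
    def allele_count(self) -> int:
        return self.het_carriers + 2 * self.hom_carriers

    @property
    def maf(self) -> float:
        return self.allele_count / (2 * self.n_patients)


def cohort_maf(het: int, hom: int, n: int, cohort: str = "cohort") -> float:
    """MAF = (het + 2*hom) / 2n under diploid autosomal counting.

    Reported values round to 4 decimals; the exact fraction is returned.
    """
    return CohortFrequency(cohort, n, het, hom).maf


def pooled_maf(frequencies: Iterable[CohortFrequency]) -> float:
    """Pool disjoint cohorts: summed allele counts over summed 2n."""
    freqs = list(frequencies)
    if not freqs:
        raise UndefinedFrequencyError("no cohorts to pool")
    seen: set[str] = set()
    for f in freqs:
        if f.cohort in seen:
            raise ContractViolation(f"cohort {f.cohort!r} pooled twice")
        seen.add(f.cohort)
    ac = sum(f.allele_count for f in freqs)
    an = sum(2 * f.n_patients for f in freqs)
    return ac / an


@dataclass(frozen=True, slots=True)
class FrequencyTier:
    """gnomAD-based rarity tier with the sources that determined it.

    ``unknown`` (absent from databases) is treated as rare downstream.
    """

    tier: str  # unknown | rare | low_frequency | common
    basis: tuple[str, ...] = ()

    @property
    def is_rare_or_unknown(self) -> bool:
        return self.tier in ("rare", "unknown")

    @property
    def is_common(self) -> bool:
        return self.tier == "common"


def tier_gnomad(
    bundle: AnnotationBundle,
    maf_rare: float = MAF_RARE,
    maf_low: float = MAF_LOW,
) -> FrequencyTier:
    """Tier a variant by the maximum of its non-null gnomAD MAFs.

    Strict comparisons as printed: rare means max < 1%, low-frequency
    means 1% <= max < 5%, common means max >= 5%.  Both fields null
    means the variant is absent from databases (tier ``unknown``).
    """
    sources = []
    if bundle.gnomad_maf_all is not None:
        sources.append(("gnomad_all", bundle.gnomad_maf_all))
    if bundle.gnomad_maf_afr is not None:
        sources.append(("gnomad_afr", bundle.gnomad_maf_afr))
    if not sources:
        return FrequencyTier("unknown", ())
    top = max(maf for _, maf in sources)
    basis = tuple(name for name, _ in sources)
    if top < maf_rare:
        return FrequencyTier("rare", basis)
    if top < maf_low:
        return FrequencyTier("low_frequency", basis)
    return FrequencyTier("common", basis)


@dataclass(frozen=True, slots=True)
class ControlDecision:
    """Outcome of the population-control MAF screen for one variant."""

    keep: bool
    reason: Optional[str] = None  # "control_maf" when excluded
    borderline: bool = False
    detail: str = ""


def _exceeds_by_alleles(freq: CohortFrequency, threshold: float) -> int:
    """How many alleles above the threshold count this cohort sits."""
    limit = math.floor(threshold * 2 * freq.n_patients)
    return freq.allele_count - limit


def control_screen(
    sac: Optional[CohortFrequency],
    eac: Optional[CohortFrequency],
    threshold: float = CONTROL_EXCLUDE,
) -> ControlDecision:
    """Exclude variants common in healthy African population controls.

    A variant is excluded when its southern African control (SAC) MAF,
    east African control (EAC) MAF, or pooled SAC+EAC MAF exceeds the
    threshold (strict ``>``, default 2%).  A single control cohort
    exceeding the threshold by at most one allele while the variant is
    absent from the other control cohort is kept and flagged
    ``borderline`` — the cautious-retention policy for singleton-scale
    control observations.
    """
    present = [f for f in (sac, eac) if f is not None]
    if not present:
        return ControlDecision(True)

    if len(present) == 2:
        pooled = pooled_maf(present)
        if pooled > threshold:
            over = [f for f in present if f.maf > threshold]
            if (
                len(over) == 1
                and _exceeds_by_alleles(over[0], threshold) <= 1
                and next(f for f in present if f is not over[0]).allele_count == 0
            ):
                return ControlDecision(
                    True,
                    borderline=True,
                    detail=f"{over[0].cohort} MAF {over[0].maf:.6f} within 1 allele "
                    f"of threshold, absent in the other control cohort",
                )
            return ControlDecision(
                False, "control_maf", detail=f"pooled control MAF {pooled:.6f} > {threshold}"
            )

    for f in present:
        if f.maf > threshold:
            others = [o for o in present if o is not f]
            if (
                _exceeds_by_alleles(f, threshold) <= 1
                and all(o.allele_count == 0 for o in others)
            ):
                return ControlDecision(
                    True,
                    borderline=True,
                    detail=f"{f.cohort} MAF {f.maf:.6f} within 1 allele of threshold, "
                    "absent in the other control cohort",
                )
            return ControlDecision(
                False, "control_maf", detail=f"{f.cohort} MAF {f.maf:.6f} > {threshold}"
            )
    return ControlDecision(True)


def vaf(ref_reads: Optional[int], alt_reads: Optional[int]) -> Optional[float]:
    """Variant allele fraction alt/(ref+alt); ``None`` when undetermined."""
    if ref_reads is None and alt_reads is None:
        return None
    ref = ref_reads or 0
    alt = alt_reads or 0
    if ref < 0 or alt < 0:
        raise ContractViolation("read counts must be non-negative")
    total = ref + alt
    if total == 0:
        log.warning("zero total depth with non-null read counts; VAF undetermined")
        return None
    return alt / total
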