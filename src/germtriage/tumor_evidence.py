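"""Tumor-matched evidence for germline candidates.

Loss of heterozygosity is called when a somatic copy-number loss overlaps
the germline locus, or a somatic record at the locus shows an allelic
fraction above 0.65 or at least 15 percentage points above the germline
allele fraction.  A Knudson second hit is a protein-altering somatic
SNV/indel in the same gene at a different position.  Tumor mutational
burden is somatic mutation count over callable megabases; group
comparisons use a pooled-variance two-sample t-test on log10(TMB).
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .errors import ConfigError, DegenerateDataError
from .types import GenomicVariant

log = logging.getLogger(__name__)

LOH_AF_THRESHOLD = 0.65
LOH_AF_DELTA = 0.15
CALLABLE_MB = 2800.0  # GRCh38 non-gap autosomal approximation


@dataclass(frozen=True, slots=True)
class SomaticVariant:
    chrom: str
    pos: int
    ref: str
    alt: str
    gene: Optional[str]
    allelic_fraction: Optional[float]
    protein_altering: bool = False


@dataclass(frozen=True, slots=True)
class CnSegment:
    """Half-open [start, end) copy-number segment, 1-based coordinates."""

    chrom: str
    start: int
    end: int
    loss: bool

    def overlaps(self, chrom: str, pos: int) -> bool:
        return self.chrom == chrom and self.start <= pos < self.end


@dataclass(frozen=True)
class SomaticProfile:
    """Tumor-matched somatic calls and labels for one patient."""

    patient_id: str
    somatic_snvs: tuple[SomaticVariant, ...] = ()
    cn_segments: tuple[CnSegment, ...] = ()
    msi_status: str = "unknown"  # MSS | MSI-H | unknown
    signature_labels: frozenset[str] = frozenset()
    # somatic events outside the candidate panel contribute to TMB only
    n_background_mutations: int = 0


@dataclass(frozen=True, slots=True)
class TumorEvidence:
    key: str
    patient_id: str
    loh: bool
    second_hit: bool
    tumor_available: bool


def detect_loh(
    variant: GenomicVariant,
    germline_af: Optional[float],
    profile: SomaticProfile,
    af_threshold: float = LOH_AF_THRESHOLD,
    af_delta: float = LOH_AF_DELTA,
) -> bool:
    """True when the tumor lost the wild-type allele at the germline locus."""
    for seg in profile.cn_segments:
        if seg.loss and seg.overlaps(variant.chrom, variant.pos):
            return True
    for sv in profile.somatic_snvs:
        if sv.chrom != variant.chrom or sv.pos != variant.pos:
            continue
        af = sv.allelic_fraction
        if af is None:
            continue
        if af > af_threshold:
            return True
        if germline_af is None:
            log.warning(
                "germline allele fraction unavailable for %s in %s; "
                "skipping the +%.0f%% LOH arm",
                variant.key,
                profile.patient_id,
                af_delta * 100,
            )
            continue
        if af >= germline_af + af_delta:
            return True
    return False


def detect_second_hit(variant: GenomicVariant, profile: SomaticProfile) -> bool:
    """Protein-altering somatic hit in the same gene, different position."""
    gene = (variant.gene or "").upper()
    if not gene:
        return False
    return any(
        sv.protein_altering
        and (sv.gene or "").upper() == gene
        and not (sv.chrom == variant.chrom and sv.pos == variant.pos)
        for sv in profile.somatic_snvs
    )


def tmb(profile: SomaticProfile, callable_mb: float = CALLABLE_MB) -> float:
    """Tumor mutational burden in mutations per callable megabase."""
    if callable_mb <= 0:
        raise ConfigError(f"callable_mb must be positive, got {callable_mb}")
    n = len(profile.somatic_snvs) + profile.n_background_mutations
    return n / callable_mb


def tmb_group_compare(
    group_a: Sequence[float], group_b: Sequence[float]
) -> tuple[float, float]:
    """Two-sample pooled-variance t-test on log10-transformed TMB.

    Non-positive TMB values cannot be log-transformed and are dropped
    with a warning.  Identical groups return (0, 1); zero within-group
    variance with differing means is degenerate and raises.
    """
    def prep(values: Sequence[float], label: str) -> np.ndarray:
        arr = np.asarray(values, dtype=float)
        bad = arr <= 0
        if bad.any():
            log.warning(
                "%d zero/negative TMB value(s) in group %s excluded from log transform",
                int(bad.sum()),
                label,
            )
        return np.log10(arr[~bad])

    a, b = prep(group_a, "A"), prep(group_b, "B")
    if a.size == 0 or b.size == 0:
        raise DegenerateDataError("empty group after removing non-positive TMB values")
    if a.size == b.size and np.array_equal(np.sort(a), np.sort(b)):
        return 0.0, 1.0
    pooled_var = (
        ((a.size - 1) * a.var(ddof=1) if a.size > 1 else 0.0)
        + ((b.size - 1) * b.var(ddof=1) if b.size > 1 else 0.0)
    )
    if math.isclose(pooled_var, 0.0, abs_tol=1e-300):
        raise DegenerateDataError(
            "zero within-group variance with differing means: t undefined"
        )
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)
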