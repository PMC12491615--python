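"""Clonal-hematopoiesis (CHIP) screening of carrier calls.

Blood-derived germline call sets pick up age-acquired somatic mutations
of hematopoietic clones; these present at depressed variant allele
fractions.  Carriers with VAF below the (conservative) 0.3 threshold are
excluded as likely CHIP; carriers in CHIP-associated or CHIP-suspect
genes with no determinable VAF are excluded conservatively; retained
carriers in CHIP-associated genes carry a -0.5 ranking penalty flag.
Filtering is per carrier: a variant stays in play as long as one carrier
survives, and excluded carriers drop out of every downstream frequency
and prevalence computation.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional

from .errors import ConfigError
from .frequency import vaf as compute_vaf
from .types import GeneLists, GenotypeCall

log = logging.getLogger(__name__)

CHIP_VAF_THRESHOLD = 0.3

RETAIN = "retain"
EXCLUDE_CHIP = "exclude_chip"
EXCLUDE_MISSING_VAF = "exclude_missing_vaf"


@dataclass(frozen=True, slots=True)
class ChipDecision:
    """Per carrier-variant CHIP screening outcome."""

    key: str
    patient_id: str
    vaf: Optional[float]
    in_chip_gene: bool
    decision: str  # retain | exclude_chip | exclude_missing_vaf
    rank_penalty: float = 0.0  # -0.5 iff retained in a CHIP-associated gene

    @property
    def retained(self) -> bool:
        return self.decision == RETAIN


def screen_carrier(
    call: GenotypeCall,
    gene: Optional[str],
    gene_lists: GeneLists,
    threshold: float = CHIP_VAF_THRESHOLD,
) -> ChipDecision:
    """Screen one carrier call; VAF comes from its read counts."""
    if not 0.0 < threshold < 1.0:
        raise ConfigError(f"CHIP VAF threshold must lie in (0, 1), got {threshold}")
    symbol = (gene or "").upper()
    in_chip = symbol in gene_lists.chip_genes
    chip_scope = in_chip or symbol in gene_lists.chip_suspect_genes
    value = compute_vaf(call.ref_reads, call.alt_reads)
    if value is None:
        if chip_scope:
            decision = EXCLUDE_MISSING_VAF
        else:
            log.warning(
                "carrier %s at %s has no determinable VAF outside CHIP scope; retained",
                call.patient_id,
                call.key,
            )
            decision = RETAIN
    elif value < threshold:  # strict: VAF exactly at threshold is retained
        decision = EXCLUDE_CHIP
    else:
        decision = RETAIN
    penalty = -0.5 if decision == RETAIN and in_chip else 0.0
    return ChipDecision(
        key=call.key,
        patient_id=call.patient_id,
        vaf=value,
        in_chip_gene=in_chip,
        decision=decision,
        rank_penalty=penalty,
    )


def chip_screen(
    calls_with_genes: Iterable[tuple[GenotypeCall, Optional[str]]],
    gene_lists: GeneLists,
    threshold: float = CHIP_VAF_THRESHOLD,
) -> list[ChipDecision]:
    """Screen every carrier call against the CHIP VAF threshold."""
    return [
        screen_carrier(call, gene, gene_lists, threshold)
        for call, gene in calls_with_genes
    ]


@dataclass(frozen=True, slots=True)
class VariantChipStatus:
    """Variant-level resolution over its carriers."""

    key: str
    retained: bool
    retained_carriers: tuple[str, ...]
    excluded_carriers: tuple[str, ...]


def multi_carrier_resolution(
    decisions: Iterable[ChipDecision],
) -> dict[str, VariantChipStatus]:
    """A variant is retained iff at least one carrier is retained."""
    grouped: dict[str, list[ChipDecision]] = {}
    for d in decisions:
        grouped.setdefault(d.key, []).append(d)
    out = {}
    for key, ds in grouped.items():
        kept = tuple(sorted(d.patient_id for d in ds if d.retained))
        dropped = tuple(sorted(d.patient_id for d in ds if not d.retained))
        out[key] = VariantChipStatus(
            key=key, retained=bool(kept), retained_carriers=kept, excluded_carriers=dropped
        )
    return out
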