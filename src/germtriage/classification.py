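"""Variant class labels: PPV, POV, PSLF-PPV, PSLF-POV or excluded.

A PPV is a ClinVar pathogenic/likely-pathogenic variant below the gnomAD
common ceiling.  A POV is a variant of unknown significance retained
because it is functionally damaging (SIFT/PolyPhen, stop or splice
disruption, or LOFTEE-flagged frameshift) and called an oncogenic driver
by the Cancer Genome Interpreter, and rare in gnomAD.  PSLF variants are
rare (or absent) in global databases yet present at >=1% frequency in a
study case cohort.  Every non-candidate receives an exclusion reason;
the class labels partition the input.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

from .errors import ConfigError
from .frequency import CohortFrequency, FrequencyTier
from .types import (
    STOP_DISRUPTING,
    AnnotationBundle,
    GeneLists,
    GenomicVariant,
)

PSLF_FLOOR = 0.01

#: machine-parseable exclusion reason codes
REASON_COMMON = "common_maf"
REASON_LOW_FREQ = "low_frequency_maf"
REASON_BENIGN = "benign_clinvar"
REASON_NOT_FUNCTIONAL = "not_functional"
REASON_NOT_DRIVER = "not_cgi_driver"
REASON_GENE_SET = "gene_set"

CANDIDATE_CLASSES = ("PPV", "POV", "PSLF_PPV", "PSLF_POV")


@dataclass(frozen=True)
class ClassifiedVariant:
    """One variant with its class label and every filter decision."""

    variant: GenomicVariant
    cls: str  # PPV | POV | PSLF_PPV | PSLF_POV | excluded
    rarity: FrequencyTier
    functional_flags: frozenset[str] = frozenset()
    in_ddr_pca_set: bool = False
    in_known_gt_panel: bool = False
    exclusion_reason: Optional[str] = None
    study_maf: tuple[CohortFrequency, ...] = ()

    def __post_init__(self) -> None:
        if self.cls != "excluded" and self.exclusion_reason is not None:
            raise ConfigError("non-excluded variant cannot carry an exclusion reason")

    @property
    def key(self) -> str:
        return self.variant.key

    @property
    def is_candidate(self) -> bool:
        return self.cls in CANDIDATE_CLASSES

    @property
    def is_ppv_class(self) -> bool:
        return self.cls in ("PPV", "PSLF_PPV")

    @property
    def stratum(self) -> str:
        return "PSLF" if self.cls.startswith("PSLF") else "rare"


def functional_flags(
    bundle: AnnotationBundle, consequence: Optional[str]
) -> frozenset[str]:
    """Evidence flags recorded for every variant regardless of class."""
    flags = set()
    if bundle.sift == "deleterious":
        flags.add("sift_deleterious")
    if bundle.polyphen == "damaging":
        flags.add("polyphen_damaging")
    if consequence in STOP_DISRUPTING:
        flags.add("stop_disrupting")
    if consequence == "splice_disrupting":
        flags.add("splice_disrupting")
    if bundle.cgi_driver == "driver":
        flags.add("cgi_driver")
    if bundle.loftee_lof == "lof":
        flags.add("plof")
    return frozenset(flags)


def _any_case_maf_at_floor(
    study_freqs: Sequence[CohortFrequency], pslf_floor: float
) -> bool:
    # A lone carrier never defines a population-level low frequency: in a
    # small case cohort a singleton already exceeds 1% (1/62 = 0.016), yet
    # such variants are rare, not population-specific.  Require at least
    # two alleles behind the floor.
    return any(f.maf >= pslf_floor and f.allele_count >= 2 for f in study_freqs)


def classify_ppv(
    bundle: AnnotationBundle,
    tier: FrequencyTier,
    study_freqs: Sequence[CohortFrequency],
    pslf_floor: float = PSLF_FLOOR,
) -> tuple[str, Optional[str]]:
    """Class for a ClinVar pathogenic/likely-pathogenic variant.

    Returns ``(class, exclusion_reason)``.  Variants common in gnomAD
    (>=5%) are excluded; rare/database-absent variants that reach the
    PSLF floor in a case cohort become PSLF-PPVs.
    """
    if tier.is_common:
        return "excluded", REASON_COMMON
    if tier.is_rare_or_unknown and _any_case_maf_at_floor(study_freqs, pslf_floor):
        return "PSLF_PPV", None
    return "PPV", None


def classify_pov(
    bundle: AnnotationBundle,
    consequence: Optional[str],
    tier: FrequencyTier,
    study_freqs: Sequence[CohortFrequency],
    pslf_floor: float = PSLF_FLOOR,
    require_cgi_driver: bool = True,
    sift_polyphen_mode: str = "or",
) -> tuple[str, Optional[str]]:
    """Class for a variant of unknown significance.

    The conjuncts are tested in order and the first failure names the
    exclusion reason: functional damage (SIFT deleterious and/or
    PolyPhen damaging, a stop or splice disruption, or a LOFTEE-flagged
    frameshift), CGI oncogenic-driver status, then gnomAD rarity.
    """
    if sift_polyphen_mode == "or":
        predicted = bundle.sift == "deleterious" or bundle.polyphen == "damaging"
    elif sift_polyphen_mode == "and":
        predicted = bundle.sift == "deleterious" and bundle.polyphen == "damaging"
    else:
        raise ConfigError(f"sift_polyphen_mode must be or/and, got {sift_polyphen_mode!r}")
    disrupting = consequence in STOP_DISRUPTING or consequence == "splice_disrupting"
    lof_frameshift = consequence == "frameshift" and bundle.loftee_lof == "lof"
    if not (predicted or disrupting or lof_frameshift):
        return "excluded", REASON_NOT_FUNCTIONAL
    if require_cgi_driver and bundle.cgi_driver != "driver":
        return "excluded", REASON_NOT_DRIVER
    if tier.is_common:
        return "excluded", REASON_COMMON
    if tier.is_rare_or_unknown:
        if _any_case_maf_at_floor(study_freqs, pslf_floor):
            return "PSLF_POV", None
        return "POV", None
    # low-frequency tier (1-5% in gnomAD) and not population-specific
    return "excluded", REASON_LOW_FREQ


def classify_variant(
    variant: GenomicVariant,
    bundle: AnnotationBundle,
    tier: FrequencyTier,
    study_freqs: Sequence[CohortFrequency],
    pslf_floor: float = PSLF_FLOOR,
    require_cgi_driver: bool = True,
    sift_polyphen_mode: str = "or",
) -> ClassifiedVariant:
    """Dispatch one annotated variant through the class rules.

    ClinVar P/LP variants go through the PPV rule, benign/likely-benign
    are excluded outright, and everything else (VUS, conflicting or
    database-absent) through the POV rule.
    """
    flags = functional_flags(bundle, variant.consequence)
    if bundle.is_plp:
        cls, reason = classify_ppv(bundle, tier, study_freqs, pslf_floor)
    elif bundle.is_benign:
        cls, reason = "excluded", REASON_BENIGN
    else:
        cls, reason = classify_pov(
            bundle,
            variant.consequence,
            tier,
            study_freqs,
            pslf_floor,
            require_cgi_driver,
            sift_polyphen_mode,
        )
    return ClassifiedVariant(
        variant=variant,
        cls=cls,
        rarity=tier,
        functional_flags=flags,
        exclusion_reason=reason,
        study_maf=tuple(study_freqs),
    )


def restrict_gene_set(
    classified: Iterable[ClassifiedVariant], gene_lists: GeneLists
) -> list[ClassifiedVariant]:
    """Keep candidates to the DDR/PCa gene universe.

    Gene symbols are compared case-insensitively; candidates in genes
    outside the set are excluded with reason ``gene_set``, and the
    known-GT-panel membership flag is set on the rest.  Already-excluded
    variants keep their original reason.
    """
    if not gene_lists.ddr_pca_genes:
        raise ConfigError("empty DDR/PCa gene list")
    out = []
    for cv in classified:
        symbol = (cv.variant.gene or "").upper()
        in_set = symbol in gene_lists.ddr_pca_genes
        in_panel = symbol in gene_lists.known_gt_genes
        if cv.cls != "excluded" and not in_set:
            cv = replace(
                cv,
                cls="excluded",
                exclusion_reason=REASON_GENE_SET,
                in_ddr_pca_set=False,
                in_known_gt_panel=False,
            )
        else:
            cv = replace(cv, in_ddr_pca_set=in_set, in_known_gt_panel=in_panel)
        out.append(cv)
    return out
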