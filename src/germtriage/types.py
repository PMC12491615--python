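"""Core domain records: variants, annotations, patients, genotype calls, gene lists.

All variant identity is carried by the normalized VCF-style key
``chrom:pos:ref/alt`` (GRCh38, 1-based, chr-prefixed).  Records are plain
frozen dataclasses; tabular IO lives in :mod:`germtriage.variant_io`.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .errors import ContractViolation

MAX_INDEL_LEN = 50  # small-variant scope: SNVs and indels < 50 bp

CHROMOSOMES = frozenset(
    [f"chr{i}" for i in range(1, 23)] + ["chrX", "chrY", "chrM"]
)

CONSEQUENCES = frozenset(
    {
        "missense",
        "stop_gain",
        "stop_loss",
        "splice_disrupting",
        "frameshift",
        "inframe_indel",
        "synonymous",
        "noncoding",
    }
)

CLINVAR_CLASSES = frozenset(
    {"pathogenic", "likely_pathogenic", "vus", "likely_benign", "benign", "absent"}
)
SIFT_CALLS = frozenset({"deleterious", "tolerated", "absent"})
POLYPHEN_CALLS = frozenset({"damaging", "benign", "absent"})
CGI_CALLS = frozenset({"driver", "passenger", "absent"})
LOFTEE_CALLS = frozenset({"lof", "non_lof", "absent"})

COHORTS = frozenset({"SAPCS", "PPCG", "SAC", "EAC", "MGRB"})

#: consequences that disrupt a stop codon
STOP_DISRUPTING = frozenset({"stop_gain", "stop_loss"})


def variant_key(chrom: str, pos: int, ref: str, alt: str) -> str:
    """VCF-style variant identifier, e.g. ``chr13:32319100:T/C``."""
    return f"{chrom}:{pos}:{ref}/{alt}"


@dataclass(frozen=True, slots=True)
class GenomicVariant:
    """One normalized small variant (SNV or indel < 50 bp) with gene context."""

    chrom: str
    pos: int  # 1-based position of the first REF base
    ref: str
    alt: str
    rsid: Optional[str] = None
    gene: Optional[str] = None
    consequence: Optional[str] = None
    aa_change: Optional[str] = None

    def __post_init__(self) -> None:
        if self.chrom not in CHROMOSOMES:
            raise ContractViolation(
                f"contig {self.chrom!r} is not a chr-prefixed GRCh38 chromosome"
            )
        if self.pos < 1:
            raise ContractViolation(f"position must be 1-based positive, got {self.pos}")
        if not self.ref or not self.alt:
            raise ContractViolation("REF and ALT must be non-empty")
        if self.ref == self.alt:
            raise ContractViolation(f"REF equals ALT at {self.chrom}:{self.pos}")
        if len(self.ref) >= MAX_INDEL_LEN or len(self.alt) >= MAX_INDEL_LEN:
            raise ContractViolation(
                f"allele longer than {MAX_INDEL_LEN - 1} bp at {self.chrom}:{self.pos}: "
                "outside small-variant scope"
            )
        if self.consequence is not None and self.consequence not in CONSEQUENCES:
            raise ContractViolation(f"unknown consequence {self.consequence!r}")

    @property
    def key(self) -> str:
        return variant_key(self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True, slots=True)
class AnnotationBundle:
    """External pathogenicity and frequency evidence for one variant.

    A ``None`` gnomAD MAF means the variant is absent from current
    databases and is treated as frequency 0 for tiering.
    """

    clinvar_class: str = "absent"
    sift: str = "absent"
    polyphen: str = "absent"
    cgi_driver: str = "absent"
    loftee_lof: str = "absent"
    gnomad_maf_all: Optional[float] = None
    gnomad_maf_afr: Optional[float] = None

    def __post_init__(self) -> None:
        checks = (
            (self.clinvar_class, CLINVAR_CLASSES, "clinvar_class"),
            (self.sift, SIFT_CALLS, "sift"),
            (self.polyphen, POLYPHEN_CALLS, "polyphen"),
            (self.cgi_driver, CGI_CALLS, "cgi_driver"),
            (self.loftee_lof, LOFTEE_CALLS, "loftee_lof"),
        )
        for value, allowed, name in checks:
            if value not in allowed:
                raise ContractViolation(f"{name}={value!r} not in {sorted(allowed)}")
        for name, maf in (("gnomad_maf_all", self.gnomad_maf_all),
                          ("gnomad_maf_afr", self.gnomad_maf_afr)):
            if maf is not None and not (0.0 <= maf <= 1.0):
                raise ContractViolation(f"{name}={maf} outside [0, 1]")

    @property
    def is_plp(self) -> bool:
        return self.clinvar_class in ("pathogenic", "likely_pathogenic")

    @property
    def is_benign(self) -> bool:
        return self.clinvar_class in ("benign", "likely_benign")


ABSENT_ANNOTATION = AnnotationBundle()


@dataclass(frozen=True, slots=True)
class PatientRecord:
    """Clinical covariates and cohort membership for one participant."""

    patient_id: str
    cohort: str
    role: str  # "case" | "control"
    age_years: Optional[float] = None
    psa_ng_ml: Optional[float] = None
    isup_gg: Optional[int] = None
    fh_prostate: Optional[bool] = None
    fh_breast_ovarian: Optional[bool] = None
    african_fraction: Optional[float] = None
    tumor_available: bool = False

    def __post_init__(self) -> None:
        if self.cohort not in COHORTS:
            raise ContractViolation(f"unknown cohort {self.cohort!r}")
        if self.role not in ("case", "control"):
            raise ContractViolation(f"role must be case/control, got {self.role!r}")
        if self.isup_gg is not None and not 1 <= self.isup_gg <= 5:
            raise ContractViolation(f"ISUP GG must be 1..5, got {self.isup_gg}")
        if self.african_fraction is not None and not 0.0 <= self.african_fraction <= 1.0:
            raise ContractViolation("african_fraction outside [0, 1]")


@dataclass(frozen=True, slots=True)
class GenotypeCall:
    """One patient's genotype at one variant.

    Read counts are ``None`` only when depth data are unavailable
    (reported downstream as an undetermined VAF).
    """

    patient_id: str
    key: str
    allele_count: int  # 0, 1 or 2 alternate alleles
    ref_reads: Optional[int] = None
    alt_reads: Optional[int] = None
    missing: bool = False  # genotype absent from the call set (./.)

    def __post_init__(self) -> None:
        if self.allele_count not in (0, 1, 2):
            raise ContractViolation(f"allele_count must be 0/1/2, got {self.allele_count}")
        for name, reads in (("ref_reads", self.ref_reads), ("alt_reads", self.alt_reads)):
            if reads is not None and reads < 0:
                raise ContractViolation(f"{name} must be non-negative")


@dataclass(frozen=True)
class GeneLists:
    """Curated gene sets driving triage: the DDR/PCa candidate universe, the
    known germline-testing panel, CHIP-associated genes (with literature
    rank), and CHIP-suspect genes used by the missing-VAF policy."""

    ddr_pca_genes: frozenset[str]
    known_gt_genes: frozenset[str]
    chip_genes: dict[str, int] = field(default_factory=dict)
    chip_suspect_genes: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        norm = lambda s: frozenset(g.upper() for g in s)  # noqa: E731
        object.__setattr__(self, "ddr_pca_genes", norm(self.ddr_pca_genes))
        object.__setattr__(self, "known_gt_genes", norm(self.known_gt_genes))
        object.__setattr__(
            self, "chip_genes", {g.upper(): r for g, r in self.chip_genes.items()}
        )
        object.__setattr__(self, "chip_suspect_genes", norm(self.chip_suspect_genes))
        if not self.known_gt_genes <= self.ddr_pca_genes:
            extra = sorted(self.known_gt_genes - self.ddr_pca_genes)
            raise ContractViolation(
                f"known GT panel genes must be a subset of the DDR/PCa set; extra: {extra}"
            )
        if any(r < 1 for r in self.chip_genes.values()):
            raise ContractViolation("CHIP gene ranks must be positive")
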