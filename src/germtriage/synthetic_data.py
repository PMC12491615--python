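"""Synthetic cohorts with planted variant classes and matched tumors.

Patient genotype data of the kind this pipeline consumes are
access-controlled; this module generates a statistically structured
stand-in: case and control cohorts with the study's sizes and clinical
marginals, an annotated variant panel with planted classes whose
realized frequencies are guaranteed to respect each class's defining
MAF tier, Hardy-Weinberg genotypes, Poisson read depths separating
germline from planted-CHIP carriers, and tumor profiles with planted
LOH/second-hit events.  A truth table records every planted label so
pipeline recovery can be scored.

Everything is deterministic under a fixed seed (one generator threaded
through sequential draws; gene and patient identifiers sorted before
sampling).
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict

from .bundle import ComparisonCohort, InputBundle
from .chip_filter import ChipDecision
from .errors import ContractViolation
from .frequency import CohortFrequency, control_screen
from .genes import DECOY_GENES, default_gene_lists
from .tumor_evidence import CnSegment, SomaticProfile, SomaticVariant
from .types import AnnotationBundle, GenomicVariant, GenotypeCall, PatientRecord

_BASES = ("A", "C", "G", "T")
#: approximate GRCh38 autosome lengths (bp), for plausible positions
_CHROM_LEN = {
    "chr1": 248_956_000, "chr2": 242_193_000, "chr3": 198_295_000,
    "chr4": 190_214_000, "chr5": 181_538_000, "chr6": 170_805_000,
    "chr7": 159_345_000, "chr8": 145_138_000, "chr9": 138_394_000,
    "chr10": 133_797_000, "chr11": 135_086_000, "chr12": 133_275_000,
    "chr13": 114_364_000, "chr14": 107_043_000, "chr15": 101_991_000,
    "chr16": 90_338_000, "chr17": 83_257_000, "chr18": 80_373_000,
    "chr19": 58_617_000, "chr20": 64_444_000, "chr21": 46_709_000,
    "chr22": 50_818_000,
}
_CHROMS = tuple(_CHROM_LEN)


class CohortSizes(BaseModel):
    model_config = ConfigDict(frozen=True)
    sapcs: int = 186
    ppcg: int = 31
    sac: int = 49
    eac: int = 40
    mgrb: int = 3209  # scale down for quick runs
    ppcg_euro: int = 959


class ClinicalSpec(BaseModel):
    model_config = ConfigDict(frozen=True)
    age_mean: dict[str, float] = {"SAPCS": 66.7, "PPCG": 64.8}
    age_sd: float = 9.0
    age_min: float = 40.0
    psa_mean: dict[str, float] = {"SAPCS": 233.6, "PPCG": 60.8}
    psa_log_sigma: float = 1.5
    # ISUP GG 1..5 probabilities; GG>=4 mass matches the printed cohort fractions
    isup_probs: dict[str, tuple[float, ...]] = {
        "SAPCS": (0.08, 0.18, 0.208, 0.30, 0.232),
        "PPCG": (0.25, 0.30, 0.256, 0.12, 0.074),
    }
    fh_prostate_p: float = 0.10
    fh_breast_ovarian_p: float = 0.05
    ancestry_beta: dict[str, tuple[float, float]] = {"SAPCS": (30.0, 1.0), "PPCG": (5.0, 2.0)}
    tumor_n: dict[str, int] = {"SAPCS": 116, "PPCG": 31}


class PanelSpec(BaseModel):
    """Planted variant counts per class (defaults mirror the study panel)."""

    model_config = ConfigDict(frozen=True)
    n_ppv: int = 45
    n_pslf_ppv: int = 1
    n_pov: int = 138
    n_pslf_pov: int = 16
    n_benign: int = 40
    n_vus_nondriver: int = 40
    n_common_plp: int = 10
    n_low_freq_vus: int = 8
    n_control_common: int = 6
    n_offpanel: int = 30
    rare_af: tuple[float, float] = (0.002, 0.006)
    pslf_af: tuple[float, float] = (0.02, 0.045)
    control_common_af: float = 0.06
    gnomad_rare_max: float = 0.005
    gnomad_absent_p: float = 0.25

    def total(self) -> int:
        return (self.n_ppv + self.n_pslf_ppv + self.n_pov + self.n_pslf_pov
                + self.n_benign + self.n_vus_nondriver + self.n_common_plp
                + self.n_low_freq_vus + self.n_control_common + self.n_offpanel)


class ReadSpec(BaseModel):
    model_config = ConfigDict(frozen=True)
    depth_mean: float = 40.0
    chip_rate: float = 0.5  # planted-CHIP probability for chip-gene carriers
    chip_fraction: float = 0.15  # alt-read binomial p for planted CHIP
    missing_vaf_rate: float = 0.05  # PPCG carriers with no read counts


class TumorSpec(BaseModel):
    model_config = ConfigDict(frozen=True)
    p_loh: float = 0.35  # conditional on planted pathogenic class, tumor available
    p_second_hit: float = 0.25
    background_rate_per_mb: float = 1.1
    msi_h_rate: float = 0.02
    callable_mb: float = 2800.0


class SimulationConfig(BaseModel):
    model_config = ConfigDict(frozen=True)
    seed: int = 1
    cohorts: CohortSizes = CohortSizes()
    clinical: ClinicalSpec = ClinicalSpec()
    panel: PanelSpec = PanelSpec()
    reads: ReadSpec = ReadSpec()
    tumor: TumorSpec = TumorSpec()
    pslf_floor: float = 0.01
    control_exclude: float = 0.02

    def validate_feasible(self) -> None:
        p = self.panel
        for lo, hi in (p.rare_af, p.pslf_af):
            if not (0.0 < lo <= hi <= 0.5):
                raise ContractViolation(f"allele-frequency range ({lo}, {hi}) infeasible")
        if not 0.0 < p.control_common_af <= 0.5:
            raise ContractViolation("control_common_af infeasible")
        if p.pslf_af[0] < self.pslf_floor:
            raise ContractViolation(
                "planted PSLF frequencies must sit at or above the PSLF floor"
            )
        if p.rare_af[1] >= self.pslf_floor:
            raise ContractViolation(
                "planted rare frequencies must sit below the PSLF floor"
            )


@dataclass
class SyntheticBundle:
    """Input bundle plus the planted truth tables."""

    bundle: InputBundle
    truth_variants: pd.DataFrame
    truth_carriers: pd.DataFrame
    config: SimulationConfig


# --------------------------------------------------------------------------
# panel construction

def _class_plan(panel: PanelSpec) -> list[dict]:
    plan = []
    def add(name, count, expected):
        plan.extend({"planted_class": name, "expected_class": expected} for _ in range(count))
    add("ppv", panel.n_ppv, "PPV")
    add("pslf_ppv", panel.n_pslf_ppv, "PSLF_PPV")
    add("pov", panel.n_pov, "POV")
    add("pslf_pov", panel.n_pslf_pov, "PSLF_POV")
    add("benign", panel.n_benign, "excluded")
    add("vus_nondriver", panel.n_vus_nondriver, "excluded")
    add("common_plp", panel.n_common_plp, "excluded")
    add("low_freq_vus", panel.n_low_freq_vus, "excluded")
    add("control_common", panel.n_control_common, "POV")  # excluded later by controls
    add("offpanel", panel.n_offpanel, "excluded")
    return plan


def _draw_alleles(rng: np.random.Generator, consequence: str) -> tuple[str, str]:
    ref = _BASES[rng.integers(4)]
    if consequence in ("frameshift",):
        if rng.random() < 0.5:  # deletion
            extra = "".join(_BASES[i] for i in rng.integers(0, 4, rng.integers(1, 5)))
            return ref + extra, ref
        extra = "".join(_BASES[i] for i in rng.integers(0, 4, rng.integers(1, 5)))
        return ref, ref + extra
    if consequence == "inframe_indel":
        extra = "".join(_BASES[i] for i in rng.integers(0, 4, 3))
        return ref + extra, ref
    alt = _BASES[rng.integers(4)]
    while alt == ref:
        alt = _BASES[rng.integers(4)]
    return ref, alt


def _annotation_for(rng: np.random.Generator, planted: str, panel: PanelSpec) -> tuple[AnnotationBundle, str]:
    """Draw (annotation, consequence) consistent with the planted class."""
    def gnomad_rare():
        if rng.random() < panel.gnomad_absent_p:
            return None, None
        all_maf = float(rng.uniform(0.0, panel.gnomad_rare_max))
        # AFR-restricted MAF runs higher but stays within the rare tier
        afr_maf = float(min(0.0099, all_maf * rng.uniform(1.0, 4.0)))
        return all_maf, afr_maf

    if planted in ("ppv", "pslf_ppv", "offpanel"):
        clinvar = "pathogenic" if rng.random() < 0.5 else "likely_pathogenic"
        consequence = ["stop_gain", "frameshift", "missense", "splice_disrupting"][rng.integers(4)]
        g_all, g_afr = gnomad_rare()
        lof = "lof" if consequence in ("stop_gain", "frameshift", "splice_disrupting") and rng.random() < 0.7 else "absent"
        return AnnotationBundle(
            clinvar_class=clinvar,
            sift="absent", polyphen="absent", cgi_driver="absent",
            loftee_lof=lof, gnomad_maf_all=g_all, gnomad_maf_afr=g_afr,
        ), consequence
    if planted == "common_plp":
        return AnnotationBundle(
            clinvar_class="pathogenic",
            gnomad_maf_all=float(rng.uniform(0.06, 0.2)),
            gnomad_maf_afr=float(rng.uniform(0.06, 0.3)),
        ), "missense"
    if planted in ("pov", "pslf_pov", "control_common", "low_freq_vus"):
        clinvar = "vus" if rng.random() < 0.6 else "absent"
        mech = rng.integers(4)
        consequence, sift, polyphen, lof = "missense", "absent", "absent", "absent"
        if mech == 0:
            sift = "deleterious"
            polyphen = "damaging" if rng.random() < 0.5 else "absent"
        elif mech == 1:
            polyphen = "damaging"
        elif mech == 2:
            consequence = "stop_gain" if rng.random() < 0.5 else "splice_disrupting"
        else:
            consequence, lof = "frameshift", "lof"
        if planted == "low_freq_vus":
            g_all = float(rng.uniform(0.015, 0.04))
            g_afr = float(rng.uniform(0.015, 0.049))
        else:
            g_all, g_afr = gnomad_rare()
        return AnnotationBundle(
            clinvar_class=clinvar, sift=sift, polyphen=polyphen,
            cgi_driver="driver", loftee_lof=lof,
            gnomad_maf_all=g_all, gnomad_maf_afr=g_afr,
        ), consequence
    if planted == "vus_nondriver":
        if rng.random() < 0.5:  # functional but not a CGI driver
            g_all, g_afr = gnomad_rare()
            return AnnotationBundle(
                clinvar_class="vus", sift="deleterious", cgi_driver="passenger",
                gnomad_maf_all=g_all, gnomad_maf_afr=g_afr,
            ), "missense"
        g_all, g_afr = gnomad_rare()
        return AnnotationBundle(  # no functional evidence at all
            clinvar_class="vus", sift="tolerated", polyphen="benign",
            cgi_driver="driver", gnomad_maf_all=g_all, gnomad_maf_afr=g_afr,
        ), "missense"
    if planted == "benign":
        return AnnotationBundle(
            clinvar_class="benign" if rng.random() < 0.5 else "likely_benign",
            gnomad_maf_all=float(rng.uniform(0.0, 0.04)),
        ), "synonymous"
    raise ContractViolation(f"unknown planted class {planted!r}")


def _draw_case_genotypes(
    rng: np.random.Generator,
    af_sapcs: float,
    af_ppcg: float,
    n_sapcs: int,
    n_ppcg: int,
    constraint: str,
    pslf_floor: float,
    max_tries: int = 2000,
):
    """Hardy-Weinberg draws with rejection so realized study MAFs respect
    the planted class's defining tier and every variant has a carrier."""
    for _ in range(max_tries):
        g_s = rng.binomial(2, af_sapcs, n_sapcs) if af_sapcs > 0 else np.zeros(n_sapcs, dtype=int)
        g_p = rng.binomial(2, af_ppcg, n_ppcg) if af_ppcg > 0 else np.zeros(n_ppcg, dtype=int)
        ac_s, ac_p = int(g_s.sum()), int(g_p.sum())
        if ac_s + ac_p == 0:
            continue
        maf_s, maf_p = ac_s / (2 * n_sapcs), ac_p / (2 * n_ppcg)
        # the PSLF floor needs >=2 alleles behind it (a singleton in a small
        # cohort is rare, not population-specific), mirroring classification
        at_floor = (maf_s >= pslf_floor and ac_s >= 2) or (
            maf_p >= pslf_floor and ac_p >= 2
        )
        if constraint == "rare" and at_floor:
            continue
        if constraint == "pslf" and not at_floor:
            continue
        return g_s, g_p
    raise ContractViolation(
        f"could not realize constraint {constraint!r} at af=({af_sapcs}, {af_ppcg}): "
        "planted frequency spec infeasible"
    )


def simulate_cohorts(
    config: SimulationConfig, out_dir: Optional[str | Path] = None
) -> SyntheticBundle:
    """Generate the full input bundle plus truth tables; optionally write it."""
    config.validate_feasible()
    rng = np.random.default_rng(config.seed)
    sizes = config.cohorts
    clin = config.clinical
    panel = config.panel
    gene_lists = default_gene_lists()
    ddr_sorted = sorted(gene_lists.ddr_pca_genes)

    # ---- patients -------------------------------------------------------
    patients: list[PatientRecord] = []
    tumor_ids: set[str] = set()
    for cohort, n, role in (
        ("SAPCS", sizes.sapcs, "case"),
        ("PPCG", sizes.ppcg, "case"),
        ("SAC", sizes.sac, "control"),
        ("EAC", sizes.eac, "control"),
    ):
        ids = [f"{cohort}{i:04d}" for i in range(1, n + 1)]
        if role == "case":
            n_tumor = min(clin.tumor_n.get(cohort, 0), n)
            with_tumor = set(rng.choice(ids, size=n_tumor, replace=False))
            tumor_ids.update(with_tumor)
            ages = np.maximum(clin.age_min, rng.normal(clin.age_mean[cohort], clin.age_sd, n))
            mu = np.log(clin.psa_mean[cohort]) - clin.psa_log_sigma**2 / 2
            psa = rng.lognormal(mu, clin.psa_log_sigma, n)
            isup = rng.choice(np.arange(1, 6), size=n, p=clin.isup_probs[cohort])
            fh_p = rng.random(n) < clin.fh_prostate_p
            fh_bo = rng.random(n) < clin.fh_breast_ovarian_p
            a, b = clin.ancestry_beta[cohort]
            afr = rng.beta(a, b, n)
            for i, pid in enumerate(ids):
                patients.append(
                    PatientRecord(
                        patient_id=pid, cohort=cohort, role="case",
                        age_years=round(float(ages[i]), 1),
                        psa_ng_ml=round(float(psa[i]), 1),
                        isup_gg=int(isup[i]),
                        fh_prostate=bool(fh_p[i]),
                        fh_breast_ovarian=bool(fh_bo[i]),
                        african_fraction=round(float(afr[i]), 4),
                        tumor_available=pid in with_tumor,
                    )
                )
        else:
            ages = rng.uniform(25, 49, n) if cohort in ("SAC", "EAC") else rng.uniform(75, 95, n)
            for i, pid in enumerate(ids):
                patients.append(
                    PatientRecord(
                        patient_id=pid, cohort=cohort, role="control",
                        age_years=round(float(ages[i]), 1),
                        tumor_available=False,
                    )
                )
    sapcs_ids = [p.patient_id for p in patients if p.cohort == "SAPCS"]
    ppcg_ids = [p.patient_id for p in patients if p.cohort == "PPCG"]
    sac_ids = [p.patient_id for p in patients if p.cohort == "SAC"]
    eac_ids = [p.patient_id for p in patients if p.cohort == "EAC"]

    # ---- variant panel --------------------------------------------------
    plan = _class_plan(panel)
    variants: list[GenomicVariant] = []
    annotations: dict[str, AnnotationBundle] = {}
    calls: list[GenotypeCall] = []
    truth_var_rows, truth_carrier_rows = [], []
    used_pos: set[tuple[str, int]] = set()
    aa_counter = itertools.count(1)

    def fresh_locus() -> tuple[str, int]:
        while True:
            chrom = _CHROMS[rng.integers(len(_CHROMS))]
            pos = int(rng.integers(1_000_000, _CHROM_LEN[chrom] - 1_000_000))
            if (chrom, pos) not in used_pos:
                used_pos.add((chrom, pos))
                return chrom, pos

    chip_scope = set(gene_lists.chip_genes) | set(gene_lists.chip_suspect_genes)
    for entry in plan:
        planted = entry["planted_class"]
        ann, consequence = _annotation_for(rng, planted, panel)
        chrom, pos = fresh_locus()
        ref, alt = _draw_alleles(rng, consequence)
        gene = (
            DECOY_GENES[rng.integers(len(DECOY_GENES))]
            if planted == "offpanel"
            else ddr_sorted[rng.integers(len(ddr_sorted))]
        )
        rsid = f"rs{int(rng.integers(10**6, 10**9))}" if rng.random() < 0.8 else None
        aa = f"p.X{next(aa_counter)}" if consequence != "synonymous" else None
        variant = GenomicVariant(chrom, pos, ref, alt, rsid, gene, consequence, aa)
        variants.append(variant)
        annotations[variant.key] = ann

        # case genotypes under the class's frequency constraint
        if planted in ("pslf_ppv", "pslf_pov"):
            af_s = float(rng.uniform(*panel.pslf_af))
            af_p = float(rng.uniform(0.0, 0.02)) if rng.random() < 0.3 else 0.0
            constraint = "pslf"
        else:
            af_s = float(rng.uniform(*panel.rare_af))
            af_p = float(rng.uniform(*panel.rare_af)) if rng.random() < 0.3 else 0.0
            constraint = "rare"
        g_s, g_p = _draw_case_genotypes(
            rng, af_s, af_p, sizes.sapcs, sizes.ppcg, constraint, config.pslf_floor
        )

        # control genotypes
        if planted == "control_common":
            for _ in range(2000):
                g_sac = rng.binomial(2, panel.control_common_af, sizes.sac)
                g_eac = rng.binomial(2, panel.control_common_af, sizes.eac)
                decision = control_screen(
                    CohortFrequency("SAC", sizes.sac, *_het_hom(g_sac)),
                    CohortFrequency("EAC", sizes.eac, *_het_hom(g_eac)),
                    config.control_exclude,
                )
                if not decision.keep:
                    break
            else:
                raise ContractViolation("control-common planting infeasible")
        else:
            # occasional singleton-scale presence in one control cohort
            g_sac = np.zeros(sizes.sac, dtype=int)
            g_eac = np.zeros(sizes.eac, dtype=int)
            if rng.random() < 0.05:
                g_sac[rng.integers(sizes.sac)] = 1
            if rng.random() < 0.05:
                g_eac[rng.integers(sizes.eac)] = 1

        het_s, hom_s = _het_hom(g_s)
        het_p, hom_p = _het_hom(g_p)
        truth_var_rows.append(
            {
                "key": variant.key, "gene": gene,
                "planted_class": planted, "expected_class": entry["expected_class"],
                "af_sapcs": af_s, "af_ppcg": af_p,
                "maf_sapcs": (het_s + 2 * hom_s) / (2 * sizes.sapcs),
                "maf_ppcg": (het_p + 2 * hom_p) / (2 * sizes.ppcg),
                "gnomad_maf_all": ann.gnomad_maf_all,
                "gnomad_maf_afr": ann.gnomad_maf_afr,
            }
        )

        # carrier calls with read counts
        for cohort_ids, genotypes, cohort in (
            (sapcs_ids, g_s, "SAPCS"),
            (ppcg_ids, g_p, "PPCG"),
            (sac_ids, g_sac, "SAC"),
            (eac_ids, g_eac, "EAC"),
        ):
            carrier_idx = np.nonzero(genotypes)[0]
            for i in carrier_idx:
                pid = cohort_ids[i]
                count = int(genotypes[i])
                is_case = cohort in ("SAPCS", "PPCG")
                chip = bool(
                    is_case
                    and count == 1
                    and gene in gene_lists.chip_genes
                    and rng.random() < config.reads.chip_rate
                )
                missing_reads = bool(
                    cohort == "PPCG" and rng.random() < config.reads.missing_vaf_rate
                )
                if missing_reads:
                    ref_reads = alt_reads = None
                else:
                    depth = int(rng.poisson(config.reads.depth_mean))
                    p_alt = config.reads.chip_fraction if chip else (1.0 if count == 2 else 0.5)
                    alt_reads = int(rng.binomial(depth, p_alt)) if depth > 0 else 0
                    ref_reads = depth - alt_reads
                calls.append(
                    GenotypeCall(pid, variant.key, count, ref_reads, alt_reads)
                )
                if is_case:
                    truth_carrier_rows.append(
                        {
                            "patient_id": pid, "key": variant.key, "gene": gene,
                            "planted_class": planted, "chip": chip,
                            "vaf_missing": missing_reads,
                            "in_chip_scope": gene in chip_scope,
                            "loh_planted": False, "second_hit_planted": False,
                        }
                    )

    # ---- tumor profiles -------------------------------------------------
    tumor_cfg = config.tumor
    pathogenic = {"ppv", "pslf_ppv", "pov", "pslf_pov"}
    events: dict[str, dict] = {pid: {"snvs": [], "segs": []} for pid in sorted(tumor_ids)}
    variant_by_key = {v.key: v for v in variants}
    for row in truth_carrier_rows:
        if row["planted_class"] not in pathogenic or row["patient_id"] not in events:
            continue
        v = variant_by_key[row["key"]]
        slot = events[row["patient_id"]]
        if rng.random() < tumor_cfg.p_loh:
            row["loh_planted"] = True
            if rng.random() < 0.5:
                half = int(rng.integers(10_000, 100_000))
                slot["segs"].append(CnSegment(v.chrom, max(1, v.pos - half), v.pos + half, True))
            else:
                slot["snvs"].append(
                    SomaticVariant(v.chrom, v.pos, v.ref, v.alt, v.gene,
                                   float(rng.uniform(0.70, 0.92)), True)
                )
        if rng.random() < tumor_cfg.p_second_hit:
            row["second_hit_planted"] = True
            chrom2, pos2 = fresh_locus()
            ref2, alt2 = _draw_alleles(rng, "missense")
            slot["snvs"].append(
                SomaticVariant(v.chrom, v.pos + int(rng.integers(100, 10_000)),
                               ref2, alt2, v.gene, float(rng.uniform(0.2, 0.6)), True)
            )
    somatic: dict[str, SomaticProfile] = {}
    for pid in sorted(tumor_ids):
        slot = events[pid]
        background = int(rng.poisson(tumor_cfg.background_rate_per_mb * tumor_cfg.callable_mb))
        somatic[pid] = SomaticProfile(
            patient_id=pid,
            somatic_snvs=tuple(slot["snvs"]),
            cn_segments=tuple(slot["segs"]),
            msi_status="MSI-H" if rng.random() < tumor_cfg.msi_h_rate else "MSS",
            n_background_mutations=background,
        )

    # ---- comparison cohorts (cross-cohort screen inputs) ----------------
    comparison: dict[str, ComparisonCohort] = {}
    african_ppv_genes = sorted(
        {r["gene"] for r in truth_var_rows if r["planted_class"] in ("ppv", "pslf_ppv")}
    )
    african_agg: dict[str, int] = {}
    for r in truth_var_rows:
        if r["planted_class"] in ("ppv", "pslf_ppv"):
            ac = int(round(r["maf_sapcs"] * 2 * sizes.sapcs + r["maf_ppcg"] * 2 * sizes.ppcg))
            african_agg[r["gene"]] = african_agg.get(r["gene"], 0) + ac
    n_cases = sizes.sapcs + sizes.ppcg
    shared = [r for r in truth_var_rows if r["planted_class"] == "ppv"][:2]
    shared_genes = {r["gene"] for r in shared}
    for name, n_comp in (("ppcg_euro", sizes.ppcg_euro), ("mgrb", sizes.mgrb)):
        comp_variants: list[GenomicVariant] = []
        comp_calls: list[GenotypeCall] = []
        comp_ids = [f"{name.upper()}{i:05d}" for i in range(1, n_comp + 1)]
        for gene in african_ppv_genes:
            if rng.random() >= 0.6:
                continue  # conserved in this comparison cohort
            # burden must not exceed the African aggregate MAF for the gene
            # (singleton-scale shared variants below count against it too)
            budget = int(np.floor(african_agg[gene] / (2 * n_cases) * 2 * n_comp))
            if gene in shared_genes:
                budget -= 1
            n_new = int(rng.integers(1, 3))
            for _ in range(n_new):
                if budget <= 0:
                    break
                chrom, pos = fresh_locus()
                ref, alt = _draw_alleles(rng, "missense")
                v = GenomicVariant(chrom, pos, ref, alt,
                                   f"rs{int(rng.integers(10**6, 10**9))}",
                                   gene, "missense", f"p.C{next(aa_counter)}")
                ac = int(rng.integers(1, min(3, budget) + 1))
                budget -= ac
                comp_variants.append(v)
                annotations[v.key] = AnnotationBundle(
                    clinvar_class="pathogenic",
                    gnomad_maf_all=float(rng.uniform(0.0, 0.002)),
                )
                for pid in rng.choice(comp_ids, size=ac, replace=False):
                    depth = int(rng.poisson(config.reads.depth_mean))
                    alt_reads = int(rng.binomial(depth, 0.5)) if depth > 0 else 0
                    comp_calls.append(GenotypeCall(pid, v.key, 1, depth - alt_reads, alt_reads))
        # a couple of African PPVs shared at singleton scale
        for r in shared:
            pid = comp_ids[int(rng.integers(n_comp))]
            depth = int(rng.poisson(config.reads.depth_mean))
            alt_reads = int(rng.binomial(depth, 0.5)) if depth > 0 else 0
            comp_variants.append(variant_by_key[r["key"]])
            comp_calls.append(GenotypeCall(pid, r["key"], 1, depth - alt_reads, alt_reads))
        comparison[name] = ComparisonCohort(name, n_comp, comp_variants, comp_calls)

    bundle = InputBundle(
        patients=patients,
        variants=variants,
        calls=calls,
        annotations=annotations,
        gene_lists=gene_lists,
        somatic=somatic,
        comparison=comparison,
    )
    truth_variants = pd.DataFrame(truth_var_rows)
    truth_carriers = pd.DataFrame(
        truth_carrier_rows,
        columns=["patient_id", "key", "gene", "planted_class", "chip", "vaf_missing",
                 "in_chip_scope", "loh_planted", "second_hit_planted"],
    )
    if out_dir is not None:
        out = Path(out_dir)
        bundle.write(out)
        truth_variants.to_csv(out / "truth_variants.tsv", sep="\t", index=False,
                              lineterminator="\n")
        truth_carriers.to_csv(out / "truth_carriers.tsv", sep="\t", index=False,
                              lineterminator="\n")
        (out / "simulation_config.json").write_text(
            config.model_dump_json(indent=2) + "\n"
        )
    return SyntheticBundle(bundle, truth_variants, truth_carriers, config)


def _het_hom(genotypes: np.ndarray) -> tuple[int, int]:
    return int((genotypes == 1).sum()), int((genotypes == 2).sum())


# --------------------------------------------------------------------------
# recovery scoring

def recovery_report(
    classified_map: dict[str, str],
    chip_decisions: list[ChipDecision],
    tumor_evidence: dict[tuple[str, str], bool],
    truth: SyntheticBundle,
) -> dict:
    """Score pipeline output against the planted truth.

    ``classified_map`` maps variant key -> recovered class (classification
    plus gene-set stages); ``tumor_evidence`` maps (patient_id, key) ->
    detected LOH flag for retained tumor-matched carriers.
    """
    tv = truth.truth_variants
    classes = ["PPV", "POV", "PSLF_PPV", "PSLF_POV", "excluded"]
    confusion = {c: {c2: 0 for c2 in classes} for c in classes}
    for row in tv.itertuples(index=False):
        got = classified_map.get(row.key, "excluded")
        confusion[row.expected_class][got] += 1
    per_class = {}
    for c in classes:
        tp = confusion[c][c]
        fn = sum(confusion[c][o] for o in classes if o != c)
        fp = sum(confusion[o][c] for o in classes if o != c)
        per_class[c] = {
            "n_planted": tp + fn,
            "recall": tp / (tp + fn) if tp + fn else None,
            "precision": tp / (tp + fp) if tp + fp else None,
        }

    chip_truth = {
        (r.patient_id, r.key): bool(r.chip)
        for r in truth.truth_carriers.itertuples(index=False)
        if not r.vaf_missing
    }
    chip_excluded = chip_total = germ_retained = germ_total = 0
    for d in chip_decisions:
        planted = chip_truth.get((d.patient_id, d.key))
        if planted is None:
            continue
        if planted:
            chip_total += 1
            chip_excluded += int(d.decision == "exclude_chip")
        else:
            germ_total += 1
            germ_retained += int(d.retained)
    loh_truth = {
        (r.patient_id, r.key): bool(r.loh_planted)
        for r in truth.truth_carriers.itertuples(index=False)
    }
    loh_detected = loh_planted_n = 0
    for pair, detected in tumor_evidence.items():
        if loh_truth.get(pair):
            loh_planted_n += 1
            loh_detected += int(detected)
    return {
        "confusion": confusion,
        "per_class": per_class,
        "chip_exclusion_sensitivity": chip_excluded / chip_total if chip_total else None,
        "germline_retention": germ_retained / germ_total if germ_total else None,
        "loh_detection_rate": loh_detected / loh_planted_n if loh_planted_n else None,
    }
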