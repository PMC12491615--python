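"""Reading, normalization and writing of all external formats.

Variant calls arrive as VCF v4.2+ (plain or bgzipped, parsed with
cyvcf2) or as flat TSV tables; annotations, clinical covariates, gene
lists, somatic calls and copy-number segments are TSV with documented
headers.  All coordinates are 1-based GRCh38 with chr-prefixed contigs;
alleles are parsimony-trimmed (shared suffix then shared prefix) so that
(chrom, pos, ref, alt) keys are canonical for joining against
gnomAD/ClinVar-style annotation tables.

Output is a directory of tab-separated tables (``ppv.tsv``, ``pov.tsv``,
``pslf.tsv``, ``excluded.tsv``, ``variant_ranking.tsv``,
``gene_ranking.tsv``, ``gene_screen.tsv``) plus a machine-readable
``run_summary.json`` holding the config snapshot, seeds and the
per-stage filter funnel.  MAF columns print to 4 decimals and VAF
columns to 6, so a write followed by a re-read reproduces the tables
byte-for-byte.
"""
from __future__ import annotations

import json
import logging
import math
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .errors import ContractViolation, ParseError
from .tumor_evidence import CnSegment, SomaticProfile, SomaticVariant
from .types import (
    CHROMOSOMES,
    AnnotationBundle,
    GeneLists,
    GenomicVariant,
    GenotypeCall,
    PatientRecord,
    variant_key,
)

log = logging.getLogger(__name__)

VARIANT_COLUMNS = ["chrom", "pos", "ref", "alt", "rsid", "gene", "consequence", "aa_change"]
CALL_COLUMNS = ["patient_id", "chrom", "pos", "ref", "alt", "allele_count",
                "ref_reads", "alt_reads", "missing"]
ANNOTATION_COLUMNS = ["chrom", "pos", "ref", "alt", "clinvar_class", "sift", "polyphen",
                      "cgi_driver", "loftee_lof", "gnomad_maf_all", "gnomad_maf_afr"]
CLINICAL_COLUMNS = ["patient_id", "cohort", "role", "age_years", "psa_ng_ml", "isup_gg",
                    "fh_prostate", "fh_breast_ovarian", "african_fraction", "tumor_available"]


def normalize_alleles(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Parsimonious REF-anchored representation of an allele pair.

    Trims the shared suffix, then the shared prefix (advancing ``pos``),
    always leaving at least one base on each side.  Idempotent.
    """
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


def normalize_variant(v: GenomicVariant) -> GenomicVariant:
    pos, ref, alt = normalize_alleles(v.pos, v.ref, v.alt)
    if (pos, ref, alt) == (v.pos, v.ref, v.alt):
        return v
    return GenomicVariant(v.chrom, pos, ref, alt, v.rsid, v.gene, v.consequence, v.aa_change)


def _infer_dialect(path: Path) -> str:
    name = path.name.lower()
    if name.endswith((".vcf", ".vcf.gz", ".vcf.bgz")):
        return "vcf"
    return "tsv"


def read_variants(
    path: str | Path, dialect: Optional[str] = None
) -> tuple[list[GenomicVariant], list[GenotypeCall]]:
    """Read a call set into normalized variants and genotype calls.

    Multi-allelic VCF rows are split into one variant per ALT; missing
    genotypes become allele_count 0 with the ``missing`` flag; GT and AD
    fields map onto :class:`GenotypeCall`.  TSV input carries variants
    only (use :func:`read_genotype_calls` for the call table).
    """
    path = Path(path)
    dialect = dialect or _infer_dialect(path)
    if dialect == "vcf":
        return _read_vcf(path)
    if dialect == "tsv":
        return _read_variant_tsv(path), []
    raise ParseError(f"unknown dialect {dialect!r}")


def _read_vcf(path: Path) -> tuple[list[GenomicVariant], list[GenotypeCall]]:
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare OSError/Exception on bad input
        raise ParseError(f"cannot open VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    variants: list[GenomicVariant] = []
    calls: list[GenotypeCall] = []
    seen: set[str] = set()
    for line_no, rec in enumerate(vcf, start=1):
        if rec.CHROM not in CHROMOSOMES:
            raise ContractViolation(
                f"{path} record {line_no}: contig {rec.CHROM!r} is not a "
                "chr-prefixed GRCh38 chromosome"
            )
        rsid = rec.ID if rec.ID and rec.ID != "." else None
        gene = rec.INFO.get("GENE")
        consequence = rec.INFO.get("CSQ")
        aa = rec.INFO.get("AA")
        genotypes = rec.genotypes if samples else []
        try:
            ad = rec.format("AD")
        except Exception:
            ad = None
        for alt_idx, alt in enumerate(rec.ALT):
            pos, ref, norm_alt = normalize_alleles(rec.POS, rec.REF, alt)
            try:
                variant = GenomicVariant(
                    rec.CHROM, pos, ref, norm_alt, rsid, gene, consequence, aa
                )
            except ContractViolation as exc:
                raise ParseError(f"{path} record {line_no}: {exc}") from exc
            if variant.key in seen:
                raise ContractViolation(
                    f"{path} record {line_no}: duplicate normalized variant {variant.key}"
                )
            seen.add(variant.key)
            variants.append(variant)
            allele_no = alt_idx + 1
            for s_idx, sample in enumerate(samples):
                gt = genotypes[s_idx]
                alleles = [a for a in gt[:-1] if isinstance(a, int)]
                missing = all(a == -1 for a in alleles)
                count = sum(1 for a in alleles if a == allele_no)
                ref_reads = alt_reads = None
                if ad is not None:
                    row = ad[s_idx]
                    if int(row[0]) >= 0:
                        ref_reads = int(row[0])
                    if len(row) > allele_no and int(row[allele_no]) >= 0:
                        alt_reads = int(row[allele_no])
                calls.append(
                    GenotypeCall(
                        patient_id=sample,
                        key=variant.key,
                        allele_count=0 if missing else count,
                        ref_reads=ref_reads,
                        alt_reads=alt_reads,
                        missing=missing,
                    )
                )
    return variants, calls


def _read_variant_tsv(path: Path) -> list[GenomicVariant]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing_cols = set(VARIANT_COLUMNS[:4]) - set(df.columns)
    if missing_cols:
        raise ParseError(f"{path}: missing columns {sorted(missing_cols)}")
    variants = []
    seen: set[str] = set()
    for idx, row in enumerate(df.itertuples(index=False), start=2):
        try:
            pos, ref, alt = normalize_alleles(int(row.pos), row.ref, row.alt)
            v = GenomicVariant(
                row.chrom,
                pos,
                ref,
                alt,
                getattr(row, "rsid", "") or None,
                getattr(row, "gene", "") or None,
                getattr(row, "consequence", "") or None,
                getattr(row, "aa_change", "") or None,
            )
        except (ValueError, ContractViolation) as exc:
            raise ParseError(f"{path} line {idx}: {exc}") from exc
        if v.key in seen:
            raise ContractViolation(f"{path} line {idx}: duplicate variant {v.key}")
        seen.add(v.key)
        variants.append(v)
    return variants


def read_genotype_calls(path: str | Path) -> list[GenotypeCall]:
    """Long-format genotype call table (one row per patient-variant)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)

    def opt_int(value: str) -> Optional[int]:
        return int(value) if value not in ("", "NA") else None

    calls = []
    for idx, row in enumerate(df.itertuples(index=False), start=2):
        try:
            pos, ref, alt = normalize_alleles(int(row.pos), row.ref, row.alt)
            calls.append(
                GenotypeCall(
                    patient_id=row.patient_id,
                    key=variant_key(row.chrom, pos, ref, alt),
                    allele_count=int(row.allele_count),
                    ref_reads=opt_int(getattr(row, "ref_reads", "")),
                    alt_reads=opt_int(getattr(row, "alt_reads", "")),
                    missing=str(getattr(row, "missing", "False")) in ("True", "true", "1"),
                )
            )
        except (ValueError, ContractViolation) as exc:
            raise ParseError(f"{path} line {idx}: {exc}") from exc
    return calls


def read_annotation_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(Path(path), sep="\t", dtype=str, keep_default_na=False)
    missing_cols = set(ANNOTATION_COLUMNS[:4]) - set(df.columns)
    if missing_cols:
        raise ParseError(f"{path}: missing columns {sorted(missing_cols)}")
    return df


def join_annotations(
    variants: Iterable[GenomicVariant], table: pd.DataFrame
) -> dict[str, AnnotationBundle]:
    """Map each variant key to its annotation bundle.

    The table is keyed by normalized (chrom, pos, ref, alt); exact
    duplicate rows deduplicate silently, conflicting duplicates raise.
    Unmatched variants receive the all-absent bundle and are logged.
    """
    table = table.drop_duplicates()
    keyed: dict[str, AnnotationBundle] = {}
    conflicts = []
    for _, row in table.iterrows():
        pos, ref, alt = normalize_alleles(int(row["pos"]), row["ref"], row["alt"])
        key = variant_key(row["chrom"], pos, ref, alt)
        bundle = AnnotationBundle(
            clinvar_class=row.get("clinvar_class") or "absent",
            sift=row.get("sift") or "absent",
            polyphen=row.get("polyphen") or "absent",
            cgi_driver=row.get("cgi_driver") or "absent",
            loftee_lof=row.get("loftee_lof") or "absent",
            gnomad_maf_all=float(row["gnomad_maf_all"]) if row.get("gnomad_maf_all") not in (None, "", "NA") else None,
            gnomad_maf_afr=float(row["gnomad_maf_afr"]) if row.get("gnomad_maf_afr") not in (None, "", "NA") else None,
        )
        if key in keyed and keyed[key] != bundle:
            conflicts.append(key)
        keyed[key] = bundle
    if conflicts:
        raise ContractViolation(
            f"conflicting annotation rows for keys: {sorted(set(conflicts))}"
        )
    out = {}
    unmatched = []
    for v in variants:
        bundle = keyed.get(v.key)
        if bundle is None:
            bundle = AnnotationBundle()
            unmatched.append(v.key)
        out[v.key] = bundle
    if unmatched:
        log.info("%d variant(s) without annotation received all-absent bundles", len(unmatched))
    return out


def read_clinical_table(path: str | Path) -> list[PatientRecord]:
    df = pd.read_csv(Path(path), sep="\t", dtype=str, keep_default_na=False)

    def opt(value: str, cast):
        return cast(value) if value not in ("", "NA") else None

    def opt_bool(value: str) -> Optional[bool]:
        if value in ("", "NA"):
            return None
        return value in ("True", "true", "1")

    patients = []
    for idx, row in enumerate(df.itertuples(index=False), start=2):
        try:
            patients.append(
                PatientRecord(
                    patient_id=row.patient_id,
                    cohort=row.cohort,
                    role=row.role,
                    age_years=opt(row.age_years, float),
                    psa_ng_ml=opt(row.psa_ng_ml, float),
                    isup_gg=opt(row.isup_gg, lambda x: int(float(x))),
                    fh_prostate=opt_bool(row.fh_prostate),
                    fh_breast_ovarian=opt_bool(row.fh_breast_ovarian),
                    african_fraction=opt(row.african_fraction, float),
                    tumor_available=str(row.tumor_available) in ("True", "true", "1"),
                )
            )
        except (ValueError, ContractViolation) as exc:
            raise ParseError(f"{path} line {idx}: {exc}") from exc
    return patients


def read_gene_lists(
    ddr_pca_path: str | Path,
    known_gt_path: str | Path,
    chip_path: Optional[str | Path] = None,
    chip_suspect_path: Optional[str | Path] = None,
) -> GeneLists:
    """Gene lists: one symbol per line; CHIP file is ``gene<TAB>rank``."""
    def read_symbols(p) -> frozenset[str]:
        return frozenset(
            line.strip().upper()
            for line in Path(p).read_text().splitlines()
            if line.strip() and not line.startswith("#")
        )

    chip: dict[str, int] = {}
    if chip_path is not None:
        for line_no, line in enumerate(Path(chip_path).read_text().splitlines(), start=1):
            if not line.strip() or line.startswith("#"):
                continue
            try:
                gene, rank = line.split("\t")
                chip[gene.strip().upper()] = int(rank)
            except ValueError as exc:
                raise ParseError(f"{chip_path} line {line_no}: {exc}") from exc
    return GeneLists(
        ddr_pca_genes=read_symbols(ddr_pca_path),
        known_gt_genes=read_symbols(known_gt_path),
        chip_genes=chip,
        chip_suspect_genes=read_symbols(chip_suspect_path) if chip_suspect_path else frozenset(),
    )


def read_somatic_profiles(
    snv_path: Optional[str | Path] = None,
    cn_path: Optional[str | Path] = None,
    label_path: Optional[str | Path] = None,
) -> dict[str, SomaticProfile]:
    """Assemble per-patient somatic profiles from TSV inputs.

    ``snv_path`` columns: patient_id, chrom, pos, ref, alt, gene,
    allelic_fraction, protein_altering.  ``cn_path`` columns:
    patient_id, chrom, start, end, loss (half-open [start, end)).
    ``label_path`` columns: patient_id, msi_status, signatures
    (comma-separated), n_background_mutations.
    """
    snvs: dict[str, list[SomaticVariant]] = {}
    if snv_path is not None:
        df = pd.read_csv(Path(snv_path), sep="\t", dtype=str, keep_default_na=False)
        for row in df.itertuples(index=False):
            af = float(row.allelic_fraction) if row.allelic_fraction not in ("", "NA") else None
            if af is not None and not 0.0 <= af <= 1.0:
                raise ContractViolation(f"allelic fraction {af} outside [0, 1]")
            snvs.setdefault(row.patient_id, []).append(
                SomaticVariant(
                    chrom=row.chrom,
                    pos=int(row.pos),
                    ref=row.ref,
                    alt=row.alt,
                    gene=row.gene or None,
                    allelic_fraction=af,
                    protein_altering=str(row.protein_altering) in ("True", "true", "1"),
                )
            )
    segments: dict[str, list[CnSegment]] = {}
    if cn_path is not None:
        df = pd.read_csv(Path(cn_path), sep="\t", dtype=str, keep_default_na=False)
        for row in df.itertuples(index=False):
            segments.setdefault(row.patient_id, []).append(
                CnSegment(
                    chrom=row.chrom,
                    start=int(row.start),
                    end=int(row.end),
                    loss=str(row.loss) in ("True", "true", "1"),
                )
            )
    labels: dict[str, dict] = {}
    if label_path is not None:
        df = pd.read_csv(Path(label_path), sep="\t", dtype=str, keep_default_na=False)
        for row in df.itertuples(index=False):
            labels[row.patient_id] = {
                "msi_status": row.msi_status or "unknown",
                "signature_labels": frozenset(
                    s for s in str(getattr(row, "signatures", "")).split(",") if s
                ),
                "n_background_mutations": int(getattr(row, "n_background_mutations", 0) or 0),
            }
    profiles = {}
    for pid in set(snvs) | set(segments) | set(labels):
        extra = labels.get(pid, {})
        profiles[pid] = SomaticProfile(
            patient_id=pid,
            somatic_snvs=tuple(snvs.get(pid, [])),
            cn_segments=tuple(segments.get(pid, [])),
            msi_status=extra.get("msi_status", "unknown"),
            signature_labels=extra.get("signature_labels", frozenset()),
            n_background_mutations=extra.get("n_background_mutations", 0),
        )
    return profiles


def format_maf(value: Optional[float]) -> str:
    """MAF printed to 4 decimals (table precision)."""
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return ""
    return f"{value:.4f}"


def format_vaf(value: Optional[float]) -> str:
    """VAF printed to 6 decimals (table precision)."""
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return ""
    return f"{value:.6f}"


def write_results(
    tables: Mapping[str, pd.DataFrame],
    run_summary: Mapping,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write every result table as TSV plus ``run_summary.json``.

    Numeric MAF/VAF columns are pre-formatted strings built by the
    pipeline, so output is deterministic and byte-stable across runs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = {}
    for name, df in tables.items():
        path = out / f"{name}.tsv"
        df.to_csv(path, sep="\t", index=False, lineterminator="\n")
        written[name] = path
    summary_path = out / "run_summary.json"
    summary_path.write_text(json.dumps(run_summary, indent=2, sort_keys=True) + "\n")
    written["run_summary"] = summary_path
    return written


def write_vcf(
    path: str | Path,
    variants: Sequence[GenomicVariant],
    calls: Iterable[GenotypeCall],
    sample_ids: Sequence[str],
) -> Path:
    """Write a minimal VCF v4.2 with GT/AD fields and gene-context INFO."""
    path = Path(path)
    by_sample: dict[tuple[str, str], GenotypeCall] = {
        (c.key, c.patient_id): c for c in calls
    }
    chrom_order = {c: i for i, c in enumerate(
        [f"chr{i}" for i in range(1, 23)] + ["chrX", "chrY", "chrM"])}
    ordered = sorted(variants, key=lambda v: (chrom_order[v.chrom], v.pos, v.ref, v.alt))
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=GENE,Number=1,Type=String,Description="HGNC symbol">\n')
        fh.write('##INFO=<ID=CSQ,Number=1,Type=String,Description="Consequence">\n')
        fh.write('##INFO=<ID=AA,Number=1,Type=String,Description="Protein change">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n')
        for c in chrom_order:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(sample_ids) + "\n")
        for v in ordered:
            info = ";".join(
                f"{tag}={val}"
                for tag, val in (("GENE", v.gene), ("CSQ", v.consequence), ("AA", v.aa_change))
                if val
            ) or "."
            cells = []
            for sid in sample_ids:
                call = by_sample.get((v.key, sid))
                if call is None:
                    cells.append("0/0:.,.")
                    continue
                if call.missing:
                    gt = "./."
                elif call.allele_count == 0:
                    gt = "0/0"
                elif call.allele_count == 1:
                    gt = "0/1"
                else:
                    gt = "1/1"
                if call.ref_reads is None and call.alt_reads is None:
                    ad = ".,."
                else:
                    ad = f"{call.ref_reads if call.ref_reads is not None else '.'}," \
                         f"{call.alt_reads if call.alt_reads is not None else '.'}"
                cells.append(f"{gt}:{ad}")
            fh.write(
                f"{v.chrom}\t{v.pos}\t{v.rsid or '.'}\t{v.ref}\t{v.alt}\t.\tPASS\t{info}\tGT:AD\t"
                + "\t".join(cells) + "\n"
            )
    return path
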