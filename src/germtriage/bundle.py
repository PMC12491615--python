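"""Input bundle: everything one pipeline run consumes, with file IO.

A bundle groups the case/control call sets, annotations, clinical
records, gene lists, optional tumor profiles and the comparison cohorts
(non-African cases, healthy aged controls) screened in the cross-cohort
step.  Bundles are built in memory by the synthetic generator or loaded
from a directory of the standard formats.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import variant_io
from .genes import default_gene_lists
from .tumor_evidence import SomaticProfile
from .types import AnnotationBundle, GeneLists, GenomicVariant, GenotypeCall, PatientRecord


@dataclass
class ComparisonCohort:
    """A non-African comparison call set screened for PPV burden."""

    name: str
    n_patients: int
    variants: list[GenomicVariant]
    calls: list[GenotypeCall]


@dataclass
class InputBundle:
    patients: list[PatientRecord]
    variants: list[GenomicVariant]
    calls: list[GenotypeCall]
    annotations: dict[str, AnnotationBundle]
    gene_lists: GeneLists
    somatic: dict[str, SomaticProfile] = field(default_factory=dict)
    comparison: dict[str, ComparisonCohort] = field(default_factory=dict)

    def cohort_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {}
        for p in self.patients:
            sizes[p.cohort] = sizes.get(p.cohort, 0) + 1
        return sizes

    def write(self, out_dir: str | Path) -> None:
        """Write the bundle as the standard on-disk formats."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        case_control = sorted(p.patient_id for p in self.patients)
        variant_io.write_vcf(out / "calls.vcf", self.variants, self.calls, case_control)

        rows = []
        for key, b in sorted(self.annotations.items()):
            chrom, pos, alleles = key.split(":")
            ref, alt = alleles.split("/")
            rows.append(
                {
                    "chrom": chrom, "pos": int(pos), "ref": ref, "alt": alt,
                    "clinvar_class": b.clinvar_class, "sift": b.sift,
                    "polyphen": b.polyphen, "cgi_driver": b.cgi_driver,
                    "loftee_lof": b.loftee_lof,
                    "gnomad_maf_all": "" if b.gnomad_maf_all is None else repr(b.gnomad_maf_all),
                    "gnomad_maf_afr": "" if b.gnomad_maf_afr is None else repr(b.gnomad_maf_afr),
                }
            )
        pd.DataFrame(rows, columns=variant_io.ANNOTATION_COLUMNS).to_csv(
            out / "annotations.tsv", sep="\t", index=False, lineterminator="\n"
        )

        clin = pd.DataFrame(
            [
                {
                    "patient_id": p.patient_id, "cohort": p.cohort, "role": p.role,
                    "age_years": "" if p.age_years is None else repr(p.age_years),
                    "psa_ng_ml": "" if p.psa_ng_ml is None else repr(p.psa_ng_ml),
                    "isup_gg": "" if p.isup_gg is None else p.isup_gg,
                    "fh_prostate": "" if p.fh_prostate is None else p.fh_prostate,
                    "fh_breast_ovarian": "" if p.fh_breast_ovarian is None else p.fh_breast_ovarian,
                    "african_fraction": "" if p.african_fraction is None else repr(p.african_fraction),
                    "tumor_available": p.tumor_available,
                }
                for p in sorted(self.patients, key=lambda p: p.patient_id)
            ],
            columns=variant_io.CLINICAL_COLUMNS,
        )
        clin.to_csv(out / "clinical.tsv", sep="\t", index=False, lineterminator="\n")

        gl = self.gene_lists
        (out / "genes_ddr.txt").write_text("\n".join(sorted(gl.ddr_pca_genes)) + "\n")
        (out / "genes_gt.txt").write_text("\n".join(sorted(gl.known_gt_genes)) + "\n")
        (out / "genes_chip.tsv").write_text(
            "".join(f"{g}\t{r}\n" for g, r in sorted(gl.chip_genes.items()))
        )
        (out / "genes_chip_suspect.txt").write_text(
            "\n".join(sorted(gl.chip_suspect_genes)) + "\n"
        )

        snv_rows, cn_rows, label_rows = [], [], []
        for pid, prof in sorted(self.somatic.items()):
            for sv in prof.somatic_snvs:
                snv_rows.append(
                    {
                        "patient_id": pid, "chrom": sv.chrom, "pos": sv.pos,
                        "ref": sv.ref, "alt": sv.alt, "gene": sv.gene or "",
                        "allelic_fraction": "" if sv.allelic_fraction is None else repr(sv.allelic_fraction),
                        "protein_altering": sv.protein_altering,
                    }
                )
            for seg in prof.cn_segments:
                cn_rows.append(
                    {
                        "patient_id": pid, "chrom": seg.chrom, "start": seg.start,
                        "end": seg.end, "loss": seg.loss,
                    }
                )
            label_rows.append(
                {
                    "patient_id": pid, "msi_status": prof.msi_status,
                    "signatures": ",".join(sorted(prof.signature_labels)),
                    "n_background_mutations": prof.n_background_mutations,
                }
            )
        pd.DataFrame(
            snv_rows,
            columns=["patient_id", "chrom", "pos", "ref", "alt", "gene",
                     "allelic_fraction", "protein_altering"],
        ).to_csv(out / "somatic_snvs.tsv", sep="\t", index=False, lineterminator="\n")
        pd.DataFrame(
            cn_rows, columns=["patient_id", "chrom", "start", "end", "loss"]
        ).to_csv(out / "somatic_cn.tsv", sep="\t", index=False, lineterminator="\n")
        pd.DataFrame(
            label_rows, columns=["patient_id", "msi_status", "signatures",
                                 "n_background_mutations"]
        ).to_csv(out / "somatic_labels.tsv", sep="\t", index=False, lineterminator="\n")

        for name, comp in sorted(self.comparison.items()):
            samples = sorted({c.patient_id for c in comp.calls})
            variant_io.write_vcf(out / f"comparison_{name}.vcf", comp.variants, comp.calls, samples)
            (out / f"comparison_{name}.n").write_text(str(comp.n_patients) + "\n")


def load_bundle(in_dir: str | Path) -> InputBundle:
    """Load a bundle previously written with :meth:`InputBundle.write`."""
    d = Path(in_dir)
    variants, calls = variant_io.read_variants(d / "calls.vcf")
    calls = [c for c in calls if c.allele_count > 0 or c.missing]
    patients = variant_io.read_clinical_table(d / "clinical.tsv")
    gene_lists = (
        variant_io.read_gene_lists(
            d / "genes_ddr.txt", d / "genes_gt.txt",
            d / "genes_chip.tsv" if (d / "genes_chip.tsv").exists() else None,
            d / "genes_chip_suspect.txt" if (d / "genes_chip_suspect.txt").exists() else None,
        )
        if (d / "genes_ddr.txt").exists()
        else default_gene_lists()
    )
    ann_table = variant_io.read_annotation_table(d / "annotations.tsv")
    somatic = variant_io.read_somatic_profiles(
        d / "somatic_snvs.tsv" if (d / "somatic_snvs.tsv").exists() else None,
        d / "somatic_cn.tsv" if (d / "somatic_cn.tsv").exists() else None,
        d / "somatic_labels.tsv" if (d / "somatic_labels.tsv").exists() else None,
    )
    comparison = {}
    for vcf_path in sorted(d.glob("comparison_*.vcf")):
        name = vcf_path.stem.removeprefix("comparison_")
        cvars, ccalls = variant_io.read_variants(vcf_path)
        ccalls = [c for c in ccalls if c.allele_count > 0]
        n = int((d / f"comparison_{name}.n").read_text().strip())
        comparison[name] = ComparisonCohort(name, n, cvars, ccalls)
    all_variants = list(variants)
    for comp in comparison.values():
        known = {v.key for v in all_variants}
        all_variants.extend(v for v in comp.variants if v.key not in known)
    annotations = variant_io.join_annotations(all_variants, ann_table)
    return InputBundle(
        patients=patients,
        variants=variants,
        calls=calls,
        annotations=annotations,
        gene_lists=gene_lists,
        somatic=somatic,
        comparison=comparison,
    )
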