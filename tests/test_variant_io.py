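"""VCF/TSV parsing, allele normalization, annotation joins, round trips."""
import textwrap

import pandas as pd
import pytest

from germtriage import variant_io
from germtriage.errors import ContractViolation
from germtriage.types import AnnotationBundle, GenomicVariant

VCF_HEADER = textwrap.dedent(
    """\
    ##fileformat=VCFv4.2
    ##INFO=<ID=GENE,Number=1,Type=String,Description="HGNC symbol">
    ##INFO=<ID=CSQ,Number=1,Type=String,Description="Consequence">
    ##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
    ##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
    ##contig=<ID=chr13>
    ##contig=<ID=chr1>
    """
)


def write_vcf(tmp_path, body, name="test.vcf"):
    path = tmp_path / name
    path.write_text(VCF_HEADER + body)
    return path


class TestReadVcf:
    def test_het_call_with_depths(self, tmp_path):
        path = write_vcf(
            tmp_path,
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\n"
            "chr13\t32319100\trs80359182\tT\tC\t.\tPASS\tGENE=BRCA2;CSQ=missense\t"
            "GT:AD\t0/1:23,18\n",
        )
        variants, calls = variant_io.read_variants(path)
        assert len(variants) == 1 and len(calls) == 1
        assert variants[0].key == "chr13:32319100:T/C"
        assert variants[0].gene == "BRCA2"
        assert calls[0].allele_count == 1
        assert (calls[0].ref_reads, calls[0].alt_reads) == (23, 18)

    def test_missing_genotype_flagged(self, tmp_path):
        path = write_vcf(
            tmp_path,
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\n"
            "chr13\t32319100\t.\tT\tC\t.\tPASS\t.\tGT\t./.\n",
        )
        _, calls = variant_io.read_variants(path)
        assert calls[0].allele_count == 0 and calls[0].missing

    def test_multiallelic_split_matches_hand_split_file(self, tmp_path):
        multi = write_vcf(
            tmp_path,
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\n"
            "chr1\t1000\t.\tT\tA,G\t.\tPASS\t.\tGT\t0/1\t0/2\n",
            "multi.vcf",
        )
        split = write_vcf(
            tmp_path,
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\n"
            "chr1\t1000\t.\tT\tA\t.\tPASS\t.\tGT\t0/1\t0/0\n"
            "chr1\t1000\t.\tT\tG\t.\tPASS\t.\tGT\t0/0\t0/1\n",
            "split.vcf",
        )
        v_multi, c_multi = variant_io.read_variants(multi)
        v_split, c_split = variant_io.read_variants(split)
        assert [v.key for v in v_multi] == [v.key for v in v_split]
        carriers = lambda calls: sorted(  # noqa: E731
            (c.key, c.patient_id, c.allele_count) for c in calls if c.allele_count
        )
        assert carriers(c_multi) == carriers(c_split)

    def test_non_grch38_contig_rejected(self, tmp_path):
        path = tmp_path / "bad.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n##contig=<ID=13>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
            "13\t32319100\t.\tT\tC\t.\tPASS\t.\n"
        )
        with pytest.raises(ContractViolation):
            variant_io.read_variants(path)


class TestNormalization:
    @pytest.mark.parametrize(
        "pos, ref, alt, expected",
        [
            (100, "AT", "GT", (100, "A", "G")),  # shared suffix trimmed
            (100, "CAG", "C", (100, "CAG", "C")),  # already parsimonious
            (100, "CAGAG", "CAG", (100, "CAG", "C")),  # suffix trimmed twice
            (100, "TCAG", "TC", (101, "CAG", "C")),  # prefix advances pos
            (100, "A", "G", (100, "A", "G")),
        ],
    )
    def test_trimming(self, pos, ref, alt, expected):
        assert variant_io.normalize_alleles(pos, ref, alt) == expected

    def test_idempotent(self):
        once = variant_io.normalize_alleles(100, "CAGAG", "CAG")
        assert variant_io.normalize_alleles(*once) == once


class TestJoinAnnotations:
    def _table(self, rows):
        return pd.DataFrame(rows, columns=variant_io.ANNOTATION_COLUMNS).astype(str)

    def test_matched_and_unmatched(self):
        v1 = GenomicVariant("chr13", 32319100, "T", "C", gene="BRCA2")
        v2 = GenomicVariant("chr1", 500, "A", "G", gene="ATM")
        table = self._table(
            [["chr13", 32319100, "T", "C", "pathogenic", "absent", "absent",
              "absent", "absent", "0.0002", "0.0009"]]
        )
        bundles = variant_io.join_annotations([v1, v2], table)
        assert bundles[v1.key].clinvar_class == "pathogenic"
        assert bundles[v1.key].gnomad_maf_all == pytest.approx(0.0002)
        assert bundles[v2.key] == AnnotationBundle()  # all-absent fallback

    def test_identical_duplicate_rows_deduplicate(self):
        v = GenomicVariant("chr13", 32319100, "T", "C")
        row = ["chr13", 32319100, "T", "C", "pathogenic", "absent", "absent",
               "absent", "absent", "", ""]
        bundles = variant_io.join_annotations([v], self._table([row, row]))
        assert bundles[v.key].clinvar_class == "pathogenic"

    def test_conflicting_duplicates_raise(self):
        v = GenomicVariant("chr13", 32319100, "T", "C")
        rows = [
            ["chr13", 32319100, "T", "C", "pathogenic", "absent", "absent",
             "absent", "absent", "", ""],
            ["chr13", 32319100, "T", "C", "benign", "absent", "absent",
             "absent", "absent", "", ""],
        ]
        with pytest.raises(ContractViolation):
            variant_io.join_annotations([v], self._table(rows))


class TestWriteResults:
    def test_round_trip_is_byte_stable(self, tmp_path):
        df = pd.DataFrame(
            {"gene": ["BRCA2"], "maf_sapcs": [variant_io.format_maf(6 / 372)],
             "vaf": [variant_io.format_vaf(9 / 43)]}
        )
        first = tmp_path / "a"
        second = tmp_path / "b"
        variant_io.write_results({"ppv": df}, {"seed": 1}, first)
        again = pd.read_csv(first / "ppv.tsv", sep="\t", dtype=str)
        variant_io.write_results({"ppv": again}, {"seed": 1}, second)
        assert (first / "ppv.tsv").read_bytes() == (second / "ppv.tsv").read_bytes()

    def test_empty_tables_write_headers(self, tmp_path):
        df = pd.DataFrame(columns=["key", "gene", "reason"])
        paths = variant_io.write_results({"excluded": df}, {}, tmp_path / "out")
        content = paths["excluded"].read_text()
        assert content == "key\tgene\treason\n"

    def test_vcf_write_read_round_trip(self, tmp_path, synthetic):
        bundle = synthetic.bundle
        samples = sorted(p.patient_id for p in bundle.patients)
        path = variant_io.write_vcf(
            tmp_path / "rt.vcf", bundle.variants, bundle.calls, samples
        )
        variants, calls = variant_io.read_variants(path)
        assert {v.key for v in variants} == {v.key for v in bundle.variants}
        original = {
            (c.patient_id, c.key): c.allele_count
            for c in bundle.calls if c.allele_count
        }
        reread = {
            (c.patient_id, c.key): c.allele_count for c in calls if c.allele_count
        }
        assert original == reread
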