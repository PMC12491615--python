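"""PPV/POV/PSLF class rules: worked cases, truth table, monotonicity."""
import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from germtriage.classification import (
    classify_pov,
    classify_ppv,
    classify_variant,
    restrict_gene_set,
)
from germtriage.errors import ConfigError
from germtriage.frequency import CohortFrequency, tier_gnomad
from germtriage.types import AnnotationBundle, GeneLists, GenomicVariant


def freq(cohort, n, het, hom=0):
    return CohortFrequency(cohort, n, het, hom)


class TestClassifyPpv:
    def test_globally_rare_but_frequent_in_cases_is_pslf(self):
        # rare in global databases (0.0002/0.0009) yet 5/186 case carriers
        bundle = AnnotationBundle(
            clinvar_class="pathogenic", gnomad_maf_all=0.0002, gnomad_maf_afr=0.0009
        )
        cls, reason = classify_ppv(
            bundle, tier_gnomad(bundle), [freq("SAPCS", 186, 5)]
        )
        assert (cls, reason) == ("PSLF_PPV", None)

    def test_database_absent_singleton_is_rare_ppv(self):
        bundle = AnnotationBundle(clinvar_class="likely_pathogenic")
        cls, _ = classify_ppv(bundle, tier_gnomad(bundle), [freq("SAPCS", 186, 1)])
        assert cls == "PPV"

    def test_common_in_gnomad_is_excluded(self):
        bundle = AnnotationBundle(clinvar_class="pathogenic", gnomad_maf_all=0.08)
        cls, reason = classify_ppv(bundle, tier_gnomad(bundle), [])
        assert (cls, reason) == ("excluded", "common_maf")

    def test_small_cohort_singleton_never_defines_pslf(self):
        # 1/62 alleles is 1.6% but a lone carrier stays in the rare class
        bundle = AnnotationBundle(clinvar_class="pathogenic", gnomad_maf_all=0.0001)
        cls, _ = classify_ppv(bundle, tier_gnomad(bundle), [freq("PPCG", 31, 1)])
        assert cls == "PPV"


class TestClassifyPov:
    def test_sift_deleterious_driver_frequent_in_cases_is_pslf_pov(self):
        bundle = AnnotationBundle(
            clinvar_class="vus", sift="deleterious", cgi_driver="driver",
            gnomad_maf_all=0.0004, gnomad_maf_afr=0.0014,
        )
        cls, _ = classify_pov(
            bundle, "missense", tier_gnomad(bundle), [freq("SAPCS", 186, 6)]
        )
        assert cls == "PSLF_POV"

    def test_no_functional_evidence_is_not_pov(self):
        bundle = AnnotationBundle(
            clinvar_class="vus", sift="tolerated", polyphen="benign", cgi_driver="driver"
        )
        cls, reason = classify_pov(bundle, "missense", tier_gnomad(bundle), [])
        assert (cls, reason) == ("excluded", "not_functional")

    def test_rule_truth_table_against_brute_enumeration(self):
        """Enumerate every evidence combination and compare with a direct
        re-reading of the rule: functional AND driver AND not-common,
        POV when rare, exclusion otherwise."""
        sifts = ["deleterious", "tolerated", "absent"]
        polyphens = ["damaging", "benign", "absent"]
        cgis = ["driver", "passenger", "absent"]
        consequences = ["missense", "stop_gain", "splice_disrupting", "frameshift"]
        loftees = ["lof", "absent"]
        gnomads = [None, 0.004, 0.02, 0.08]
        for sift, poly, cgi, csq, lof, g in itertools.product(
            sifts, polyphens, cgis, consequences, loftees, gnomads
        ):
            bundle = AnnotationBundle(
                clinvar_class="vus", sift=sift, polyphen=poly, cgi_driver=cgi,
                loftee_lof=lof, gnomad_maf_all=g,
            )
            cls, _ = classify_pov(bundle, csq, tier_gnomad(bundle), [])
            functional = (
                sift == "deleterious" or poly == "damaging"
                or csq in ("stop_gain", "splice_disrupting")
                or (csq == "frameshift" and lof == "lof")
            )
            expected = (
                "POV"
                if functional and cgi == "driver" and (g is None or g < 0.01)
                else "excluded"
            )
            assert cls == expected, (sift, poly, cgi, csq, lof, g)

    def test_cgi_requirement_is_configurable(self):
        bundle = AnnotationBundle(clinvar_class="vus", sift="deleterious",
                                  cgi_driver="passenger", gnomad_maf_all=0.001)
        cls, _ = classify_pov(bundle, "missense", tier_gnomad(bundle), [],
                              require_cgi_driver=False)
        assert cls == "POV"


def make_variant(gene="BRCA2", consequence="missense"):
    return GenomicVariant("chr13", 32319100, "T", "C", gene=gene,
                          consequence=consequence)


class TestDispatchAndGeneSet:
    def test_benign_clinvar_excluded_outright(self):
        cv = classify_variant(
            make_variant(), AnnotationBundle(clinvar_class="benign"),
            tier_gnomad(AnnotationBundle()), [],
        )
        assert cv.cls == "excluded" and cv.exclusion_reason == "benign_clinvar"

    def test_class_labels_partition(self):
        bundle = AnnotationBundle(clinvar_class="pathogenic")
        cv = classify_variant(make_variant(), bundle, tier_gnomad(bundle), [])
        assert cv.cls in ("PPV", "POV", "PSLF_PPV", "PSLF_POV", "excluded")
        assert (cv.cls == "excluded") == (cv.exclusion_reason is not None)

    def test_case_insensitive_gene_symbols(self, gene_lists):
        bundle = AnnotationBundle(clinvar_class="pathogenic")
        cv = classify_variant(make_variant(gene="Brca2"), bundle,
                              tier_gnomad(bundle), [])
        restricted = restrict_gene_set([cv], gene_lists)[0]
        assert restricted.cls == "PPV" and restricted.in_known_gt_panel

    def test_gene_outside_candidate_universe_excluded(self, gene_lists):
        bundle = AnnotationBundle(clinvar_class="pathogenic")
        cv = classify_variant(make_variant(gene="TTN"), bundle, tier_gnomad(bundle), [])
        restricted = restrict_gene_set([cv], gene_lists)[0]
        assert restricted.cls == "excluded"
        assert restricted.exclusion_reason == "gene_set"

    def test_empty_gene_list_is_a_configuration_error(self):
        with pytest.raises((ConfigError, Exception)):
            restrict_gene_set([], GeneLists(frozenset(), frozenset()))

    @given(
        clinvar=st.sampled_from(["pathogenic", "likely_pathogenic", "vus", "absent"]),
        sift=st.sampled_from(["deleterious", "tolerated", "absent"]),
        cgi=st.sampled_from(["driver", "passenger", "absent"]),
        gnomad=st.one_of(st.none(), st.floats(0, 0.2)),
    )
    @settings(max_examples=200, deadline=None)
    def test_weakening_evidence_never_promotes(self, clinvar, sift, cgi, gnomad):
        """P/LP -> VUS, driver -> passenger, deleterious -> tolerated must
        never move a variant from excluded toward a candidate class."""
        strength = {"excluded": 0, "POV": 1, "PSLF_POV": 1, "PPV": 2, "PSLF_PPV": 2}
        weaker = {
            "pathogenic": "vus", "likely_pathogenic": "vus",
            "vus": "vus", "absent": "absent",
        }
        bundle = AnnotationBundle(clinvar_class=clinvar, sift=sift,
                                  cgi_driver=cgi, gnomad_maf_all=gnomad)
        weak = AnnotationBundle(
            clinvar_class=weaker[clinvar],
            sift="tolerated" if sift == "deleterious" else sift,
            cgi_driver="passenger" if cgi == "driver" else cgi,
            gnomad_maf_all=gnomad,
        )
        v = make_variant()
        before = classify_variant(v, bundle, tier_gnomad(bundle), [])
        after = classify_variant(v, weak, tier_gnomad(weak), [])
        assert strength[after.cls] <= strength[before.cls]
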