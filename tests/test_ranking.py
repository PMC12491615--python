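"""9-step carrier scoring, variant/gene aggregation and prevalence."""
import numpy as np
import pytest

from _oracles import random_carrier_case, score_case_with_oracle, score_case_with_pipeline
from germtriage.chip_filter import ChipDecision
from germtriage.classification import ClassifiedVariant
from germtriage.errors import ConfigError, UndefinedFrequencyError
from germtriage.frequency import FrequencyTier
from germtriage.ranking import (
    GeneSummary,
    prevalence,
    rank_genes,
    rank_variant,
    score_carrier,
)
from germtriage.tumor_evidence import TumorEvidence
from germtriage.types import GenomicVariant, PatientRecord


def make_cv(cls="POV", gene="ATM", flags=frozenset()):
    v = GenomicVariant("chr11", 108345818, "C", "T", gene=gene,
                       consequence="missense")
    return ClassifiedVariant(variant=v, cls=cls, rarity=FrequencyTier("rare"),
                             functional_flags=flags)


def make_chip(cv, pid="P1", in_chip=False):
    return ChipDecision(cv.key, pid, 0.5, in_chip, "retain",
                        -0.5 if in_chip else 0.0)


def make_patient(pid="P1", cohort="SAPCS", **kw):
    defaults = dict(age_years=67.0, psa_ng_ml=40.0, isup_gg=2,
                    fh_prostate=False, fh_breast_ovarian=False,
                    tumor_available=True)
    defaults.update(kw)
    return PatientRecord(patient_id=pid, cohort=cohort, role="case", **defaults)


def make_tumor(cv, pid="P1", loh=False, second=False, available=True):
    return TumorEvidence(cv.key, pid, loh, second, available)


class TestScoreCarrier:
    def test_all_zero_case(self):
        cv = make_cv("POV")
        score = score_carrier(cv, make_chip(cv), make_patient(),
                              make_tumor(cv), sac_maf=0.015, eac_maf=0.015)
        assert score.total == 0.0

    def test_maximal_hand_sum(self):
        # PPV + controls clean + pLoF + 12y younger + ISUP5 + PSA200 + FH + LOH
        cv = make_cv("PPV", flags=frozenset({"plof"}))
        patient = make_patient(age_years=55.0, isup_gg=5, psa_ng_ml=200.0,
                               fh_prostate=True)
        score = score_carrier(cv, make_chip(cv), patient,
                              make_tumor(cv, loh=True), sac_maf=0.0, eac_maf=0.0)
        assert score.total == 9.0

    def test_retained_chip_gene_with_missing_tumor(self):
        cv = make_cv("POV", gene="JAK2")
        patient = make_patient(tumor_available=False)
        score = score_carrier(cv, make_chip(cv, in_chip=True), patient,
                              None, sac_maf=0.0, eac_maf=0.0)
        assert score.total == pytest.approx(1.0)  # -0.5 + 1 + 0.5

    def test_unknown_cohort_with_age_is_an_error(self):
        cv = make_cv()
        patient = PatientRecord("P9", "SAC", "case", age_years=50.0)
        with pytest.raises(ConfigError):
            score_carrier(cv, make_chip(cv), patient, None)

    def test_missing_clinical_fields_contribute_zero(self):
        cv = make_cv("POV")
        patient = PatientRecord("P1", "SAPCS", "case", tumor_available=True)
        score = score_carrier(cv, make_chip(cv), patient, make_tumor(cv),
                              sac_maf=0.02, eac_maf=0.02)
        assert score.total == 0.0

    def test_family_history_bonuses_are_additive(self):
        cv = make_cv("POV")
        patient = make_patient(fh_prostate=True, fh_breast_ovarian=True)
        score = score_carrier(cv, make_chip(cv), patient, make_tumor(cv),
                              sac_maf=0.02, eac_maf=0.02)
        assert score.total == pytest.approx(1.5)

    def test_brute_force_oracle_equivalence(self):
        rng = np.random.default_rng(1)
        for _ in range(2000):
            case = random_carrier_case(rng)
            assert score_case_with_pipeline(case) == score_case_with_oracle(case)


class TestRankVariant:
    def test_single_carrier_identity(self):
        cv = make_cv()
        scores = [score_carrier(cv, make_chip(cv), make_patient(isup_gg=5),
                                make_tumor(cv), sac_maf=0.0, eac_maf=0.0)]
        assert rank_variant(cv, scores).variant_rank == scores[0].total

    def test_recurrence_weighted_sum(self):
        cv = make_cv()
        scores = [
            score_carrier(cv, make_chip(cv, pid=f"P{i}"),
                          make_patient(pid=f"P{i}", tumor_available=False), None,
                          sac_maf=0.0, eac_maf=0.0)
            for i in range(5)
        ]
        assert all(s.total == pytest.approx(1.5) for s in scores)
        vs = rank_variant(cv, scores)
        assert vs.variant_rank == pytest.approx(7.5)
        vs_mean = rank_variant(cv, scores, mode="mean")
        assert vs_mean.variant_rank == pytest.approx(1.5)

    def test_rank_readds_from_breakdown(self):
        cv = make_cv("PPV", flags=frozenset({"plof"}))
        scores = [
            score_carrier(cv, make_chip(cv, pid=f"P{i}"),
                          make_patient(pid=f"P{i}", age_years=50.0, isup_gg=4),
                          make_tumor(cv, pid=f"P{i}", second=True),
                          sac_maf=0.0, eac_maf=0.0)
            for i in range(3)
        ]
        vs = rank_variant(cv, scores)
        readded = sum(v for cs in vs.carrier_scores for _, v in cs.components)
        assert vs.variant_rank == pytest.approx(readded)


class TestRankGenes:
    def test_rare_and_pslf_strata_are_separate_rows(self):
        cv_rare = make_cv("POV", gene="POLQ")
        cv_pslf = make_cv("PSLF_POV", gene="POLQ")
        scores = [score_carrier(cv_rare, make_chip(cv_rare), make_patient(),
                                make_tumor(cv_rare), sac_maf=0.0, eac_maf=0.0)]
        pslf_scores = [score_carrier(cv_pslf, make_chip(cv_pslf), make_patient(),
                                     make_tumor(cv_pslf), sac_maf=0.0, eac_maf=0.0)]
        summaries = rank_genes(
            [rank_variant(cv_rare, scores), rank_variant(cv_pslf, pslf_scores)]
        )
        assert len(summaries) == 2
        assert all(s.gene == "POLQ" for s in summaries)
        assert {s.stratum for s in summaries} == {"rare", "PSLF"}

    def test_gene_weight_sums_variant_ranks(self):
        cvs = [make_cv("POV", gene="ATM"), make_cv("PPV", gene="ATM")]
        variant_scores = []
        for cv in cvs:
            cs = [score_carrier(cv, make_chip(cv), make_patient(tumor_available=False),
                                None, sac_maf=0.0, eac_maf=0.0)]
            variant_scores.append(rank_variant(cv, cs))
        summary = rank_genes(variant_scores)[0]
        assert summary.gene_weight == pytest.approx(
            sum(vs.variant_rank for vs in variant_scores)
        )
        assert summary.n_variants == 2

    def test_ties_break_deterministically(self):
        cvs = [make_cv("POV", gene=g) for g in ("ZZZ3", "ATM")]
        # same weight, same carriers: alphabetical gene order decides
        variant_scores = []
        for cv in cvs:
            cs = [score_carrier(cv, make_chip(cv), make_patient(tumor_available=False),
                                None, sac_maf=0.0, eac_maf=0.0)]
            variant_scores.append(rank_variant(cv, cs))
        genes = [s.gene for s in rank_genes(variant_scores)]
        assert genes == sorted(genes)


class TestPrevalence:
    def _patients(self, n, cohort="SAPCS", fraction=0.95):
        return [
            PatientRecord(f"{cohort}{i:04d}", cohort, "case",
                          african_fraction=fraction)
            for i in range(n)
        ]

    def test_multi_variant_carrier_counts_once(self):
        patients = self._patients(217)
        pairs = [("SAPCS0001", "RAD54L"), ("SAPCS0001", "PMS2"),
                 ("SAPCS0001", "FANCA")]
        n, d, pct = prevalence(pairs, patients, frozenset({"RAD54L", "PMS2", "FANCA"}))
        assert (n, d) == (1, 217)

    def test_duplicating_pairs_is_invariant(self):
        patients = self._patients(100)
        pairs = [("SAPCS0001", "ATM"), ("SAPCS0002", "ATM")]
        base = prevalence(pairs, patients)
        assert prevalence(pairs * 3, patients) == base

    def test_ancestry_floor_is_strict(self):
        patients = self._patients(50, fraction=0.9)
        with pytest.raises(UndefinedFrequencyError):
            prevalence([], patients, ancestry_floor=0.9)

    def test_controls_never_enter_denominator(self):
        patients = self._patients(10) + [
            PatientRecord("SAC0001", "SAC", "control")
        ]
        _, d, _ = prevalence([], patients)
        assert d == 10
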