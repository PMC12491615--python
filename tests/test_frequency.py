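"""Cohort MAF arithmetic, gnomAD tiering, control screen and VAF."""
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from germtriage.errors import ContractViolation, UndefinedFrequencyError
from germtriage.frequency import (
    CohortFrequency,
    cohort_maf,
    control_screen,
    pooled_maf,
    tier_gnomad,
    vaf,
)
from germtriage.types import AnnotationBundle


class TestCohortMaf:
    @pytest.mark.parametrize(
        "het, hom, n, expected",
        [
            (6, 0, 186, 0.0161),  # 6 het carriers among 186 cases
            (13, 1, 186, 0.0403),  # includes one homozygote: 15 alleles / 372
            (0, 0, 50, 0.0),
            (23, 0, 186, 0.0618),
            (2, 0, 31, 0.0323),
        ],
    )
    def test_diploid_counting(self, het, hom, n, expected):
        assert round(cohort_maf(het, hom, n), 4) == expected

    def test_empty_cohort_is_undefined(self):
        with pytest.raises(UndefinedFrequencyError):
            cohort_maf(0, 0, 0)

    def test_carriers_cannot_exceed_cohort(self):
        with pytest.raises(ContractViolation):
            cohort_maf(40, 20, 50)

    @given(het=st.integers(0, 20), hom=st.integers(0, 10), n=st.integers(30, 500),
           k=st.integers(2, 5))
    @settings(max_examples=100, deadline=None)
    def test_scale_consistency(self, het, hom, n, k):
        if het + hom > n:
            return
        assert cohort_maf(het, hom, n) == pytest.approx(cohort_maf(k * het, k * hom, k * n))


class TestPooledMaf:
    def test_pooling_printed_counts(self):
        sapcs = CohortFrequency("SAPCS", 186, 9, 0)
        ppcg = CohortFrequency("PPCG", 31, 1, 0)
        assert round(pooled_maf([sapcs, ppcg]), 4) == 0.0230

    def test_single_cohort_identity(self):
        f = CohortFrequency("SAC", 49, 3, 1)
        assert pooled_maf([f]) == f.maf

    def test_hand_arithmetic(self):
        sac = CohortFrequency("SAC", 49, 2, 0)
        eac = CohortFrequency("EAC", 40, 1, 0)
        assert pooled_maf([sac, eac]) == pytest.approx(3 / 178)

    def test_overlapping_cohorts_rejected(self):
        f = CohortFrequency("SAC", 49, 1, 0)
        with pytest.raises(ContractViolation):
            pooled_maf([f, f])

    @given(
        het1=st.integers(0, 10), het2=st.integers(0, 10),
        n1=st.integers(20, 300), n2=st.integers(20, 300),
    )
    @settings(max_examples=100, deadline=None)
    def test_pooled_between_min_and_max(self, het1, het2, n1, n2):
        a = CohortFrequency("SAC", n1, het1, 0)
        b = CohortFrequency("EAC", n2, het2, 0)
        pooled = pooled_maf([a, b])
        assert min(a.maf, b.maf) <= pooled <= max(a.maf, b.maf)


class TestGnomadTier:
    @pytest.mark.parametrize(
        "all_maf, afr_maf, tier",
        [
            (0.0002, 0.0009, "rare"),
            (0.0031, 0.0107, "low_frequency"),
            (None, None, "unknown"),
            (0.06, None, "common"),
            (0.01, 0.0001, "low_frequency"),  # boundary 1% leaves the rare tier
            (0.0099, None, "rare"),
        ],
    )
    def test_max_of_known_sources(self, all_maf, afr_maf, tier):
        bundle = AnnotationBundle(gnomad_maf_all=all_maf, gnomad_maf_afr=afr_maf)
        assert tier_gnomad(bundle).tier == tier

    @given(
        a=st.one_of(st.none(), st.floats(0, 1)),
        b=st.one_of(st.none(), st.floats(0, 1)),
        bump=st.floats(0, 0.5),
    )
    @settings(max_examples=150, deadline=None)
    def test_monotone_in_either_source(self, a, b, bump):
        order = {"unknown": 0, "rare": 0, "low_frequency": 1, "common": 2}
        before = tier_gnomad(AnnotationBundle(gnomad_maf_all=a, gnomad_maf_afr=b))
        bumped = min(1.0, (a or 0.0) + bump)
        after = tier_gnomad(AnnotationBundle(gnomad_maf_all=bumped, gnomad_maf_afr=b))
        assert order[after.tier] >= order[before.tier]


class TestControlScreen:
    def test_single_control_cohort_over_threshold_excludes(self):
        # 4 alleles in 43 east African control genomes: clearly over 2%
        eac = CohortFrequency("EAC", 43, 4, 0)
        decision = control_screen(None, eac)
        assert not decision.keep and decision.reason == "control_maf"

    def test_pooled_controls_over_threshold_exclude(self):
        sac = CohortFrequency("SAC", 49, 4, 0)
        eac = CohortFrequency("EAC", 40, 2, 0)
        assert pooled_maf([sac, eac]) > 0.02
        assert not control_screen(sac, eac).keep

    def test_absent_from_both_controls_keeps(self):
        sac = CohortFrequency("SAC", 49, 0, 0)
        eac = CohortFrequency("EAC", 40, 0, 0)
        assert control_screen(sac, eac).keep

    def test_borderline_single_cohort_kept_with_flag(self):
        # two SAC alleles (MAF 0.0204) exceed 2% by one allele; absent in EAC
        sac = CohortFrequency("SAC", 49, 2, 0)
        eac = CohortFrequency("EAC", 40, 0, 0)
        decision = control_screen(sac, eac)
        assert decision.keep and decision.borderline

    def test_borderline_needs_absence_in_other_cohort(self):
        # same SAC excess, but the variant is also seen in EAC: excluded
        sac = CohortFrequency("SAC", 49, 2, 0)
        eac = CohortFrequency("EAC", 40, 1, 0)
        decision = control_screen(sac, eac)
        assert not decision.keep and not decision.borderline


class TestVaf:
    @pytest.mark.parametrize(
        "ref, alt, expected",
        [
            (34, 9, 9 / 43),  # 0.209302...
            (10, 10, 0.5),
            (0, 7, 1.0),
            (None, None, None),
        ],
    )
    def test_read_fraction(self, ref, alt, expected):
        result = vaf(ref, alt)
        if expected is None:
            assert result is None
        else:
            assert result == pytest.approx(expected)

    def test_zero_depth_is_undetermined(self):
        assert vaf(0, 0) is None
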