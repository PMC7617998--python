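"""Pedigree eligibility, LOD scoring and the binomial evidence tests."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import binom

from modyburden import (
    CosegConfig,
    Individual,
    Pedigree,
    combined_lod,
    coseg_tests,
    cosegregation_count,
    lod_score,
    pedigree_eligible,
    two_sided_binomial,
)

from conftest import binomial_minlike_oracle, lod_enumeration_oracle


class TestTwoSidedBinomial:
    @pytest.mark.parametrize(
        "k,n,p0,printed",
        [
            (20, 22, 0.5, 0.0001),  # strong co-segregation
            (11, 12, 0.5, 0.006),
            (8, 9, 0.5, 0.04),
            (7, 7, 0.5, 0.02),
            (8, 23, 0.1, 0.001),    # excess adult non-penetrant carriers
            (4, 15, 0.1, 0.06),
            (3, 18, 0.1, 0.4),
            (2, 9, 0.1, 0.2),
            (3, 13, 0.1, 0.1),
            (0, 4, 0.1, 1.0),       # most probable outcome
        ],
    )
    def test_reference_values_at_printed_precision(self, k, n, p0, printed):
        p = two_sided_binomial(k, n, p0)
        assert float(f"{p:.0e}") == pytest.approx(printed)

    def test_exact_value(self):
        assert two_sided_binomial(20, 22, 0.5) == pytest.approx(
            1.2111663818359375e-4
        )

    def test_asymmetric_null_includes_lower_tail(self):
        # against p0=0.1, k=3/18 must gather lower-tail outcomes too
        p = two_sided_binomial(3, 18, 0.1)
        upper_only = float(binom.sf(2, 18, 0.1))
        assert p > upper_only
        assert p == pytest.approx(0.4163, abs=2e-4)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(n=st.integers(1, 50), k_frac=st.floats(0, 1))
    def test_symmetric_null_equals_doubled_tail(self, n, k_frac):
        """For p0=0.5 the minimum-likelihood p equals min(1, twice the
        smaller tail), by symmetry of the pmf."""
        k = min(n, int(round(k_frac * n)))
        p = two_sided_binomial(k, n, 0.5)
        tail = min(binom.cdf(k, n, 0.5), binom.sf(k - 1, n, 0.5))
        assert p == pytest.approx(min(1.0, 2 * tail), rel=1e-9)

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(
        n=st.integers(1, 40),
        k_frac=st.floats(0, 1),
        p0=st.sampled_from([0.1, 0.3, 0.5, 0.9]),
    )
    def test_matches_enumeration_oracle(self, n, k_frac, p0):
        k = min(n, int(round(k_frac * n)))
        assert two_sided_binomial(k, n, p0) == pytest.approx(
            binomial_minlike_oracle(k, n, p0), rel=1e-9
        )

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            two_sided_binomial(5, 4, 0.5)
        with pytest.raises(ValueError):
            two_sided_binomial(1, 4, 0.0)


class TestLod:
    def test_four_consistent_meioses(self, nuclear_coseg_pedigree):
        assert lod_score(nuclear_coseg_pedigree) == pytest.approx(
            4 * math.log10(2), rel=1e-12
        )

    def test_no_genotyped_nonfounders_scores_zero(self):
        ped = Pedigree(
            "P",
            [
                Individual(id="F", genotype="carrier", affected="yes"),
                Individual(id="M", genotype="non_carrier", affected="no"),
                Individual(id="C", father_id="F", mother_id="M"),
            ],
        )
        assert lod_score(ped) == 0.0

    def test_three_generation_with_inconsistency(self, three_generation_pedigree):
        # 10 informative meioses, one discordant: maximized two-point LOD
        expected = 9 * math.log10(1.8) + math.log10(0.2)
        assert lod_score(three_generation_pedigree) == pytest.approx(
            expected, rel=1e-9
        )

    def test_matches_transmission_enumeration_oracle(
        self, nuclear_coseg_pedigree, three_generation_pedigree
    ):
        for ped in (nuclear_coseg_pedigree, three_generation_pedigree):
            assert lod_score(ped) == pytest.approx(
                lod_enumeration_oracle(ped), abs=2e-4
            )

    def test_oracle_agreement_with_unknown_affection_member(self):
        """A genotyped child of unknown affection is uninformative for both
        the counting rule and the enumeration oracle."""
        members = [
            Individual(id="F", genotype="carrier", affected="yes", sex="male"),
            Individual(id="M", genotype="non_carrier", affected="no",
                       sex="female"),
            Individual(id="C1", father_id="F", mother_id="M",
                       genotype="carrier", affected="yes"),
            Individual(id="C2", father_id="F", mother_id="M",
                       genotype="carrier", affected="unknown"),
            Individual(id="C3", father_id="F", mother_id="M",
                       genotype="non_carrier", affected="no"),
        ]
        ped = Pedigree("U", members)
        assert lod_score(ped) == pytest.approx(2 * math.log10(2))
        assert lod_score(ped) == pytest.approx(
            lod_enumeration_oracle(ped), abs=2e-4
        )

    def test_cyclic_pedigree_rejected(self):
        with pytest.raises(ValueError):
            Pedigree(
                "C",
                [
                    Individual(id="A", father_id="B"),
                    Individual(id="B", father_id="A"),
                ],
            )

    def test_combined_lod_additive_and_permutation_invariant(self):
        assert combined_lod([1.2, 2.1]) == pytest.approx(3.3)
        assert combined_lod([]) == 0.0
        assert combined_lod([2.7, 2.7, 2.7]) == pytest.approx(8.1)
        assert combined_lod([0.5, 1.5, 2.0]) == combined_lod([2.0, 0.5, 1.5])


class TestEligibility:
    def test_requires_four_cosegregations(self, nuclear_coseg_pedigree):
        cfg = CosegConfig()
        assert cosegregation_count(nuclear_coseg_pedigree) == 4
        assert pedigree_eligible(nuclear_coseg_pedigree, 0.0, cfg)
        small = Pedigree(
            "S", nuclear_coseg_pedigree.individuals[:5]
        )  # only 3 informative children
        assert cosegregation_count(small) == 3
        assert not pedigree_eligible(small, 0.0, cfg)

    def test_frequency_cap_strict(self, nuclear_coseg_pedigree):
        cfg = CosegConfig()
        assert not pedigree_eligible(nuclear_coseg_pedigree, 1 / 1000, cfg)
        assert not pedigree_eligible(nuclear_coseg_pedigree, 1 / 1500, cfg)
        assert pedigree_eligible(nuclear_coseg_pedigree, 1 / 2000, cfg)


class TestCosegTests:
    def test_proportions_and_age_gate(self, three_generation_pedigree):
        res = coseg_tests(three_generation_pedigree)
        # affected genotyped: F, C1, C2, C5, G1, G3, G5 -> 7; carriers 6
        assert (res.n_affected_carriers, res.n_affected_genotyped) == (6, 7)
        assert res.coseg_p == pytest.approx(
            two_sided_binomial(6, 7, 0.5)
        )
        # unaffected >= 25: M, C3, C4, S1, S2, G2, G4 -> 7, none carriers
        assert (res.n_unaffected_carriers_age_ok,
                res.n_unaffected_genotyped_age_ok) == (0, 7)

    def test_young_carrier_excluded_from_nonpenetrance(self):
        members = [
            Individual(id="F", genotype="carrier", affected="yes", sex="male"),
            Individual(id="M", genotype="non_carrier", affected="no",
                       age=50, sex="female"),
            Individual(id="C1", father_id="F", mother_id="M",
                       genotype="carrier", affected="no", age=20),
            Individual(id="C2", father_id="F", mother_id="M",
                       genotype="carrier", affected="no", age=30),
            Individual(id="C3", father_id="F", mother_id="M",
                       genotype="non_carrier", affected="no", age=None),
        ]
        res = coseg_tests(Pedigree("A", members))
        # C1 is under 25 and C3 has no certified age: both excluded
        assert res.n_unaffected_genotyped_age_ok == 2  # M and C2
        assert res.n_unaffected_carriers_age_ok == 1

    def test_unknowns_excluded_from_denominators(self):
        members = [
            Individual(id="F", genotype="carrier", affected="yes", sex="male"),
            Individual(id="M", genotype="unknown", affected="yes", age=60,
                       sex="female"),
            Individual(id="C", father_id="F", mother_id="M",
                       genotype="carrier", affected="unknown", age=40),
        ]
        res = coseg_tests(Pedigree("B", members))
        assert res.n_affected_genotyped == 1  # only F

    def test_zero_denominator_yields_none(self, caplog):
        members = [
            Individual(id="F", genotype="carrier", affected="yes", sex="male"),
            Individual(id="M", genotype="non_carrier", affected="yes",
                       sex="female"),
        ]
        with caplog.at_level("WARNING", logger="modyburden"):
            res = coseg_tests(Pedigree("Z", members))
        assert res.nonpenetrance_p is None
        assert res.coseg_p is not None
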