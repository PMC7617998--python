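"""Qualifying-variant selection, carrier collapsing and the Fisher burden
test with its sensitivity grid."""

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from modyburden import (
    BurdenConfig,
    CohortGenotypes,
    StudyData,
    VariantClass,
    VariantRecord,
    count_carriers,
    fisher_burden,
    run_suite,
    select_qualifying,
)
from modyburden.burden import (
    control_allele_frequencies,
    primary_grid,
    reference_allele_frequencies,
    results_to_frame,
    sensitivity_grid,
)
from modyburden.pipeline import build_grid, qc_study
from modyburden.synthetic_data import (
    default_study_config,
    simulate_cohorts,
    simulate_gene_models,
)

from conftest import fisher_minlike_oracle


def ptv(pos, gene="G3", chrom="1"):
    return VariantRecord(chrom=chrom, pos=pos, ref="A", alt="T",
                         consequence="stop_gain", gene=gene)


class TestSelectQualifying:
    def test_nmd_policy(self, three_exon_gene):
        subject = ptv(1005)    # first exon: degraded by NMD
        escape = ptv(2250)     # last exon: escapes
        cfg = BurdenConfig(variant_class=VariantClass.PTV)
        af = {}
        kept = select_qualifying([subject, escape], three_exon_gene, cfg, af)
        assert kept == {subject.key}
        only_escape = replace(cfg, region_scope="nmd_escape_only")
        kept = select_qualifying(
            [subject, escape], three_exon_gene, only_escape, af
        )
        assert kept == {escape.key}

    def test_single_exon_gene_keeps_all_ptvs(self, single_exon_gene):
        variants = [ptv(600, gene="G1", chrom="2"), ptv(1500, gene="G1", chrom="2")]
        cfg = BurdenConfig(variant_class=VariantClass.PTV)
        kept = select_qualifying(variants, single_exon_gene, cfg, {})
        assert kept == {v.key for v in variants}

    def test_maf_threshold_strict(self, three_exon_gene):
        v = ptv(1005)
        cfg = BurdenConfig(variant_class=VariantClass.PTV, maf_threshold=1e-4)
        assert select_qualifying([v], three_exon_gene, cfg, {v.key: 5e-5})
        assert not select_qualifying([v], three_exon_gene, cfg, {v.key: 1e-4})
        # the same variant at AF 2e-4 is dropped at 1e-4 but kept at 2e-4...
        assert not select_qualifying([v], three_exon_gene, cfg, {v.key: 2e-4})
        lenient = replace(cfg, maf_threshold=2.000001e-4)
        assert select_qualifying([v], three_exon_gene, lenient, {v.key: 2e-4})

    def test_absent_frequency_means_zero(self, three_exon_gene):
        v = ptv(1005)
        cfg = BurdenConfig(variant_class=VariantClass.PTV)
        assert select_qualifying([v], three_exon_gene, cfg, {}) == {v.key}

    def test_mac1_restriction(self, three_exon_gene):
        v1, v2 = ptv(1005), ptv(1010)
        cfg = BurdenConfig(variant_class=VariantClass.PTV, mac1_only=True)
        kept = select_qualifying(
            [v1, v2], three_exon_gene, cfg, {}, mac={v1.key: 1, v2.key: 3}
        )
        assert kept == {v1.key}
        with pytest.raises(ValueError):
            select_qualifying([v1], three_exon_gene, cfg, {})

    def test_domain_scopes_partition(self, three_exon_gene):
        inside = VariantRecord(chrom="1", pos=1030, ref="A", alt="T",
                               consequence="missense", revel=0.9,
                               protein_pos=20, gene="G3")
        outside = VariantRecord(chrom="1", pos=1200, ref="A", alt="T",
                                consequence="missense", revel=0.9,
                                protein_pos=60, gene="G3")
        base = BurdenConfig(variant_class=VariantClass.DAMAGING_MISSENSE)
        in_d = select_qualifying(
            [inside, outside], three_exon_gene,
            replace(base, region_scope="in_domain"), {},
        )
        out_d = select_qualifying(
            [inside, outside], three_exon_gene,
            replace(base, region_scope="out_domain"), {},
        )
        assert in_d == {inside.key} and out_d == {outside.key}
        assert in_d | out_d == select_qualifying(
            [inside, outside], three_exon_gene, base, {}
        )


class TestCountCarriers:
    def test_carrier_collapse_counts_individuals_once(self):
        g = CohortGenotypes(n=100)
        g.carriers[("1", 1, "A", "T")] = np.array([3, 7])
        g.carriers[("1", 2, "A", "T")] = np.array([7, 9])
        assert count_carriers(g, g.carriers.keys()) == 3

    def test_empty_qualifying_set(self):
        assert count_carriers(CohortGenotypes(n=10), []) == 0


class TestFisherBurden:
    def test_reference_example(self):
        p, or_, ci = fisher_burden(2, 10, 1, 100)
        assert p == pytest.approx(0.0214, abs=2e-4)
        assert or_ == pytest.approx(24.75, abs=0.01)
        assert ci[0] < 24.75 < ci[1]

    def test_no_association(self):
        p, or_, _ = fisher_burden(1, 10, 10, 100)
        assert p == pytest.approx(1.0)
        assert or_ == pytest.approx(1.0)

    def test_degenerate_table(self):
        assert fisher_burden(0, 10, 0, 100) == (1.0, None, None)

    def test_haldane_correction_on_zero_cell(self):
        p, or_, ci = fisher_burden(3, 10, 0, 100)
        # OR from the corrected table (3.5 * 100.5) / (7.5 * 0.5)
        assert or_ == pytest.approx(3.5 * 100.5 / (7.5 * 0.5))
        assert ci[0] > 0 and np.isfinite(ci[1])

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_burden(5, 3, 0, 10)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        a=st.integers(0, 40), b=st.integers(0, 160),
        c=st.integers(0, 100), d=st.integers(0, 200),
    )
    def test_matches_hypergeometric_enumeration(self, a, b, c, d):
        """Fisher p equals full enumeration for tables with total <= 500."""
        if (a + c) == 0:
            return
        p, _, _ = fisher_burden(a, a + b, c, c + d)
        assert p == pytest.approx(
            fisher_minlike_oracle(a, b, c, d), rel=1e-6, abs=1e-12
        )


@pytest.fixture(scope="module")
def qc_passed_study():
    cfg = default_study_config(n_case=2571, n_control=30000, seed=7)
    models = simulate_gene_models(cfg)
    study = simulate_cohorts(models, cfg)
    study_qc, _, _ = qc_study(study)
    return study_qc


class TestSuite:
    def test_primary_grid_is_18_rows(self, qc_passed_study):
        results = run_suite(qc_passed_study, primary_grid(genes=()))
        assert len(results) == 18
        df = results_to_frame(results)
        assert set(df["class"]) == {"PTV", "DAMAGING_MISSENSE", "SYNONYMOUS"}
        assert df["gene"].nunique() == 6

    def test_maf_tier_monotonicity(self, qc_passed_study):
        """Qualifying sets nest: MAF 5e-5 within 1e-4 within 2e-4; the MAC=1
        set is inside every MAF tier."""
        study = qc_passed_study
        af = control_allele_frequencies(study)
        mac = {
            v.key: len(study.case.carriers.get(v.key, ()))
            + len(study.control.carriers.get(v.key, ()))
            for v in study.variants
        }
        for gene, model in study.gene_models.items():
            gvars = study.variants_of(gene)
            for cls in (VariantClass.PTV, VariantClass.SYNONYMOUS):
                base = BurdenConfig(variant_class=cls)
                sets = [
                    select_qualifying(
                        gvars, model, replace(base, maf_threshold=t), af
                    )
                    for t in (5e-5, 1e-4, 2e-4)
                ]
                assert sets[0] <= sets[1] <= sets[2]
                # a combined singleton has control AC <= 1, hence control AF
                # below every tier: the MAC=1 set nests inside all of them
                mac1 = select_qualifying(
                    gvars, model,
                    replace(base, mac1_only=True, maf_threshold=None),
                    af, mac=mac,
                )
                assert mac1 <= sets[0]

    def test_domain_partition_conserves_carriers(self, qc_passed_study):
        """in-domain + out-of-domain carriers equal all-region carriers for
        every gene and class."""
        study = qc_passed_study
        af = reference_allele_frequencies(study)
        for gene, model in study.gene_models.items():
            gvars = study.variants_of(gene)
            for cls in (VariantClass.PTV, VariantClass.DAMAGING_MISSENSE,
                        VariantClass.SYNONYMOUS):
                base = BurdenConfig(variant_class=cls)
                all_keys = select_qualifying(gvars, model, base, af)
                in_keys = select_qualifying(
                    gvars, model, replace(base, region_scope="in_domain"), af
                )
                out_keys = select_qualifying(
                    gvars, model, replace(base, region_scope="out_domain"), af
                )
                assert in_keys | out_keys == all_keys
                assert not (in_keys & out_keys)
                for coh in (study.case, study.control):
                    # one variant per carrier within a gene => counts add
                    assert (
                        coh.carrier_count(in_keys) + coh.carrier_count(out_keys)
                        == coh.carrier_count(all_keys)
                    )

    def test_sensitivity_grid_contains_ptv_only_tiers(self):
        tiers = {c.tier for c in sensitivity_grid(BurdenConfig())}
        assert {"no_maf", "nmd_escape"} <= tiers
        non_ptv = sensitivity_grid(
            BurdenConfig(variant_class=VariantClass.SYNONYMOUS)
        )
        assert "no_maf" not in {c.tier for c in non_ptv}

    def test_missing_gene_model_is_error(self, qc_passed_study):
        study = qc_passed_study
        broken = StudyData(
            case=study.case, control=study.control,
            variants=study.variants, gene_models={},
        )
        with pytest.raises(ValueError):
            run_suite(broken, primary_grid(genes=()))

    def test_full_grid_shape(self, qc_passed_study):
        df = results_to_frame(run_suite(qc_passed_study, build_grid("full")))
        # 3 primary + 5 shared tiers x 3 classes + 2 PTV-only tiers, x 6 genes
        assert len(df) == 6 * (3 + 15 + 2)
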