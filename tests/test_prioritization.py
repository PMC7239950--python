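"""Patient-number formula, dependency classes, druggability scoring, tests."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from gemini_loh import prioritization as pri
from gemini_loh.formats_io import ValidationError, VariantRecord
from gemini_loh.variant_catalog import classify_protein_change, heterozygosity


def annotation(**kw):
    base = dict(
        has_ligand_bound_structure=False,
        structure_druggable_or_tractable=False,
        ligand_druggability_percentile=0.0,
        has_ec_number=False,
        visual_pocket_score=0,
        charge_altering=False,
        introduces_cysteine=False,
    )
    base.update(kw)
    return pri.DruggabilityAnnotation(**base)


class TestPatientsPerYear:
    def test_worked_example(self):
        # kappa=1,735,350 new US cases/year, chi=2pq at MAF 0.177, lambda=0.09
        pi = pri.patients_per_year(1_735_350, heterozygosity(0.177), 0.09)
        assert pi == pytest.approx(22_750, abs=5)
        # published inputs are rounded; agreement with 22,470 within ~1.5%
        assert abs(pi - 22_470) / 22_470 < 0.02

    def test_zero_loh_rate(self):
        assert pri.patients_per_year(1_735_350, 0.29, 0.0) == 0

    def test_linearity_in_lambda(self):
        lo = 1_735_350 * 0.2913 * 0.05 * 0.5
        hi = 1_735_350 * 0.2913 * 0.10 * 0.5
        assert hi == pytest.approx(2 * lo)
        assert pri.patients_per_year(1_735_350, 0.2913, 0.10) in (
            2 * pri.patients_per_year(1_735_350, 0.2913, 0.05) + d for d in (-1, 0, 1)
        )

    @given(
        st.floats(0, 2e6), st.floats(0, 0.5), st.floats(0, 1),
        st.floats(0, 0.5), st.floats(0, 1),
    )
    def test_monotone_in_each_argument(self, kappa, chi, lam, chi2, lam2):
        base = pri.patients_per_year(kappa, chi, lam)
        assert pri.patients_per_year(kappa, max(chi, chi2), lam) >= base
        assert pri.patients_per_year(kappa, chi, max(lam, lam2)) >= base

    def test_invalid_inputs(self):
        with pytest.raises(ValidationError):
            pri.patients_per_year(-1, 0.2, 0.1)
        with pytest.raises(ValidationError):
            pri.patients_per_year(100, 0.7, 0.1)


class TestDependency:
    @pytest.mark.parametrize(
        "scores,strong",
        [([-0.52], True), ([-0.14], False), ([-0.5], True)],  # boundary inclusive
    )
    def test_threshold(self, scores, strong):
        _, got = pri.classify_dependency(scores)
        assert got is strong

    def test_median_over_nonmissing(self):
        median, strong = pri.classify_dependency([-0.9, float("nan"), -0.3])
        assert median == pytest.approx(-0.6)
        assert strong

    def test_empty_missing(self):
        median, strong = pri.classify_dependency([])
        assert math.isnan(median) and not strong


class TestEnrichment:
    def test_reported_dependency_enrichment_counts(self):
        # 413/1183 strongly dependent target genes vs 623/17,212 background
        assert pri.enrichment_test(413, 1183, 623, 17_212) < 1e-4

    def test_null_proportion_near_half(self):
        p = pri.enrichment_test(50, 1000, 500, 10_000)
        assert 0.3 < p < 0.7

    def test_depletion_near_one(self):
        assert pri.enrichment_test(0, 100, 50, 100) > 0.999

    def test_invalid_counts(self):
        with pytest.raises(ValidationError):
            pri.enrichment_test(5, 4, 1, 10)

    @given(st.integers(0, 50), st.integers(1, 50), st.integers(1, 99))
    def test_agrees_with_brute_force_tail_sum(self, k, n, bg_pct):
        k = min(k, n)
        p0 = bg_pct / 100
        expected = sum(stats.binom.pmf(j, n, p0) for j in range(k, n + 1))
        assert pri.enrichment_test(k, n, bg_pct, 100) == pytest.approx(
            expected, abs=1e-9
        )


class TestChargeAndCysteine:
    @pytest.mark.parametrize(
        "ref,alt,expected",
        [
            ("D", "A", True),  # negative -> neutral
            ("P", "H", True),  # neutral -> positive (H counted charged)
            ("L", "V", False),
            ("K", "R", False),  # positive -> positive
            ("A", "AD", True),  # inserted negative residue
            ("A", "AG", False),
            ("AD", "A", True),  # deleted charged residue
        ],
    )
    def test_charge_change(self, ref, alt, expected):
        change = classify_protein_change(ref, alt, 1)
        assert pri.charge_change(change) is expected

    @pytest.mark.parametrize(
        "ref,alt,expected",
        [("R", "C", True), ("C", "R", True), ("A", "AC", True), ("L", "V", False)],
    )
    def test_introduces_cysteine(self, ref, alt, expected):
        change = classify_protein_change(ref, alt, 1)
        assert pri.introduces_cysteine(change) is expected


class TestCompositeScore:
    def test_extremes(self):
        assert pri.composite_score(annotation()) == 0
        assert (
            pri.composite_score(
                annotation(
                    has_ligand_bound_structure=True,
                    structure_druggable_or_tractable=True,
                    ligand_druggability_percentile=95.0,
                    has_ec_number=True,
                    visual_pocket_score=4,
                    charge_altering=True,
                    introduces_cysteine=True,
                )
            )
            == 7
        )

    def test_six_with_visual_and_cysteine(self):
        # pattern of a top candidate scoring 6 including visual + cysteine
        ann = annotation(
            has_ligand_bound_structure=True,
            structure_druggable_or_tractable=True,
            ligand_druggability_percentile=92.0,
            has_ec_number=True,
            visual_pocket_score=3,
            charge_altering=False,
            introduces_cysteine=True,
        )
        assert pri.composite_score(ann) == 6

    @given(
        st.booleans(), st.booleans(), st.floats(0, 100), st.booleans(),
        st.integers(0, 4), st.booleans(), st.booleans(),
    )
    def test_equals_brute_force_recount(self, b1, b2, pct, b3, vis, b4, b5):
        ann = annotation(
            has_ligand_bound_structure=b1,
            structure_druggable_or_tractable=b2,
            ligand_druggability_percentile=pct,
            has_ec_number=b3,
            visual_pocket_score=vis,
            charge_altering=b4,
            introduces_cysteine=b5,
        )
        recount = sum([b1, b2, pct >= 90, b3, vis >= 3, b4, b5])
        assert pri.composite_score(ann) == recount
        assert 0 <= pri.composite_score(ann) <= 7


class TestYatesChiSquare:
    def test_hand_computed_example(self):
        # E = (20, 80, 20, 80); each |O-E| = 20 -> (19.5)^2 terms
        stat, p = pri.yates_chi_square([[40, 60], [0, 100]])
        assert stat == pytest.approx(47.53125, abs=1e-3)
        assert p < 1e-10

    def test_table_equal_to_expecteds(self):
        stat, p = pri.yates_chi_square([[20, 80], [20, 80]])
        assert stat == 0.0 and p == 1.0

    def test_transpose_invariant(self):
        a = pri.yates_chi_square([[30, 10], [12, 48]])
        b = pri.yates_chi_square([[30, 12], [10, 48]])
        assert a[0] == pytest.approx(b[0])

    def test_zero_marginal_raises(self):
        with pytest.raises(ValidationError):
            pri.yates_chi_square([[0, 0], [5, 5]])


class TestAssembleCompendium:
    def make_catalog(self):
        return [
            VariantRecord("rs1", "ESS1", "1", 100, "A", "G", "missense_variant", 0.2),
            VariantRecord("rs2", "ESS1", "1", 50, "C", "T", "synonymous_variant", 0.1),
            VariantRecord("rs3", "ESS2", "2", 10, "A", "T", "missense_variant", 0.3),
            VariantRecord("rs4", "NONESS", "3", 10, "G", "C", "missense_variant", 0.4),
        ]

    def test_hand_counted_join(self):
        comp = pri.assemble_compendium(
            {"ESS1", "ESS2"},
            self.make_catalog(),
            {"ESS1": 0.1, "ESS2": 0.0, "NONESS": 0.5},
            pam_specific_ids={"rs1"},
        )
        assert len(comp) == 3
        assert list(comp["variant_id"]) == ["rs2", "rs1", "rs3"]  # gene, position
        assert bool(comp.loc[comp["variant_id"] == "rs1", "pam_allele_specific"].iloc[0])

    def test_no_essential_genes_empty(self):
        comp = pri.assemble_compendium(set(), self.make_catalog(), {}, set())
        assert comp.empty

    def test_zero_loh_rate_is_annotation_not_filter(self):
        comp = pri.assemble_compendium(
            {"ESS2"}, self.make_catalog(), {"ESS2": 0.0}, set()
        )
        assert len(comp) == 1
        assert comp["patients_per_year"].iloc[0] == 0

    def test_patients_recompute_from_stored_chi_lambda(self):
        comp = pri.assemble_compendium(
            {"ESS1", "ESS2"},
            self.make_catalog(),
            {"ESS1": 0.2, "ESS2": 0.4},
            set(),
        )
        for _, row in comp.iterrows():
            expected = pri.patients_per_year(
                pri.KAPPA_US_CASES_PER_YEAR, row["heterozygosity"], row["loh_rate_pan"]
            )
            assert row["patients_per_year"] == expected

    def test_gene_without_loh_characterization_warns_but_emits(self, caplog):
        with caplog.at_level("WARNING"):
            comp = pri.assemble_compendium(
                {"ESS1"}, self.make_catalog()[:1], {}, set()
            )
        assert len(comp) == 1
        assert np.isnan(comp["loh_rate_pan"].iloc[0])
        assert "LOH" in caplog.text
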