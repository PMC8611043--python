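"""Allele, carrier and gene-set burden tests against control counts."""

import math
from fractions import Fraction
from itertools import product

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from eoefam.burden import (
    ContingencyTable2x2,
    GeneSet,
    carrier_burden,
    count_alleles,
    family_carrier_summary,
    fisher_exact_two_tailed,
    odds_ratio_chisq,
    second_hit_enrichment,
)
from eoefam.datasets import DESMOSOME_GO_0030057, cohort_family_candidates
from eoefam.filtering import HET, HOM_ALT, HOM_REF


def enumeration_two_tailed(table: ContingencyTable2x2) -> float:
    """Exhaustive margin-preserving enumeration oracle for the two-tailed
    Fisher P (probability-mass rule, exact rational hypergeometric masses)."""
    a, b, c, d = table.a, table.b, table.c, table.d
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def mass(x: int) -> Fraction:
        return Fraction(math.comb(r1, x) * math.comb(r2, c1 - x), math.comb(n, c1))

    observed = mass(a)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    # mirror the library's guard against floating ties: include masses within
    # 1e-7 relative of the observed mass
    total = sum(
        (m for x in range(lo, hi + 1) if (m := mass(x)) <= observed * (1 + Fraction(1, 10**7))),
        Fraction(0),
    )
    return float(total)


class TestCountAlleles:
    def test_two_gene_cohort_tally(self):
        """62 subjects over DSP+PPL: 12 single-gene hets and one dual het give
        14 minor of 248 alleles."""
        subjects = [f"s{i}" for i in range(62)]
        genes = ["DSP", "PPL"]
        genotypes = {(s, g): HOM_REF for s in subjects for g in genes}
        for i in range(12):
            genotypes[(f"s{i}", genes[i % 2])] = HET
        genotypes[("s12", "DSP")] = HET
        genotypes[("s12", "PPL")] = HET
        counts = count_alleles(subjects, genes, genotypes)
        assert (counts.minor, counts.major) == (14, 234)

    def test_no_carriers(self):
        subjects = [f"s{i}" for i in range(10)]
        genotypes = {(s, g): HOM_REF for s in subjects for g in ("DSP", "PPL")}
        counts = count_alleles(subjects, ("DSP", "PPL"), genotypes)
        assert (counts.minor, counts.major) == (0, 40)

    def test_matches_bruteforce_tally(self):
        rng = np.random.default_rng(5)
        subjects = [f"s{i}" for i in range(40)]
        genes = ["G1", "G2", "G3"]
        choices = [HOM_REF, HET, HOM_ALT]
        genotypes = {
            (s, g): choices[rng.integers(3)] for s in subjects for g in genes
        }
        counts = count_alleles(subjects, genes, genotypes)
        minor = sum(
            {HOM_REF: 0, HET: 1, HOM_ALT: 2}[genotypes[(s, g)]]
            for s in subjects
            for g in genes
        )
        assert counts.minor == minor
        assert counts.total == 2 * len(subjects) * len(genes)

    def test_missing_genotype_policies(self):
        subjects = ["s1", "s2"]
        genotypes = {("s1", "DSP"): HET}
        with pytest.warns(UserWarning, match="missing a genotype"):
            kept = count_alleles(subjects, ["DSP"], genotypes, on_missing="major")
        assert (kept.minor, kept.major) == (1, 3)
        dropped = count_alleles(subjects, ["DSP"], genotypes, on_missing="drop")
        assert (dropped.minor, dropped.major) == (1, 1)


class TestFisherAndOddsRatio:
    def test_symmetric_table(self):
        assert fisher_exact_two_tailed(ContingencyTable2x2(1, 1, 1, 1)) == pytest.approx(1.0)

    def test_balanced_table_null(self):
        or_, chi2 = odds_ratio_chisq(ContingencyTable2x2(10, 10, 10, 10))
        assert or_ == 1.0 and chi2 == 0.0

    def test_direct_arithmetic_or(self):
        or_, chi2 = odds_ratio_chisq(ContingencyTable2x2(14, 234, 3079, 130401))
        assert or_ == pytest.approx((14 * 130401) / (234 * 3079), rel=1e-12)
        assert chi2 > 0

    def test_zero_cell_haldane_correction(self):
        or_, _ = odds_ratio_chisq(ContingencyTable2x2(0, 10, 5, 5))
        assert or_ == pytest.approx((0.5 * 5.5) / (10.5 * 5.5), rel=1e-12)
        assert math.isfinite(or_)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="zero margin"):
            odds_ratio_chisq(ContingencyTable2x2(0, 0, 5, 5))

    def test_all_zero_table_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable2x2(0, 0, 0, 0)

    @given(st.lists(st.integers(0, 12), min_size=4, max_size=4))
    def test_matches_enumeration_oracle(self, cells):
        a, b, c, d = cells
        if a + b + c + d == 0:
            return
        table = ContingencyTable2x2(a, b, c, d)
        assert fisher_exact_two_tailed(table) == pytest.approx(
            enumeration_two_tailed(table), rel=1e-9, abs=1e-12
        )

    @given(st.lists(st.integers(0, 20), min_size=4, max_size=4))
    def test_invariant_to_simultaneous_row_and_column_swap(self, cells):
        a, b, c, d = cells
        if a + b + c + d == 0:
            return
        p1 = fisher_exact_two_tailed(ContingencyTable2x2(a, b, c, d))
        p2 = fisher_exact_two_tailed(ContingencyTable2x2(d, c, b, a))
        assert p1 == pytest.approx(p2, rel=1e-9)

    @given(st.lists(st.integers(1, 30), min_size=4, max_size=4))
    def test_or_direction_matches_fractions_and_chi2_zero_iff_unity(self, cells):
        a, b, c, d = cells
        or_, chi2 = odds_ratio_chisq(ContingencyTable2x2(a, b, c, d))
        case_frac, control_frac = a / (a + b), c / (c + d)
        assert (or_ > 1) == (case_frac > control_frac)
        assert (chi2 == pytest.approx(0.0, abs=1e-12)) == (or_ == pytest.approx(1.0))


class TestCarrierBurden:
    def test_identical_rates_give_p_one(self):
        res = carrier_burden(2, 4, 2, 4)
        assert res.p_fisher_two_tailed == pytest.approx(1.0)

    def test_carriers_exceeding_total_rejected(self):
        with pytest.raises(ValueError, match="exceed"):
            carrier_burden(5, 4, 10, 100)

    def test_small_tables_match_enumeration(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            ct, cn, tt, tn = rng.integers(0, 10, 4)
            res = carrier_burden(int(ct), int(ct + cn), int(tt), int(tt + tn + 1))
            assert res.p_fisher_two_tailed == pytest.approx(
                enumeration_two_tailed(res.table), rel=1e-9, abs=1e-12
            )


class TestSecondHitEnrichment:
    def test_planted_dual_hits_counted(self):
        subjects = [f"s{i}" for i in range(20)]
        hits = {
            "s0": ["DSP", "DSG1"],  # dual hit
            "s1": ["PPL", "DSC2"],  # dual hit
            "s2": ["DSP"],  # primary only
            "s3": ["DSG1"],  # second-hit gene only
            "s4": ["DSP", "PPL"],  # both primary, no other desmosome gene
            "s5": ["DSP", "TSLP"],  # second gene outside the set
        }
        res = second_hit_enrichment(
            hits, subjects, ("DSP", "PPL"), DESMOSOME_GO_0030057, 206, 4822
        )
        assert res.table.a == 2 and res.table.b == 18

    def test_zero_dual_hits_everywhere(self):
        res = second_hit_enrichment(
            {}, ["s1", "s2"], ("DSP", "PPL"), DESMOSOME_GO_0030057, 0, 100
        )
        assert res.p_fisher_two_tailed == pytest.approx(1.0)

    def test_primary_exclusion_toggle(self):
        subjects = ["s0"]
        hits = {"s0": ["DSP", "PPL"]}
        excl = second_hit_enrichment(
            hits, subjects, ("DSP", "PPL"), DESMOSOME_GO_0030057, 1, 100
        )
        incl = second_hit_enrichment(
            hits, subjects, ("DSP", "PPL"), DESMOSOME_GO_0030057, 1, 100,
            exclude_primary=False,
        )
        assert excl.table.a == 0 and incl.table.a == 1

    def test_empty_gene_set_rejected(self):
        with pytest.raises(ValueError):
            GeneSet("empty", ())
        only_primary = GeneSet("just-primaries", ("DSP", "PPL"))
        with pytest.raises(ValueError, match="empty after exclusions"):
            second_hit_enrichment({}, ["s1"], ("DSP", "PPL"), only_primary, 1, 10)


class TestFamilyCarrierSummary:
    def test_cohort_accounting(self):
        summary = family_carrier_summary(cohort_family_candidates())
        assert (summary.n_carrier_families, summary.n_families) == (13, 62)
        assert summary.percent == 21.0

    def test_no_carrier_families(self):
        summary = family_carrier_summary({"F1": [], "F2": []})
        assert summary.percent == 0.0

    def test_simulated_cohort_matches_truth(self):
        from eoefam.filtering import filter_cohort
        from eoefam.simulate import SimConfig, simulate_cohort

        cfg = SimConfig(n_families=6, mean_depth=80.0, seed=3)
        cohort = simulate_cohort(cfg)
        result = filter_cohort(cohort.genotype_calls, cohort.annotations, cohort.pedigrees)
        per_family = {
            fam.pedigree.family_id: [
                c
                for c in result.candidates
                if any(
                    c.genotypes.get(ind.individual_id) in (HET, HOM_ALT)
                    for ind in fam.pedigree
                )
                and c.variant_id == fam.variant.variant_id
            ]
            for fam in cohort.families
        }
        summary = family_carrier_summary(per_family)
        truth_carrier_families = sum(
            any(fam.truth_carriers().values()) for fam in cohort.families
        )
        assert summary.n_carrier_families == truth_carrier_families == 6
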