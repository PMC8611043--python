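"""Mendelian checks, co-segregation and the concordance statistic."""

import math
from fractions import Fraction

import pytest
from hypothesis import given
from hypothesis import strategies as st

from eoefam.datasets import synthetic_replication_families
from eoefam.filtering import HET, HOM_ALT, HOM_REF
from eoefam.pedigree import AFFECTED, UNAFFECTED, UNKNOWN, Individual, Pedigree
from eoefam.segregation import (
    binomial_upper_tail,
    check_mendelian,
    cosegregates_discovery,
    score_concordance,
)


def rational_upper_tail(k: int, n: int, p: float) -> Fraction:
    """Independent exact-rational oracle for the binomial upper tail."""
    fp = Fraction(p)
    return sum(
        Fraction(math.comb(n, j)) * fp**j * (1 - fp) ** (n - j)
        for j in range(k, n + 1)
    )


class TestCheckMendelian:
    @pytest.mark.parametrize(
        "child, father, mother, n_violations",
        [
            (HET, HOM_REF, HOM_REF, 1),  # de novo het is impossible here
            (HET, HET, HOM_REF, 0),
            (HOM_ALT, HET, HOM_REF, 1),  # needs an alt allele from each parent
            (HOM_REF, HOM_ALT, HET, 1),
            (HET, "missing", HOM_REF, 0),  # missing parent is uninformative
        ],
    )
    def test_trio_consistency(self, trio_pedigree, child, father, mother, n_violations):
        genotypes = {"T1_C": child, "T1_FA": father, "T1_MO": mother}
        assert len(check_mendelian(trio_pedigree, genotypes)) == n_violations

    def test_cyclic_pedigree_rejected(self):
        with pytest.raises(ValueError, match="cycle"):
            Pedigree(
                "C1",
                [
                    Individual("a", father_id="b"),
                    Individual("b", father_id="a"),
                ],
            )


def _extended_family(members):
    """members: (iid, affection, genotype or None); all are founders (structure
    is irrelevant to discovery co-segregation)."""
    individuals = [Individual(iid, affection=aff) for iid, aff, _ in members]
    genotypes = {iid: g for iid, _, g in members if g is not None}
    return Pedigree("D1", individuals), genotypes


class TestDiscoveryCosegregation:
    def test_tolerates_unaffected_carriers(self):
        # five affected carriers plus two carriers never diagnosed: the
        # variant still co-segregates, the extra carriers are reported
        members = [(f"a{i}", AFFECTED, HET) for i in range(5)]
        members += [("u1", UNKNOWN, HET), ("u2", UNAFFECTED, HET)]
        members += [("n1", UNAFFECTED, HOM_REF)]
        ped, genotypes = _extended_family(members)
        res = cosegregates_discovery(ped, genotypes)
        assert res.cosegregates
        assert res.affected_carriers == 5
        assert res.unaffected_carriers == 2

    def test_affected_noncarrier_breaks_cosegregation(self):
        ped, genotypes = _extended_family(
            [("a1", AFFECTED, HET), ("a2", AFFECTED, HOM_REF)]
        )
        res = cosegregates_discovery(ped, genotypes)
        assert not res.cosegregates
        assert res.affected_noncarriers == 1

    def test_all_affected_carriers(self):
        ped, genotypes = _extended_family([("a1", AFFECTED, HET), ("a2", AFFECTED, HOM_ALT)])
        res = cosegregates_discovery(ped, genotypes)
        assert res.cosegregates and res.unaffected_carriers == 0

    def test_requires_genotyped_affected(self):
        ped, genotypes = _extended_family([("u1", UNAFFECTED, HET), ("a1", AFFECTED, None)])
        with pytest.raises(ValueError, match="no genotyped affected"):
            cosegregates_discovery(ped, genotypes)


class TestScoreConcordance:
    def test_replication_reconstruction(self):
        """The synthetic replication cohort scores 18 concordant of 23 units."""
        res = score_concordance(synthetic_replication_families())
        assert (res.k_concordant, res.n_units) == (18, 23)
        assert round(res.percent, 1) == 78.3
        # exact one-sided binomial tail: 44,552 / 2^23
        assert res.p_binomial == pytest.approx(44552 / 2**23, rel=1e-12)

    def test_all_concordant_closed_form(self):
        # the first three reconstruction families have only concordant units
        fams = synthetic_replication_families()[:3]
        res = score_concordance(fams)
        assert res.proportion == 1.0
        assert res.p_binomial == pytest.approx(0.5**res.n_units, rel=1e-12)

    def test_half_concordant_even_n_exceeds_half(self):
        fams = synthetic_replication_families()
        # families R04 and R06 each contribute one concordant dyad and one
        # discordant sibling: k = n/2
        res = score_concordance([fams[3], fams[5]])
        assert res.n_units == 4 and res.k_concordant == 2
        assert res.p_binomial > 0.5

    def test_invariant_to_family_order_and_sibling_labels(self):
        fams = synthetic_replication_families()
        forward = score_concordance(fams)
        backward = score_concordance(list(reversed(fams)))
        assert (forward.k_concordant, forward.n_units, forward.p_binomial) == (
            backward.k_concordant,
            backward.n_units,
            backward.p_binomial,
        )

    def test_two_sided_tail_doubles(self):
        fams = synthetic_replication_families()
        one = score_concordance(fams, tail="one")
        two = score_concordance(fams, tail="two")
        assert two.p_binomial == pytest.approx(2 * one.p_binomial, rel=1e-12)

    def test_proband_must_be_carrier(self):
        ped, pro, genotypes = synthetic_replication_families()[0]
        bad = dict(genotypes, **{pro: HOM_REF})
        with pytest.raises(ValueError, match="not a genotyped carrier"):
            score_concordance([(ped, pro, bad)])

    def test_parent_inference_from_single_genotyped_parent(self):
        # R03: only the father is genotyped (het); the mother is inferred
        # hom-ref, and with both parents unaffected the dyad is concordant
        fam = synthetic_replication_families()[2]
        res = score_concordance([fam])
        dyads = [u for u in res.units if u.kind == "parent_dyad"]
        assert len(dyads) == 1 and dyads[0].concordant


class TestBinomialUpperTail:
    @pytest.mark.parametrize(
        "k, n, p, expected",
        [
            (0, 17, 0.5, 1.0),
            (5, 5, 0.5, 0.03125),
            (3, 3, 0.25, 0.25**3),
            (23, 23, 0.5, 0.5**23),
        ],
    )
    def test_closed_forms(self, k, n, p, expected):
        assert binomial_upper_tail(k, n, p) == pytest.approx(expected, rel=1e-14)

    def test_reconstructed_concordance_tail(self):
        assert binomial_upper_tail(18, 23, 0.5) == pytest.approx(
            float(Fraction(44552, 8388608)), rel=1e-12
        )

    @given(
        n=st.integers(1, 50),
        frac=st.floats(0.0, 1.0),
        p=st.sampled_from([0.5, 0.25, 0.1, 0.73, 0.999]),
    )
    def test_matches_rational_oracle(self, n, frac, p):
        k = round(frac * n)
        expected = float(rational_upper_tail(k, n, p))
        assert binomial_upper_tail(k, n, p) == pytest.approx(expected, rel=1e-12, abs=1e-300)

    @given(n=st.integers(1, 60), p=st.sampled_from([0.5, 0.2]))
    def test_monotone_nonincreasing_in_k(self, n, p):
        tails = [binomial_upper_tail(k, n, p) for k in range(n + 1)]
        assert all(a >= b for a, b in zip(tails, tails[1:]))

    def test_large_n_stable(self):
        from scipy.stats import binom

        got = binomial_upper_tail(5200, 10000, 0.5)
        assert got == pytest.approx(float(binom.sf(5199, 10000, 0.5)), rel=1e-9)
        got = binomial_upper_tail(9000, 10000, 0.5)
        assert got == pytest.approx(float(binom.sf(8999, 10000, 0.5)), rel=1e-8)

    @pytest.mark.parametrize("k, n, p", [(-1, 5, 0.5), (6, 5, 0.5), (2, 5, 1.5)])
    def test_rejects_out_of_range(self, k, n, p):
        with pytest.raises((ValueError, TypeError)):
            binomial_upper_tail(k, n, p)
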