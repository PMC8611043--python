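"""Mendelian checking, co-segregation, and genotype-phenotype concordance.

Two pedigree-level questions are answered here for a rare heterozygous variant
under an autosomal-dominant model:

* **Discovery co-segregation** — in an extended pedigree, does every genotyped
  affected member carry the variant?  Unaffected carriers do not break
  co-segregation (incomplete penetrance; such relatives may simply be
  undiagnosed) but are counted and reported.

* **Replication concordance** — across the replication families, how often
  does phenotype predict genotype among the proband's first-degree relatives?
  Each genotyped sibling is one scoring unit; the two parents collapse into a
  single *dyad* unit because the proband's heterozygosity plus a single
  founder origin makes one parent's genotype infer the other's.  The chance
  null treats every unit as a fair coin, so the reported P value is the exact
  binomial upper tail at p = 1/2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .filtering import HET, HOM_ALT, HOM_REF, MISSING, is_carrier
from .pedigree import AFFECTED, UNKNOWN, Individual, Pedigree

__all__ = [
    "MendelianViolation",
    "CosegregationResult",
    "ConcordanceUnit",
    "ConcordanceResult",
    "check_mendelian",
    "cosegregates_discovery",
    "score_concordance",
    "binomial_upper_tail",
]

_ALT_DOSE = {HOM_REF: 0, HET: 1, HOM_ALT: 2}


@dataclass(frozen=True)
class MendelianViolation:
    family_id: str
    child_id: str
    child_genotype: str
    father_genotype: str
    mother_genotype: str


def _possible_child_doses(father: int, mother: int) -> set[int]:
    halves = {0: (0,), 1: (0, 1), 2: (1,)}
    return {a + b for a in halves[father] for b in halves[mother]}


def check_mendelian(
    pedigree: Pedigree, genotypes: Mapping[str, str]
) -> list[MendelianViolation]:
    """List children whose genotype is impossible given both parents' genotypes
    at a bi-allelic autosomal site.  Missing genotypes are uninformative."""
    violations = []
    for child in pedigree.trios():
        gc = genotypes.get(child.individual_id, MISSING)
        gf = genotypes.get(child.father_id, MISSING)
        gm = genotypes.get(child.mother_id, MISSING)
        if MISSING in (gc, gf, gm):
            continue
        if _ALT_DOSE[gc] not in _possible_child_doses(_ALT_DOSE[gf], _ALT_DOSE[gm]):
            violations.append(
                MendelianViolation(pedigree.family_id, child.individual_id, gc, gf, gm)
            )
    return violations


@dataclass(frozen=True)
class CosegregationResult:
    cosegregates: bool
    affected_carriers: int
    affected_noncarriers: int
    unaffected_carriers: int


def cosegregates_discovery(
    pedigree: Pedigree, genotypes: Mapping[str, str]
) -> CosegregationResult:
    """Discovery-pedigree co-segregation under autosomal dominance.

    Co-segregation holds iff every genotyped affected member carries the
    variant.  Unaffected (or unassessed) carriers are reported but tolerated —
    they are compatible with incomplete penetrance or undiagnosed disease.
    """
    affected_carriers = affected_noncarriers = unaffected_carriers = 0
    n_genotyped_affected = 0
    for ind in pedigree:
        g = genotypes.get(ind.individual_id, MISSING)
        if g == MISSING:
            continue
        carrier = is_carrier(g)
        if ind.affection == AFFECTED:
            n_genotyped_affected += 1
            if carrier:
                affected_carriers += 1
            else:
                affected_noncarriers += 1
        elif carrier:
            unaffected_carriers += 1
    if n_genotyped_affected == 0:
        raise ValueError(
            f"family {pedigree.family_id}: no genotyped affected member"
        )
    return CosegregationResult(
        cosegregates=affected_noncarriers == 0,
        affected_carriers=affected_carriers,
        affected_noncarriers=affected_noncarriers,
        unaffected_carriers=unaffected_carriers,
    )


@dataclass(frozen=True)
class ConcordanceUnit:
    unit_id: str
    kind: str  # "sibling" | "parent_dyad"
    concordant: bool


@dataclass(frozen=True)
class ConcordanceResult:
    units: tuple[ConcordanceUnit, ...]
    n_units: int
    k_concordant: int
    proportion: float
    p_binomial: float

    @property
    def percent(self) -> float:
        return 100.0 * self.proportion


def _sibling_units(
    ped: Pedigree, proband: Individual, genotypes: Mapping[str, str]
) -> Iterable[ConcordanceUnit]:
    for sib in ped.full_siblings(proband.individual_id):
        g = genotypes.get(sib.individual_id, MISSING)
        if g == MISSING:
            continue
        if sib.affection == UNKNOWN:
            # symptomatic-but-unscoped relatives are excluded, not scored
            continue
        concordant = is_carrier(g) == (sib.affection == AFFECTED)
        yield ConcordanceUnit(f"{ped.family_id}:{sib.individual_id}", "sibling", concordant)


def _dyad_unit(
    ped: Pedigree, proband: Individual, genotypes: Mapping[str, str]
) -> ConcordanceUnit | None:
    father = ped.members.get(proband.father_id) if proband.father_id else None
    mother = ped.members.get(proband.mother_id) if proband.mother_id else None
    if father is None and mother is None:
        return None

    def observed(ind: Individual | None) -> bool | None:
        if ind is None:
            return None
        g = genotypes.get(ind.individual_id, MISSING)
        return None if g == MISSING else is_carrier(g)

    fc, mc = observed(father), observed(mother)
    if fc is None and mc is None:
        return None  # nothing observed, nothing inferable
    # single founder origin + heterozygous proband: one parent's genotype
    # determines the other's, so an ungenotyped parent is inferred as the
    # complement of the genotyped one
    if fc is None:
        fc = not mc
    if mc is None:
        mc = not fc

    f_aff = father is not None and father.affection == AFFECTED
    m_aff = mother is not None and mother.affection == AFFECTED
    if f_aff or m_aff:
        # phenotype predicts genotype parent-by-parent: affected <=> carrier
        concordant = (fc == f_aff) and (mc == m_aff)
    else:
        # neither parent affected: the (unaffected) transmitting parent must be
        # the only carrier — two carriers or none contradicts the single origin
        concordant = fc != mc
    return ConcordanceUnit(f"{ped.family_id}:parents", "parent_dyad", concordant)


def score_concordance(
    families: Sequence[tuple[Pedigree, str, Mapping[str, str]]],
    tail: str = "one",
    p_null: float = 0.5,
) -> ConcordanceResult:
    """Score genotype-phenotype concordance over first-degree-relative units.

    Parameters
    ----------
    families
        ``(pedigree, proband_id, genotypes)`` triples; the proband must be a
        genotyped carrier of the candidate variant.
    tail
        ``"one"`` (default) for the exact upper-tail binomial P(X >= k | n,
        p_null); ``"two"`` doubles the smaller tail (capped at 1).
    """
    if tail not in ("one", "two"):
        raise ValueError("tail must be 'one' or 'two'")
    units: list[ConcordanceUnit] = []
    for ped, proband_id, genotypes in families:
        proband = ped.members.get(proband_id)
        if proband is None:
            raise ValueError(f"proband {proband_id!r} not in family {ped.family_id}")
        if not is_carrier(genotypes.get(proband_id, MISSING)):
            raise ValueError(
                f"proband {proband_id!r} of family {ped.family_id} is not a "
                "genotyped carrier"
            )
        units.extend(_sibling_units(ped, proband, genotypes))
        dyad = _dyad_unit(ped, proband, genotypes)
        if dyad is not None:
            units.append(dyad)
    n = len(units)
    if n == 0:
        raise ValueError("no scoreable first-degree-relative units")
    k = sum(u.concordant for u in units)
    upper = binomial_upper_tail(k, n, p_null)
    if tail == "one":
        p = upper
    else:
        lower = binomial_upper_tail(n - k, n, 1.0 - p_null)  # = P(X <= k)
        p = min(1.0, 2.0 * min(upper, lower))
    return ConcordanceResult(
        units=tuple(units),
        n_units=n,
        k_concordant=k,
        proportion=k / n,
        p_binomial=p,
    )


def binomial_upper_tail(k: int, n: int, p: float) -> float:
    """Exact binomial upper tail  P(X >= k) = sum_{j=k}^{n} C(n,j) p^j (1-p)^(n-j).

    Exact integer binomial coefficients are used up to n = 1000 (each term is
    then correct to one ulp of its factors); beyond that the terms are
    accumulated in log space, which stays stable to n = 10,000 and above.
    """
    if not (isinstance(k, int) and isinstance(n, int)):
        raise TypeError("k and n must be integers")
    if not 0 <= k <= n:
        raise ValueError("require 0 <= k <= n")
    if not 0.0 <= p <= 1.0:
        raise ValueError("require 0 <= p <= 1")
    if k == 0:
        return 1.0
    if p == 0.0:
        return 0.0
    if p == 1.0:
        return 1.0
    log_p, log_q = math.log(p), math.log1p(-p)
    if n <= 1000:
        terms = [
            math.comb(n, j) * math.exp(j * log_p + (n - j) * log_q)
            for j in range(k, n + 1)
        ]
        return min(1.0, math.fsum(terms))
    logs = [
        math.lgamma(n + 1) - math.lgamma(j + 1) - math.lgamma(n - j + 1)
        + j * log_p + (n - j) * log_q
        for j in range(k, n + 1)
    ]
    m = max(logs)
    return min(1.0, math.exp(m) * math.fsum(math.exp(l - m) for l in logs))
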