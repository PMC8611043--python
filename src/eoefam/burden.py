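"""Case-control burden tests against external control counts.

Three constructions are supported, all reducing to a 2x2 table tested with the
two-tailed Fisher's exact test (P) and summarized by the odds ratio and the
Pearson chi-square statistic:

* **allele-level gene burden** — each subject contributes two alleles per
  tested gene (so four per subject for a two-gene test) and the minor-allele
  count is compared with reference-cohort allele counts;
* **subject-level carrier burden** — carriers vs non-carriers compared with a
  control cohort's carrier counts;
* **gene-set "second hit" enrichment** — a case carrier is a subject with a
  qualifying variant in a primary gene *and* a second qualifying variant in
  another member of a gene set (default: the GO:0030057 desmosome set with the
  primary genes excluded).

The allele-level test treats the two alleles of a subject as independent
observations.  That is the construction under test here; it ignores
within-subject dependence and is not a general recommendation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from scipy.stats import fisher_exact

from .filtering import HET, HOM_ALT, MISSING

__all__ = [
    "ContingencyTable2x2",
    "BurdenResult",
    "GeneSet",
    "AlleleCounts",
    "count_alleles",
    "fisher_exact_two_tailed",
    "odds_ratio_chisq",
    "burden_result",
    "carrier_burden",
    "second_hit_enrichment",
    "family_carrier_summary",
    "CarrierSummary",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts with rows = cases/controls, columns = minor/major alleles or
    carrier/non-carrier subjects."""

    a: int  # cases, minor / carriers
    b: int  # cases, major / non-carriers
    c: int  # controls, minor / carriers
    d: int  # controls, major / non-carriers
    label: str = ""

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("table is all zero")

    def as_rows(self) -> list[list[int]]:
        return [[self.a, self.b], [self.c, self.d]]

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class BurdenResult:
    table: ContingencyTable2x2
    odds_ratio: float
    chi_square: float
    p_fisher_two_tailed: float


@dataclass(frozen=True)
class GeneSet:
    """A named gene set, e.g. the GO:0030057 desmosome membership."""

    set_id: str
    gene_symbols: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.gene_symbols:
            raise ValueError("gene set is empty")
        if len(set(self.gene_symbols)) != len(self.gene_symbols):
            raise ValueError("gene set has duplicate symbols")

    def __contains__(self, gene: str) -> bool:
        return gene in self.gene_symbols


def fisher_exact_two_tailed(table: ContingencyTable2x2) -> float:
    """Two-tailed Fisher's exact P: the sum, over all tables with the observed
    margins, of hypergeometric probabilities no larger than the observed
    table's (the convention of mainstream statistics libraries)."""
    return float(fisher_exact(table.as_rows(), alternative="two-sided")[1])


def odds_ratio_chisq(table: ContingencyTable2x2) -> tuple[float, float]:
    """Odds ratio and Pearson chi-square (1 df, no continuity correction).

    A zero cell triggers the Haldane-Anscombe +0.5 correction for the odds
    ratio.  The chi-square requires all four margins nonzero.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if 0 in (a + b, c + d, a + c, b + d):
        raise ValueError("zero margin: chi-square undefined")
    if 0 in (a, b, c, d):
        fa, fb, fc, fd = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        or_ = (fa * fd) / (fb * fc)
    else:
        or_ = (a * d) / (b * c)
    n = table.total
    chi2 = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
    return or_, chi2


def burden_result(table: ContingencyTable2x2) -> BurdenResult:
    """Bundle OR, chi-square and Fisher P for one table.

    A zero margin leaves the Fisher P defined but the OR and chi-square not;
    those are reported as NaN rather than raising.
    """
    try:
        or_, chi2 = odds_ratio_chisq(table)
    except ValueError:
        or_ = chi2 = float("nan")
    return BurdenResult(table, or_, chi2, fisher_exact_two_tailed(table))


@dataclass(frozen=True)
class AlleleCounts:
    minor: int
    major: int

    @property
    def total(self) -> int:
        return self.minor + self.major


def count_alleles(
    subjects: Sequence[str],
    genes: Sequence[str],
    genotypes: Mapping[tuple[str, str], str],
    on_missing: str = "major",
) -> AlleleCounts:
    """Tally qualifying minor/major alleles, two alleles per subject per gene.

    ``genotypes`` maps ``(subject_id, gene)`` to the subject's qualifying
    genotype in that gene (het = 1 minor allele, hom-alt = 2); an absent or
    missing entry contributes two major alleles with a warning when
    ``on_missing="major"`` (the default), or drops the subject entirely when
    ``on_missing="drop"``.
    """
    if on_missing not in ("major", "drop"):
        raise ValueError("on_missing must be 'major' or 'drop'")
    kept = []
    for s in subjects:
        gts = [genotypes.get((s, g), MISSING) for g in genes]
        if MISSING in gts:
            if on_missing == "drop":
                continue
            warnings.warn(
                f"subject {s!r} missing a genotype; counted as major alleles",
                stacklevel=2,
            )
        kept.append(gts)
    minor = sum(
        {HET: 1, HOM_ALT: 2}.get(g, 0) for gts in kept for g in gts
    )
    total = 2 * len(genes) * len(kept)
    return AlleleCounts(minor=minor, major=total - minor)


def carrier_burden(
    case_carriers: int,
    case_total: int,
    control_carriers: int,
    control_total: int,
    label: str = "",
) -> BurdenResult:
    """Subject-level carrier burden: carriers/non-carriers x cases/controls."""
    if case_carriers > case_total or control_carriers > control_total:
        raise ValueError("carriers exceed group total")
    table = ContingencyTable2x2(
        case_carriers,
        case_total - case_carriers,
        control_carriers,
        control_total - control_carriers,
        label=label,
    )
    return burden_result(table)


def second_hit_enrichment(
    subject_gene_hits: Mapping[str, Iterable[str]],
    subjects: Sequence[str],
    primary_genes: Sequence[str],
    gene_set: GeneSet,
    control_carriers: int,
    control_total: int,
    exclude_primary: bool = True,
) -> BurdenResult:
    """Dual-hit carrier burden: a case carrier holds a qualifying variant in a
    primary gene *and* one in another gene-set member.

    ``subject_gene_hits`` maps each subject to the genes in which they carry
    at least one qualifying variant.  With ``exclude_primary`` (default) the
    second hit must fall outside the primary genes.
    """
    primary = set(primary_genes)
    second = set(gene_set.gene_symbols)
    if exclude_primary:
        second -= primary
    if not second:
        raise ValueError("second-hit gene set is empty after exclusions")
    n_dual = 0
    for s in subjects:
        hits = set(subject_gene_hits.get(s, ()))
        if hits & primary and hits & second:
            n_dual += 1
    return carrier_burden(
        n_dual,
        len(subjects),
        control_carriers,
        control_total,
        label=f"{'+'.join(sorted(primary))} with second hit in {gene_set.set_id}",
    )


@dataclass(frozen=True)
class CarrierSummary:
    n_carrier_families: int
    n_families: int
    percent: float


def family_carrier_summary(
    family_candidates: Mapping[str, Iterable[object]],
) -> CarrierSummary:
    """Count families with >= 1 qualifying candidate variant.

    ``family_candidates`` maps every cohort family (carrier or not) to its
    candidate-variant list; the percentage is reported to one decimal place.
    """
    n_families = len(family_candidates)
    n_carriers = sum(1 for v in family_candidates.values() if len(list(v)) > 0)
    pct = round(100.0 * n_carriers / n_families, 1) if n_families else 0.0
    return CarrierSummary(n_carriers, n_families, pct)
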