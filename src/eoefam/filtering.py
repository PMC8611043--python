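"""Genotype-level QC and variant-level rarity/deleteriousness filtering.

The filtering cascade mirrors a standard family-exome prioritization: genotype
calls are screened on read depth, genotype quality and alternate-allele ratio;
variants are then screened on minor allele frequency in European-ancestry
reference populations plus an internal cohort, and on an in-silico
pathogenicity consensus over ten prediction algorithms (a variant is kept when
at least one algorithm calls it damaging; protein-truncating consequences are
kept unconditionally).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .pedigree import Pedigree

HOM_REF = "hom_ref"
HET = "het"
HOM_ALT = "hom_alt"
MISSING = "missing"

GENOTYPES = (HOM_REF, HET, HOM_ALT, MISSING)

#: The fixed in-silico pathogenicity algorithm panel (dbNSFP-style names).
PREDICTION_ALGORITHMS = (
    "SIFT",
    "Polyphen2_HDIV",
    "Polyphen2_HVAR",
    "LRT",
    "MutationTaster",
    "MutationAssessor",
    "FATHMM",
    "CADD",
    "RadialSVM",
    "LR",
)

#: Conservation annotations (descriptive only; not used as a filter).
CONSERVATION_ALGORITHMS = ("PhyloP", "SiPhy", "GERP++")

#: Consequence classes that pass the deleteriousness filter unconditionally.
TRUNCATING_CONSEQUENCES = frozenset(
    {"frameshift_deletion", "frameshift_insertion", "stopgain", "stoploss"}
)

DAMAGING = "damaging"
BENIGN = "benign"


def is_carrier(genotype: str) -> bool:
    """True for genotypes carrying at least one alternate allele."""
    return genotype in (HET, HOM_ALT)


@dataclass(frozen=True)
class GenotypeCall:
    """One sample x variant call with its read-level evidence.

    ``alt_allele_ratio`` is alternate reads / depth and is ``None`` when
    depth is zero (the call is then unusable).
    """

    sample_id: str
    variant_id: str
    called_genotype: str
    depth: int
    genotype_quality: int
    alt_allele_ratio: float | None

    def __post_init__(self) -> None:
        if self.called_genotype not in GENOTYPES:
            raise ValueError(f"bad genotype {self.called_genotype!r}")
        if self.depth < 0:
            raise ValueError("depth must be >= 0")
        if self.genotype_quality < 0:
            raise ValueError("genotype quality must be >= 0")
        if self.depth == 0 and self.alt_allele_ratio is not None:
            raise ValueError("alt_allele_ratio must be missing when depth is 0")


@dataclass(frozen=True)
class VariantAnnotation:
    """Per-variant annotations driving the rarity/pathogenicity filters.

    ``maf_by_source`` holds European-ancestry reference-population MAFs keyed
    by source (``1kG_EUR``, ``ESP_EUR``, ``ExAC_EUR``); absent entries mean the
    variant was not observed there.  ``prediction_calls`` maps each of the ten
    panel algorithms to ``"damaging"``/``"benign"``; absent means no call.
    """

    variant_id: str
    gene: str
    consequence: str = "missense"
    protein_change: str = ""
    maf_by_source: Mapping[str, float] = field(default_factory=dict)
    maf_internal: float | None = None
    prediction_calls: Mapping[str, str] = field(default_factory=dict)
    conservation_flags: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for src, maf in self.maf_by_source.items():
            if not 0.0 <= maf <= 1.0:
                raise ValueError(f"MAF {maf} for {src} outside [0, 1]")
        if self.maf_internal is not None and not 0.0 <= self.maf_internal <= 1.0:
            raise ValueError(f"internal MAF {self.maf_internal} outside [0, 1]")
        for alg in self.prediction_calls:
            if alg not in PREDICTION_ALGORITHMS:
                raise ValueError(f"unknown prediction algorithm {alg!r}")


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the filtering cascade.

    Depth and genotype-quality thresholds are exclusive (a call must exceed
    them); the heterozygote allele-ratio band is inclusive at both ends; the
    homozygous bands are exclusive.  MAF cutoffs are exclusive upper bounds.
    """

    min_depth: int = 15
    min_gq: int = 20
    hom_ref_max_ratio: float = 0.15
    het_ratio_band: tuple[float, float] = (0.30, 0.70)
    hom_alt_min_ratio: float = 0.85
    public_maf_max: float = 0.001
    internal_maf_max: float = 0.01
    min_damaging_algorithms: int = 1

    def __post_init__(self) -> None:
        lo, hi = self.het_ratio_band
        if not (0.0 <= self.hom_ref_max_ratio <= lo <= hi <= self.hom_alt_min_ratio <= 1.0):
            raise ValueError("allele-ratio bands out of order or degenerate")
        if self.min_depth < 0 or self.min_gq < 0:
            raise ValueError("depth/GQ thresholds must be non-negative")
        for m in (self.public_maf_max, self.internal_maf_max):
            if not 0.0 < m <= 1.0:
                raise ValueError("MAF cutoffs must be in (0, 1]")
        if self.min_damaging_algorithms < 1:
            raise ValueError("min_damaging_algorithms must be >= 1")


@dataclass(frozen=True)
class QCResult:
    """Outcome of genotype QC: pass, fail(reason) or missing(reason)."""

    status: str  # "pass" | "fail" | "missing"
    genotype: str  # validated genotype ("missing" unless status == "pass")
    reason: str | None = None

    @property
    def passed(self) -> bool:
        return self.status == "pass"


def qc_genotype(call: GenotypeCall, cfg: FilterConfig | None = None) -> QCResult:
    """Screen one genotype call on depth, quality and allele-ratio consistency.

    A call fails outright on depth <= ``min_depth`` or GQ <= ``min_gq``
    (both thresholds exclusive).  Otherwise the called genotype must sit in its
    permitted allele-ratio region: hom-ref below ``hom_ref_max_ratio``, het
    inside ``het_ratio_band`` (inclusive), hom-alt above ``hom_alt_min_ratio``.
    A ratio outside the called genotype's region sets the call to missing with
    reason ``"ratio_genotype_mismatch"`` rather than re-calling it.
    """
    cfg = cfg or FilterConfig()
    if call.depth > 0 and call.alt_allele_ratio is None:
        raise ValueError(
            f"{call.sample_id}/{call.variant_id}: ratio missing with nonzero depth"
        )
    if call.depth <= cfg.min_depth:
        return QCResult("fail", MISSING, "depth")
    if call.genotype_quality <= cfg.min_gq:
        return QCResult("fail", MISSING, "gq")
    if call.called_genotype == MISSING:
        return QCResult("fail", MISSING, "no_call")
    ratio = call.alt_allele_ratio
    assert ratio is not None  # depth > min_depth > 0 here
    lo, hi = cfg.het_ratio_band
    ok = {
        HOM_REF: ratio < cfg.hom_ref_max_ratio,
        HET: lo <= ratio <= hi,
        HOM_ALT: ratio > cfg.hom_alt_min_ratio,
    }[call.called_genotype]
    if not ok:
        return QCResult("missing", MISSING, "ratio_genotype_mismatch")
    return QCResult("pass", call.called_genotype)


_PUBLIC_SOURCES = ("1kG_EUR", "ESP_EUR", "ExAC_EUR")


def is_rare(ann: VariantAnnotation, cfg: FilterConfig | None = None) -> bool:
    """Rarity filter: every present public EUR MAF below the public cutoff and
    the internal-cohort MAF (when present) below the internal cutoff.

    Absent MAFs are treated as zero: a variant never observed in a reference
    population is by construction rare there.
    """
    cfg = cfg or FilterConfig()
    for src in _PUBLIC_SOURCES:
        maf = ann.maf_by_source.get(src)
        if maf is not None and maf >= cfg.public_maf_max:
            return False
    if ann.maf_internal is not None and ann.maf_internal >= cfg.internal_maf_max:
        return False
    return True


def is_deleterious(ann: VariantAnnotation, cfg: FilterConfig | None = None) -> bool:
    """Pathogenicity consensus: damaging in >= ``min_damaging_algorithms`` of
    the ten-algorithm panel, or a protein-truncating consequence (which passes
    unconditionally since the algorithms only score missense changes)."""
    cfg = cfg or FilterConfig()
    if ann.consequence in TRUNCATING_CONSEQUENCES:
        return True
    n_damaging = sum(
        1 for call in ann.prediction_calls.values() if call == DAMAGING
    )
    return n_damaging >= cfg.min_damaging_algorithms


@dataclass(frozen=True)
class CandidateVariant:
    """A variant surviving the cascade, with its validated genotype matrix."""

    annotation: VariantAnnotation
    genotypes: Mapping[str, str]  # sample_id -> validated genotype

    @property
    def variant_id(self) -> str:
        return self.annotation.variant_id

    @property
    def gene(self) -> str:
        return self.annotation.gene

    def carriers(self) -> list[str]:
        return [s for s, g in self.genotypes.items() if is_carrier(g)]


@dataclass(frozen=True)
class FilterLogEntry:
    variant_id: str
    stage: str  # "maf" | "prediction" | "genotype_qc" | "no_informative_call"
    reason: str


@dataclass
class FilterResult:
    candidates: list[CandidateVariant]
    log: list[FilterLogEntry]


def filter_cohort(
    calls: Sequence[GenotypeCall],
    annotations: Sequence[VariantAnnotation],
    pedigrees: Sequence[Pedigree],
    cfg: FilterConfig | None = None,
) -> FilterResult:
    """Apply the full cascade to a cohort.

    Returns variants passing both :func:`is_rare` and :func:`is_deleterious`,
    each with a per-sample genotype matrix after :func:`qc_genotype`
    (QC-failing calls become missing; a variant needs at least one informative
    call to be retained).  Output order follows the annotation input order, so
    identical inputs give identical outputs.
    """
    cfg = cfg or FilterConfig()
    known_variants = {a.variant_id for a in annotations}
    known_samples = {i.individual_id for ped in pedigrees for i in ped}
    dangling_v = sorted({c.variant_id for c in calls} - known_variants)
    dangling_s = sorted({c.sample_id for c in calls} - known_samples)
    if dangling_v or dangling_s:
        raise ValueError(
            "dangling identifiers in genotype calls: "
            f"variants {dangling_v}, samples {dangling_s}"
        )

    by_variant: dict[str, list[GenotypeCall]] = {}
    for call in calls:
        by_variant.setdefault(call.variant_id, []).append(call)

    candidates: list[CandidateVariant] = []
    log: list[FilterLogEntry] = []
    for ann in annotations:
        if not is_rare(ann, cfg):
            log.append(FilterLogEntry(ann.variant_id, "maf", "not_rare"))
            continue
        if not is_deleterious(ann, cfg):
            log.append(FilterLogEntry(ann.variant_id, "prediction", "not_damaging"))
            continue
        genotypes: dict[str, str] = {}
        informative = 0
        for call in by_variant.get(ann.variant_id, []):
            qc = qc_genotype(call, cfg)
            genotypes[call.sample_id] = qc.genotype
            if qc.passed:
                informative += 1
            else:
                log.append(
                    FilterLogEntry(ann.variant_id, "genotype_qc", f"{call.sample_id}:{qc.reason}")
                )
        if informative == 0:
            log.append(FilterLogEntry(ann.variant_id, "no_informative_call", "all_calls_failed_qc"))
            continue
        candidates.append(CandidateVariant(ann, genotypes))
    return FilterResult(candidates, log)
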