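"""Synthetic multiplex-family cohorts for exercising the analysis pipeline.

The generator emulates the study design the pipeline assumes: multi-generation
families segregating one rare heterozygous autosomal-dominant variant from a
single founder, with tunable penetrance and phenocopy rate, read-level noise
(overdispersed depth, binomial alternate-read counts, Phred-like genotype
quality) and annotation tables in stated MAF regimes.  Everything downstream —
QC filtering, Mendelian checks, co-segregation, concordance, burden counting —
is testable against the generator's truth layer with no external data.

Randomness flows from a single integer seed through one
:class:`numpy.random.Generator`; identical seed and configuration give
bit-identical output files.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np

from .filtering import (
    DAMAGING,
    BENIGN,
    HET,
    HOM_ALT,
    HOM_REF,
    MISSING,
    GenotypeCall,
    PREDICTION_ALGORITHMS,
    CONSERVATION_ALGORITHMS,
    VariantAnnotation,
)
from .pedigree import AFFECTED, UNAFFECTED, Individual, Pedigree

__all__ = [
    "SimConfig",
    "SimVariant",
    "FamilySim",
    "SimulatedCohort",
    "simulate_pedigree",
    "simulate_genotype_calls",
    "simulate_cohort",
    "write_cohort",
]


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the generator.

    Defaults describe a multiplex-family exome study: three-generation
    families, a dominant variant with high but incomplete penetrance (carriers
    without disease are expected), a small phenocopy rate (affected
    non-carriers from the elevated familial background risk), ~60x mean exome
    coverage with negative-binomial overdispersion, heterozygote alternate
    read fraction 0.5 and a 0.5% sequencing error rate.
    """

    n_generations: int = 3
    n_families: int = 12
    penetrance: float = 0.8
    phenocopy_rate: float = 0.05
    mean_depth: float = 60.0
    depth_dispersion: float = 8.0
    het_alt_fraction: float = 0.5
    gq_mean: float = 60.0
    gq_sd: float = 15.0
    error_rate: float = 0.005
    mean_children: float = 2.2
    require_multiplex: bool = True
    n_neutral_variants: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_generations < 2:
            raise ValueError("n_generations must be >= 2")
        if self.n_families < 1:
            raise ValueError("n_families must be >= 1")
        for name in ("penetrance", "phenocopy_rate", "het_alt_fraction", "error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.mean_depth <= 0 or self.depth_dispersion <= 0:
            raise ValueError("mean_depth and depth_dispersion must be > 0")
        if self.gq_sd < 0 or self.mean_children < 1:
            raise ValueError("gq_sd must be >= 0 and mean_children >= 1")
        if self.n_neutral_variants < 0:
            raise ValueError("n_neutral_variants must be >= 0")


@dataclass(frozen=True)
class SimVariant:
    variant_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    family_id: str | None  # None for cohort-wide neutral variants


@dataclass
class FamilySim:
    """One simulated family: pedigree plus the truth genotype layer for the
    family's planted variant (before read-level noise)."""

    pedigree: Pedigree
    variant: SimVariant
    truth_genotypes: dict[str, str]  # individual_id -> hom_ref/het

    def truth_carriers(self) -> dict[str, bool]:
        return {iid: g in (HET, HOM_ALT) for iid, g in self.truth_genotypes.items()}


_MULTIPLEX_MAX_TRIES = 200


def _draw_family(
    config: SimConfig, rng: np.random.Generator, family_id: str
) -> tuple[list[Individual], dict[str, str]]:
    counter = 0

    def next_id() -> str:
        nonlocal counter
        counter += 1
        return f"{family_id}_I{counter:02d}"

    individuals: list[Individual] = []
    truth: dict[str, str] = {}

    def add(ind: Individual, genotype: str) -> Individual:
        individuals.append(ind)
        truth[ind.individual_id] = genotype
        return ind

    founder = add(Individual(next_id(), sex="male"), HET)
    spouse = add(Individual(next_id(), sex="female"), HOM_REF)
    couples = [(founder, spouse)]
    for gen in range(2, config.n_generations + 1):
        next_couples = []
        for father, mother in couples:
            n_children = 1 + rng.poisson(config.mean_children - 1.0)
            for _ in range(n_children):
                parent_carrier = (
                    truth[father.individual_id] == HET
                    or truth[mother.individual_id] == HET
                )
                # independent fair coin for transmission from a het parent
                carrier = parent_carrier and rng.random() < 0.5
                sex = "male" if rng.random() < 0.5 else "female"
                child = add(
                    Individual(
                        next_id(),
                        father_id=father.individual_id,
                        mother_id=mother.individual_id,
                        sex=sex,
                    ),
                    HET if carrier else HOM_REF,
                )
                if gen < config.n_generations:
                    married_in = add(
                        Individual(
                            next_id(),
                            sex="female" if sex == "male" else "male",
                        ),
                        HOM_REF,
                    )
                    next_couples.append(
                        (child, married_in) if sex == "male" else (married_in, child)
                    )
        couples = next_couples

    # phenotypes: penetrance for carriers, phenocopy rate for non-carriers
    with_pheno = []
    for ind in individuals:
        p = config.penetrance if truth[ind.individual_id] == HET else config.phenocopy_rate
        affection = AFFECTED if rng.random() < p else UNAFFECTED
        with_pheno.append(replace(ind, affection=affection))
    return with_pheno, truth


def simulate_pedigree(
    config: SimConfig,
    rng: np.random.Generator | None = None,
    family_id: str = "F1",
    variant: SimVariant | None = None,
) -> FamilySim:
    """Simulate one multi-generation family segregating a founder het variant.

    The founder of the family line is heterozygous; transmission to each child
    is an independent fair coin; married-in spouses are non-carriers (single
    founder origin, no de novo events).  When ``require_multiplex`` is set the
    family is redrawn until it has at least two affected members (capped at
    200 attempts, after which the last draw is kept — relevant only for
    configurations that cannot produce two affected, such as penetrance and
    phenocopy rate both zero).
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    if variant is None:
        variant = SimVariant(f"var_{family_id}", "6", 7_542_000, "G", "A", "DSP", family_id)
    for _ in range(_MULTIPLEX_MAX_TRIES):
        individuals, truth = _draw_family(config, rng, family_id)
        if not config.require_multiplex:
            break
        if sum(1 for i in individuals if i.affection == AFFECTED) >= 2:
            break
    return FamilySim(Pedigree(family_id, individuals), variant, truth)


def simulate_genotype_calls(
    family: FamilySim,
    config: SimConfig,
    rng: np.random.Generator,
    truth_genotypes: Mapping[str, str] | None = None,
    variant_id: str | None = None,
) -> list[GenotypeCall]:
    """Overlay read-level noise on a truth genotype layer.

    Per call: total depth ~ negative binomial with mean ``mean_depth`` and
    dispersion ``depth_dispersion``; alternate reads ~ binomial(depth, p) with
    p = ``error_rate`` for hom-ref, ``het_alt_fraction`` for het and
    1 − ``error_rate`` for hom-alt; GQ ~ round(Normal(gq_mean, gq_sd))
    clipped at zero.  A zero-depth draw yields a call with a missing allele
    ratio and a missing genotype (unusable downstream).
    """
    truth = truth_genotypes if truth_genotypes is not None else family.truth_genotypes
    vid = variant_id if variant_id is not None else family.variant.variant_id
    r = config.depth_dispersion
    p_nb = r / (r + config.mean_depth)
    alt_p = {
        HOM_REF: config.error_rate,
        HET: config.het_alt_fraction,
        HOM_ALT: 1.0 - config.error_rate,
    }
    calls = []
    for ind in family.pedigree:
        g = truth[ind.individual_id]
        depth = int(rng.negative_binomial(r, p_nb))
        gq = max(0, int(round(rng.normal(config.gq_mean, config.gq_sd))))
        if depth == 0:
            calls.append(
                GenotypeCall(ind.individual_id, vid, MISSING, 0, gq, None)
            )
            continue
        alt = int(rng.binomial(depth, alt_p[g]))
        calls.append(
            GenotypeCall(ind.individual_id, vid, g, depth, gq, alt / depth)
        )
    return calls


def _rare_damaging_annotation(
    rng: np.random.Generator, variant: SimVariant
) -> VariantAnnotation:
    # rare regime: absent from a source with prob 1/3, else MAF ~ U(0, 5e-4)
    mafs = {
        src: float(rng.uniform(0.0, 5e-4))
        for src in ("1kG_EUR", "ESP_EUR", "ExAC_EUR")
        if rng.random() > 1 / 3
    }
    calls = {
        alg: DAMAGING if rng.random() < 0.4 else BENIGN
        for alg in PREDICTION_ALGORITHMS
    }
    if DAMAGING not in calls.values():
        calls["SIFT"] = DAMAGING  # planted variants are damaging by design
    cons = {
        alg: "conserved" if rng.random() < 0.8 else "not"
        for alg in CONSERVATION_ALGORITHMS
    }
    return VariantAnnotation(
        variant_id=variant.variant_id,
        gene=variant.gene,
        consequence="missense",
        protein_change=f"p.X{variant.pos % 997}Y",
        maf_by_source=mafs,
        maf_internal=float(rng.uniform(0.0, 5e-3)) if rng.random() < 0.5 else None,
        prediction_calls=calls,
        conservation_flags=cons,
    )


def _neutral_annotation(
    rng: np.random.Generator, variant: SimVariant, maf: float
) -> VariantAnnotation:
    mafs = {src: maf for src in ("1kG_EUR", "ESP_EUR", "ExAC_EUR")}
    calls = {alg: BENIGN for alg in PREDICTION_ALGORITHMS}
    return VariantAnnotation(
        variant_id=variant.variant_id,
        gene=variant.gene,
        consequence="missense",
        protein_change=f"p.A{variant.pos % 997}B",
        maf_by_source=mafs,
        maf_internal=maf,
        prediction_calls=calls,
        conservation_flags={},
    )


def _gene_drop_neutral(
    ped: Pedigree, maf: float, rng: np.random.Generator
) -> dict[str, str]:
    """Mendelian gene-dropping of an unlinked bi-allelic variant: founders get
    Binomial(2, maf) alternate alleles, children inherit one allele from each
    parent."""
    doses: dict[str, int] = {}

    def dose(iid: str) -> int:
        if iid in doses:
            return doses[iid]
        ind = ped.members[iid]
        if ind.father_id is None or ind.mother_id is None:
            d = int(rng.binomial(2, maf))
        else:
            d = sum(
                int(rng.random() < dose(pid) / 2.0)
                for pid in (ind.father_id, ind.mother_id)
            )
        doses[iid] = d
        return d

    code = {0: HOM_REF, 1: HET, 2: HOM_ALT}
    return {ind.individual_id: code[dose(ind.individual_id)] for ind in ped}


@dataclass
class SimulatedCohort:
    """A full synthetic cohort: pedigrees with truth layers, noisy genotype
    calls and annotation/control tables."""

    config: SimConfig
    families: list[FamilySim]
    neutral_variants: list[SimVariant]
    truth_genotypes: dict[tuple[str, str], str]  # (individual, variant) -> genotype
    genotype_calls: list[GenotypeCall]
    annotations: list[VariantAnnotation]
    control_counts: dict[str, tuple[int, int]]  # stratum -> (carriers, total)

    @property
    def pedigrees(self) -> list[Pedigree]:
        return [f.pedigree for f in self.families]

    def truth_carriers(self) -> dict[str, bool]:
        """Carrier flags for each family's planted variant, from the truth
        genotype layer."""
        out: dict[str, bool] = {}
        for fam in self.families:
            out.update(fam.truth_carriers())
        return out


_GENE_CYCLE = (("DSP", "6", 7_542_000), ("PPL", "16", 4_932_000))


def simulate_cohort(config: SimConfig) -> SimulatedCohort:
    """Simulate ``n_families`` families, each segregating its own planted rare
    damaging variant (genes alternate between DSP and PPL), plus optional
    cohort-wide neutral variants (common, benign) gene-dropped through every
    pedigree for filter and Mendelian testing."""
    rng = np.random.default_rng(config.seed)
    families: list[FamilySim] = []
    annotations: list[VariantAnnotation] = []
    truth: dict[tuple[str, str], str] = {}
    calls: list[GenotypeCall] = []
    for i in range(config.n_families):
        fid = f"F{i + 1:03d}"
        gene, chrom, base = _GENE_CYCLE[i % len(_GENE_CYCLE)]
        variant = SimVariant(f"var_{fid}", chrom, base + i, "G", "A", gene, fid)
        fam = simulate_pedigree(config, rng, fid, variant)
        families.append(fam)
        annotations.append(_rare_damaging_annotation(rng, variant))
    # joint-called cohort: every sample gets a call at every family variant
    # (a family's planted variant is hom-ref truth outside that family)
    for fam in families:
        vid = fam.variant.variant_id
        for other in families:
            if other is fam:
                layer = fam.truth_genotypes
            else:
                layer = {ind.individual_id: HOM_REF for ind in other.pedigree}
            for iid, g in layer.items():
                truth[(iid, vid)] = g
            calls.extend(
                simulate_genotype_calls(
                    other, config, rng, truth_genotypes=layer, variant_id=vid
                )
            )

    neutral: list[SimVariant] = []
    for j in range(config.n_neutral_variants):
        variant = SimVariant(f"neutral_{j + 1:03d}", "2", 1_000_000 + j, "C", "T", f"GENE{j + 1}", None)
        maf = float(rng.uniform(0.05, 0.4))
        neutral.append(variant)
        annotations.append(_neutral_annotation(rng, variant, maf))
        for fam in families:
            layer = _gene_drop_neutral(fam.pedigree, maf, rng)
            for iid, g in layer.items():
                truth[(iid, variant.variant_id)] = g
            calls.extend(
                simulate_genotype_calls(
                    fam, config, rng, truth_genotypes=layer, variant_id=variant.variant_id
                )
            )

    # plausible external control-cohort counts for burden-test plumbing
    control_total = 5000
    control_carriers = int(rng.binomial(control_total, 0.05))
    control_counts = {"gene_carriers": (control_carriers, control_total)}
    return SimulatedCohort(
        config=config,
        families=families,
        neutral_variants=neutral,
        truth_genotypes=truth,
        genotype_calls=calls,
        annotations=annotations,
        control_counts=control_counts,
    )


def write_cohort(cohort: SimulatedCohort, out_dir: str | Path) -> dict[str, Path]:
    """Write the cohort as VCF + PED + annotation and control-count TSVs.

    Delegates to :mod:`eoefam.io`; reading the files back reproduces the
    cohort's pedigrees, calls and annotations (the truth layer is simulation
    metadata and is not serialized).
    """
    from . import io as eio

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    variants = [f.variant for f in cohort.families] + cohort.neutral_variants
    paths = {
        "vcf": eio.write_vcf(out_dir / "cohort.vcf", variants, cohort.pedigrees, cohort.genotype_calls),
        "ped": eio.write_ped_file(cohort.pedigrees, out_dir / "cohort.ped"),
        "annotations": eio.write_annotations(cohort.annotations, out_dir / "annotations.tsv"),
        "controls": eio.write_control_counts(cohort.control_counts, out_dir / "controls.tsv"),
    }
    return paths
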