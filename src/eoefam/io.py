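"""Reading and writing the cohort file formats.

* VCF v4.2 with per-sample ``GT:DP:AD:GQ`` — written by a small fixed-schema
  emitter, read back through :mod:`cyvcf2`.
* 6-column PED (delegated to :mod:`eoefam.pedigree`).
* Tab-separated annotation tables (per-population MAFs, per-algorithm
  deleteriousness calls, conservation flags) and control-count tables, via
  :mod:`pandas`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from cyvcf2 import VCF

from .filtering import (
    CONSERVATION_ALGORITHMS,
    GenotypeCall,
    HET,
    HOM_ALT,
    HOM_REF,
    MISSING,
    PREDICTION_ALGORITHMS,
    VariantAnnotation,
)
from .pedigree import Pedigree, read_ped, write_ped

__all__ = [
    "VariantSite",
    "CohortData",
    "write_vcf",
    "read_vcf",
    "write_ped_file",
    "write_annotations",
    "read_annotations",
    "write_control_counts",
    "read_control_counts",
    "read_cohort",
]


@dataclass(frozen=True)
class VariantSite:
    variant_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str


_GT_FIELD = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1", MISSING: "./."}
_GT_CODE = {0: HOM_REF, 1: HET, 2: HOM_ALT, 3: MISSING}

_VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths (ref,alt)">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">
"""


def write_vcf(
    path: str | Path,
    variants: Sequence,
    pedigrees: Sequence[Pedigree],
    calls: Sequence[GenotypeCall],
) -> Path:
    """Write bi-allelic records with per-sample GT:DP:AD:GQ.

    ``variants`` need ``variant_id``/``chrom``/``pos``/``ref``/``alt``/``gene``
    attributes.  Samples are all pedigree members in pedigree order; a sample
    without a call for a variant is written fully missing.
    """
    path = Path(path)
    samples = [ind.individual_id for ped in pedigrees for ind in ped]
    by_key = {(c.sample_id, c.variant_id): c for c in calls}
    lines = [_VCF_HEADER.rstrip("\n")]
    for chrom in sorted({v.chrom for v in variants}):
        lines.append(f"##contig=<ID={chrom}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples))
    ordered = sorted(variants, key=lambda v: (v.chrom, v.pos, v.variant_id))
    for v in ordered:
        fields = [v.chrom, str(v.pos), v.variant_id, v.ref, v.alt, ".", "PASS", f"GENE={v.gene}", "GT:DP:AD:GQ"]
        for s in samples:
            call = by_key.get((s, v.variant_id))
            if call is None or call.depth == 0 or call.called_genotype == MISSING:
                gq = call.genotype_quality if call is not None else 0
                dp = call.depth if call is not None else 0
                fields.append(f"./.:{dp}:0,0:{gq}")
                continue
            alt_reads = round(call.alt_allele_ratio * call.depth)
            fields.append(
                f"{_GT_FIELD[call.called_genotype]}:{call.depth}:"
                f"{call.depth - alt_reads},{alt_reads}:{call.genotype_quality}"
            )
        lines.append("\t".join(fields))
    path.write_text("\n".join(lines) + "\n")
    return path


def read_vcf(path: str | Path) -> tuple[list[VariantSite], list[GenotypeCall]]:
    """Read a VCF written by :func:`write_vcf` (or any bi-allelic VCF carrying
    GT/DP/AD/GQ) into variant sites and genotype calls."""
    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    sites: list[VariantSite] = []
    calls: list[GenotypeCall] = []
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise ValueError(f"record {rec.ID} is not bi-allelic; split multi-allelics first")
        gene = rec.INFO.get("GENE", "")
        sites.append(
            VariantSite(rec.ID or f"{rec.CHROM}:{rec.POS}", rec.CHROM, rec.POS, rec.REF, rec.ALT[0], gene)
        )
        gts = rec.gt_types  # 0 hom_ref, 1 het, 2 hom_alt, 3 unknown
        dps = rec.format("DP")
        ads = rec.format("AD")
        gqs = rec.format("GQ")
        for i, sample in enumerate(samples):
            depth = int(dps[i][0]) if dps is not None else 0
            depth = max(depth, 0)  # cyvcf2 encodes missing as a large negative
            gq = int(gqs[i][0]) if gqs is not None and gqs[i][0] >= 0 else 0
            genotype = _GT_CODE[int(gts[i])]
            if depth <= 0 or genotype == MISSING:
                calls.append(GenotypeCall(sample, sites[-1].variant_id, MISSING, max(depth, 0), gq, None))
                continue
            alt_reads = int(ads[i][1]) if ads is not None else 0
            calls.append(
                GenotypeCall(sample, sites[-1].variant_id, genotype, depth, gq, alt_reads / depth)
            )
    return sites, calls


def write_ped_file(pedigrees: Iterable[Pedigree], path: str | Path) -> Path:
    return write_ped(pedigrees, path)


_MAF_COLUMNS = {
    "maf_1kg_eur": "1kG_EUR",
    "maf_esp_eur": "ESP_EUR",
    "maf_exac_eur": "ExAC_EUR",
}
_CONS_COLUMNS = {"phylop": "PhyloP", "siphy": "SiPhy", "gerp": "GERP++"}


def write_annotations(annotations: Sequence[VariantAnnotation], path: str | Path) -> Path:
    """Write the annotation table as TSV; empty cells mean absent values."""
    rows = []
    for ann in annotations:
        row: dict[str, object] = {
            "variant_id": ann.variant_id,
            "gene": ann.gene,
            "consequence": ann.consequence,
            "protein_change": ann.protein_change,
        }
        for col, src in _MAF_COLUMNS.items():
            maf = ann.maf_by_source.get(src)
            row[col] = "" if maf is None else repr(maf)
        row["maf_internal"] = "" if ann.maf_internal is None else repr(ann.maf_internal)
        for alg in PREDICTION_ALGORITHMS:
            row[alg] = ann.prediction_calls.get(alg, "")
        for col, alg in _CONS_COLUMNS.items():
            row[col] = ann.conservation_flags.get(alg, "")
        rows.append(row)
    columns = (
        ["variant_id", "gene", "consequence", "protein_change"]
        + list(_MAF_COLUMNS)
        + ["maf_internal"]
        + list(PREDICTION_ALGORITHMS)
        + list(_CONS_COLUMNS)
    )
    pd.DataFrame(rows, columns=columns).to_csv(path, sep="\t", index=False)
    return Path(path)


def read_annotations(path: str | Path) -> list[VariantAnnotation]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    annotations = []
    for _, row in df.iterrows():
        mafs = {
            src: float(row[col]) for col, src in _MAF_COLUMNS.items() if row[col] != ""
        }
        annotations.append(
            VariantAnnotation(
                variant_id=row["variant_id"],
                gene=row["gene"],
                consequence=row["consequence"],
                protein_change=row["protein_change"],
                maf_by_source=mafs,
                maf_internal=float(row["maf_internal"]) if row["maf_internal"] != "" else None,
                prediction_calls={
                    alg: row[alg] for alg in PREDICTION_ALGORITHMS if row.get(alg, "") != ""
                },
                conservation_flags={
                    alg: row[col] for col, alg in _CONS_COLUMNS.items() if row.get(col, "") != ""
                },
            )
        )
    return annotations


def write_control_counts(counts: Mapping[str, tuple[int, int]], path: str | Path) -> Path:
    """Control-count TSV: one row per stratum with carrier (or minor-allele)
    and total counts."""
    df = pd.DataFrame(
        [(stratum, c, t) for stratum, (c, t) in counts.items()],
        columns=["stratum", "carriers", "total"],
    )
    df.to_csv(path, sep="\t", index=False)
    return Path(path)


def read_control_counts(path: str | Path) -> dict[str, tuple[int, int]]:
    df = pd.read_csv(path, sep="\t")
    return {
        str(row["stratum"]): (int(row["carriers"]), int(row["total"]))
        for _, row in df.iterrows()
    }


@dataclass
class CohortData:
    """An on-disk cohort read back into memory (no simulation truth layer)."""

    pedigrees: list[Pedigree]
    variants: list[VariantSite]
    genotype_calls: list[GenotypeCall]
    annotations: list[VariantAnnotation]
    control_counts: dict[str, tuple[int, int]]


def read_cohort(directory: str | Path) -> CohortData:
    """Read a directory produced by :func:`eoefam.simulate.write_cohort`."""
    directory = Path(directory)
    variants, calls = read_vcf(directory / "cohort.vcf")
    return CohortData(
        pedigrees=read_ped(directory / "cohort.ped"),
        variants=variants,
        genotype_calls=calls,
        annotations=read_annotations(directory / "annotations.tsv"),
        control_counts=read_control_counts(directory / "controls.tsv"),
    )
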