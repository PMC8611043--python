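"""Pedigree data structures and PED-format input/output.

A :class:`Pedigree` is the unit of segregation analysis: a family graph with
sex, parental links and affection status.  "Affected" means histologically
confirmed eosinophilic esophagitis; every other status — including relatives
with symptoms who were never scoped — is non-affected for scoring purposes,
although genuinely unassessed relatives can be flagged ``unknown`` so that
concordance scoring can exclude them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

AFFECTED = "affected"
UNAFFECTED = "unaffected"
UNKNOWN = "unknown"

_PED_PHENOTYPE = {AFFECTED: "2", UNAFFECTED: "1", UNKNOWN: "0"}
_PED_PHENOTYPE_REV = {"2": AFFECTED, "1": UNAFFECTED, "0": UNKNOWN, "-9": UNKNOWN}
_PED_SEX = {"male": "1", "female": "2", "unknown": "0"}
_PED_SEX_REV = {"1": "male", "2": "female", "0": "unknown"}


@dataclass(frozen=True)
class Individual:
    """One pedigree member; parent ids are ``None`` for founders."""

    individual_id: str
    father_id: str | None = None
    mother_id: str | None = None
    sex: str = "unknown"
    affection: str = UNAFFECTED

    def __post_init__(self) -> None:
        if self.affection not in (AFFECTED, UNAFFECTED, UNKNOWN):
            raise ValueError(f"bad affection status {self.affection!r}")
        if self.sex not in ("male", "female", "unknown"):
            raise ValueError(f"bad sex {self.sex!r}")


@dataclass
class Pedigree:
    """A single family: individuals with resolvable, acyclic parent links."""

    family_id: str
    individuals: list[Individual]
    members: dict[str, Individual] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.members = {}
        for ind in self.individuals:
            if ind.individual_id in self.members:
                raise ValueError(
                    f"duplicate individual {ind.individual_id!r} in {self.family_id}"
                )
            self.members[ind.individual_id] = ind
        for ind in self.individuals:
            for pid in (ind.father_id, ind.mother_id):
                if pid is not None and pid not in self.members:
                    raise ValueError(
                        f"parent {pid!r} of {ind.individual_id!r} not in family "
                        f"{self.family_id}"
                    )
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        # DFS through parent links; an individual reachable from itself is a cycle
        state: dict[str, int] = {}  # 0 = in progress, 1 = done

        def visit(iid: str) -> None:
            if state.get(iid) == 1:
                return
            if state.get(iid) == 0:
                raise ValueError(f"pedigree {self.family_id} contains a cycle at {iid!r}")
            state[iid] = 0
            ind = self.members[iid]
            for pid in (ind.father_id, ind.mother_id):
                if pid is not None:
                    visit(pid)
            state[iid] = 1

        for iid in self.members:
            visit(iid)

    def __iter__(self) -> Iterator[Individual]:
        return iter(self.individuals)

    def __len__(self) -> int:
        return len(self.individuals)

    def affected(self) -> list[Individual]:
        return [i for i in self.individuals if i.affection == AFFECTED]

    def founders(self) -> list[Individual]:
        return [i for i in self.individuals if i.father_id is None and i.mother_id is None]

    def children_of(self, individual_id: str) -> list[Individual]:
        return [
            i
            for i in self.individuals
            if individual_id in (i.father_id, i.mother_id)
        ]

    def full_siblings(self, individual_id: str) -> list[Individual]:
        """Individuals sharing both (non-missing) parents with the given member."""
        ind = self.members[individual_id]
        if ind.father_id is None or ind.mother_id is None:
            return []
        return [
            i
            for i in self.individuals
            if i.individual_id != individual_id
            and i.father_id == ind.father_id
            and i.mother_id == ind.mother_id
        ]

    def trios(self) -> list[Individual]:
        """Members with both parents present in the family."""
        return [
            i
            for i in self.individuals
            if i.father_id is not None and i.mother_id is not None
        ]


def write_ped(pedigrees: Iterable[Pedigree], path: str | Path) -> Path:
    """Write families as 6-column whitespace-delimited PED.

    Phenotype coding: 1 = unaffected, 2 = affected, 0 = unknown.  Missing
    parents are written as ``0``.
    """
    path = Path(path)
    lines = []
    for ped in pedigrees:
        for ind in ped:
            lines.append(
                "\t".join(
                    [
                        ped.family_id,
                        ind.individual_id,
                        ind.father_id or "0",
                        ind.mother_id or "0",
                        _PED_SEX[ind.sex],
                        _PED_PHENOTYPE[ind.affection],
                    ]
                )
            )
    path.write_text("\n".join(lines) + ("\n" if lines else ""))
    return path


def read_ped(path: str | Path) -> list[Pedigree]:
    """Read a 6-column PED file into a list of pedigrees (input order kept)."""
    families: dict[str, list[Individual]] = {}
    order: list[str] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) < 6:
            raise ValueError(f"PED line {lineno}: expected 6 columns, got {len(fields)}")
        fam, iid, fid, mid, sex, pheno = fields[:6]
        if pheno not in _PED_PHENOTYPE_REV:
            raise ValueError(f"PED line {lineno}: bad phenotype code {pheno!r}")
        if sex not in _PED_SEX_REV:
            raise ValueError(f"PED line {lineno}: bad sex code {sex!r}")
        if fam not in families:
            families[fam] = []
            order.append(fam)
        families[fam].append(
            Individual(
                individual_id=iid,
                father_id=None if fid == "0" else fid,
                mother_id=None if mid == "0" else mid,
                sex=_PED_SEX_REV[sex],
                affection=_PED_PHENOTYPE_REV[pheno],
            )
        )
    return [Pedigree(fam, inds) for fam, inds in ((f, families[f]) for f in order)]
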