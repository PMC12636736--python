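"""Pedigree model and linkage-format (PED) I/O.

A pedigree is a family of individuals with parent links, sex and affection
status.  Individuals either have both parents recorded inside the pedigree
or none (founders).  The module exposes the two views the recessive screen
needs: the sequenced trio (father, mother, proband) and full-sibling sets
for segregation follow-up.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

log = logging.getLogger(__name__)

__all__ = [
    "Sex",
    "Phenotype",
    "Individual",
    "Pedigree",
    "PedigreeError",
    "PedParseError",
    "read_ped",
    "write_ped",
    "extract_trio",
    "siblings_of",
]


class PedigreeError(ValueError):
    """A pedigree violates a structural invariant."""


class PedParseError(PedigreeError):
    """A PED file row could not be parsed."""


class Sex(enum.Enum):
    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"


class Phenotype(enum.Enum):
    AFFECTED = "affected"
    UNAFFECTED = "unaffected"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class Individual:
    """One pedigree member; ``father_id``/``mother_id`` are ``None`` for founders."""

    individual_id: str
    father_id: str | None = None
    mother_id: str | None = None
    sex: Sex = Sex.UNKNOWN
    phenotype: Phenotype = Phenotype.UNKNOWN

    def __post_init__(self) -> None:
        if not self.individual_id:
            raise PedigreeError("individual_id must be non-empty")
        if (self.father_id is None) != (self.mother_id is None):
            raise PedigreeError(
                f"individual {self.individual_id!r}: either both parents or neither "
                "must be recorded"
            )

    @property
    def is_founder(self) -> bool:
        return self.father_id is None and self.mother_id is None


@dataclass
class Pedigree:
    """A family: ordered members with validated parent links.

    Invariants enforced at construction: unique non-empty ids, parent ids
    reference members, the parent graph is acyclic, and at least one founder
    exists.
    """

    family_id: str
    members: list[Individual] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [m.individual_id for m in self.members]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise PedigreeError(
                f"family {self.family_id!r}: duplicate individual id(s) {sorted(dupes)}"
            )
        self._index = {m.individual_id: m for m in self.members}
        for m in self.members:
            for pid in (m.father_id, m.mother_id):
                if pid is not None and pid not in self._index:
                    raise PedigreeError(
                        f"family {self.family_id!r}: {m.individual_id!r} references "
                        f"unknown parent {pid!r}"
                    )
        if self.members and not any(m.is_founder for m in self.members):
            raise PedigreeError(f"family {self.family_id!r}: no founder present")
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        # DFS from each member through parent links; a repeat on the active
        # path means an individual is its own ancestor.
        WHITE, GREY, BLACK = 0, 1, 2
        color = {i: WHITE for i in self._index}

        def visit(iid: str) -> None:
            color[iid] = GREY
            m = self._index[iid]
            for pid in (m.father_id, m.mother_id):
                if pid is None:
                    continue
                if color[pid] == GREY:
                    raise PedigreeError(
                        f"family {self.family_id!r}: ancestry cycle through {pid!r}"
                    )
                if color[pid] == WHITE:
                    visit(pid)
            color[iid] = BLACK

        for iid in self._index:
            if color[iid] == WHITE:
                visit(iid)

    def __contains__(self, individual_id: str) -> bool:
        return individual_id in self._index

    def __len__(self) -> int:
        return len(self.members)

    def get(self, individual_id: str) -> Individual:
        try:
            return self._index[individual_id]
        except KeyError:
            raise KeyError(
                f"individual {individual_id!r} not in family {self.family_id!r}"
            ) from None

    @property
    def founders(self) -> list[Individual]:
        return [m for m in self.members if m.is_founder]

    @property
    def affected(self) -> list[Individual]:
        return [m for m in self.members if m.phenotype is Phenotype.AFFECTED]

    def parents_of_affected(self) -> set[str]:
        """Ids of obligate carriers: every recorded parent of an affected member."""
        out: set[str] = set()
        for m in self.affected:
            for pid in (m.father_id, m.mother_id):
                if pid is not None:
                    out.add(pid)
        return out


_SEX_CODES = {"1": Sex.MALE, "2": Sex.FEMALE}
_PHENO_CODES = {"2": Phenotype.AFFECTED, "1": Phenotype.UNAFFECTED}
_SEX_OUT = {Sex.MALE: "1", Sex.FEMALE: "2", Sex.UNKNOWN: "0"}
_PHENO_OUT = {
    Phenotype.AFFECTED: "2",
    Phenotype.UNAFFECTED: "1",
    Phenotype.UNKNOWN: "0",
}


def read_ped(path: str | Path) -> list[Pedigree]:
    """Read a 6-column linkage-format PED file into pedigrees.

    Whitespace-delimited columns: family, individual, father, mother, sex,
    phenotype.  Parent id ``0`` means "no parent"; phenotype ``2`` affected,
    ``1`` unaffected, ``0``/``-9`` unknown (both conventions circulate).
    Extra columns are ignored with a warning.  Families are returned in
    first-appearance order.
    """
    path = Path(path)
    families: dict[str, list[Individual]] = {}
    warned_extra = False
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            cols = line.split()
            if len(cols) < 6:
                raise PedParseError(
                    f"{path}:{lineno}: expected >=6 columns, got {len(cols)}"
                )
            if len(cols) > 6 and not warned_extra:
                log.warning("%s:%d: ignoring extra PED columns", path, lineno)
                warned_extra = True
            fam, iid, fid, mid, sex, pheno = cols[:6]
            if pheno not in ("2", "1", "0", "-9"):
                raise PedParseError(
                    f"{path}:{lineno}: unrecognized phenotype code {pheno!r}"
                )
            member = Individual(
                individual_id=iid,
                father_id=None if fid == "0" else fid,
                mother_id=None if mid == "0" else mid,
                sex=_SEX_CODES.get(sex, Sex.UNKNOWN),
                phenotype=_PHENO_CODES.get(pheno, Phenotype.UNKNOWN),
            )
            bucket = families.setdefault(fam, [])
            if any(m.individual_id == iid for m in bucket):
                raise PedigreeError(
                    f"{path}:{lineno}: duplicate individual {iid!r} in family {fam!r}"
                )
            bucket.append(member)
    return [Pedigree(family_id=fam, members=mem) for fam, mem in families.items()]


def write_ped(pedigrees: Iterable[Pedigree], path: str | Path) -> None:
    """Write pedigrees as tab-delimited 6-column PED."""
    path = Path(path)
    with path.open("w") as fh:
        for ped in pedigrees:
            for m in ped.members:
                fh.write(
                    "\t".join(
                        [
                            ped.family_id,
                            m.individual_id,
                            m.father_id or "0",
                            m.mother_id or "0",
                            _SEX_OUT[m.sex],
                            _PHENO_OUT[m.phenotype],
                        ]
                    )
                    + "\n"
                )


def extract_trio(
    ped: Pedigree, proband_id: str
) -> tuple[Individual, Individual, Individual]:
    """Return the (father, mother, proband) trio around ``proband_id``.

    Raises ``KeyError`` if the proband is absent and ``PedigreeError`` if it
    has no recorded parents (a founder has no trio).
    """
    proband = ped.get(proband_id)
    if proband.father_id is None or proband.mother_id is None:
        raise PedigreeError(
            f"individual {proband_id!r} has no recorded parents; trio undefined"
        )
    return ped.get(proband.father_id), ped.get(proband.mother_id), proband


def siblings_of(ped: Pedigree, individual_id: str) -> list[Individual]:
    """Full siblings of ``individual_id``: members sharing both parents.

    Founders and half-siblings are never returned (the screen's families are
    full-sib litters).
    """
    me = ped.get(individual_id)
    if me.is_founder:
        return []
    return [
        m
        for m in ped.members
        if m.individual_id != individual_id
        and m.father_id == me.father_id
        and m.mother_id == me.mother_id
    ]
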