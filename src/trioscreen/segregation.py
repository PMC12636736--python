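"""Segregation consistency of a candidate variant across pedigrees.

This is the computational analogue of targeted Sanger follow-up: genotype
the candidate site in additional family members and ask whether every
observed call is compatible with a fully penetrant autosomal-recessive
model (no phenocopies).  Per individual with a non-missing call:

* affected individuals must be homozygous alternate;
* unaffected individuals must not be homozygous alternate;
* a parent of any affected individual is an obligate carrier and must carry
  at least one alternate allele (het or hom_alt);
* phenotype-unknown individuals contribute no rule (but still count as
  obligate carriers if they parent an affected member).

A family with no evaluable rule (every relevant call missing) is
inconclusive.  Across families, a single inconsistent family excludes the
candidate; support requires every evaluated family consistent and at least
one family with three or more informative calls — exclusion is decisive,
support is provisional.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .pedigree import Pedigree, Phenotype
from .variants import Genotype, GenotypeCall, VariantKey, parse_genotype

__all__ = [
    "GenotypeTable",
    "SegregationVerdict",
    "SegregationStatus",
    "CandidateDecision",
    "Violation",
    "check_recessive_segregation",
    "evaluate_candidate",
    "read_calls_tsv",
    "verdict_to_dict",
]


class SegregationStatus(enum.Enum):
    CONSISTENT = "consistent"
    INCONSISTENT = "inconsistent"
    INCONCLUSIVE = "inconclusive"


class CandidateDecision(enum.Enum):
    SUPPORTED = "supported"
    EXCLUDED = "excluded"
    INCONCLUSIVE = "inconclusive"


@dataclass(frozen=True)
class Violation:
    individual_id: str
    observed: GenotypeCall
    allowed: frozenset[GenotypeCall]


@dataclass
class GenotypeTable:
    """Observed calls for one variant in one family (missing allowed)."""

    variant_key: VariantKey
    calls: dict[str, Genotype] = field(default_factory=dict)

    @classmethod
    def from_calls(
        cls, variant_key: VariantKey, calls: Mapping[str, GenotypeCall | Genotype | str]
    ) -> "GenotypeTable":
        norm: dict[str, Genotype] = {}
        for iid, c in calls.items():
            if isinstance(c, Genotype):
                norm[iid] = c
            elif isinstance(c, GenotypeCall):
                norm[iid] = Genotype(c)
            else:
                norm[iid] = parse_genotype(c)
        return cls(variant_key=variant_key, calls=norm)


@dataclass
class SegregationVerdict:
    status: SegregationStatus
    violations: list[Violation]
    n_informative: int


_ANY = frozenset({GenotypeCall.HOM_REF, GenotypeCall.HET, GenotypeCall.HOM_ALT})
_CARRIER = frozenset({GenotypeCall.HET, GenotypeCall.HOM_ALT})
_NOT_HOM_ALT = frozenset({GenotypeCall.HOM_REF, GenotypeCall.HET})
_HOM_ALT_ONLY = frozenset({GenotypeCall.HOM_ALT})


def _allowed_calls(ped: Pedigree, individual_id: str, obligate: set[str]) -> frozenset:
    """Intersection of all rules that apply to this individual; _ANY if none."""
    m = ped.get(individual_id)
    allowed = _ANY
    if m.phenotype is Phenotype.AFFECTED:
        allowed &= _HOM_ALT_ONLY
    elif m.phenotype is Phenotype.UNAFFECTED:
        allowed &= _NOT_HOM_ALT
    if individual_id in obligate:
        allowed &= _CARRIER
    return allowed


def check_recessive_segregation(
    ped: Pedigree, table: GenotypeTable
) -> SegregationVerdict:
    """Judge one family's calls against the recessive model.

    Raises ``KeyError`` if the table names an individual outside the
    pedigree.  Individuals with a missing call are ignored; an individual
    with a call but no applicable rule (phenotype unknown, not an obligate
    carrier) is uninformative.
    """
    for iid in table.calls:
        ped.get(iid)  # raises KeyError for foreign ids
    obligate = ped.parents_of_affected()
    violations: list[Violation] = []
    n_informative = 0
    for iid, gt in table.calls.items():
        if gt.call is GenotypeCall.MISSING:
            continue
        allowed = _allowed_calls(ped, iid, obligate)
        if allowed == _ANY:
            continue
        n_informative += 1
        if gt.call not in allowed:
            violations.append(Violation(iid, gt.call, allowed))
    if n_informative == 0:
        status = SegregationStatus.INCONCLUSIVE
    elif violations:
        status = SegregationStatus.INCONSISTENT
    else:
        status = SegregationStatus.CONSISTENT
    return SegregationVerdict(
        status=status, violations=violations, n_informative=n_informative
    )


def evaluate_candidate(
    pedigrees: Sequence[Pedigree], tables: Mapping[str, GenotypeTable]
) -> tuple[CandidateDecision, dict[str, SegregationVerdict]]:
    """Combine per-family verdicts into a candidate-level decision.

    ``tables`` maps family id to that family's genotype table; only families
    with a table are evaluated.  Any inconsistent family excludes the
    candidate.  Support requires every evaluated family consistent and at
    least one with n_informative >= 3.  Everything else is inconclusive.
    """
    evaluated = [p for p in pedigrees if p.family_id in tables]
    if not evaluated:
        raise ValueError("evaluate_candidate requires at least one family with calls")
    verdicts = {
        p.family_id: check_recessive_segregation(p, tables[p.family_id])
        for p in evaluated
    }
    statuses = [v.status for v in verdicts.values()]
    if SegregationStatus.INCONSISTENT in statuses:
        decision = CandidateDecision.EXCLUDED
    elif all(s is SegregationStatus.CONSISTENT for s in statuses) and any(
        v.n_informative >= 3 for v in verdicts.values()
    ):
        decision = CandidateDecision.SUPPORTED
    else:
        decision = CandidateDecision.INCONCLUSIVE
    return decision, verdicts


def read_calls_tsv(path: str | Path, variant_key: VariantKey) -> GenotypeTable:
    """Read a two-column (individual, call) TSV into a genotype table."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    for col in ("individual", "call"):
        if col not in df.columns:
            raise ValueError(f"{path}: calls table lacks column {col!r}")
    return GenotypeTable.from_calls(
        variant_key, dict(zip(df["individual"], df["call"]))
    )


def verdict_to_dict(verdict: SegregationVerdict) -> dict:
    return {
        "status": verdict.status.value,
        "n_informative": verdict.n_informative,
        "violations": [
            {
                "individual": v.individual_id,
                "observed": v.observed.value,
                "allowed": sorted(c.value for c in v.allowed),
            }
            for v in verdict.violations
        ],
    }


def write_verdict_json(
    verdict: SegregationVerdict | Mapping[str, SegregationVerdict], path: str | Path
) -> None:
    if isinstance(verdict, SegregationVerdict):
        payload: object = verdict_to_dict(verdict)
    else:
        payload = {fam: verdict_to_dict(v) for fam, v in verdict.items()}
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
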