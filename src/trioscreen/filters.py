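"""Autosomal-recessive trio filters for SNV/indel and copy-number records.

The screen extracts variants whose trio genotype configuration matches a
fully penetrant recessive model with two carrier parents:

* SNV/indel: father het (0/1), mother het (0/1), proband homozygous
  alternate (1/1).  The pattern is deliberately strict — a homozygous-
  alternate parent fails even though it is recessive-compatible, because
  obligate-carrier parents who have produced unaffected offspring must be
  heterozygous.  A permissive mode (parents carry >=1 alternate allele) is
  available behind a flag.
* CNV: deletions only, with copy number 1 in both parents and 0 in the
  proband (a homozygous deletion in the affected child of two hemizygous
  carriers).

Missing calls never pass: absence of evidence excludes a site.  Sex
chromosomes and mitochondria are excluded before testing, since the model
is autosomal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .variants import GenotypeCall, VariantClass, VariantRecord

log = logging.getLogger(__name__)

__all__ = [
    "TrioAssignment",
    "CandidateVariants",
    "TrioAssignmentError",
    "recessive_snv_pass",
    "recessive_cnv_pass",
    "apply_filters",
    "is_autosomal",
]

_NON_AUTOSOMAL = {"x", "y", "mt", "m"}


class TrioAssignmentError(KeyError):
    """A trio sample is absent from a record."""


@dataclass(frozen=True)
class TrioAssignment:
    """Maps the pedigree trio onto VCF sample ids."""

    father_sample: str
    mother_sample: str
    proband_sample: str

    def __post_init__(self) -> None:
        ids = (self.father_sample, self.mother_sample, self.proband_sample)
        if len(set(ids)) != 3:
            raise ValueError(f"trio sample ids must be distinct, got {ids}")

    @property
    def samples(self) -> tuple[str, str, str]:
        return (self.father_sample, self.mother_sample, self.proband_sample)


def is_autosomal(chrom: str) -> bool:
    """True unless ``chrom`` names a sex chromosome or mitochondrion."""
    bare = chrom[3:] if chrom.lower().startswith("chr") else chrom
    return bare.lower() not in _NON_AUTOSOMAL


def _trio_calls(
    record: VariantRecord, trio: TrioAssignment
) -> tuple[GenotypeCall, GenotypeCall, GenotypeCall]:
    try:
        return tuple(record.genotypes[s].call for s in trio.samples)  # type: ignore[return-value]
    except KeyError as e:
        raise TrioAssignmentError(
            f"sample {e.args[0]!r} absent from record {record.chrom}:{record.pos}"
        ) from None


def recessive_snv_pass(
    record: VariantRecord, trio: TrioAssignment, permissive_parents: bool = False
) -> bool:
    """True iff the trio genotypes match the recessive extraction pattern.

    Strict (default): father het AND mother het AND proband hom_alt.
    Permissive: each parent carries at least one alternate allele (het or
    hom_alt) and the proband is hom_alt.  Any missing genotype fails.
    """
    if record.variant_class.is_cnv:
        raise ValueError("recessive_snv_pass expects an SNV/indel record")
    father, mother, proband = _trio_calls(record, trio)
    if proband is not GenotypeCall.HOM_ALT:
        return False
    if permissive_parents:
        carrier = (GenotypeCall.HET, GenotypeCall.HOM_ALT)
        return father in carrier and mother in carrier
    return father is GenotypeCall.HET and mother is GenotypeCall.HET


def recessive_cnv_pass(record: VariantRecord, trio: TrioAssignment) -> bool:
    """True iff the record is a deletion with CN 1/1/0 (father/mother/proband).

    A missing copy-number value fails (logged), never raises.
    """
    if not record.variant_class.is_cnv:
        raise ValueError("recessive_cnv_pass expects a CNV record")
    if record.variant_class is not VariantClass.CNV_DELETION:
        return False
    missing = [s for s in trio.samples if s not in record.copy_numbers]
    if missing:
        raise TrioAssignmentError(
            f"sample(s) {missing} absent from CNV record {record.chrom}:{record.pos}"
        )
    cns = [record.copy_numbers[s] for s in trio.samples]
    if any(cn is None for cn in cns):
        log.info(
            "CNV %s:%d-%d: missing copy number for trio; excluded",
            record.chrom,
            record.pos,
            record.end or record.pos,
        )
        return False
    father_cn, mother_cn, proband_cn = cns
    return father_cn == 1 and mother_cn == 1 and proband_cn == 0


@dataclass
class CandidateVariants:
    """Filter survivors, partitioned by record class, with per-class counts."""

    snv_indel: list[VariantRecord] = field(default_factory=list)
    cnv: list[VariantRecord] = field(default_factory=list)
    n_examined_snv: int = 0
    n_examined_cnv: int = 0
    n_skipped_non_autosomal: int = 0
    n_skipped_filtered: int = 0

    @property
    def all_records(self) -> list[VariantRecord]:
        return self.snv_indel + self.cnv


def apply_filters(
    records: Iterable[VariantRecord],
    trio: TrioAssignment,
    pass_only: bool = False,
    permissive_parents: bool = False,
    chromosome_allowlist: Sequence[str] | None = None,
) -> CandidateVariants:
    """Run both recessive filters over a record stream, preserving order.

    ``chromosome_allowlist=None`` applies the default autosomal rule
    (exclude X/Y/MT); an explicit allow-list restricts to those names.
    ``pass_only`` additionally drops records whose FILTER is not PASS.
    """
    allowed = set(chromosome_allowlist) if chromosome_allowlist is not None else None
    out = CandidateVariants()
    for rec in records:
        if allowed is not None:
            if rec.chrom not in allowed:
                out.n_skipped_non_autosomal += 1
                continue
        elif not is_autosomal(rec.chrom):
            out.n_skipped_non_autosomal += 1
            continue
        if pass_only and not rec.is_pass:
            out.n_skipped_filtered += 1
            continue
        if rec.variant_class.is_cnv:
            out.n_examined_cnv += 1
            if recessive_cnv_pass(rec, trio):
                out.cnv.append(rec)
        else:
            out.n_examined_snv += 1
            if recessive_snv_pass(rec, trio, permissive_parents=permissive_parents):
                out.snv_indel.append(rec)
    log.info(
        "recessive filters: %d/%d SNV/indel and %d/%d CNV records passed "
        "(%d non-autosomal, %d non-PASS skipped)",
        len(out.snv_indel),
        out.n_examined_snv,
        len(out.cnv),
        out.n_examined_cnv,
        out.n_skipped_non_autosomal,
        out.n_skipped_filtered,
    )
    return out
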