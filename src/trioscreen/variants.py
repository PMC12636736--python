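"""VCF records for SNV/indel and copy-number sites, plus consequence tables.

SNV/indel records carry per-sample diploid genotypes restricted to biallelic
coding (multiallelic input lines are split, one output record per alternate
allele).  Copy-number records come from symbolic ``<DEL>``/``<DUP>`` alleles
with a per-sample ``CN`` FORMAT field; the recessive CNV filter consumes the
CN values only, never the GT of a symbolic record.  Coordinates are 1-based
inclusive throughout (VCF convention).

Consequence annotations are VEP-style rows keyed by (chrom, pos, ref, alt)
and gene, each carrying one or more Sequence Ontology terms.
"""

from __future__ import annotations

import enum
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd
import pysam

log = logging.getLogger(__name__)

__all__ = [
    "GenotypeCall",
    "Genotype",
    "VariantClass",
    "VariantRecord",
    "ConsequenceAnnotation",
    "GenotypeParseError",
    "MultiallelicGenotypeError",
    "VcfFormatError",
    "VcfHeaderError",
    "parse_genotype",
    "read_vcf",
    "write_vcf",
    "read_consequences",
    "write_consequences",
    "normalize_chrom",
]

VariantKey = tuple[str, int, str, str]


class GenotypeParseError(ValueError):
    """A genotype string could not be interpreted."""


class MultiallelicGenotypeError(GenotypeParseError):
    """A genotype string carries an allele index > 1 (multiallelic leak)."""


class VcfFormatError(ValueError):
    """A VCF record violates the expected structure."""


class VcfHeaderError(ValueError):
    """The VCF header lacks an expected sample."""


class GenotypeCall(enum.Enum):
    HOM_REF = "hom_ref"
    HET = "het"
    HOM_ALT = "hom_alt"
    MISSING = "missing"


@dataclass(frozen=True)
class Genotype:
    """A diploid biallelic call; phase is carried but never changes the call."""

    call: GenotypeCall
    phased: bool = False


_GT_RE = re.compile(r"^([0-9.]+)([/|])([0-9.]+)$")


def parse_genotype(gt_string: str) -> Genotype:
    """Parse a VCF GT string into a biallelic :class:`Genotype`.

    ``0/0`` -> hom_ref, ``0/1``/``1/0`` -> het, ``1/1`` -> hom_alt; ``|``
    separators set the phased flag.  ``.`` tokens (``./.``, ``.``, ``.|.``
    and any half-missing call such as ``./1``) map to missing — a partial
    call is treated conservatively as no call.  Allele indices above 1 raise
    :class:`MultiallelicGenotypeError`.
    """
    if gt_string in (".", "./.", ".|."):
        return Genotype(GenotypeCall.MISSING, phased="|" in gt_string)
    m = _GT_RE.match(gt_string)
    if m is None:
        raise GenotypeParseError(f"malformed genotype string {gt_string!r}")
    a, sep, b = m.groups()
    phased = sep == "|"
    alleles: list[int | None] = []
    for tok in (a, b):
        if tok == ".":
            alleles.append(None)
            continue
        try:
            idx = int(tok)
        except ValueError:
            raise GenotypeParseError(f"malformed genotype string {gt_string!r}") from None
        if idx > 1:
            raise MultiallelicGenotypeError(
                f"allele index {idx} in {gt_string!r}: biallelic coding expected"
            )
        alleles.append(idx)
    return Genotype(_call_from_alleles(alleles), phased=phased)


def _call_from_alleles(alleles: Sequence[int | None]) -> GenotypeCall:
    if any(a is None for a in alleles):
        return GenotypeCall.MISSING
    total = sum(alleles)  # type: ignore[arg-type]
    return (GenotypeCall.HOM_REF, GenotypeCall.HET, GenotypeCall.HOM_ALT)[total]


class VariantClass(enum.Enum):
    SNV = "snv"
    INDEL = "indel"
    CNV_DELETION = "cnv_deletion"
    CNV_DUPLICATION = "cnv_duplication"

    @property
    def is_cnv(self) -> bool:
        return self in (VariantClass.CNV_DELETION, VariantClass.CNV_DUPLICATION)


@dataclass
class VariantRecord:
    """One biallelic variant site with per-sample calls.

    Non-CNV records carry ``genotypes`` for every sample; CNV records carry
    ``copy_numbers`` (``None`` for a sample with no CN value) and a 1-based
    inclusive ``end``.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    variant_class: VariantClass
    genotypes: dict[str, Genotype] = field(default_factory=dict)
    copy_numbers: dict[str, int | None] = field(default_factory=dict)
    end: int | None = None
    filters: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.variant_class is VariantClass.SNV:
            if len(self.ref) != 1 or len(self.alt) != 1 or self.ref == self.alt:
                raise VcfFormatError(
                    f"{self.chrom}:{self.pos}: SNV requires single differing "
                    f"ref/alt bases, got {self.ref!r}>{self.alt!r}"
                )
        if self.variant_class.is_cnv:
            if self.end is None or self.end < self.pos:
                raise VcfFormatError(
                    f"{self.chrom}:{self.pos}: CNV record requires end >= pos"
                )

    @property
    def key(self) -> VariantKey:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_pass(self) -> bool:
        """True when the FILTER column is PASS or absent."""
        return self.filters == () or self.filters == ("PASS",)

    @property
    def samples(self) -> set[str]:
        return set(self.copy_numbers if self.variant_class.is_cnv else self.genotypes)


@dataclass(frozen=True)
class ConsequenceAnnotation:
    """Sequence Ontology consequence terms for one (variant, gene) pair."""

    variant_key: VariantKey
    gene_id: str
    consequence_terms: frozenset[str]

    def __post_init__(self) -> None:
        if not self.consequence_terms:
            raise ValueError("consequence_terms must be non-empty")


def normalize_chrom(name: str, prefix: str | None = None) -> str:
    """Normalize a chromosome name's ``chr`` prefix.

    ``prefix=None`` keeps the name verbatim; ``prefix=""`` strips a leading
    ``chr``; ``prefix="chr"`` ensures it is present.
    """
    if prefix is None:
        return name
    bare = name[3:] if name.lower().startswith("chr") else name
    return prefix + bare


def _snv_or_indel(ref: str, alt: str) -> VariantClass:
    if len(ref) == 1 and len(alt) == 1:
        return VariantClass.SNV
    return VariantClass.INDEL


def _recode_gt(
    gt: tuple[int | None, ...] | None, alt_index: int
) -> Sequence[int | None]:
    """Recode a possibly multiallelic GT tuple against one alternate allele.

    Reference stays 0, the chosen alt becomes 1, and any other alternate
    allele makes the genotype missing (the call is uninformative for this
    biallelic record).
    """
    if gt is None:
        return (None, None)
    out: list[int | None] = []
    for a in gt:
        if a is None:
            out.append(None)
        elif a == 0:
            out.append(0)
        elif a == alt_index:
            out.append(1)
        else:
            return (None, None)
    return out


def read_vcf(
    path: str | Path,
    sample_ids: Sequence[str] | None = None,
    chrom_prefix: str | None = None,
) -> Iterator[VariantRecord]:
    """Stream VariantRecords from a VCF 4.x file (plain or bgzipped).

    Multiallelic lines are split into one biallelic record per alternate
    allele, genotypes recoded against that allele; genotypes carrying a
    different alternate become missing.  Symbolic ``<DEL>``/``<DUP>`` lines
    become CNV records with per-sample copy numbers from FORMAT/CN and the
    end coordinate from INFO/END (a symbolic record without an explicit END
    raises :class:`VcfFormatError`; consequently symbolic records must span
    more than one base).

    If ``sample_ids`` is given, every id must be present in the header.
    """
    path = Path(path)
    with pysam.VariantFile(str(path)) as vf:
        header_samples = list(vf.header.samples)
        if sample_ids is not None:
            missing = [s for s in sample_ids if s not in header_samples]
            if missing:
                raise VcfHeaderError(f"{path}: samples absent from header: {missing}")
            wanted = list(sample_ids)
        else:
            wanted = header_samples
        for rec in vf:
            yield from _convert_record(rec, wanted, chrom_prefix)


def _convert_record(
    rec: "pysam.VariantRecord", samples: Sequence[str], chrom_prefix: str | None
) -> Iterator[VariantRecord]:
    chrom = normalize_chrom(rec.chrom, chrom_prefix)
    filters = tuple(rec.filter.keys())
    alts = rec.alts or ()
    for alt_index, alt in enumerate(alts, start=1):
        if alt in ("<DEL>", "<DUP>"):
            # pysam folds INFO/END into rec.stop; without END, stop falls
            # back to pos + len(ref) - 1, which a true SV interval exceeds.
            end = rec.stop
            if end <= rec.pos + len(rec.ref) - 1:
                raise VcfFormatError(
                    f"{chrom}:{rec.pos}: symbolic {alt} record lacks INFO/END"
                )
            cns: dict[str, int | None] = {}
            for s in samples:
                cn = rec.samples[s].get("CN")
                cns[s] = int(cn) if cn is not None else None
            yield VariantRecord(
                chrom=chrom,
                pos=rec.pos,
                ref=rec.ref,
                alt=alt,
                variant_class=(
                    VariantClass.CNV_DELETION
                    if alt == "<DEL>"
                    else VariantClass.CNV_DUPLICATION
                ),
                copy_numbers=cns,
                end=end,
                filters=filters,
            )
            continue
        gts: dict[str, Genotype] = {}
        for s in samples:
            smp = rec.samples[s]
            alleles = _recode_gt(smp.get("GT"), alt_index)
            gts[s] = Genotype(_call_from_alleles(alleles), phased=bool(smp.phased))
        yield VariantRecord(
            chrom=chrom,
            pos=rec.pos,
            ref=rec.ref,
            alt=alt,
            variant_class=_snv_or_indel(rec.ref, alt),
            genotypes=gts,
            filters=filters,
        )


_CALL_TO_ALLELES = {
    GenotypeCall.HOM_REF: (0, 0),
    GenotypeCall.HET: (0, 1),
    GenotypeCall.HOM_ALT: (1, 1),
    GenotypeCall.MISSING: (None, None),
}


def write_vcf(
    records: Iterable[VariantRecord],
    path: str | Path,
    sample_ids: Sequence[str],
    contigs: Mapping[str, int] | None = None,
) -> None:
    """Write records as a VCF 4.2 file readable by :func:`read_vcf`.

    ``contigs`` maps contig name to length; contigs seen only in records get
    a generous default length so coordinates always fit.
    """
    records = list(records)
    path = Path(path)
    header = pysam.VariantHeader()
    seen: dict[str, int] = dict(contigs or {})
    for r in records:
        seen.setdefault(r.chrom, 500_000_000)
    for name, length in seen.items():
        header.contigs.add(name, length=length)
    header.info.add("END", 1, "Integer", "End position (1-based inclusive)")
    header.info.add("SVTYPE", 1, "String", "Structural variant type")
    for r in records:
        for f in r.filters:
            if f != "PASS" and f not in header.filters:
                header.filters.add(f, None, None, "Site filter")
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("CN", 1, "Integer", "Copy number")
    for s in sample_ids:
        header.add_sample(s)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for r in records:
            kwargs = {"contig": r.chrom, "start": r.pos - 1, "alleles": (r.ref, r.alt)}
            if r.variant_class.is_cnv:
                kwargs["stop"] = r.end
            rec = out.new_record(**kwargs)
            for f in r.filters:
                rec.filter.add(f)
            if r.variant_class.is_cnv:
                rec.stop = r.end
                rec.info["SVTYPE"] = (
                    "DEL" if r.variant_class is VariantClass.CNV_DELETION else "DUP"
                )
                for s in sample_ids:
                    cn = r.copy_numbers.get(s)
                    if cn is not None:
                        rec.samples[s]["CN"] = cn
            else:
                for s in sample_ids:
                    g = r.genotypes[s]
                    rec.samples[s]["GT"] = _CALL_TO_ALLELES[g.call]
                    rec.samples[s].phased = g.phased
            out.write(rec)


_CONSEQ_COLUMNS = ["chrom", "pos", "ref", "alt", "gene_id", "consequence_terms"]


def read_consequences(path: str | Path) -> list[ConsequenceAnnotation]:
    """Read a VEP-style TSV of consequence annotations.

    Columns: chrom, pos, ref, alt, gene_id, consequence_terms (comma-
    separated Sequence Ontology terms).  Unknown terms are retained verbatim
    (the impact classifier downgrades them later).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    missing = [c for c in _CONSEQ_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: annotation table lacks column(s) {missing}")
    out = []
    for row in df.itertuples(index=False):
        terms = frozenset(t.strip() for t in row.consequence_terms.split(",") if t.strip())
        out.append(
            ConsequenceAnnotation(
                variant_key=(row.chrom, int(row.pos), row.ref, row.alt),
                gene_id=row.gene_id,
                consequence_terms=terms,
            )
        )
    return out


def write_consequences(
    annotations: Iterable[ConsequenceAnnotation], path: str | Path
) -> None:
    rows = [
        {
            "chrom": a.variant_key[0],
            "pos": a.variant_key[1],
            "ref": a.variant_key[2],
            "alt": a.variant_key[3],
            "gene_id": a.gene_id,
            "consequence_terms": ",".join(sorted(a.consequence_terms)),
        }
        for a in annotations
    ]
    pd.DataFrame(rows, columns=_CONSEQ_COLUMNS).to_csv(path, sep="\t", index=False)
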