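"""Impact triage and gene-level aggregation of filter survivors.

Consequence terms are mapped to the four-tier HIGH/MODERATE/LOW/MODIFIER
impact scale through a frozen in-repo copy of the public VEP Sequence
Ontology taxonomy, so tier counts are reproducible offline and do not drift
with annotation-tool releases.  A variant's tier is the maximum over its
terms; a variant annotated against several genes appears in each gene's
candidate list but counts once in the tier tally (variant counts and gene
counts are separate bookkeeping).  CNV deletion survivors are assigned HIGH
impact for every gene they overlap — a homozygous deletion ablates the
transcript.
"""

from __future__ import annotations

import enum
import functools
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from intervaltree import IntervalTree

from .filters import CandidateVariants
from .variants import ConsequenceAnnotation, VariantKey, VariantRecord

log = logging.getLogger(__name__)

__all__ = [
    "ImpactClass",
    "GeneCandidate",
    "GeneMap",
    "TierTally",
    "TriageReport",
    "SO_IMPACT",
    "classify_impact",
    "genes_overlapping",
    "aggregate_by_gene",
    "read_bed",
    "write_report",
]


@functools.total_ordering
class ImpactClass(enum.Enum):
    """VEP-style impact tier with total order high > moderate > low > modifier."""

    MODIFIER = 0
    LOW = 1
    MODERATE = 2
    HIGH = 3

    def __lt__(self, other: "ImpactClass") -> bool:
        if not isinstance(other, ImpactClass):
            return NotImplemented
        return self.value < other.value

    def __str__(self) -> str:
        return self.name.lower()


# Frozen Sequence Ontology term -> impact table (public VEP taxonomy).
SO_IMPACT: Mapping[str, ImpactClass] = {
    # HIGH
    "transcript_ablation": ImpactClass.HIGH,
    "splice_acceptor_variant": ImpactClass.HIGH,
    "splice_donor_variant": ImpactClass.HIGH,
    "stop_gained": ImpactClass.HIGH,
    "frameshift_variant": ImpactClass.HIGH,
    "stop_lost": ImpactClass.HIGH,
    "start_lost": ImpactClass.HIGH,
    "transcript_amplification": ImpactClass.HIGH,
    "feature_elongation": ImpactClass.HIGH,
    "feature_truncation": ImpactClass.HIGH,
    # MODERATE
    "inframe_insertion": ImpactClass.MODERATE,
    "inframe_deletion": ImpactClass.MODERATE,
    "missense_variant": ImpactClass.MODERATE,
    "protein_altering_variant": ImpactClass.MODERATE,
    # LOW
    "splice_donor_5th_base_variant": ImpactClass.LOW,
    "splice_region_variant": ImpactClass.LOW,
    "splice_donor_region_variant": ImpactClass.LOW,
    "splice_polypyrimidine_tract_variant": ImpactClass.LOW,
    "incomplete_terminal_codon_variant": ImpactClass.LOW,
    "start_retained_variant": ImpactClass.LOW,
    "stop_retained_variant": ImpactClass.LOW,
    "synonymous_variant": ImpactClass.LOW,
    # MODIFIER
    "coding_sequence_variant": ImpactClass.MODIFIER,
    "mature_miRNA_variant": ImpactClass.MODIFIER,
    "5_prime_UTR_variant": ImpactClass.MODIFIER,
    "3_prime_UTR_variant": ImpactClass.MODIFIER,
    "non_coding_transcript_exon_variant": ImpactClass.MODIFIER,
    "intron_variant": ImpactClass.MODIFIER,
    "NMD_transcript_variant": ImpactClass.MODIFIER,
    "non_coding_transcript_variant": ImpactClass.MODIFIER,
    "coding_transcript_variant": ImpactClass.MODIFIER,
    "upstream_gene_variant": ImpactClass.MODIFIER,
    "downstream_gene_variant": ImpactClass.MODIFIER,
    "TFBS_ablation": ImpactClass.MODIFIER,
    "TFBS_amplification": ImpactClass.MODIFIER,
    "TF_binding_site_variant": ImpactClass.MODIFIER,
    "regulatory_region_ablation": ImpactClass.MODIFIER,
    "regulatory_region_amplification": ImpactClass.MODIFIER,
    "regulatory_region_variant": ImpactClass.MODIFIER,
    "intergenic_variant": ImpactClass.MODIFIER,
    "sequence_variant": ImpactClass.MODIFIER,
}


def classify_impact(terms: Iterable[str]) -> ImpactClass:
    """Maximum impact tier over a non-empty set of SO consequence terms.

    Unknown terms map to MODIFIER with a warning, so novel annotation
    vocabulary can never silently promote a variant.
    """
    terms = list(terms)
    if not terms:
        raise ValueError("classify_impact requires a non-empty term set")
    best = ImpactClass.MODIFIER
    for t in terms:
        impact = SO_IMPACT.get(t)
        if impact is None:
            log.warning("unknown consequence term %r treated as MODIFIER", t)
            impact = ImpactClass.MODIFIER
        best = max(best, impact)
    return best


@dataclass(frozen=True)
class GeneInterval:
    """A gene footprint in 0-based half-open BED coordinates."""

    chrom: str
    start: int
    end: int
    gene_id: str


class GeneMap:
    """Gene intervals indexed for overlap queries (0-based half-open)."""

    def __init__(self, intervals: Iterable[GeneInterval] | Iterable[tuple]):
        self.intervals: list[GeneInterval] = [
            g if isinstance(g, GeneInterval) else GeneInterval(*g) for g in intervals
        ]
        self._trees: dict[str, IntervalTree] = {}
        for g in self.intervals:
            self._trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end, g)

    def __len__(self) -> int:
        return len(self.intervals)

    def overlapping(self, chrom: str, start0: int, end0: int) -> list[GeneInterval]:
        """Genes overlapping [start0, end0) by >=1 base, sorted by (start, gene_id)."""
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        hits = [iv.data for iv in tree.overlap(start0, end0)]
        return sorted(hits, key=lambda g: (g.start, g.gene_id))

    def containing(self, chrom: str, pos1: int) -> list[GeneInterval]:
        """Genes containing the 1-based position ``pos1``."""
        return self.overlapping(chrom, pos1 - 1, pos1)


def read_bed(path: str | Path) -> GeneMap:
    """Read a BED file (chrom, start, end, name) into a :class:`GeneMap`."""
    intervals = []
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 4:
                raise ValueError(f"{path}:{lineno}: BED row needs >=4 columns")
            intervals.append(
                GeneInterval(cols[0], int(cols[1]), int(cols[2]), cols[3])
            )
    return GeneMap(intervals)


def write_bed(gene_map: GeneMap, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for g in sorted(gene_map.intervals, key=lambda g: (g.chrom, g.start, g.gene_id)):
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\n")


def genes_overlapping(cnv: VariantRecord, gene_map: GeneMap) -> list[str]:
    """Gene ids whose interval overlaps a CNV record by at least one base.

    The record's 1-based inclusive [pos, end] span is converted to 0-based
    half-open [pos-1, end) for the intersection.  Ordering is deterministic:
    (chrom, start, gene_id).  A chromosome absent from the map yields an
    empty set with a warning.
    """
    if cnv.end is None:
        raise ValueError("genes_overlapping requires a record with an end coordinate")
    hits = gene_map.overlapping(cnv.chrom, cnv.pos - 1, cnv.end)
    if not hits and cnv.chrom not in gene_map._trees:
        log.warning("chromosome %r not present in gene map", cnv.chrom)
    return [g.gene_id for g in hits]


@dataclass
class GeneCandidate:
    """A gene with at least one surviving variant."""

    gene_id: str
    variants: list[tuple[VariantKey, ImpactClass]]

    @property
    def max_impact(self) -> ImpactClass:
        return max(impact for _, impact in self.variants)

    @property
    def n_variants(self) -> int:
        return len(self.variants)


@dataclass
class TierTally:
    """Distinct surviving annotated variants per impact tier."""

    high: int = 0
    moderate: int = 0
    low: int = 0
    modifier: int = 0

    def add(self, impact: ImpactClass) -> None:
        setattr(self, str(impact), getattr(self, str(impact)) + 1)

    @property
    def total(self) -> int:
        return self.high + self.moderate + self.low + self.modifier

    def as_dict(self) -> dict[str, int]:
        return {
            "high": self.high,
            "moderate": self.moderate,
            "low": self.low,
            "modifier": self.modifier,
        }


@dataclass
class TriageReport:
    genes: list[GeneCandidate]
    tally: TierTally
    unannotated: list[VariantKey] = field(default_factory=list)

    def gene(self, gene_id: str) -> GeneCandidate | None:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        return None


def aggregate_by_gene(
    candidates: CandidateVariants,
    annotations: Iterable[ConsequenceAnnotation],
    gene_map: GeneMap,
) -> TriageReport:
    """Group surviving variants by gene and tally impact tiers.

    SNV/indel survivors are joined to their consequence annotations by
    variant key; per-gene impact is classified from that gene's terms, while
    the tier tally takes each variant's maximum over all its annotations
    (once per variant).  CNV survivors contribute HIGH impact to every
    overlapped gene and count once in the HIGH tally when they hit at least
    one gene.  Survivors with no annotation (or CNVs overlapping no gene)
    are reported separately, not tallied.  Genes are sorted by descending
    max impact, then gene id.
    """
    by_key: dict[VariantKey, list[ConsequenceAnnotation]] = {}
    for ann in annotations:
        by_key.setdefault(ann.variant_key, []).append(ann)

    gene_variants: dict[str, list[tuple[VariantKey, ImpactClass]]] = {}
    tally = TierTally()
    unannotated: list[VariantKey] = []

    for rec in candidates.snv_indel:
        anns = by_key.get(rec.key)
        if not anns:
            unannotated.append(rec.key)
            continue
        per_gene = {a.gene_id: classify_impact(a.consequence_terms) for a in anns}
        for gene_id, impact in per_gene.items():
            gene_variants.setdefault(gene_id, []).append((rec.key, impact))
        tally.add(max(per_gene.values()))

    for rec in candidates.cnv:
        genes = genes_overlapping(rec, gene_map)
        if not genes:
            unannotated.append(rec.key)
            continue
        for gene_id in genes:
            gene_variants.setdefault(gene_id, []).append((rec.key, ImpactClass.HIGH))
        tally.add(ImpactClass.HIGH)
        log.info(
            "CNV survivor %s:%d-%d assigned HIGH impact in gene(s) %s",
            rec.chrom,
            rec.pos,
            rec.end or rec.pos,
            ",".join(genes),
        )

    genes = [GeneCandidate(gene_id=g, variants=v) for g, v in gene_variants.items()]
    genes.sort(key=lambda g: (-g.max_impact.value, g.gene_id))
    return TriageReport(genes=genes, tally=tally, unannotated=unannotated)


def write_report(report: TriageReport, path: str | Path) -> None:
    """Write the gene-level candidate report as TSV."""
    with Path(path).open("w") as fh:
        fh.write("gene_id\tmax_impact\tn_variants\tvariant_keys\n")
        for g in report.genes:
            keys = ";".join(f"{c}:{p}:{r}>{a}" for (c, p, r, a), _ in g.variants)
            fh.write(f"{g.gene_id}\t{g.max_impact}\t{g.n_variants}\t{keys}\n")
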