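"""Synthetic nuclear-family WGS-like data for the recessive screen.

The generator emulates the study design the screen was built for: two
carrier parents and a litter of offspring (default four: two affected, two
unaffected), genome-wide biallelic background SNVs in Hardy–Weinberg
proportions, one planted fully penetrant recessive causal SNV (both parents
forced heterozygous), planted recessive copy-number deletions, and a
VEP-like consequence table.  Sites are unlinked (no recombination/LD) —
the filters under test are single-site.  Everything is reproducible from
the seed: the same configuration writes byte-identical fixtures.

Observed genotypes may carry simulated genotyping error; the error-free
truth is kept separately so error-sensitivity experiments can quantify
filter dropout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .pedigree import Individual, Pedigree, Phenotype, Sex, write_ped
from .triage import GeneInterval, GeneMap, write_bed
from .variants import (
    ConsequenceAnnotation,
    Genotype,
    GenotypeCall,
    VariantClass,
    VariantRecord,
    write_consequences,
    write_vcf,
)

__all__ = ["SimulationConfig", "SimulatedFamily", "simulate_family", "write_fixture"]

_CALLS = (GenotypeCall.HOM_REF, GenotypeCall.HET, GenotypeCall.HOM_ALT)

# Background consequence vocabulary: mostly modifier/low, a minority
# moderate/high, so triage tallies are nontrivial.
_BACKGROUND_TERMS = (
    ("intron_variant", 0.455),
    ("upstream_gene_variant", 0.08),
    ("downstream_gene_variant", 0.07),
    ("synonymous_variant", 0.20),
    ("splice_region_variant", 0.03),
    ("missense_variant", 0.14),
    ("stop_gained", 0.015),
    ("splice_donor_variant", 0.005),
    ("stop_lost", 0.005),
)

_N_AUTOSOMES = 20  # rat karyotype: chr1..chr20 autosomes
_GENES_PER_CHROM = 15
_GENE_LENGTH = 100_000
_GENE_SPACING = 2_000_000
_CONTIG_LENGTH = 40_000_000


def default_gene_map() -> list[GeneInterval]:
    """A regular lattice of genes over the 20 rat autosomes (BED coordinates)."""
    genes = []
    for c in range(1, _N_AUTOSOMES + 1):
        for i in range(_GENES_PER_CHROM):
            start = 1_000_000 + i * _GENE_SPACING
            genes.append(
                GeneInterval(f"chr{c}", start, start + _GENE_LENGTH, f"G{c:02d}.{i:02d}")
            )
    return genes


@dataclass
class SimulationConfig:
    """Parameters of one simulated family experiment.

    ``n_affected_offspring`` conditions the causal-site transmissions so the
    litter contains exactly that many homozygous-alternate offspring
    (matching the ascertained family structure); ``None`` leaves causal
    transmission unconditioned.  Background sites are never conditioned.
    """

    seed: int = 0
    n_background_snvs: int = 2000
    founder_alt_freq: float = 0.2
    n_offspring: int = 4
    n_cnv_background: int = 20
    cnv_deletion_freq: float = 0.15
    genotyping_error_rate: float = 0.0
    gene_map: list[GeneInterval] = field(default_factory=default_gene_map)
    causal_site: tuple[str, int, str] | None = None  # (chrom, pos, gene_id)
    causal_term: str = "stop_gained"
    penetrance: float = 1.0
    n_affected_offspring: int | None = 2
    family_id: str = "FAM1"

    def __post_init__(self) -> None:
        for name in ("founder_alt_freq", "cnv_deletion_freq", "genotyping_error_rate", "penetrance"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("n_background_snvs", "n_cnv_background"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_offspring < 1:
            raise ValueError("n_offspring must be >= 1")
        if self.n_affected_offspring is not None and not (
            1 <= self.n_affected_offspring <= self.n_offspring
        ):
            raise ValueError("n_affected_offspring must be in [1, n_offspring]")
        if not self.gene_map:
            raise ValueError("gene_map must be non-empty")
        if self.causal_site is None:
            # default: the midpoint of a fixed gene near the middle of the map
            g = self.gene_map[len(self.gene_map) // 2]
            self.causal_site = (g.chrom, (g.start + g.end) // 2, g.gene_id)
        chrom, pos, gene_id = self.causal_site
        if not any(
            g.chrom == chrom and g.start < pos <= g.end and g.gene_id == gene_id
            for g in self.gene_map
        ):
            raise ValueError(
                f"causal_site {self.causal_site} does not fall inside its gene interval"
            )

    @property
    def sample_ids(self) -> list[str]:
        return ["FA", "MO"] + [f"C{i + 1}" for i in range(self.n_offspring)]


@dataclass
class SimulatedFamily:
    """One simulated experiment: inputs plus ground truth."""

    config: SimulationConfig
    pedigree: Pedigree
    records: list[VariantRecord]
    annotations: list[ConsequenceAnnotation]
    gene_map: GeneMap
    truth: dict

    @property
    def sample_ids(self) -> list[str]:
        return self.config.sample_ids


def _chrom_sort_key(chrom: str, pos: int) -> tuple[int, int]:
    bare = chrom[3:] if chrom.startswith("chr") else chrom
    return (int(bare), pos)


def _weighted_choice(rng: np.random.Generator, table: Sequence[tuple[str, float]]) -> str:
    names = [t for t, _ in table]
    weights = np.array([w for _, w in table])
    return names[int(rng.choice(len(names), p=weights / weights.sum()))]


def simulate_family(config: SimulationConfig) -> SimulatedFamily:
    """Simulate one family's pedigree, variants, annotations and truth.

    Founder background genotypes are Hardy–Weinberg draws at the configured
    alternate-allele frequency; each offspring inherits one uniformly chosen
    haplotype per parent per site (unlinked).  Both founders are forced
    heterozygous at the causal site; an offspring is affected iff it is
    homozygous alternate there and a penetrance draw succeeds.  Copy-number
    deletions are transmitted as per-haplotype 0/1 deletion alleles with
    copy number ``2 - (deleted haplotypes)``; one planted deletion follows
    the recessive pattern with the proband forced to copy number 0.
    Genotyping error flips each observed SNV call to a uniformly chosen
    different (non-missing) call with the configured probability.
    """
    rng = np.random.default_rng(config.seed)
    cfg = config
    gene_map = GeneMap(cfg.gene_map)
    samples = cfg.sample_ids
    n_off = cfg.n_offspring

    # --- SNV sites -----------------------------------------------------
    causal_chrom, causal_pos, causal_gene = cfg.causal_site
    sites: list[tuple[str, int, GeneInterval]] = []
    seen = {(causal_chrom, causal_pos)}
    genes = cfg.gene_map
    while len(sites) < cfg.n_background_snvs:
        g = genes[int(rng.integers(len(genes)))]
        pos = int(rng.integers(g.start + 1, g.end + 1))  # 1-based within gene
        if (g.chrom, pos) in seen:
            continue
        seen.add((g.chrom, pos))
        sites.append((g.chrom, pos, g))
    causal_interval = next(
        g for g in genes if g.gene_id == causal_gene and g.chrom == causal_chrom
    )
    sites.append((causal_chrom, causal_pos, causal_interval))
    order = sorted(range(len(sites)), key=lambda i: _chrom_sort_key(sites[i][0], sites[i][1]))
    sites = [sites[i] for i in order]
    n_sites = len(sites)
    causal_idx = next(
        i for i, (c, p, _) in enumerate(sites) if (c, p) == (causal_chrom, causal_pos)
    )

    # founder haplotypes: [parent, haplotype, site]
    founder = (rng.random((2, 2, n_sites)) < cfg.founder_alt_freq).astype(np.int8)
    founder[:, 0, causal_idx] = 0  # both parents obligate het at the causal site
    founder[:, 1, causal_idx] = 1

    # offspring transmissions: each child picks one haplotype per parent per site
    picks = rng.integers(0, 2, size=(n_off, 2, n_sites))
    if cfg.n_affected_offspring is not None:
        # condition the causal-site transmission vector on the litter's
        # ascertained composition (rejection sampling)
        for _ in range(100_000):
            col = picks[:, :, causal_idx]
            hom_alt = (founder[0, col[:, 0], causal_idx] + founder[1, col[:, 1], causal_idx]) == 2
            if int(hom_alt.sum()) == cfg.n_affected_offspring:
                break
            picks[:, :, causal_idx] = rng.integers(0, 2, size=(n_off, 2))
        else:  # pragma: no cover
            raise RuntimeError("causal-site conditioning did not converge")

    site_idx = np.arange(n_sites)
    child_alleles = np.empty((n_off, 2, n_sites), dtype=np.int8)
    for k in range(n_off):
        child_alleles[k, 0] = founder[0, picks[k, 0], site_idx]
        child_alleles[k, 1] = founder[1, picks[k, 1], site_idx]

    # true calls per individual (0=hom_ref, 1=het, 2=hom_alt)
    true_calls = np.empty((2 + n_off, n_sites), dtype=np.int8)
    true_calls[0] = founder[0].sum(axis=0)
    true_calls[1] = founder[1].sum(axis=0)
    for k in range(n_off):
        true_calls[2 + k] = child_alleles[k].sum(axis=0)

    observed = true_calls.copy()
    if cfg.genotyping_error_rate > 0:
        err = rng.random(observed.shape) < cfg.genotyping_error_rate
        shift = rng.integers(1, 3, size=observed.shape)
        observed[err] = (observed[err] + shift[err]) % 3

    # phenotypes from the error-free causal genotype
    pen = rng.random(n_off) < cfg.penetrance
    affected = (true_calls[2:, causal_idx] == 2) & pen

    members = [
        Individual("FA", sex=Sex.MALE, phenotype=Phenotype.UNAFFECTED),
        Individual("MO", sex=Sex.FEMALE, phenotype=Phenotype.UNAFFECTED),
    ]
    for k in range(n_off):
        members.append(
            Individual(
                f"C{k + 1}",
                father_id="FA",
                mother_id="MO",
                sex=Sex.MALE if k % 2 == 0 else Sex.FEMALE,
                phenotype=Phenotype.AFFECTED if affected[k] else Phenotype.UNAFFECTED,
            )
        )
    pedigree = Pedigree(family_id=cfg.family_id, members=members)
    affected_ids = [f"C{k + 1}" for k in range(n_off) if affected[k]]
    proband_id = affected_ids[0] if affected_ids else None

    # --- SNV records and annotations ----------------------------------
    bases = "ACGT"
    records: list[VariantRecord] = []
    annotations: list[ConsequenceAnnotation] = []
    for i, (chrom, pos, gene) in enumerate(sites):
        ref_i = int(rng.integers(4))
        alt_i = (ref_i + 1 + int(rng.integers(3))) % 4
        ref, alt = bases[ref_i], bases[alt_i]
        gts = {
            s: Genotype(_CALLS[int(observed[j, i])]) for j, s in enumerate(samples)
        }
        rec = VariantRecord(
            chrom=chrom, pos=pos, ref=ref, alt=alt,
            variant_class=VariantClass.SNV, genotypes=gts,
        )
        records.append(rec)
        term = cfg.causal_term if i == causal_idx else _weighted_choice(rng, _BACKGROUND_TERMS)
        annotations.append(
            ConsequenceAnnotation(
                variant_key=rec.key, gene_id=gene.gene_id,
                consequence_terms=frozenset({term}),
            )
        )
    causal_key = records[causal_idx].key

    # --- CNV deletions -------------------------------------------------
    cnv_records: list[VariantRecord] = []

    def _cnv_record(chrom: str, start1: int, end1: int, del_alleles: np.ndarray) -> VariantRecord:
        cns = {s: int(2 - del_alleles[j].sum()) for j, s in enumerate(samples)}
        return VariantRecord(
            chrom=chrom, pos=start1, ref="N", alt="<DEL>",
            variant_class=VariantClass.CNV_DELETION,
            copy_numbers=cns, end=end1,
        )

    def _transmit_cnv(founder_del: np.ndarray, forced_proband: int | None) -> np.ndarray:
        # founder_del: [parent, haplotype] 0/1 deletion alleles
        alleles = np.zeros((2 + n_off, 2), dtype=np.int8)
        alleles[0] = founder_del[0]
        alleles[1] = founder_del[1]
        for k in range(n_off):
            if forced_proband is not None and (2 + k) == forced_proband:
                # proband receives the deleted haplotype from each parent
                alleles[2 + k, 0] = 1
                alleles[2 + k, 1] = 1
                continue
            alleles[2 + k, 0] = founder_del[0, int(rng.integers(2))]
            alleles[2 + k, 1] = founder_del[1, int(rng.integers(2))]
        return alleles

    for _ in range(cfg.n_cnv_background):
        c = int(rng.integers(1, _N_AUTOSOMES + 1))
        length = int(rng.integers(5_000, 50_000))
        start1 = int(rng.integers(1, _CONTIG_LENGTH - length))
        founder_del = (rng.random((2, 2)) < cfg.cnv_deletion_freq).astype(np.int8)
        cnv_records.append(
            _cnv_record(f"chr{c}", start1, start1 + length, _transmit_cnv(founder_del, None))
        )

    # planted recessive deletion: hemizygous parents, proband copy number 0
    cnv_gene = next(
        g for g in genes if g.gene_id != causal_gene and g.chrom != causal_chrom
    )
    cnv_start1 = cnv_gene.start + 1 + _GENE_LENGTH // 4
    cnv_end1 = cnv_gene.end - _GENE_LENGTH // 4
    founder_del = np.array([[1, 0], [1, 0]], dtype=np.int8)
    proband_row = 2 + int(proband_id[1:]) - 1 if proband_id else None
    causal_cnv = _cnv_record(
        cnv_gene.chrom, cnv_start1, cnv_end1, _transmit_cnv(founder_del, proband_row)
    )
    cnv_records.append(causal_cnv)

    records.extend(cnv_records)
    records.sort(key=lambda r: _chrom_sort_key(r.chrom, r.pos))

    truth = {
        "seed": cfg.seed,
        "proband_id": proband_id,
        "affected": affected_ids,
        "unaffected": [m.individual_id for m in members[2:] if m.phenotype is Phenotype.UNAFFECTED],
        "causal_snv": {
            "chrom": causal_key[0], "pos": causal_key[1],
            "ref": causal_key[2], "alt": causal_key[3],
            "gene_id": causal_gene, "consequence": cfg.causal_term,
        },
        "causal_cnv": {
            "chrom": causal_cnv.chrom, "pos": causal_cnv.pos,
            "end": causal_cnv.end, "gene_id": cnv_gene.gene_id,
        },
        "causal_true_calls": {
            s: _CALLS[int(true_calls[j, causal_idx])].value
            for j, s in enumerate(samples)
        },
    }
    return SimulatedFamily(
        config=cfg, pedigree=pedigree, records=records,
        annotations=annotations, gene_map=gene_map, truth=truth,
    )


def write_fixture(sim: SimulatedFamily, outdir: str | Path) -> dict[str, Path]:
    """Write the standard fixture file set into ``outdir``.

    Produces family.vcf, family.ped, genes.bed, consequences.tsv and
    truth.json; reruns with the same seed overwrite byte-identically.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": outdir / "family.vcf",
        "ped": outdir / "family.ped",
        "bed": outdir / "genes.bed",
        "consequences": outdir / "consequences.tsv",
        "truth": outdir / "truth.json",
    }
    contigs = {f"chr{c}": _CONTIG_LENGTH for c in range(1, _N_AUTOSOMES + 1)}
    for r in sim.records:
        contigs.setdefault(r.chrom, _CONTIG_LENGTH)
    write_vcf(sim.records, paths["vcf"], sim.sample_ids, contigs=contigs)
    write_ped([sim.pedigree], paths["ped"])
    write_bed(sim.gene_map, paths["bed"])
    write_consequences(sim.annotations, paths["consequences"])
    paths["truth"].write_text(json.dumps(sim.truth, indent=2, sort_keys=True) + "\n")
    return paths
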