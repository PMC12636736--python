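"""End-to-end orchestration: simulate/load -> filter -> triage -> segregate.

A run consumes either a simulation block (synthetic family) or a set of
input paths (VCF + PED + gene BED + consequence TSV), applies the recessive
trio filters, triages survivors into gene candidates, judges each surviving
SNV's segregation across the full pedigree, and writes stage outputs plus a
machine-readable JSON report.  The report carries a provenance block
(package version, configuration hash, seed) so any run can be repeated
exactly — by-construction reproducibility stands in for data deposition.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import __version__
from .filters import CandidateVariants, TrioAssignment, apply_filters
from .pedigree import Pedigree, extract_trio, read_ped
from .segregation import (
    GenotypeTable,
    evaluate_candidate,
    verdict_to_dict,
)
from .simulate import SimulatedFamily, SimulationConfig, simulate_family, write_fixture
from .triage import GeneMap, aggregate_by_gene, read_bed, write_report
from .variants import read_consequences, read_vcf, write_vcf

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunReport", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one of ``simulation`` or the four input paths must be given.
    ``proband_id`` may be omitted for simulated runs (the simulator's truth
    supplies it).
    """

    outdir: str | Path = "trioscreen_out"
    simulation: SimulationConfig | None = None
    vcf: str | Path | None = None
    ped: str | Path | None = None
    bed: str | Path | None = None
    annotations: str | Path | None = None
    proband_id: str | None = None
    family_id: str | None = None
    pass_only: bool = False
    permissive_parents: bool = False
    chromosome_allowlist: list[str] | None = None

    def __post_init__(self) -> None:
        paths = [self.vcf, self.ped, self.bed, self.annotations]
        has_paths = any(p is not None for p in paths)
        if (self.simulation is None) == (not has_paths):
            raise ValueError(
                "exactly one of a simulation block or input paths must be configured"
            )
        if has_paths and not all(p is not None for p in paths):
            raise ValueError("file-input runs need vcf, ped, bed and annotations paths")
        if has_paths and self.proband_id is None:
            raise ValueError("file-input runs need a proband_id")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("simulation", None)
        if sim is not None:
            sim = SimulationConfig(**sim)
        return cls(simulation=sim, **raw)

    def to_jsonable(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        if self.simulation is not None:
            sim = dataclasses.asdict(self.simulation)
            sim["gene_map"] = [
                [g.chrom, g.start, g.end, g.gene_id] for g in self.simulation.gene_map
            ]
            d["simulation"] = sim
        for k in ("outdir", "vcf", "ped", "bed", "annotations"):
            if d[k] is not None:
                d[k] = str(d[k])
        return d

    def config_hash(self) -> str:
        # outdir is excluded: the hash identifies the experiment, not where
        # its outputs land
        d = self.to_jsonable()
        d.pop("outdir")
        canon = json.dumps(d, sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


@dataclass
class RunReport:
    report: dict[str, Any] = field(default_factory=dict)

    def __getitem__(self, key: str) -> Any:
        return self.report[key]


def _load_inputs(config: RunConfig, outdir: Path):
    if config.simulation is not None:
        sim: SimulatedFamily = simulate_family(config.simulation)
        fixture_dir = outdir / "fixture"
        write_fixture(sim, fixture_dir)
        proband = config.proband_id or sim.truth["proband_id"]
        if proband is None:
            raise PipelineError("simulate: no affected offspring; no proband available")
        return sim.pedigree, sim.records, sim.annotations, sim.gene_map, proband, sim
    pedigrees = read_ped(config.ped)
    if config.family_id is not None:
        ped = next(p for p in pedigrees if p.family_id == config.family_id)
    else:
        ped = pedigrees[0]
    sample_ids = [m.individual_id for m in ped.members]
    records = list(read_vcf(config.vcf, sample_ids=sample_ids))
    annotations = read_consequences(config.annotations)
    gene_map = read_bed(config.bed)
    return ped, records, annotations, gene_map, config.proband_id, None


def _segregate_survivors(
    ped: Pedigree, candidates: CandidateVariants
) -> dict[str, dict[str, Any]]:
    """Judge each surviving SNV's segregation over the whole pedigree."""
    decisions: dict[str, dict[str, Any]] = {}
    for rec in candidates.snv_indel:
        table = GenotypeTable(
            variant_key=rec.key,
            calls={m.individual_id: rec.genotypes[m.individual_id]
                   for m in ped.members if m.individual_id in rec.genotypes},
        )
        decision, verdicts = evaluate_candidate([ped], {ped.family_id: table})
        key = f"{rec.chrom}:{rec.pos}:{rec.ref}>{rec.alt}"
        decisions[key] = {
            "decision": decision.value,
            "families": {fam: verdict_to_dict(v) for fam, v in verdicts.items()},
        }
    return decisions


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute all stages and write outputs + report.json under ``outdir``."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    stage = "load"
    try:
        ped, records, annotations, gene_map, proband_id, sim = _load_inputs(
            config, outdir
        )
        father, mother, proband = extract_trio(ped, proband_id)
        trio = TrioAssignment(
            father_sample=father.individual_id,
            mother_sample=mother.individual_id,
            proband_sample=proband.individual_id,
        )

        stage = "filter"
        candidates = apply_filters(
            records,
            trio,
            pass_only=config.pass_only,
            permissive_parents=config.permissive_parents,
            chromosome_allowlist=config.chromosome_allowlist,
        )
        sample_ids = [m.individual_id for m in ped.members]
        write_vcf(candidates.all_records, outdir / "candidates.vcf", sample_ids)

        stage = "triage"
        triage_report = aggregate_by_gene(candidates, annotations, gene_map)
        write_report(triage_report, outdir / "triage.tsv")

        stage = "segregate"
        decisions = _segregate_survivors(ped, candidates)
        (outdir / "segregation.json").write_text(
            json.dumps(decisions, indent=2) + "\n"
        )

        stage = "report"
        report = {
            "counts": {
                "n_records": len(records),
                "n_examined_snv": candidates.n_examined_snv,
                "n_examined_cnv": candidates.n_examined_cnv,
                "n_pass_snv": len(candidates.snv_indel),
                "n_pass_cnv": len(candidates.cnv),
                "n_skipped_non_autosomal": candidates.n_skipped_non_autosomal,
                "n_skipped_filtered": candidates.n_skipped_filtered,
                "n_genes": len(triage_report.genes),
                "n_unannotated": len(triage_report.unannotated),
            },
            "tier_tally": triage_report.tally.as_dict(),
            "genes": [
                {
                    "gene_id": g.gene_id,
                    "max_impact": str(g.max_impact),
                    "n_variants": g.n_variants,
                }
                for g in triage_report.genes
            ],
            "segregation": decisions,
            "trio": {
                "father": trio.father_sample,
                "mother": trio.mother_sample,
                "proband": trio.proband_sample,
            },
            "provenance": {
                "tool": "trioscreen",
                "version": __version__,
                "config_hash": config.config_hash(),
                "seed": config.simulation.seed if config.simulation else None,
                "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S%z"),
            },
        }
        if sim is not None:
            report["truth"] = sim.truth
        (outdir / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True) + "\n"
        )
    except PipelineError:
        raise
    except Exception as e:
        raise PipelineError(f"{stage}: {e}") from e
    log.info(
        "pipeline complete: %d/%d SNV and %d/%d CNV survivors across %d genes",
        report["counts"]["n_pass_snv"],
        report["counts"]["n_examined_snv"],
        report["counts"]["n_pass_cnv"],
        report["counts"]["n_examined_cnv"],
        report["counts"]["n_genes"],
    )
    return RunReport(report=report)
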