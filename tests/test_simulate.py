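import json

import numpy as np
import pytest
from scipy import stats

from trioscreen.filters import TrioAssignment, recessive_cnv_pass, recessive_snv_pass
from trioscreen.pedigree import Phenotype
from trioscreen.simulate import (
    SimulationConfig,
    default_gene_map,
    simulate_family,
    write_fixture,
)
from trioscreen.variants import GenotypeCall, VariantClass

HR, HET, HA = GenotypeCall.HOM_REF, GenotypeCall.HET, GenotypeCall.HOM_ALT

# unordered Mendelian transmission table: parent calls -> possible child calls
MENDEL = {
    (HR, HR): {HR},
    (HR, HET): {HR, HET},
    (HR, HA): {HET},
    (HET, HET): {HR, HET, HA},
    (HET, HA): {HET, HA},
    (HA, HA): {HA},
}


def possible_child_calls(father, mother):
    key = tuple(sorted((father, mother), key=lambda c: c.value))
    return MENDEL[(key[0], key[1])] if key in MENDEL else MENDEL[(key[1], key[0])]


@pytest.fixture(scope="module")
def small_sim():
    return simulate_family(SimulationConfig(seed=5, n_background_snvs=400, n_cnv_background=10))


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"founder_alt_freq": 1.5},
            {"genotyping_error_rate": -0.1},
            {"penetrance": 2.0},
            {"n_background_snvs": -1},
            {"n_offspring": 0},
            {"n_affected_offspring": 5, "n_offspring": 4},
            {"causal_site": ("chr99", 5, "nope")},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimulationConfig(**kwargs)

    def test_default_causal_site_inside_its_gene(self):
        cfg = SimulationConfig()
        chrom, pos, gene_id = cfg.causal_site
        g = next(x for x in cfg.gene_map if x.gene_id == gene_id)
        assert g.chrom == chrom and g.start < pos <= g.end


class TestFamilyStructure:
    def test_litter_composition(self, small_sim):
        ped = small_sim.pedigree
        assert len(ped) == 6
        assert {m.individual_id for m in ped.founders} == {"FA", "MO"}
        assert len(ped.affected) == 2  # default ascertained litter: 2 affected
        assert small_sim.truth["proband_id"] in {m.individual_id for m in ped.affected}

    def test_parents_forced_heterozygous_at_causal_site(self, small_sim):
        calls = small_sim.truth["causal_true_calls"]
        assert calls["FA"] == "het" and calls["MO"] == "het"

    def test_affected_iff_hom_alt_at_causal_site(self, small_sim):
        # penetrance 1, error 0: phenotype is determined by the causal genotype
        truth = small_sim.truth
        for m in small_sim.pedigree.members[2:]:
            expected = truth["causal_true_calls"][m.individual_id] == "hom_alt"
            assert (m.phenotype is Phenotype.AFFECTED) == expected


class TestMendelianStructure:
    def test_error_free_offspring_calls_are_mendelian(self, small_sim):
        for rec in small_sim.records:
            if rec.variant_class.is_cnv:
                continue
            fa, mo = rec.genotypes["FA"].call, rec.genotypes["MO"].call
            for child in ("C1", "C2", "C3", "C4"):
                assert rec.genotypes[child].call in possible_child_calls(fa, mo)

    def test_cnv_copy_numbers_are_transmission_consistent(self, small_sim):
        # child CN = one transmitted haplotype per parent, each 0 or 1 copies
        for rec in small_sim.records:
            if not rec.variant_class.is_cnv:
                continue
            fa, mo = rec.copy_numbers["FA"], rec.copy_numbers["MO"]
            for child in ("C1", "C2", "C3", "C4"):
                cn = rec.copy_numbers[child]
                fa_halves = {1} if fa == 2 else {0, 1} if fa == 1 else {0}
                mo_halves = {1} if mo == 2 else {0, 1} if mo == 1 else {0}
                assert cn in {a + b for a in fa_halves for b in mo_halves}

    def test_proband_hom_alt_quarter_among_double_het_sites(self):
        # classic recessive ratio: among background sites where both parents
        # are carriers, the proband is homozygous alternate in 1/4 of cases
        sim = simulate_family(
            SimulationConfig(seed=20, n_background_snvs=10_000, founder_alt_freq=0.5,
                             n_cnv_background=0)
        )
        proband = sim.truth["proband_id"]
        causal = (sim.truth["causal_snv"]["chrom"], sim.truth["causal_snv"]["pos"])
        both_het = hom_alt = 0
        for rec in sim.records:
            if rec.variant_class.is_cnv or (rec.chrom, rec.pos) == causal:
                continue
            if rec.genotypes["FA"].call is HET and rec.genotypes["MO"].call is HET:
                both_het += 1
                hom_alt += rec.genotypes[proband].call is HA
        assert both_het > 1000
        sigma = (0.25 * 0.75 / both_het) ** 0.5
        assert abs(hom_alt / both_het - 0.25) < 3 * sigma

    def test_founder_genotypes_in_hardy_weinberg_proportions(self):
        sim = simulate_family(
            SimulationConfig(seed=13, n_background_snvs=10_000, founder_alt_freq=0.5,
                             n_cnv_background=0)
        )
        causal = (sim.truth["causal_snv"]["chrom"], sim.truth["causal_snv"]["pos"])
        counts = {HR: 0, HET: 0, HA: 0}
        for rec in sim.records:
            if rec.variant_class.is_cnv or (rec.chrom, rec.pos) == causal:
                continue
            counts[rec.genotypes["FA"].call] += 1
        n = sum(counts.values())
        expected = [0.25 * n, 0.5 * n, 0.25 * n]
        chi2 = stats.chisquare([counts[HR], counts[HET], counts[HA]], expected)
        assert chi2.pvalue > 0.01


class TestCausalPlanting:
    def test_causal_snv_and_cnv_pass_their_filters(self, small_sim):
        truth = small_sim.truth
        trio = TrioAssignment("FA", "MO", truth["proband_id"])
        snv_key = (
            truth["causal_snv"]["chrom"], truth["causal_snv"]["pos"],
            truth["causal_snv"]["ref"], truth["causal_snv"]["alt"],
        )
        snv_rec = next(r for r in small_sim.records if r.key == snv_key)
        assert recessive_snv_pass(snv_rec, trio)
        cnv_rec = next(
            r for r in small_sim.records
            if r.variant_class.is_cnv
            and (r.chrom, r.pos) == (truth["causal_cnv"]["chrom"], truth["causal_cnv"]["pos"])
        )
        assert recessive_cnv_pass(cnv_rec, trio)

    def test_genotyping_error_preserves_truth_sidecar(self):
        cfg = SimulationConfig(seed=3, n_background_snvs=300, genotyping_error_rate=0.1)
        sim = simulate_family(cfg)
        # truth genotypes at the causal site stay error-free
        assert sim.truth["causal_true_calls"]["FA"] == "het"
        assert sim.truth["causal_true_calls"]["MO"] == "het"
        assert sim.truth["causal_true_calls"][sim.truth["proband_id"]] == "hom_alt"

    def test_error_rate_corrupts_some_observed_calls(self):
        clean = simulate_family(SimulationConfig(seed=3, n_background_snvs=300))
        noisy = simulate_family(
            SimulationConfig(seed=3, n_background_snvs=300, genotyping_error_rate=0.1)
        )
        diffs = 0
        noisy_by_pos = {(r.chrom, r.pos): r for r in noisy.records if not r.variant_class.is_cnv}
        for rec in clean.records:
            if rec.variant_class.is_cnv:
                continue
            other = noisy_by_pos[(rec.chrom, rec.pos)]
            diffs += sum(
                rec.genotypes[s].call is not other.genotypes[s].call
                for s in rec.genotypes
            )
        assert diffs > 0


class TestFixtureFiles:
    def test_fixture_file_set(self, small_sim, tmp_path):
        paths = write_fixture(small_sim, tmp_path / "fx")
        assert sorted(p.name for p in paths.values()) == [
            "consequences.tsv", "family.ped", "family.vcf", "genes.bed", "truth.json",
        ]
        truth = json.loads(paths["truth"].read_text())
        assert truth["causal_snv"]["gene_id"] == small_sim.truth["causal_snv"]["gene_id"]
        header = paths["vcf"].read_text().splitlines()
        samples = next(l for l in header if l.startswith("#CHROM")).split("\t")[9:]
        assert samples == ["FA", "MO", "C1", "C2", "C3", "C4"]

    def test_same_seed_byte_identical(self, tmp_path):
        cfg = SimulationConfig(seed=9, n_background_snvs=120, n_cnv_background=4)
        a = write_fixture(simulate_family(cfg), tmp_path / "a")
        b = write_fixture(simulate_family(cfg), tmp_path / "b")
        for k in a:
            assert a[k].read_bytes() == b[k].read_bytes(), k

    def test_different_seed_differs(self, tmp_path):
        a = write_fixture(
            simulate_family(SimulationConfig(seed=1, n_background_snvs=120)), tmp_path / "a"
        )
        b = write_fixture(
            simulate_family(SimulationConfig(seed=2, n_background_snvs=120)), tmp_path / "b"
        )
        assert a["vcf"].read_bytes() != b["vcf"].read_bytes()

    def test_no_background_yields_causal_and_cnvs_only(self, tmp_path):
        cfg = SimulationConfig(seed=1, n_background_snvs=0, n_cnv_background=2)
        sim = simulate_family(cfg)
        snvs = [r for r in sim.records if not r.variant_class.is_cnv]
        cnvs = [r for r in sim.records if r.variant_class.is_cnv]
        assert len(snvs) == 1 and len(cnvs) == 3  # causal SNV + 2 background + 1 planted CNV
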