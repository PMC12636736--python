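import textwrap

import pytest
from hypothesis import settings

from trioscreen.pedigree import Individual, Pedigree, Phenotype, Sex
from trioscreen.variants import Genotype, GenotypeCall, VariantClass, VariantRecord

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

SAMPLES = ["FA", "MO", "C1", "C2", "C3", "C4"]

VCF_HEADER = textwrap.dedent(
    """\
    ##fileformat=VCFv4.2
    ##contig=<ID=chr1,length=200000000>
    ##contig=<ID=chr2,length=200000000>
    ##contig=<ID=chrX,length=170000000>
    ##INFO=<ID=END,Number=1,Type=Integer,Description="End position">
    ##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">
    ##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
    ##FORMAT=<ID=CN,Number=1,Type=Integer,Description="Copy number">
    """
)


def write_text_vcf(path, body, samples=("FA", "MO", "C1")):
    """Write a small VCF from header + literal body lines."""
    cols = "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples)
    path.write_text(VCF_HEADER + cols + "\n" + textwrap.dedent(body))
    return path


def snv(chrom, pos, calls, ref="A", alt="T", samples=("FA", "MO", "C1")):
    """Build an SNV record from per-sample GenotypeCall values."""
    return VariantRecord(
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        variant_class=VariantClass.SNV,
        genotypes={s: Genotype(c) for s, c in zip(samples, calls)},
    )


def cnv(chrom, pos, end, cns, deletion=True, samples=("FA", "MO", "C1")):
    """Build a CNV record from per-sample copy numbers."""
    return VariantRecord(
        chrom=chrom,
        pos=pos,
        ref="N",
        alt="<DEL>" if deletion else "<DUP>",
        variant_class=VariantClass.CNV_DELETION if deletion else VariantClass.CNV_DUPLICATION,
        copy_numbers=dict(zip(samples, cns)),
        end=end,
    )


@pytest.fixture
def family1():
    """The sequenced nuclear family: carrier parents, 2 affected + 2 unaffected."""
    return Pedigree(
        family_id="F1",
        members=[
            Individual("FA", sex=Sex.MALE, phenotype=Phenotype.UNAFFECTED),
            Individual("MO", sex=Sex.FEMALE, phenotype=Phenotype.UNAFFECTED),
            Individual("C1", "FA", "MO", Sex.MALE, Phenotype.AFFECTED),
            Individual("C2", "FA", "MO", Sex.FEMALE, Phenotype.AFFECTED),
            Individual("C3", "FA", "MO", Sex.MALE, Phenotype.UNAFFECTED),
            Individual("C4", "FA", "MO", Sex.FEMALE, Phenotype.UNAFFECTED),
        ],
    )
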