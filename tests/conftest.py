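import textwrap

import pytest

from transpoly.simulate import GeneSetSpec, SimConfig, simulate_bundle

VCF_HEADER = textwrap.dedent(
    """\
    ##fileformat=VCFv4.2
    ##contig=<ID=1,length=100000>
    ##contig=<ID=2,length=100000>
    ##contig=<ID=X,length=100000>
    ##contig=<ID=MT,length=20000>
    ##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
    #CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tN1\tN2\tN3
    """
)


def make_vcf(tmp_path, records, name="archaic.vcf"):
    """Write a 3-sample VCF from (chrom, pos, id, ref, alt, gt1, gt2, gt3) rows."""
    lines = [VCF_HEADER]
    for chrom, pos, rid, ref, alt, *gts in records:
        lines.append(
            f"{chrom}\t{pos}\t{rid}\t{ref}\t{alt}\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n"
        )
    path = tmp_path / name
    path.write_text("".join(lines))
    return path


@pytest.fixture
def vcf_factory(tmp_path):
    def factory(records, name="archaic.vcf"):
        return make_vcf(tmp_path, records, name)

    return factory


@pytest.fixture(scope="session")
def small_bundle():
    """A small but complete synthetic dataset shared across tests."""
    cfg = SimConfig(
        n_genes=150,
        exon_count_mean=0.5,
        exon_len_mean=400.0,
        exon_len_sd=60.0,
        poly_rate=0.02,
        share_prob=0.3,
        gene_sets=(GeneSetSpec("TARGET", 15, 1.0),),
        seed=20240901,
    )
    return simulate_bundle(cfg)
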