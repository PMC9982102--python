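import numpy as np
import pandas as pd
import pytest

from heteropeus.genotype_io import GenotypeMatrix


def make_matrix(
    dosage,
    samples=None,
    chrom="chr1",
    qual=500.0,
    depth=None,
    gq=None,
    positions=None,
):
    """Build a GenotypeMatrix from a dosage array with sensible defaults."""
    dosage = np.asarray(dosage, dtype=np.int8)
    n_samples, n_sites = dosage.shape
    if samples is None:
        samples = [f"S{i}" for i in range(n_samples)]
    if positions is None:
        positions = np.arange(1, n_sites + 1) * 100
    qual = np.broadcast_to(np.asarray(qual, dtype=float), (n_sites,))
    sites = pd.DataFrame(
        {
            "chrom": [chrom] * n_sites,
            "pos": positions,
            "ref": ["A"] * n_sites,
            "alt": ["G"] * n_sites,
            "qual": qual,
        }
    )
    return GenotypeMatrix(samples, sites, dosage, depth, gq)


def write_vcf_text(path, samples, records):
    """Write a small VCF by hand for reader tests.

    records: (chrom, pos, ref, alt, qual, calls) with calls a list of
    'GT:DP:GQ' strings (or 'GT' alone when fmt is 'GT').
    """
    fmt = "GT:DP:GQ" if records and ":" in records[0][5][0] else "GT"
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">',
        '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">',
        "##contig=<ID=chr1>",
        "##contig=<ID=chr2>",
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples),
    ]
    for chrom, pos, ref, alt, qual, calls in records:
        lines.append(
            f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t{qual}\t.\t.\t{fmt}\t" + "\t".join(calls)
        )
    path.write_text("\n".join(lines) + "\n")
    return str(path)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_sim_cfg():
    """Desk-scale simulation: full 19 x 5 panel, small genome."""
    from heteropeus.simulate import SimulationConfig

    return SimulationConfig(
        seed=7,
        n_chromosomes=2,
        chrom_length=300_000,
        n_genes=30,
        n_snps=600,
    )
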