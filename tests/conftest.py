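import numpy as np
import pytest

from admixepi import (
    PopulationFrequencies,
    build_cohort,
    draw_ancestral_frequencies,
    sample_founder_haplotypes,
)


@pytest.fixture(scope="session")
def small_panel():
    """Independent-sites founder panel: 800 SNPs, fst 0.2, 80 haplotypes/pop."""
    freqs = draw_ancestral_frequencies(800, 0.2, seed=11)
    return sample_founder_haplotypes(freqs, 80, seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_panel):
    """500-individual admixed cohort over 5 segments of a 50-Mb chromosome."""
    return build_cohort(small_panel, 500, 50_000_000, n_segments=5, seed=11)


@pytest.fixture(scope="session")
def aim_cohort():
    """Recombination-free cohort whose SNPs are all perfect AIMs.

    Every SNP is fixed for opposite alleles in the two populations, so
    genotype dosage must equal reference-ancestry dosage everywhere.
    """
    m = 20
    freqs = PopulationFrequencies(
        positions=np.arange(1, m + 1) * 100_000,
        freq_pop1=np.zeros(m),
        freq_pop2=np.ones(m),
        fst=0.5,
    )
    founders = sample_founder_haplotypes(freqs, 10, seed=3)
    return build_cohort(founders, 40, 2_100_000, recomb_rate=0.0,
                        n_segments=4, seed=3)


def write_vcf(path, records, samples, phased=True):
    """Write a handcrafted VCF for import tests.

    ``records`` is a list of (chrom, pos1based, ref, alts, genotype rows),
    where each genotype row is a (a0, a1) pair per sample.
    """
    sep = "|" if phased else "/"
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##contig=<ID=chr20>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for chrom, pos, ref, alts, gts in records:
            cols = "\t".join(f"{a}{sep}{b}" for a, b in gts)
            fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{alts}\t.\tPASS\t.\tGT\t{cols}\n")
    return path
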