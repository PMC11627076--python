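from __future__ import annotations

import numpy as np
import pytest

from genodyn import synthetic
from genodyn.frequency_io import (
    AlleleFrequencyTable,
    HaploblockRecord,
    SnpInfo,
)

VCF_HEADER = [
    "##fileformat=VCFv4.2",
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    "##contig=<ID=1>",
]


def make_vcf(path, samples, records):
    """Write a minimal plain-text VCF.

    ``records``: iterables of (chrom, pos, snp_id, ref, alt, [genotypes]);
    ``alt`` may be a comma-joined string for multi-allelic records.
    """
    lines = list(VCF_HEADER)
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(samples)
    )
    for chrom, pos, snp_id, ref, alt, gts in records:
        lines.append(
            f"{chrom}\t{pos}\t{snp_id}\t{ref}\t{alt}\t.\tPASS\t.\tGT\t"
            + "\t".join(gts)
        )
    path.write_text("\n".join(lines) + "\n")
    return path


def make_panel(path, mapping):
    lines = ["sample\tpopulation"]
    lines += [f"{s}\t{p}" for s, p in mapping.items()]
    path.write_text("\n".join(lines) + "\n")
    return path


def simple_freq_table(pop_freqs, snp_prefix="snp", alleles=("A", "G")):
    """Frequency table from {population: [major-allele freqs]} (one per SNP)."""
    pops = list(pop_freqs)
    n = len(next(iter(pop_freqs.values())))
    major, minor = alleles
    snps = [
        SnpInfo(f"{snp_prefix}{i}", "1", 100 * (i + 1), major, minor)
        for i in range(n)
    ]
    freqs = {
        (s.snp_id, pop): {major: pop_freqs[pop][i], minor: 1 - pop_freqs[pop][i]}
        for i, s in enumerate(snps)
        for pop in pops
    }
    return AlleleFrequencyTable(snps, pops, freqs)


def random_block(rng, n_snps=None, population="POPX", block_id="b1",
                 fix_snps=False):
    """Random haploblock: Dirichlet haplotype distribution, optional fixing."""
    if n_snps is None:
        n_snps = int(rng.integers(1, 5))
    haps = []
    for k in range(2**n_snps):
        haps.append("".join("AG"[(k >> i) & 1] for i in range(n_snps)))
    p = rng.dirichlet(np.ones(len(haps)) * 0.5)
    if fix_snps and n_snps > 1:
        # collapse a random subset of SNPs onto the 'A' allele
        n_fix = int(rng.integers(1, n_snps))
        fixed = rng.choice(n_snps, size=n_fix, replace=False)
        merged: dict = {}
        for h, w in zip(haps, p):
            h2 = "".join(
                "A" if i in fixed else c for i, c in enumerate(h)
            )
            merged[h2] = merged.get(h2, 0.0) + w
        freq = merged
    else:
        freq = dict(zip(haps, p))
    total = sum(freq.values())
    freq = {h: w / total for h, w in freq.items() if w > 0}
    return HaploblockRecord(
        block_id=block_id,
        population_code=population,
        snp_ids=tuple(f"s{i}" for i in range(n_snps)),
        haplotype_freq=freq,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240)


@pytest.fixture(scope="session")
def small_scenario():
    return synthetic.generate_scenario(
        synthetic.default_config(seed=7, n_null_snps=20)
    )
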