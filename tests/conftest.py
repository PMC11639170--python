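import numpy as np
import pytest

from abbaclust.ingest import SiteTable, SpeciesMap


def make_table(freqs, chrom_index=None, pos=None, chrom_names=None) -> SiteTable:
    """SiteTable from a list/array of (fP1, fP2, fP3, fP4) rows."""
    freqs = np.atleast_2d(np.asarray(freqs, dtype=float))
    n = len(freqs)
    if chrom_index is None:
        chrom_index = np.zeros(n, dtype=np.int32)
    if chrom_names is None:
        chrom_names = [str(c + 1) for c in range(int(np.max(chrom_index)) + 1 if n else 1)]
    if pos is None:
        pos = np.zeros(n, dtype=np.int64)
        for c in np.unique(chrom_index):
            sel = chrom_index == c
            pos[sel] = np.arange(1, sel.sum() + 1)
    return SiteTable(chrom_names, np.asarray(chrom_index), np.asarray(pos), freqs)


VCF_HEADER = """\
##fileformat=VCFv4.2
##contig=<ID={contigs}>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}
"""


def write_vcf_text(path, records, samples, contig="1"):
    """Write a minimal VCF; records are (chrom, pos, ref, alt, [genotypes])."""
    with open(path, "w") as fh:
        fh.write(VCF_HEADER.format(contigs=contig, samples="\t".join(samples)))
        for chrom, pos, ref, alt, gts in records:
            row = [chrom, str(pos), ".", ref, alt, ".", "PASS", ".", "GT"] + list(gts)
            fh.write("\t".join(row) + "\n")
    return path


@pytest.fixture
def one_each_map():
    """One diploid sample per species, samples named like the species."""
    return SpeciesMap(
        {"p1": "sp1", "p2": "sp2", "p3": "sp3", "p4": "sp4"},
        ("sp1", "sp2", "sp3"),
        "sp4",
    )


@pytest.fixture(scope="session")
def small_null_sim():
    """Small no-introgression, no-rate-variation dataset (study parameters
    otherwise: Ne=1e5, mu=2e-9, t=1e7)."""
    from abbaclust import simulate as S

    config = S.ScenarioConfig(length=5e4, seed=301)
    ts, truth = S.simulate_dataset(config)
    return config, ts, truth
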