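"""Read variant data into per-site derived-allele frequency tables.

The ABBA-BABA framework works on a species trio (P1, P2, P3) plus an
outgroup P4.  For every retained site the table stores the frequency of
the derived allele "B" in each of the four species, where the derived
allele is defined as the allele occurring at lower frequency among the
outgroup's called alleles.  Sites with more than two observed alleles
across the four species are ignored, as are monomorphic sites and sites
at which any of the four species has no called alleles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

#: Reporting floor for p-values throughout the package.
P_FLOOR = 2.3e-16


class ConfigurationError(ValueError):
    """Invalid species map / trio configuration."""


class VCFParseError(ValueError):
    """Malformed VCF record."""


@dataclass(frozen=True)
class SpeciesMap:
    """Assignment of VCF samples to species and of species to trio roles.

    Parameters
    ----------
    sample_to_species
        Mapping from VCF sample id to species name.
    trio
        Ordered (P1, P2, P3) species names.
    outgroup
        Outgroup (P4) species name.
    """

    sample_to_species: dict[str, str]
    trio: tuple[str, str, str]
    outgroup: str

    def __post_init__(self) -> None:
        names = (*self.trio, self.outgroup)
        if len(set(names)) != 4:
            raise ConfigurationError(f"trio + outgroup species must be distinct, got {names}")
        present = set(self.sample_to_species.values())
        for sp in names:
            if sp not in present:
                raise ConfigurationError(f"species {sp!r} has no samples in the species map")

    @property
    def species(self) -> tuple[str, str, str, str]:
        return (*self.trio, self.outgroup)

    def samples_for(self, species: str) -> list[str]:
        return [s for s, sp in self.sample_to_species.items() if sp == species]

    def swapped(self) -> "SpeciesMap":
        """Return a map with P1 and P2 roles exchanged."""
        p1, p2, p3 = self.trio
        return SpeciesMap(self.sample_to_species, (p2, p1, p3), self.outgroup)

    @classmethod
    def from_sets_file(cls, path, trio: tuple[str, str, str] | None = None) -> "SpeciesMap":
        """Read a two-column SETS file (sample TAB species).

        The outgroup species is labelled "Outgroup".  If ``trio`` is not
        given, the remaining species in order of first appearance form
        (P1, P2, P3); exactly three non-outgroup species must then be
        present.
        """
        mapping: dict[str, str] = {}
        order: list[str] = []
        with open(path) as fh:
            for line_no, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t") if "\t" in line else line.split()
                if len(parts) != 2:
                    raise ConfigurationError(f"{path}:{line_no}: expected 'sample<TAB>species'")
                sample, species = parts
                mapping[sample] = species
                if species != "Outgroup" and species not in order:
                    order.append(species)
        if "Outgroup" not in mapping.values():
            raise ConfigurationError(f"{path}: no sample labelled with species 'Outgroup'")
        if trio is None:
            if len(order) != 3:
                raise ConfigurationError(
                    f"{path}: found {len(order)} ingroup species, need exactly 3 or an explicit trio"
                )
            trio = (order[0], order[1], order[2])
        return cls(mapping, trio, "Outgroup")


@dataclass
class SiteTable:
    """Per-site derived-allele frequencies for (P1, P2, P3, P4).

    Attributes
    ----------
    chrom_names
        Chromosome/scaffold ids in input order.
    chrom_index
        Per-site index into ``chrom_names`` (non-decreasing).
    pos
        1-based positions, strictly increasing within a chromosome.
    freqs
        Array of shape (n, 4): derived-allele frequency in P1, P2, P3, P4.
    drop_counts
        Bookkeeping of filtered input records by category.
    """

    chrom_names: list[str]
    chrom_index: np.ndarray
    pos: np.ndarray
    freqs: np.ndarray
    drop_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.chrom_index = np.asarray(self.chrom_index, dtype=np.int32)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.freqs = np.asarray(self.freqs, dtype=np.float64)
        if self.freqs.shape != (len(self.pos), 4):
            raise ValueError("freqs must have shape (n_sites, 4)")

    @property
    def n(self) -> int:
        return len(self.pos)

    def chrom_slices(self) -> list[tuple[str, slice]]:
        """Contiguous slice per chromosome, in storage order."""
        out = []
        if self.n == 0:
            return out
        bounds = np.flatnonzero(np.diff(self.chrom_index)) + 1
        starts = np.concatenate([[0], bounds])
        ends = np.concatenate([bounds, [self.n]])
        for a, b in zip(starts, ends):
            out.append((self.chrom_names[self.chrom_index[a]], slice(int(a), int(b))))
        return out

    def swap_p1_p2(self) -> "SiteTable":
        """Table with the P1 and P2 frequency columns exchanged."""
        return SiteTable(
            self.chrom_names,
            self.chrom_index,
            self.pos,
            self.freqs[:, [1, 0, 2, 3]],
            dict(self.drop_counts),
        )


def polarize_counts(
    counts: np.ndarray,
    n_record_alleles: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, dict[str, int]]:
    """Polarize per-site allele counts and apply the site filters.

    Parameters
    ----------
    counts
        Integer array (n_sites, 4, n_alleles): called-allele counts per
        species (P1, P2, P3, P4) and allele index.  Allele index order
        follows the VCF convention (REF first, then ALTs).
    n_record_alleles
        Number of alleles each site's record declares (REF + ALTs).  A
        site is multi-allelic when its record lists more than two
        alleles, even if fewer are observed among the four species —
        matching how a VCF-reading tool sees "multi-allelic sites".
        When omitted, observed alleles decide.

    Returns
    -------
    keep : bool array (n_sites,)
        Sites passing the filters.
    freqs : float array (n_kept, 4)
        Derived-allele frequencies for the kept sites.
    dropped : dict
        Counts of sites dropped as "missing_species", "multiallelic" or
        "monomorphic", plus the number of retained outgroup 50/50 ties.

    Notes
    -----
    The derived allele is the lower-frequency allele among the
    outgroup's called alleles.  If the outgroup is 50/50 polymorphic,
    the globally rarer allele (summed over all four species) is chosen;
    if that is also tied, the later allele index (the VCF ALT) is used.
    Filter precedence: missing species, then multi-allelic, then
    monomorphic.
    """
    counts = np.asarray(counts)
    n = counts.shape[0]
    if n == 0:
        return np.zeros(0, bool), np.zeros((0, 4)), {}
    species_called = counts.sum(axis=2)  # (n, 4)
    allele_totals = counts.sum(axis=1)  # (n, K)
    observed = allele_totals > 0
    n_obs = observed.sum(axis=1)
    n_alleles = n_obs if n_record_alleles is None else np.asarray(n_record_alleles)

    missing = (species_called == 0).any(axis=1)
    multi = ~missing & ((n_alleles > 2) | (n_obs > 2))
    mono = ~missing & ~multi & (n_obs <= 1)
    keep = ~(missing | multi | mono)

    k = counts.shape[2]
    # First and last observed allele index; for bi-allelic sites these
    # are exactly the two segregating alleles.
    a1 = np.argmax(observed, axis=1)
    a2 = k - 1 - np.argmax(observed[:, ::-1], axis=1)

    idx = np.arange(n)
    out_c1 = counts[idx, 3, a1]
    out_c2 = counts[idx, 3, a2]
    tot_c1 = allele_totals[idx, a1]
    tot_c2 = allele_totals[idx, a2]
    # Lower outgroup frequency wins; ties resolved by global rarity,
    # then by the later (ALT-side) allele index.
    derived = np.where(
        out_c2 < out_c1,
        a2,
        np.where(
            out_c1 < out_c2,
            a1,
            np.where(tot_c2 < tot_c1, a2, np.where(tot_c1 < tot_c2, a1, a2)),
        ),
    )
    ties = int((keep & (out_c1 == out_c2)).sum())

    kept_idx = np.flatnonzero(keep)
    der = derived[kept_idx]
    with np.errstate(invalid="ignore"):
        freqs = counts[kept_idx, :, :][np.arange(len(kept_idx)), :, der] / species_called[kept_idx]
    dropped = {
        "missing_species": int(missing.sum()),
        "multiallelic": int(multi.sum()),
        "monomorphic": int(mono.sum()),
        "outgroup_ties": ties,
    }
    return keep, freqs, dropped


def build_site_table(
    chroms: list[str],
    chrom_index: np.ndarray,
    pos: np.ndarray,
    counts: np.ndarray,
    extra_drops: dict[str, int] | None = None,
    n_record_alleles: np.ndarray | None = None,
) -> SiteTable:
    """Polarize, filter, and assemble a :class:`SiteTable`."""
    keep, freqs, dropped = polarize_counts(counts, n_record_alleles)
    if extra_drops:
        for key, val in extra_drops.items():
            dropped[key] = dropped.get(key, 0) + val
    keep_idx = np.flatnonzero(keep)
    table = SiteTable(
        chroms,
        np.asarray(chrom_index)[keep_idx],
        np.asarray(pos)[keep_idx],
        freqs,
        dropped,
    )
    if dropped.get("outgroup_ties", 0):
        logger.info("retained %d sites with a 50/50 outgroup; derived allele chosen by tie rule",
                    dropped["outgroup_ties"])
    return table


def load_site_table(vcf_path, species_map: SpeciesMap) -> SiteTable:
    """Read a VCF into a :class:`SiteTable` for the mapped trio + outgroup.

    Frequencies are computed per species over non-missing allele calls.
    Indels and other non-SNP records are skipped with a logged count.

    Parameters
    ----------
    vcf_path
        Path to a VCF 4.x file (plain or bgzipped).
    species_map
        Sample-to-species assignment with trio and outgroup roles.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path), gts012=False)
    vcf_samples = list(vcf.samples)
    sample_set = set(vcf_samples)
    for sample in species_map.sample_to_species:
        if sample not in sample_set:
            raise ConfigurationError(f"sample {sample!r} in species map not found in VCF")

    species_cols: list[np.ndarray] = []
    for sp in species_map.species:
        cols = [vcf_samples.index(s) for s in species_map.samples_for(sp)]
        if not cols:
            raise ConfigurationError(f"species {sp!r} has no samples in the VCF")
        species_cols.append(np.asarray(cols, dtype=np.intp))

    chrom_names: list[str] = []
    chrom_lookup: dict[str, int] = {}
    chrom_index: list[int] = []
    positions: list[int] = []
    counts_list: list[np.ndarray] = []
    record_alleles: list[int] = []
    n_non_snp = 0
    k_max = 2

    for rec_no, var in enumerate(vcf, 1):
        try:
            alts = var.ALT or []
            if len(var.REF) != 1 or any(len(a) != 1 or a not in "ACGTacgt" for a in alts):
                n_non_snp += 1
                continue
            k = 1 + len(alts)
            gts = var.genotype.array()  # (n_samples, ploidy + 1); last col is phasing
            alleles = gts[:, :-1]
            site_counts = np.zeros((4, max(k, 2)), dtype=np.int32)
            for j, cols in enumerate(species_cols):
                calls = alleles[cols].ravel()
                calls = calls[calls >= 0]
                if calls.size:
                    site_counts[j, :] = np.bincount(calls, minlength=max(k, 2))[: max(k, 2)]
            k_max = max(k_max, site_counts.shape[1])
        except Exception as exc:  # pragma: no cover - defensive
            raise VCFParseError(f"malformed VCF record #{rec_no} at {var.CHROM}:{var.POS}: {exc}") from exc
        chrom = var.CHROM
        if chrom not in chrom_lookup:
            chrom_lookup[chrom] = len(chrom_names)
            chrom_names.append(chrom)
        chrom_index.append(chrom_lookup[chrom])
        positions.append(var.POS)
        counts_list.append(site_counts)
        record_alleles.append(k)

    if n_non_snp:
        logger.info("skipped %d non-SNP records", n_non_snp)
    if not counts_list:
        return SiteTable(chrom_names, np.zeros(0, np.int32), np.zeros(0, np.int64),
                         np.zeros((0, 4)), {"non_snp": n_non_snp})

    counts = np.zeros((len(counts_list), 4, k_max), dtype=np.int32)
    for i, sc in enumerate(counts_list):
        counts[i, :, : sc.shape[1]] = sc
    return build_site_table(chrom_names, np.asarray(chrom_index), np.asarray(positions),
                            counts, {"non_snp": n_non_snp},
                            n_record_alleles=np.asarray(record_alleles))
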