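# Methods

This note documents the statistical procedures, the simulation model,
the numerical choices, and the limits of what the test suite shows.

## Site table and polarization

All frequency-based statistics work on a per-site table of
derived-allele frequencies for an ordered trio (P1, P2, P3) and an
outgroup P4.  Frequencies are computed per species over non-missing
allele calls.  The derived allele "B" at a site is the allele at lower
frequency among the outgroup's called alleles.  When the outgroup is
exactly 50/50 polymorphic the site is retained (and counted in the
log): the globally rarer allele — summed over all four species — is
taken as derived, and if that is also tied, the VCF ALT allele.  This
rule is deterministic and orientation-invariant except in the doubly
tied case.

Site filters, in order of precedence:

1. non-SNP records (indels, symbolic alleles) are skipped;
2. sites where any of the four species has zero called alleles are
   dropped (all four frequencies are required);
3. multi-allelic sites are dropped.  *Multi-allelic* is decided from
   the record's allele list (REF + ALTs), not from the alleles observed
   in the four species: a site whose record lists three alleles is
   ignored even if only two survive among the samples.  This is how a
   VCF-reading tool perceives multi-allelicity, and with heavy
   homoplasy (old phylogenies, fast branches) the distinction is
   material — under the fast-P2 scenario below, observed-level
   filtering retains ~2% more sites and inflates the frequency-weighted
   ABBA count by ~4% relative to record-level filtering, moving it out
   of the range this implementation reproduces;
4. monomorphic sites (a single allele observed across the four
   species) are dropped.

The VCF reader (cyvcf2) and the direct tree-sequence path used on
simulated data share one polarization/filter implementation and are
tested to produce identical tables.

## Patterson's D and the block jackknife

C_ABBA = Σ (1−f_P1) f_P2 f_P3 and C_BABA = Σ f_P1 (1−f_P2) f_P3 over
retained sites; D = (C_ABBA − C_BABA)/(C_ABBA + C_BABA).  By default
the trio is rotated (P1 ↔ P2) when D < 0, so reported D ≥ 0 and "ABBA"
names the excess pattern; the rotation is flagged because *which* pair
the excess implicates is diagnostic (a fast P2 branch produces an
apparent P1–P3 signal).

Significance: delete-one block jackknife over 20 contiguous blocks
holding (near-)equal numbers of retained variant sites.  Equal
*variant-count* blocks are the default because they equalize the
information per block; equal-bp blocks are available (`by="bp"`).
Blocks never span chromosome boundaries; with several chromosomes the
block budget is allocated proportionally to chromosome site counts.
SE² = (g−1)/g · Σ (D₋ⱼ − D̄₋)², Z = D/SE, and p is the two-sided
standard-normal tail, floored at 2.3e-16 (the reporting floor used
throughout, chosen for comparability with the reference tool).  Zero
jackknife variance is reported as a degenerate status instead of a
p-value.

## Strong-site clustering test

A site is a *strong ABBA site* when

(1−f_P1) f_P2 f_P3 (1−f_P4) + f_P1 (1−f_P2)(1−f_P3) f_P4 > 0.5,

i.e. most sampled alleles support the ABBA configuration or its
polarization flip; *strong BABA sites* analogously.  The two scores
cannot both exceed 0.5, so labels are exclusive.  Classification runs
after D-rotation by default, so the tested pattern is the putatively
introgressed one (disable with `rotate=False`).

For each chromosome, the ordinal positions of strong ABBA sites are
recorded within a background vector — all retained polymorphic sites
(sensitive version) or strong ABBA + strong BABA sites (robust
version) — and concatenated across chromosomes with cumulative
offsets.  Dividing by the background length gives values on [0, 1]
that are compared to Uniform(0, 1) with a one-sample two-sided
Kolmogorov–Smirnov test.  Clustering (significant KS) supports genuine
introgression; homoplasies driven by among-species rate variation are
spread homogeneously.  The robust version additionally cancels
mutation-rate variation along the genome, which inflates strong ABBA
and strong BABA densities equally; its known blind spot is very strong
introgression, where introgressed tracts dominate the background
itself.

Numerical choices: p-values use the exact KS null below 50 strong
sites and the asymptotic Kolmogorov distribution above (ordinal
discreteness is negligible at the site counts involved; the Monte-Carlo
calibration test verifies a 5% ± 1% rejection rate at n=200 drawn from
10,000).  No p-value is reported below 10 strong ABBA sites
(`min_sites`), where the KS test is meaningless.  The 2.3e-16 floor
applies.

## Tree-set statistics

Trees are 4-taxon newick (one per line); a taxon map assigns labels to
roles P1..P4.  Topology and branch quantities are computed
root-agnostically: the trio topology is the quartet split (the cherry
pair not containing P4), and the trio internal branch is recovered
from patristic distances, I = [d(Y,X) + d(Z,P4) − d(Y,Z) − d(X,P4)]/2
for cherry {Y,Z}, which is exact on additive trees regardless of where
the newick is rooted.  Trees with I below 0.001 substitutions/site
(configurable) are flagged uninformative and excluded from topology
counts; unparseable trees or trees missing taxa are skipped and
counted.

Constrained Dtree = (C_P2,P3 − C_P1,P3)/(C_P2,P3 + C_P1,P3) tests
explicitly for P2–P3 introgression with a one-sided *exact* binomial
tail P(X ≥ C_P2,P3 | n, ½) — exact rather than normal-approximate, so
small discordant counts are handled safely.  The unconstrained variant
(second- vs third-most-frequent topology) is available behind a flag
but is not the default, since it can underestimate strong
introgression when the modal topology is not the species tree.

MMS17: for ultrametric, time-calibrated local trees, the pair MRCA age
is taken as half the patristic distance of the pair (equal to the MRCA
node age on a clock tree; for mildly non-ultrametric trees — flagged
when root-to-tip spread exceeds 1e-6 relative — it degrades gracefully
to the mean tip-to-MRCA path length).  Pair means over all trees give
dMRCA = difference of the two largest means.  No internal-branch filter
is applied.  The statistic carries no formal test; the identities of
the two oldest pairs are reported because the pathological case where
P1–P2 ranks among the oldest (very fast P2, old phylogenies) signals
an unreliable dMRCA.

## Simulation model

Four species on a ladder phylogeny: P1/P2 diverge t_{P1,P2} ∈ {1, 2, 3}
× 10⁷ generations ago, P3 and P4 branch off 10⁷ and 2×10⁷ generations
earlier, so the internode distances (and hence ILS expectations) are
constant across phylogeny ages.  All populations have equal constant
diploid size Ne (default 10⁵).  One 20-Mbp chromosome recombines at
r = 10⁻⁸; mutations follow HKY with κ = 2 (uniform equilibrium
frequencies and uniformly drawn ancestral alleles, since nothing else
is specified by the design) at μ (default 2×10⁻⁹).  Introgression is
symmetric P2↔P3 migration at rate m per individual per generation,
active from the P1/P2 divergence until 2.5×10⁶ generations later.
Five diploids are sampled per species.

Among-species rate variation (scale s on the P2 branch) uses the
sampling-time work-around rather than a true rate change, preserving
the homoplasy/reversal structure that drives the false positives:

* s < 1: P2 sampled (1−s)·t_{P1,P2} in the past (branch shortened);
* s > 1: every divergence and the migration window shifted
  (s−1)·t_{P1,P2} into the past; P1, P3, P4 sampled at that shift, P2
  at the present (branch extended).

A `rate_mode="branch"` flag is reserved for a direct branch-rate
implementation; it is currently not implemented for s ≠ 1 because the
coalescent engine has no per-population mutation rate and manual edge
placement would amount to rewriting the mutation engine.  The
work-around's branch-length arithmetic is instead cross-checked against
closed-form divergence expectations (below).

Ground truth extracted from the genealogical record:

* **introgressed fraction** — the union of genome intervals whose
  migration records pass between P2 and P3; every record pertains to a
  lineage segment ancestral to ≥1 sample, so this is the most
  inclusive reading of "affected by introgression" (≥1 sampled lineage);
* **single-topology tracts** — maximal runs of adjacent local trees
  sharing one trio topology, computed on one haploid genome per
  species (first haplotype of the first individual, matching the data
  reduction used for tree-based analyses);
* **c-gene length** — chromosome length / number of distinct
  genealogical trees (recombination-unbroken regions);
* **dxy** — per-site mean pairwise differences between species
  (tree-sequence site-mode divergence);
* **variable / multi-allelic site counts** — variable among the 40
  sampled haplotypes; multi-allelic per record allele list.

Window alignments for tree inference replicate the study's data
reduction: 5000×200 bp, 2000×500 bp, or 1000×1000 bp windows with
uniform start spacing L/n_windows; per window one haploid sequence per
species (first allele of the first individual) at the dataset's
variable sites, all other positions filled with one random nucleotide
shared by the four sequences.

Determinism: a scenario seed drives ancestry, mutation, and fill
randomness through independent derived streams, so identical configs
give byte-identical VCFs.

### Validation oracle for divergence

With the sampling work-around, E[dxy(P1,P2)] ≈ μ[(1+s)·t_{P1,P2} +
4Ne], minus a multiple-hit deficit of order dxy² (about 5% at
dxy ≈ 0.076, the deepest scenario).  The oracle test uses shallow
parameters (total divergence ≈ 0.02, deficit ≈ 1%) and checks the
simulated dxy within 5%.

## Problem sizes

The coalescent under this design is expensive: branch lengths of
10⁷–10⁸ generations with r = 10⁻⁸ imply roughly one distinct genealogy
per ~20 bp (the c-gene scale), i.e. about a million marginal trees on
the full 20-Mbp chromosome.  The package defaults keep the full study
chromosome, but the test suite and the acceptance script analyze
desk-scale chromosomes of 0.1–1 Mbp.  This is statistically principled:

* D, dxy, introgressed fractions, and tract-length means are *ratio*
  statistics whose expectations do not depend on chromosome length;
  only their sampling noise grows (∝ 1/√L), which the desk-scale
  assertions account for;
* variable-site and pattern counts are *extensive* (linear in L) and
  are compared per 20 Mbp via their density;
* significance levels scale with the number of sites, so desk-scale
  thresholds are set for the simulated length (e.g. p < 10⁻⁶ where the
  full chromosome yields p < 10⁻¹⁰).

At 0.5–1 Mbp every published range re-emerges: the null D sits below
0.015-with-noise, s = 0.25 gives D ≈ 0.19 supporting P2–P3, s = 4
gives a rotated (P1–P3) signal with the published ABBA-count density,
m = 10⁻⁷ gives D ≈ 0.7 with ~30–45% of the chromosome introgressed and
~500–800 bp tracts, and the c-gene mean is 19–20 bp.

## What the synthetic data do and do not show

The simulator emulates the study conditions: neutral evolution,
constant Ne, a clean ladder phylogeny, uniform rates along the genome
(optional piecewise recombination/mutation maps exist as hooks but are
off by default), free recombination across a single chromosome, and
complete, error-free genotypes.  Passing tests therefore demonstrate
correctness of the statistics and reproduction of the simulated
behaviour — not robustness to selection, demographic change, genotype
error, reference bias, missing data patterns, or gene flow among other
pairs, none of which are modelled.  The clustering test in particular
assumes contiguous genomic coordinates within chromosomes; fragmented
assemblies weaken it by construction, and large low-recombination
regions (e.g. inversions) can produce genuine-looking clustering from
ILS alone — the per-site label output (`--site-labels`) supports
scanning for such regions.

## Known limitations

* The jackknife uses the equal-block variance formula; blocks differ
  by at most one site, so the weighted (unequal-block) refinement is
  unnecessary.
* The exact KS branch engages only below 50 strong sites; between ~50
  and a few hundred sites the asymptotic p is mildly conservative.
* MMS17 pair ages from half patristic distances are exact only for
  clock-like trees; strongly non-ultrametric inputs are flagged, not
  corrected.
* The simulator's migration records grow with m; very strong migration
  on long chromosomes is memory-heavy.
* `rate_mode="branch"` is a declared stub (see above).
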