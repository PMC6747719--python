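# Methods

## Profile model and search

Family profiles are gapped position-specific scoring matrices rather than
full profile HMMs. Each column stores log₂-odds scores
`score(a, c) = log2(f(a|c) / bg(a))` with
`f(a|c) = (count(a, c) + w·bg(a)) / (non-gap count(c) + w)`, pseudocount
weight `w = 1` and a uniform background by default (an alignment-composition
background is available). The unknown residue `X` is treated as missing data
during estimation and scores 0 in every column, so it neither rewards nor
penalizes a match. Before estimation, seed alignments are trimmed only at
their extremities: scanning inward from each end, terminal columns whose gap
fraction exceeds a threshold (0.5 by default) are dropped and the scan stops
at the first retained column; the alignment core is never altered.

Search is affine-gap Smith–Waterman of the profile against each target
protein (gap open 4 bits, extend 1 bit; numba-compiled kernel, verified
against exhaustive enumeration of all local alignments on small instances).
Profile coverage is the fraction of profile columns spanned by the optimal
local alignment — coverage *of the profile*, so a short target can never
reach high coverage against a long profile by chance.

This design trades the extra sensitivity of a Plan7 HMM (position-specific
gap states, glocal mode) for a model that is fully transparent and testable
while preserving exactly the filtering semantics that matter downstream:
a bit score, an independent E-value, and a profile-coverage fraction.

## E-value calibration

Score statistics are calibrated per profile on `n_decoys = 1000` i.i.d.
background sequences of length 250 (about the length of the real family
proteins). The decoy score sample is summarized by a Gumbel law fitted by
the method of moments (`λ = π / (sd·√6)`, `μ = mean − γ/λ` with γ Euler's
constant), and a hit's i-evalue against a database of `N` sequences is
`N·exp(−λ(S − μ))`. Reported E-values are floored at 1e-300; genuine
homologs routinely underflow the exponential. Zero-variance decoy scores
raise a calibration error rather than produce a degenerate fit.

The moment fit uses the whole decoy distribution, so its 5%-tail estimate
carries both the Gumbel-approximation error of gapped local alignment scores
and the sampling error of the calibration sample. Empirically the pass rate
at the `E = 0.05·n` cutoff lands between ~3.5% and ~6.5% of fresh decoys; the
sanity check in the test suite therefore draws 1000 fresh decoys, whose 99%
binomial band ([3.2%, 6.8%]) accommodates that combined noise.

Retention thresholds are strict inequalities: i-evalue `< 1e-20` and
coverage `> 0.8` (system detection) or `> 0.9` (profile curation). When
several profiles pass on one protein, only the best (smallest i-evalue) hit
is kept; ties break by higher bit score, then lexicographic family name.
For multi-domain proteins — e.g. a ubiT–ubiU gene fusion — an opt-in mode
(`allow_nonoverlapping_multi=True`) keeps one family per non-overlapping
target span, where any overlap exceeding 20% of the shorter span
disqualifies the later hit.

## Dereplication

Greedy single-pass centroid clustering: sequences are processed in
descending length order (ties by id), each joining the first centroid with
identity at or above the threshold (80% by default), otherwise founding a
new centroid. The length-sorted order makes the outcome independent of the
input order. Identity is computed from a global affine-gap alignment
(BLOSUM62, open 10, extend 1, via Biopython's `PairwiseAligner`) as
matches divided by alignment columns *including gap columns* — one fixed
convention, since clustering tools differ on the denominator and the choice
materially changes the threshold's meaning.

## Locus detection and architecture classes

Gene coordinates are ranks (0-based gene order per replicon); strand is
parsed but ignored because co-localization is counted in intervening genes.
Member genes are partitioned per replicon into maximal runs where each
consecutive pair is separated by at most `inter_gene_max_space` non-member
genes (5 for the three-gene model, 10 for the comprehensive model; exactly
`max_space` intervening genes stays in the same locus). Circular replicons
(off by default) wrap the count around the origin and merge the terminal
loci when the wrap gap qualifies. Exchangeable profile groups (e.g. two
alternative ubiT profiles) are collapsed to one logical family before
partitioning, and accessory families are reported within loci but never
drive the class.

A genome with all three core families is a `three_gene_locus` when some
locus holds all three, a `two_gene_locus` when the best locus holds two,
and `dispersed` when no two co-localize; fewer than three present is
`incomplete`. With several candidate loci the call uses the best one
(three > two > dispersed). ubiU–ubiV adjacency means zero intervening genes
on the same replicon — or one fusion protein carrying both families. The
headline adjacency and co-occurrence percentages are integer-rounded, with
the exact fractions reported alongside; the adjacency denominator is the
set of genomes harboring all three genes.

Multi-replicon genomes are resolved per replicon and aggregated per genome,
so a "third gene elsewhere" may sit on another replicon.

## Synthetic data: what it emulates, and what it does not

Generators are pure functions of their spec and seed. Family members are
the consensus with i.i.d. per-site substitutions, uniform over the 19
alternative residues (expected identity `1 − divergence`); decoys are
background-composition proteins with lengths uniform in [150, 450];
genomes are single replicons in which members are planted to realize an
exact architecture inventory, with distinct loci separated by more than the
largest co-localization window (≥ 11 intervening genes). Fusion proteins
concatenate two members through a 10-residue background linker. Motif
alignments plant cysteine columns at exact conservation counts
(`round(c·n)` rows carry C; the first row — the reference — is always a
carrier) so threshold tests are deterministic; Bernoulli sampling is
available behind a flag.

The default study conditions mirror the analysis the pipeline was built
for: an architecture inventory of 106 three-gene-locus, 82 two-gene-locus
(39 with the ubiU–ubiV pair adjacent, the remainder co-localizing
ubiT–ubiU) and 21 dispersed genomes; a 221-genome co-occurrence panel
(that inventory plus one fusion genome, totalling 210 complete genomes,
plus 11 partial genomes); a ten-family motif panel with eight families
carrying four cysteine columns at 97–100% conservation, one with none and
one with two mildly (60–80%) and three poorly (40–65%) conserved cysteines;
and an end-to-end recovery fixture of 12 genomes × 200 decoys with members
diverged 20% from consensus. These sizes keep every check within seconds to
a couple of minutes on one CPU while exercising each architecture and
filter path.

What the generators do **not** model: phylogenetically correlated
divergence (sites and lineages are i.i.d.), indels within families, codon
or GC structure, operon strandedness, shared ancestry between decoys and
families, or database-scale composition biases. Passing the recovery tests
therefore demonstrates the correctness of the scoring, calibration,
filtering and classification machinery under the stated noise model — not
the sensitivity of the profiles on real, deeply diverged proteomes, which
additionally depends on seed-set curation.

## Numerical and degenerate-input choices

- Alignments need ≥ 2 rows; all-gap rows and all-trimmed cores are errors.
- Zero-pseudocount profiles score unobserved residues −∞ (exact forbidden
  states); an all-gap column with zero pseudocount is an error.
- Percentages are rounded half-to-even by Python's `round`; exact fractions
  are always reported next to rounded headline numbers.
- Empty panels report `None` (`NA` in TSV) rather than 0 for undefined
  fractions.
- Deterministic tie-breaks throughout: best-hit (i-evalue, bit score,
  family name), dereplication processing order (length, id), locus member
  order (rank, family).
- Derived seeds stay below 2³¹; every stochastic routine takes an explicit
  seed or `numpy` Generator.

## Known limitations

- The PSSM search has no position-specific gap penalties and no glocal
  mode; very fragmented homologs may fall below the coverage filter.
- Gumbel parameters are fitted at one decoy length; E-values are not
  length-corrected per target (adequate at the extreme 1e-20 cutoff used
  here, where true and false scores are separated by hundreds of bits).
- The greedy dereplication is O(n²) pairwise alignments — fine for family
  sets of hundreds, not for millions.
- GFF3 parsing covers CDS features with `protein_id`/`ID` attributes; rich
  attribute semantics (phases, multi-line features) are out of scope.
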