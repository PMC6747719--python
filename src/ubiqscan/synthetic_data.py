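"""Synthetic fixtures with known ground truth.

Emulates the statistical structure of the real inputs the pipeline was
designed for: seed alignments of diverged family members, bacterial
proteomes in which those members hide among unrelated decoy proteins,
gene orders realizing a stated architecture inventory (adjacent / gapped
/ split across loci / dispersed / fused), and family alignments with
cysteine columns planted at stated conservation levels.

All generators are pure functions of (spec, seed): repeat runs are
byte-identical.  Decoy proteins are drawn from the background residue
distribution with lengths uniform in [150, 450] - long enough that
threshold-passing chance hits are negligible at calibrated E-values.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .io_formats import (
    AMINO_ACIDS,
    GeneFeature,
    GenomeAnnotation,
    SeedAlignment,
    SequenceRecord,
    ValidationError,
    make_alignment,
)

logger = logging.getLogger("ubiqscan")

CORE_FAMILIES = ("ubiT", "ubiU", "ubiV")

#: members of distinct loci are separated by more intervening genes than
#: the largest co-localization window used anywhere in the pipeline (10)
MIN_LOCUS_SEPARATION = 11

#: residues joining the two halves of a fusion protein
FUSION_LINKER_LENGTH = 10

_AA_BYTES = np.frombuffer(AMINO_ACIDS.encode(), dtype=np.uint8)


def _rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def random_protein(rng: np.random.Generator, length: int,
                   background: np.ndarray | None = None) -> str:
    if background is None:
        draws = rng.integers(0, 20, size=length)
        return bytes(_AA_BYTES[draws]).decode()
    return bytes(rng.choice(_AA_BYTES, size=length, p=background)).decode()


def gen_consensus(family: str, length: int, seed: int) -> SequenceRecord:
    """A random background-composition consensus sequence for one family."""
    return SequenceRecord(f"{family}_consensus", random_protein(_rng(seed), length))


def default_consensi(seed: int = 0) -> dict[str, SequenceRecord]:
    """Consensus sequences at the approximate real protein lengths
    (ubiT ~174 aa, ubiU ~330 aa, ubiV ~300 aa)."""
    lengths = {"ubiT": 174, "ubiU": 330, "ubiV": 300}
    return {
        fam: gen_consensus(fam, n, seed * 1000 + i)
        for i, (fam, n) in enumerate(lengths.items())
    }


def mutate_sequence(residues: str, divergence: float,
                    rng: np.random.Generator) -> str:
    """I.i.d. per-site substitution, uniform over the 19 alternatives."""
    arr = np.frombuffer(residues.encode(), dtype=np.uint8).copy()
    idx = np.where(rng.random(arr.shape[0]) < divergence)[0]
    if idx.size:
        choices = _AA_BYTES[rng.integers(0, 19, size=idx.size)]
        # remap collisions with the original residue onto the 20th letter,
        # which keeps the draw uniform over the 19 alternatives
        choices[choices == arr[idx]] = _AA_BYTES[19]
        arr[idx] = choices
    return bytes(arr).decode()


def gen_family_members(
    consensus: SequenceRecord, n: int, divergence: float, seed: int
) -> list[SequenceRecord]:
    """n diverged copies of a consensus; expected identity = 1 - divergence."""
    if n < 1:
        raise ValidationError("n must be >= 1")
    if not (0.0 <= divergence < 1.0):
        raise ValidationError("divergence must be in [0, 1)")
    rng = _rng(seed)
    return [
        SequenceRecord(f"{consensus.id}_m{i}", mutate_sequence(consensus.residues, divergence, rng))
        for i in range(n)
    ]


def gen_seed_alignment(
    consensus: SequenceRecord, n_rows: int, divergence: float, seed: int
) -> SeedAlignment:
    """Trivial (ungapped) alignment of diverged family members."""
    members = gen_family_members(consensus, n_rows, divergence, seed)
    return make_alignment((m.id, m.residues) for m in members)


# ---------------------------------------------------------------------------
# genome panels
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ArchSpec:
    """One architecture condition with its genome count.

    kind: three_gene_locus | two_gene_locus | dispersed | incomplete | fusion.
    ``gaps`` are the intervening-gene counts inside the locus: for a
    three-gene locus (gap T-U, gap U-V); for a two-gene locus a single gap
    between the paired genes.  ``pair`` names the co-localized families of
    a two-gene locus; ``present`` names the families of an incomplete
    genome.
    """

    kind: str
    count: int
    gaps: tuple[int, ...] = (0, 0)
    pair: tuple[str, str] = ("ubiU", "ubiV")
    present: tuple[str, ...] = ("ubiT",)

    def __post_init__(self) -> None:
        kinds = {"three_gene_locus", "two_gene_locus", "dispersed",
                 "incomplete", "fusion"}
        if self.kind not in kinds:
            raise ValidationError(f"unknown architecture kind {self.kind!r}")
        if self.count < 0:
            raise ValidationError("count must be >= 0")
        if any(g < 0 for g in self.gaps):
            raise ValidationError("gaps must be >= 0")


@dataclass(frozen=True)
class GenomeSimSpec:
    inventory: tuple[ArchSpec, ...]
    decoys_per_genome: int = 36
    divergence: float = 0.0
    taxon_orders: tuple[str, ...] = (
        "Enterobacterales", "Burkholderiales", "Rhodospirillales",
    )
    seed: int = 0

    @property
    def n_genomes(self) -> int:
        return sum(a.count for a in self.inventory)


@dataclass(frozen=True)
class SyntheticGenome:
    """One generated genome with its ground truth."""

    annotation: GenomeAnnotation
    proteome: tuple[SequenceRecord, ...]
    assignments: Mapping[str, tuple[str, ...]]  # planted protein -> families
    truth: Mapping[str, object]  # arch_class, adjacent, gaps, taxon_order

    @property
    def genome_id(self) -> str:
        return self.annotation.genome_id

    @property
    def proteome_by_id(self) -> dict[str, SequenceRecord]:
        return {r.id: r for r in self.proteome}


def _member_layout(arch: ArchSpec, m: int, rng: np.random.Generator):
    """Ranks and family tuples for the planted genes of one genome.

    Returns (list of (rank, families tuple), expected class, expected
    ubiU-ubiV adjacency).  Distinct loci are separated by at least
    MIN_LOCUS_SEPARATION intervening genes.
    """
    sep = MIN_LOCUS_SEPARATION

    def spaced(n_points: int) -> list[int]:
        # evenly spread points; guaranteed pairwise separation > sep
        if n_points == 1:
            return [int(rng.integers(0, m))]
        pts = [round(i * (m - 1) / (n_points - 1)) for i in range(n_points)]
        for a, b in zip(pts, pts[1:]):
            if b - a - 1 < sep:
                raise ValidationError(
                    f"architecture {arch.kind!r} needs a larger replicon: "
                    f"{m} genes leave only {b - a - 1} intervening"
                )
        return pts

    if arch.kind == "three_gene_locus":
        g1, g2 = arch.gaps[0], arch.gaps[1]
        span = 3 + g1 + g2
        if span > m:
            raise ValidationError(
                f"gap signature {arch.gaps} incompatible with {m} genes per replicon"
            )
        s = int(rng.integers(0, m - span + 1))
        ranks = [s, s + 1 + g1, s + 2 + g1 + g2]
        placed = list(zip(ranks, [("ubiT",), ("ubiU",), ("ubiV",)]))
        return placed, "three_gene_locus", g2 == 0

    if arch.kind == "fusion":
        s = int(rng.integers(0, m - 1))
        placed = [(s, ("ubiT", "ubiU")), (s + 1, ("ubiV",))]
        return placed, "three_gene_locus", True

    if arch.kind == "two_gene_locus":
        g = arch.gaps[0]
        span = 2 + g
        if span + sep + 1 > m:
            raise ValidationError(
                f"two-gene layout incompatible with {m} genes per replicon"
            )
        s = int(rng.integers(0, 2))
        third_rank = m - 1 - int(rng.integers(0, 2))
        if third_rank - (s + span - 1) - 1 < sep:
            raise ValidationError(
                f"two-gene layout incompatible with {m} genes per replicon"
            )
        a, b = arch.pair
        third = next(f for f in CORE_FAMILIES if f not in arch.pair)
        placed = [(s, (a,)), (s + 1 + g, (b,)), (third_rank, (third,))]
        adjacent = g == 0 and set(arch.pair) == {"ubiU", "ubiV"}
        return placed, "two_gene_locus", adjacent

    if arch.kind == "dispersed":
        ranks = spaced(3)
        placed = list(zip(ranks, [("ubiT",), ("ubiU",), ("ubiV",)]))
        return placed, "dispersed", False

    # incomplete
    fams = arch.present
    ranks = spaced(len(fams))
    placed = [(r, (f,)) for r, f in zip(sorted(ranks), fams)]
    return placed, "incomplete", False


def gen_genome_set(
    spec: GenomeSimSpec,
    consensi: Mapping[str, SequenceRecord] | None = None,
) -> list[SyntheticGenome]:
    """Generate one genome per inventory slot, with truth tables.

    Each genome is a single replicon of decoy genes plus family members
    placed to realize exactly its assigned architecture and gap signature.
    Fusion genomes carry one protein concatenating two family members
    through a short background-composition linker.  Deterministic given
    ``spec.seed``.
    """
    if consensi is None:
        consensi = default_consensi(spec.seed)
    for fam in CORE_FAMILIES:
        if fam not in consensi:
            raise ValidationError(f"consensus for family {fam!r} missing")
    master = _rng(spec.seed)
    genomes: list[SyntheticGenome] = []
    idx = 0
    for arch in spec.inventory:
        for _ in range(arch.count):
            gid = f"G{idx:04d}"
            taxon = spec.taxon_orders[idx % len(spec.taxon_orders)]
            rng = _rng(int(master.integers(0, 2**31 - 1)))
            n_member_genes = {
                "three_gene_locus": 3, "two_gene_locus": 3, "dispersed": 3,
                "fusion": 2, "incomplete": len(arch.present),
            }[arch.kind]
            m = spec.decoys_per_genome + n_member_genes
            placed, expected_class, expected_adjacent = _member_layout(arch, m, rng)
            member_ranks = {rank: fams for rank, fams in placed}
            features: list[GeneFeature] = []
            proteome: list[SequenceRecord] = []
            assignments: dict[str, tuple[str, ...]] = {}
            gap_truth = []
            prev_rank = None
            for rank in range(m):
                pid = f"{gid}|p{rank:04d}"
                strand = "+" if rng.random() < 0.5 else "-"
                if rank in member_ranks:
                    fams = member_ranks[rank]
                    parts = [
                        mutate_sequence(consensi[f].residues, spec.divergence, rng)
                        for f in fams
                    ]
                    if len(parts) > 1:  # fusion protein
                        linker = random_protein(rng, FUSION_LINKER_LENGTH)
                        residues = linker.join(parts)
                    else:
                        residues = parts[0]
                    proteome.append(SequenceRecord(pid, residues))
                    assignments[pid] = fams
                    if prev_rank is not None:
                        gap_truth.append(rank - prev_rank - 1)
                    prev_rank = rank
                else:
                    length = int(rng.integers(150, 451))
                    proteome.append(SequenceRecord(pid, random_protein(rng, length)))
                features.append(GeneFeature(gid, "chr", rank, strand, pid, taxon))
            annotation = GenomeAnnotation(gid, {"chr": features})
            truth = {
                "genome_id": gid,
                "arch_class": expected_class,
                "ubiU_ubiV_adjacent": expected_adjacent,
                "gaps": tuple(gap_truth),
                "taxon_order": taxon,
                "n_planted": len(assignments),
            }
            genomes.append(
                SyntheticGenome(annotation, tuple(proteome), assignments, truth)
            )
            idx += 1
    logger.info("generated %d synthetic genomes", len(genomes))
    return genomes


def printed_architecture_inventory() -> tuple[ArchSpec, ...]:
    """The published architecture inventory of the complete genomes:
    106 three-gene loci, 82 two-gene loci of which 39 carry the ubiU-ubiV
    pair adjacent (the rest co-localize ubiT with ubiU), and 21 genomes
    with the three genes dispersed."""
    return (
        ArchSpec("three_gene_locus", 106, gaps=(0, 0)),
        ArchSpec("two_gene_locus", 39, gaps=(0,), pair=("ubiU", "ubiV")),
        ArchSpec("two_gene_locus", 43, gaps=(0,), pair=("ubiT", "ubiU")),
        ArchSpec("dispersed", 21),
    )


def cooccurrence_inventory() -> tuple[ArchSpec, ...]:
    """A 221-genome panel: 210 genomes with the full three-gene system
    (the architecture inventory plus one fusion genome) and 11 genomes
    carrying only a subset of the families."""
    return printed_architecture_inventory() + (
        ArchSpec("fusion", 1),
        ArchSpec("incomplete", 4, present=("ubiT",)),
        ArchSpec("incomplete", 4, present=("ubiU", "ubiV")),
        ArchSpec("incomplete", 3, present=("ubiV",)),
    )


def default_genome_spec(seed: int = 0) -> GenomeSimSpec:
    """The default end-to-end recovery fixture: a 12-genome panel covering
    every architecture, 200 decoy genes per genome, members diverged by
    20% from their family consensus."""
    inventory = (
        ArchSpec("three_gene_locus", 1, gaps=(0, 0)),
        ArchSpec("three_gene_locus", 1, gaps=(1, 0)),
        ArchSpec("three_gene_locus", 1, gaps=(3, 0)),
        ArchSpec("three_gene_locus", 1, gaps=(0, 1)),
        ArchSpec("two_gene_locus", 2, gaps=(0,), pair=("ubiU", "ubiV")),
        ArchSpec("two_gene_locus", 2, gaps=(0,), pair=("ubiT", "ubiU")),
        ArchSpec("dispersed", 2),
        ArchSpec("incomplete", 1, present=("ubiT",)),
        ArchSpec("incomplete", 1, present=("ubiU", "ubiV")),
    )
    return GenomeSimSpec(
        inventory=inventory, decoys_per_genome=200, divergence=0.2, seed=seed
    )


# ---------------------------------------------------------------------------
# motif alignments
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FamilyMotifSpec:
    name: str
    n_sequences: int
    length: int
    positions: tuple[int, ...] = ()  # 1-based planted cysteine positions
    conservations: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if list(self.positions) != sorted(set(self.positions)):
            raise ValidationError("positions must be strictly increasing")
        if self.positions and self.positions[-1] > self.length:
            raise ValidationError("planted position outside sequence length")
        if len(self.positions) != len(self.conservations):
            raise ValidationError("positions and conservations differ in length")
        if any(not (0.0 <= c <= 1.0) for c in self.conservations):
            raise ValidationError("conservation targets must be in [0, 1]")


@dataclass(frozen=True)
class MotifSimSpec:
    families: tuple[FamilyMotifSpec, ...]
    seed: int = 0
    bernoulli: bool = False  # sample per-row C carriage instead of exact counts


_NON_C = AMINO_ACIDS.replace("C", "")
_NON_C_BYTES = np.frombuffer(_NON_C.encode(), dtype=np.uint8)


def gen_motif_alignments(spec: MotifSimSpec) -> dict[str, SeedAlignment]:
    """Ungapped family alignments with planted cysteine-column conservation.

    At each planted position exactly round(conservation * n) rows carry C
    (Bernoulli sampling behind ``spec.bernoulli`` for stochastic tests);
    the first row - the reference by convention - is always among the
    carriers whenever the count allows.  All other sites are i.i.d.
    background residues.
    """
    master = _rng(spec.seed)
    out: dict[str, SeedAlignment] = {}
    for fam in spec.families:
        rng = _rng(int(master.integers(0, 2**31 - 1)))
        n, L = fam.n_sequences, fam.length
        grid = _AA_BYTES[rng.integers(0, 20, size=(n, L))]
        for pos, cons in zip(fam.positions, fam.conservations):
            col = pos - 1
            if spec.bernoulli:
                carriers = np.where(rng.random(n) < cons)[0]
            else:
                n_c = min(n, _round_half_up(cons * n))
                order = np.concatenate(([0], 1 + rng.permutation(n - 1)))
                carriers = order[:n_c]
            non_carriers = np.setdiff1d(np.arange(n), carriers)
            grid[carriers, col] = ord("C")
            grid[non_carriers, col] = _NON_C_BYTES[
                rng.integers(0, len(_NON_C), size=len(non_carriers))
            ]
        rows = [
            (f"{fam.name}_s{i}", bytes(grid[i]).decode()) for i in range(n)
        ]
        out[fam.name] = make_alignment(rows)
    return out


def default_motif_spec(seed: int = 0) -> MotifSimSpec:
    """A 10-family panel emulating the U32 peptidase family inventory:
    eight families with four cysteine columns planted at 97-100%
    conservation, one family with no cysteine columns, and one with two
    mildly (60-80%) plus three poorly (40-65%) conserved cysteines."""
    rng = _rng(seed)
    families = []
    for i in range(8):
        positions = tuple(
            int(p) for p in sorted(rng.choice(np.arange(20, 280), size=4, replace=False))
        )
        conservations = tuple(float(c) for c in rng.uniform(0.97, 1.0, size=4))
        families.append(
            FamilyMotifSpec(f"PepU32#{i + 1}", 100, 300, positions, conservations)
        )
    families.append(FamilyMotifSpec("PepU32#9", 100, 300))  # no planted Cys
    positions = tuple(
        int(p) for p in sorted(rng.choice(np.arange(20, 280), size=5, replace=False))
    )
    conservations = tuple(float(c) for c in rng.uniform(0.60, 0.80, size=2)) + tuple(
        float(c) for c in rng.uniform(0.40, 0.65, size=3)
    )
    families.append(
        FamilyMotifSpec("PepU32#10", 100, 300, positions, conservations)
    )
    return MotifSimSpec(families=tuple(families), seed=seed)
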