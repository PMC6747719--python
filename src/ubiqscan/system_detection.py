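"""Co-localized gene-system detection and architecture classification.

Given per-protein family assignments and gene order, member genes are
partitioned per replicon into loci: maximal runs in which each
consecutive pair of member genes has at most ``inter_gene_max_space``
non-member genes between them (the boundary case "exactly max_space
intervening" stays in the same locus).  Each genome is then classified
into an architecture class:

- ``three_gene_locus`` - all three core families present in one locus;
- ``two_gene_locus``   - all three present, exactly two share a locus;
- ``dispersed``        - all three present, no two share a locus;
- ``incomplete``       - fewer than three core families present.

Accessory families are carried along in loci but never drive the class.
A dual-family fusion protein contributes both of its families at one rank
and counts as adjacency for the pair it fuses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io_formats import GenomeAnnotation, SequenceRecord, SystemModel, ValidationError

logger = logging.getLogger("ubiqscan")

ARCH_CLASSES = ("three_gene_locus", "two_gene_locus", "dispersed", "incomplete")

#: default pair whose strict adjacency is reported per genome
DEFAULT_ADJACENT_PAIR = ("ubiU", "ubiV")


@dataclass(frozen=True)
class LocusMember:
    rank: int
    family: str
    protein_id: str


@dataclass(frozen=True)
class Locus:
    """A maximal co-localized run of system member genes on one replicon."""

    genome_id: str
    replicon_id: str
    members: tuple[LocusMember, ...]

    @property
    def span(self) -> tuple[int, int]:
        ranks = [m.rank for m in self.members]
        return (min(ranks), max(ranks))

    @property
    def families(self) -> frozenset[str]:
        return frozenset(m.family for m in self.members)

    @property
    def gap_signature(self) -> tuple[int, ...]:
        """Intervening non-member gene counts between consecutive members.

        Two families on one fusion protein share a rank and contribute an
        intervening count of 0.
        """
        out = []
        for a, b in zip(self.members, self.members[1:]):
            out.append(max(0, b.rank - a.rank - 1))
        return tuple(out)


@dataclass(frozen=True)
class ArchitectureCall:
    genome_id: str
    arch_class: str
    present_families: frozenset[str]
    loci: tuple[Locus, ...]
    ubiU_ubiV_adjacent: bool
    gap_signature: tuple[tuple[int, ...], ...]  # one tuple per locus


@dataclass(frozen=True)
class CooccurrenceSummary:
    """Presence/absence statistics over a genome panel."""

    n_genomes: int
    n_with_any_core: int
    n_with_all_core: int
    n_with_all_markers: int
    n_with_two_markers: int
    n_all_core_no_hydroxylase: int
    pct_all_core_of_any: int | None  # headline, rounded to nearest integer
    frac_all_core_of_any: float | None  # exact fraction

    def __post_init__(self) -> None:
        if self.n_with_all_core > self.n_with_any_core:
            raise ValidationError("all-core count exceeds at-least-one count")


def normalize_assignments(
    assignments: Mapping[str, object], model: SystemModel
) -> dict[str, tuple[str, ...]]:
    """Collapse exchangeable groups and restrict to model families.

    Accepts a single family or an iterable of families (fusion proteins)
    per protein; returns protein_id -> tuple of logical family names.
    """
    out: dict[str, tuple[str, ...]] = {}
    for pid, fam in assignments.items():
        fams = (fam,) if isinstance(fam, str) else tuple(fam)
        logical = tuple(
            model.logical_family(f) for f in fams
            if model.logical_family(f) in model.logical_families
        )
        if logical:
            out[pid] = logical
    return out


def detect_loci(
    assignments: Mapping[str, object],
    genome: GenomeAnnotation,
    model: SystemModel,
) -> list[Locus]:
    """Partition member genes of one genome into loci, per replicon.

    ``assignments`` maps protein ids of this genome to a family name (or an
    iterable of family names for fusion proteins); exchangeable groups are
    collapsed internally.  A protein id absent from the genome raises an
    error naming it.  Singleton loci are allowed.  On circular replicons
    the intervening count wraps around rank m-1 -> 0 and the terminal loci
    are merged when the wrap gap is within ``inter_gene_max_space``.
    """
    logical = normalize_assignments(assignments, model)
    known = genome.protein_ids
    for pid in assignments:
        if pid not in known:
            raise ValidationError(
                f"protein {pid!r} not found in genome {genome.genome_id!r}"
            )
    loci: list[Locus] = []
    for rep_id, feats in genome.replicons.items():
        members: list[LocusMember] = []
        for f in feats:
            for fam in logical.get(f.protein_id, ()):
                members.append(LocusMember(f.rank, fam, f.protein_id))
        if not members:
            continue
        members.sort(key=lambda m: (m.rank, m.family))
        runs: list[list[LocusMember]] = [[members[0]]]
        for m in members[1:]:
            gap = m.rank - runs[-1][-1].rank - 1
            if gap <= model.inter_gene_max_space:
                runs[-1].append(m)
            else:
                runs.append([m])
        if genome.is_circular(rep_id) and len(runs) > 1:
            m_total = len(feats)
            wrap_gap = (m_total - runs[-1][-1].rank - 1) + runs[0][0].rank
            if wrap_gap <= model.inter_gene_max_space:
                runs[0] = runs.pop() + runs[0]
        loci.extend(
            Locus(genome.genome_id, rep_id, tuple(run)) for run in runs
        )
    return loci


def classify_architecture(
    loci: Sequence[Locus],
    model: SystemModel,
    genome_id: str | None = None,
    adjacent_pair: tuple[str, str] = DEFAULT_ADJACENT_PAIR,
) -> ArchitectureCall:
    """Classify one genome's loci into the architecture taxonomy.

    The class is determined by the best locus: a locus holding all three
    core (logical mandatory) families beats one holding two, which beats
    none sharing (three_gene_locus > two_gene_locus > dispersed).
    Adjacency of ``adjacent_pair`` is true iff some locus carries both
    families at consecutive ranks (0 intervening genes) or on a single
    fusion protein.
    """
    core = model.logical_mandatory
    if genome_id is None:
        genome_id = loci[0].genome_id if loci else "?"
    present = frozenset().union(*[l.families for l in loci]) if loci else frozenset()
    present_core = present & core
    if len(present_core) < len(core):
        arch = "incomplete"
    else:
        best = max((len(l.families & core) for l in loci), default=0)
        if best >= len(core):
            arch = "three_gene_locus"
        elif best >= 2:
            arch = "two_gene_locus"
        else:
            arch = "dispersed"
    pair = frozenset(model.logical_family(f) for f in adjacent_pair)
    adjacent = False
    for locus in loci:
        for a, b in zip(locus.members, locus.members[1:]):
            gap = max(0, b.rank - a.rank - 1)
            if gap == 0 and frozenset((a.family, b.family)) == pair:
                adjacent = True
    return ArchitectureCall(
        genome_id=genome_id,
        arch_class=arch,
        present_families=present,
        loci=tuple(loci),
        ubiU_ubiV_adjacent=adjacent,
        gap_signature=tuple(l.gap_signature for l in loci),
    )


def call_genome(
    assignments: Mapping[str, object],
    genome: GenomeAnnotation,
    model: SystemModel,
    adjacent_pair: tuple[str, str] = DEFAULT_ADJACENT_PAIR,
) -> ArchitectureCall:
    """detect_loci + classify_architecture for one genome.

    Only core (mandatory) families take part in locus partitioning for the
    class call, so accessory members cannot bridge or split core loci.
    """
    core_assignments = {}
    for pid, fams in normalize_assignments(assignments, model).items():
        core = tuple(f for f in fams if f in model.logical_mandatory)
        if core:
            core_assignments[pid] = core
    loci = detect_loci(core_assignments, genome, model)
    return classify_architecture(
        loci, model, genome_id=genome.genome_id, adjacent_pair=adjacent_pair
    )


# ---------------------------------------------------------------------------
# panel summaries
# ---------------------------------------------------------------------------

DEFAULT_MARKERS = frozenset({"ubiA", "ubiE", "ubiG"})
DEFAULT_HYDROXYLASES = frozenset(
    {"ubiF", "ubiH", "ubiI", "ubiL", "ubiM", "coq7"}
)


def cooccurrence_summary(
    calls: Sequence[ArchitectureCall],
    marker_presence: Mapping[str, Iterable[str]] | None = None,
    core_families: frozenset[str] = frozenset({"ubiT", "ubiU", "ubiV"}),
    marker_families: frozenset[str] = DEFAULT_MARKERS,
    hydroxylase_families: frozenset[str] = DEFAULT_HYDROXYLASES,
) -> CooccurrenceSummary:
    """Panel-level presence/absence counts and the headline percentage.

    ``marker_presence`` maps genome_id to the set of additional (marker and
    hydroxylase) families found in that genome.  The headline percentage is
    all-three among at-least-one, rounded to the nearest integer; the exact
    fraction is reported alongside.
    """
    seen: set[str] = set()
    for c in calls:
        if c.genome_id in seen:
            raise ValidationError(f"duplicate genome id {c.genome_id!r}")
        seen.add(c.genome_id)
    marker_presence = {k: frozenset(v) for k, v in (marker_presence or {}).items()}
    n_any = 0
    n_all = 0
    n_all_markers = 0
    n_two_markers = 0
    n_all_core_no_hyd = 0
    for c in calls:
        core_present = c.present_families & core_families
        extra = marker_presence.get(c.genome_id, frozenset())
        if core_present:
            n_any += 1
        if core_present == core_families:
            n_all += 1
            if not (extra & hydroxylase_families):
                n_all_core_no_hyd += 1
        n_mark = len(extra & marker_families)
        if n_mark == len(marker_families):
            n_all_markers += 1
        if n_mark >= 2:
            n_two_markers += 1
    if n_any:
        frac = n_all / n_any
        pct = round(100.0 * frac)
    else:
        frac = None
        pct = None
    return CooccurrenceSummary(
        n_genomes=len(calls),
        n_with_any_core=n_any,
        n_with_all_core=n_all,
        n_with_all_markers=n_all_markers,
        n_with_two_markers=n_two_markers,
        n_all_core_no_hydroxylase=n_all_core_no_hyd,
        pct_all_core_of_any=pct,
        frac_all_core_of_any=frac,
    )


def adjacency_fraction(calls: Sequence[ArchitectureCall]) -> float | None:
    """Fraction of complete genomes in which the focal pair is adjacent.

    Restricted to genomes with all three core families (class !=
    incomplete); returns None on empty input.
    """
    complete = [c for c in calls if c.arch_class != "incomplete"]
    if not complete:
        return None
    return sum(c.ubiU_ubiV_adjacent for c in complete) / len(complete)


def summarize_by_taxon(
    calls: Sequence[ArchitectureCall],
    taxon_orders: Mapping[str, str],
) -> pd.DataFrame:
    """Per-taxon-order panel table (Fig-3A-style proportions).

    Columns: taxon_order, n_genomes, frac_all_three (genomes with all core
    families), frac_single_locus (of those, fraction with one 3-gene
    locus).  Orders are sorted lexicographically; an unlabeled genome
    raises an error naming it.
    """
    rows = []
    for c in calls:
        if c.genome_id not in taxon_orders:
            raise ValidationError(f"genome {c.genome_id!r} has no taxon order label")
        rows.append(
            {
                "taxon_order": taxon_orders[c.genome_id],
                "all_three": c.arch_class != "incomplete",
                "single_locus": c.arch_class == "three_gene_locus",
            }
        )
    df = pd.DataFrame(rows)
    grouped = df.groupby("taxon_order", sort=True)
    out = pd.DataFrame(
        {
            "n_genomes": grouped.size(),
            "frac_all_three": grouped["all_three"].mean(),
        }
    )
    single = df[df["all_three"]].groupby("taxon_order")["single_locus"].mean()
    out["frac_single_locus"] = single.reindex(out.index)
    return out.reset_index()


def reseed_colocalized_profile(
    calls: Sequence[ArchitectureCall],
    proteome: Mapping[str, SequenceRecord],
    anchor_families: frozenset[str] | set[str],
    target_family: str,
) -> list[SequenceRecord]:
    """Collect target-family sequences co-localized with all anchors.

    Scans each genome's loci for one containing the target family together
    with every anchor family and returns the target member sequences in
    input order, for use as a fresh seed set (trim -> build -> calibrate).
    Returns an empty list (with a warning) when nothing co-localizes.
    """
    anchors = frozenset(anchor_families)
    out: list[SequenceRecord] = []
    seen: set[str] = set()
    for call in calls:
        for locus in call.loci:
            if anchors <= locus.families and target_family in locus.families:
                for m in locus.members:
                    if m.family == target_family and m.protein_id not in seen:
                        seen.add(m.protein_id)
                        out.append(proteome[m.protein_id])
    if not out:
        logger.warning(
            "no %s sequences co-localized with %s", target_family, sorted(anchors)
        )
    return out


def calls_to_rows(calls: Sequence[ArchitectureCall]) -> list[dict]:
    """Flatten calls for TSV reporting."""
    rows = []
    for c in calls:
        rows.append(
            {
                "genome": c.genome_id,
                "class": c.arch_class,
                "present_families": ",".join(sorted(c.present_families)),
                "ubiU_ubiV_adjacent": c.ubiU_ubiV_adjacent,
                "n_loci": len(c.loci),
                "gap_signature": ";".join(
                    "-".join(str(g) for g in sig) if sig else "."
                    for sig in c.gap_signature
                ),
                "loci_spans": ";".join(
                    f"{l.replicon_id}:{l.span[0]}-{l.span[1]}" for l in c.loci
                ),
            }
        )
    return rows
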