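"""Greedy centroid dereplication of protein sets at a fixed identity level.

Used to limit taxonomic sampling bias before building alignments and
motif statistics: sequences within the identity threshold of an existing
centroid are absorbed, everything else founds a new centroid.  The
identity convention is fixed and documented here (matches over all
alignment columns, gap columns included in the denominator) because
clustering tools vary on this point.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

from Bio.Align import PairwiseAligner, substitution_matrices

from .io_formats import SequenceRecord

logger = logging.getLogger("ubiqscan")


@dataclass(frozen=True)
class IdentityResult:
    seq_a: str
    seq_b: str
    identity: float
    aligned_length: int


def _make_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -1.0
    return aligner


_ALIGNER = _make_aligner()


def pairwise_identity(a: SequenceRecord, b: SequenceRecord) -> IdentityResult:
    """Global affine-gap alignment identity between two protein sequences.

    identity = identical aligned residue pairs / alignment columns, with
    gap columns counted in the denominator; symmetric in (a, b).
    """
    alignment = _ALIGNER.align(a.residues, b.residues)[0]
    row_a = str(alignment[0])
    row_b = str(alignment[1])
    matches = sum(
        1 for x, y in zip(row_a, row_b) if x == y and x != "-"
    )
    columns = len(row_a)
    return IdentityResult(a.id, b.id, matches / columns, columns)


def dereplicate(
    seqs: Sequence[SequenceRecord], threshold: float = 0.8
) -> tuple[list[SequenceRecord], dict[str, str]]:
    """Single-pass greedy clustering at the given identity threshold.

    Sequences are processed in descending length order (ties broken by id),
    which makes the result independent of input order.  Each sequence joins
    the first existing centroid with identity >= threshold, else it becomes
    a new centroid.  Returns (centroids, membership mapping id -> centroid
    id); centroids are members of their own cluster.
    """
    if not seqs:
        raise ValueError("dereplicate: empty input")
    if not (0.0 <= threshold <= 1.0):
        raise ValueError("threshold outside [0, 1]")
    ordered = sorted(seqs, key=lambda s: (-len(s.residues), s.id))
    centroids: list[SequenceRecord] = []
    membership: dict[str, str] = {}
    for seq in ordered:
        assigned = False
        for centroid in centroids:
            if pairwise_identity(centroid, seq).identity >= threshold:
                membership[seq.id] = centroid.id
                assigned = True
                break
        if not assigned:
            centroids.append(seq)
            membership[seq.id] = seq.id
    logger.debug(
        "dereplicated %d sequences into %d centroids at %.0f%% identity",
        len(seqs), len(centroids), 100 * threshold,
    )
    return centroids, membership


def merge_families(
    *family_sets: Sequence[SequenceRecord], label: str | None = None
) -> list[SequenceRecord]:
    """Concatenate several family sequence sets under one label.

    Data-preparation convenience for families that were split into domain
    halves upstream (e.g. the two RlhA domain families): the whole
    sequences are pooled into one set before dereplication.  Duplicate ids
    keep their first occurrence.
    """
    seen: set[str] = set()
    merged: list[SequenceRecord] = []
    for family in family_sets:
        for seq in family:
            if seq.id not in seen:
                seen.add(seq.id)
                merged.append(seq)
    if label:
        logger.info("merged %d sequences under family %r", len(merged), label)
    return merged
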