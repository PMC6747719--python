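"""Conserved-cysteine columns and CX_nC spacing patterns in family alignments.

Candidate iron-sulfur ligand motifs are detected as alignment columns
whose cysteine conservation reaches a threshold (97% by default, the
level observed for 4-Cys clusters in most U32 peptidase families).
Conservation is counted over *all* rows, gaps included in the
denominator: a sequence gapped at the column lacks the cysteine and
counts against conservation.

Conserved columns are mapped to 1-based ungapped positions on a
reference row (first row by default) and rendered as a spacing pattern:
``CX6CX16CX38C`` means 6, 16 and 38 residues between consecutive
conserved cysteines.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Mapping, Sequence

from .io_formats import GAP, SeedAlignment, ValidationError

logger = logging.getLogger("ubiqscan")


@dataclass(frozen=True)
class ColumnComposition:
    index: int
    counts: Mapping[str, int]  # residues plus the gap character
    cys_conservation: float

    @property
    def n_rows(self) -> int:
        return sum(self.counts.values())


@dataclass(frozen=True)
class CysMotif:
    """Ordered conserved cysteines on a reference sequence."""

    family: str
    reference_id: str
    positions: tuple[int, ...]  # strictly increasing, 1-based ungapped
    spacings: tuple[int, ...]
    pattern: str
    column_conservations: tuple[float, ...]


def column_composition(aln: SeedAlignment) -> list[ColumnComposition]:
    """Residue counts and cysteine conservation for every column."""
    out = []
    n_rows = aln.n_rows
    for c in range(aln.n_columns):
        col = aln.column(c)
        counts = {ch: col.count(ch) for ch in set(col)}
        out.append(
            ColumnComposition(
                index=c,
                counts=counts,
                cys_conservation=counts.get("C", 0) / n_rows,
            )
        )
    return out


def detect_cys_cluster(
    compositions: Sequence[ColumnComposition],
    min_conservation: float = 0.97,
    k: int = 4,
) -> list[list[int]]:
    """Maximal runs of cysteine-conserved columns, in alignment order.

    A column qualifies when cys_conservation >= min_conservation; the
    family "has a conserved k-Cys cluster" when the total number of
    qualifying columns is at least ``k`` (see :func:`has_cys_cluster`).
    """
    if not (0.0 < min_conservation <= 1.0):
        raise ValidationError("min_conservation must be in (0, 1]")
    if k < 1:
        raise ValidationError("k must be >= 1")
    runs: list[list[int]] = []
    for comp in compositions:
        if comp.cys_conservation >= min_conservation:
            if runs and runs[-1][-1] == comp.index - 1:
                runs[-1].append(comp.index)
            else:
                runs.append([comp.index])
    return runs


def conserved_cys_columns(
    compositions: Sequence[ColumnComposition],
    min_conservation: float = 0.97,
) -> list[int]:
    return [c for run in detect_cys_cluster(compositions, min_conservation, 1) for c in run]


def has_cys_cluster(
    compositions: Sequence[ColumnComposition],
    min_conservation: float = 0.97,
    k: int = 4,
) -> bool:
    runs = detect_cys_cluster(compositions, min_conservation, k)
    return sum(len(r) for r in runs) >= k


def map_columns_to_reference(
    aln: SeedAlignment, reference_id: str, columns: Sequence[int]
) -> list[int]:
    """Convert alignment column indices to 1-based ungapped reference positions.

    Position = number of non-gap reference residues in columns 0..c
    inclusive.  A reference gap at a requested column raises an error
    naming the column.
    """
    ref = None
    for name, s in aln.rows:
        if name == reference_id:
            ref = s
            break
    if ref is None:
        raise ValidationError(f"reference {reference_id!r} not in alignment")
    positions = []
    for c in columns:
        if not (0 <= c < len(ref)):
            raise ValidationError(f"column {c} outside alignment")
        if ref[c] == GAP:
            raise ValidationError(
                f"reference {reference_id!r} is gapped at column {c}"
            )
        positions.append(sum(1 for ch in ref[: c + 1] if ch != GAP))
    return positions


def spacing_pattern(positions: Sequence[int]) -> str:
    """Render strictly increasing 1-based positions as a CX{n}C pattern.

    n = residues between consecutive cysteines; n = 0 renders as "CC".
    """
    if not positions:
        raise ValidationError("no positions")
    for a, b in zip(positions, positions[1:]):
        if b <= a:
            raise ValidationError("positions must be strictly increasing")
    parts = ["C"]
    for a, b in zip(positions, positions[1:]):
        n = b - a - 1
        parts.append("C" if n == 0 else f"X{n}C")
    return "".join(parts)


_PATTERN_RE = re.compile(r"^C(?:(?:X\d+)?C)*$")


def parse_spacing_pattern(pattern: str) -> list[int]:
    """Inverse of :func:`spacing_pattern`: recover the spacing list."""
    if not _PATTERN_RE.match(pattern):
        raise ValidationError(f"malformed spacing pattern {pattern!r}")
    spacings = []
    i = 1  # skip leading C
    while i < len(pattern):
        if pattern[i] == "C":
            spacings.append(0)
            i += 1
        else:  # X<digits>C
            j = i + 1
            while pattern[j].isdigit():
                j += 1
            spacings.append(int(pattern[i + 1 : j]))
            i = j + 1
    return spacings


def extract_family_motif(
    aln: SeedAlignment,
    family: str,
    reference_id: str | None = None,
    min_conservation: float = 0.97,
    k: int = 4,
) -> CysMotif | None:
    """Full per-family motif extraction; None when no k-Cys cluster exists.

    When more than ``k`` conserved columns exist the motif lists all of
    them in order - ``k`` is a minimum, not a selection.
    """
    if reference_id is None:
        reference_id = aln.rows[0][0]
    comps = column_composition(aln)
    if not has_cys_cluster(comps, min_conservation, k):
        return None
    columns = conserved_cys_columns(comps, min_conservation)
    positions = map_columns_to_reference(aln, reference_id, columns)
    conservations = tuple(comps[c].cys_conservation for c in columns)
    pattern = spacing_pattern(positions)
    spacings = tuple(b - a - 1 for a, b in zip(positions, positions[1:]))
    return CysMotif(
        family=family,
        reference_id=reference_id,
        positions=tuple(positions),
        spacings=spacings,
        pattern=pattern,
        column_conservations=conservations,
    )


def family_motif_report(
    families: Mapping[str, tuple[SeedAlignment, str | None]],
    min_conservation: float = 0.97,
    k: int = 4,
) -> list[dict]:
    """One report row per family: cluster flag, pattern, conservations.

    ``families`` maps family name to (alignment, reference id or None for
    the first row).  Errors from member operations are re-raised with the
    family name attached.
    """
    rows = []
    for family, (aln, ref) in families.items():
        try:
            motif = extract_family_motif(aln, family, ref, min_conservation, k)
        except ValidationError as exc:
            raise ValidationError(f"family {family!r}: {exc}") from exc
        if motif is None:
            rows.append(
                {
                    "family": family,
                    "has_cluster": False,
                    "n_conserved_cys": 0,
                    "pattern": "",
                    "positions": "",
                    "conservations": "",
                }
            )
        else:
            rows.append(
                {
                    "family": family,
                    "has_cluster": True,
                    "n_conserved_cys": len(motif.positions),
                    "pattern": motif.pattern,
                    "positions": ",".join(str(p) for p in motif.positions),
                    "conservations": ",".join(
                        format(c, ".4g") for c in motif.column_conservations
                    ),
                }
            )
    return rows
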