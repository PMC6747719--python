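"""Readers and writers for the formats the pipeline touches.

Sequences travel as FASTA, alignments as aligned FASTA, gene order as
GFF3 or a 6-column TSV, gene-system models as JSON (YAML accepted as a
convenience alias of the same schema) and every report as TSV.

Gene coordinates are *rank-based*: a gene's coordinate is its 0-based
position in gene order along its replicon.  Co-localization counts
intervening genes, so base-pair distances are never needed.  Strand is
parsed and retained but ignored downstream.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

logger = logging.getLogger("ubiqscan")

#: the 20 standard amino acids, in the conventional alphabetical one-letter order
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: residue alphabet accepted in sequence records (X = unknown residue)
ALPHABET = AMINO_ACIDS + "X"
GAP = "-"


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


class ValidationError(ValueError):
    """Raised when a parsed object violates a domain invariant."""


# ---------------------------------------------------------------------------
# sequences and alignments
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SequenceRecord:
    """An ungapped protein sequence with a unique id."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("sequence record with empty id")
        if not self.residues:
            raise ValidationError(f"sequence {self.id!r} has no residues")
        bad = set(self.residues) - set(ALPHABET)
        if bad:
            raise ValidationError(
                f"sequence {self.id!r} contains invalid characters {sorted(bad)!r}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class SeedAlignment:
    """A protein multiple alignment ('-' for gaps), row order preserved."""

    rows: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if len(self.rows) < 2:
            raise ValidationError("alignment needs at least 2 rows")
        width = len(self.rows[0][1])
        if width < 1:
            raise ValidationError("alignment has zero columns")
        for name, aligned in self.rows:
            if len(aligned) != width:
                raise ValidationError(
                    f"ragged alignment: row {name!r} has length "
                    f"{len(aligned)}, expected {width}"
                )
            ungapped = aligned.replace(GAP, "")
            if not ungapped:
                raise ValidationError(f"row {name!r} is all gaps")
            SequenceRecord(name, ungapped)  # ungapped row must be a valid record

    @property
    def n_columns(self) -> int:
        return len(self.rows[0][1])

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.rows)

    def column(self, i: int) -> str:
        return "".join(aligned[i] for _, aligned in self.rows)

    def ungapped(self, row_id: str) -> SequenceRecord:
        for name, aligned in self.rows:
            if name == row_id:
                return SequenceRecord(name, aligned.replace(GAP, ""))
        raise KeyError(row_id)


def make_alignment(rows: Iterable[tuple[str, str]]) -> SeedAlignment:
    return SeedAlignment(tuple((str(n), str(s).upper()) for n, s in rows))


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    records = [
        SequenceRecord(r.id, str(r.seq).upper(), r.description)
        for r in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    bio = [
        _BioSeqRecord(Seq(r.residues), id=r.id, description=r.description)
        for r in records
    ]
    SeqIO.write(bio, str(path), "fasta")


def read_alignment(path: str | Path) -> SeedAlignment:
    """Read an aligned FASTA file.

    Raises :class:`FormatError` naming the offending record on ragged rows
    and on empty files.
    """
    raw = [(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), "fasta")]
    if not raw:
        raise FormatError(f"{path}: empty alignment file")
    try:
        return make_alignment(raw)
    except ValidationError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_alignment(aln: SeedAlignment, path: str | Path) -> None:
    bio = [_BioSeqRecord(Seq(s), id=n, description="") for n, s in aln.rows]
    SeqIO.write(bio, str(path), "fasta")


# ---------------------------------------------------------------------------
# gene order
# ---------------------------------------------------------------------------

STRANDS = frozenset({"+", "-"})


@dataclass(frozen=True)
class GeneFeature:
    """One gene in rank-based coordinates on a replicon."""

    genome_id: str
    replicon_id: str
    rank: int
    strand: str
    protein_id: str
    taxon_order: str | None = None

    def __post_init__(self) -> None:
        if self.rank < 0:
            raise ValidationError(f"feature {self.protein_id!r}: negative rank")
        if self.strand not in STRANDS:
            raise ValidationError(
                f"feature {self.protein_id!r}: unknown strand {self.strand!r}"
            )


@dataclass
class GenomeAnnotation:
    """Ordered gene features per replicon for one genome.

    Within each replicon ranks are consecutive integers ``0..m-1``.
    ``circular`` marks replicons whose adjacency wraps around rank m-1 -> 0
    (default false).
    """

    genome_id: str
    replicons: dict[str, list[GeneFeature]]
    circular: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for rep, feats in self.replicons.items():
            ranks = [f.rank for f in feats]
            if ranks != list(range(len(feats))):
                raise ValidationError(
                    f"genome {self.genome_id!r} replicon {rep!r}: ranks are "
                    f"not consecutive 0-based integers"
                )

    def is_circular(self, replicon_id: str) -> bool:
        return bool(self.circular.get(replicon_id, False))

    @property
    def protein_ids(self) -> set[str]:
        return {f.protein_id for feats in self.replicons.values() for f in feats}

    def feature_of(self, protein_id: str) -> GeneFeature:
        for feats in self.replicons.values():
            for f in feats:
                if f.protein_id == protein_id:
                    return f
        raise KeyError(protein_id)

    @property
    def taxon_order(self) -> str | None:
        for feats in self.replicons.values():
            for f in feats:
                if f.taxon_order:
                    return f.taxon_order
        return None


def _normalise_strand(s: str) -> str:
    # tolerate the typographic minus that appears in some exports
    return "-" if s in {"-", "−"} else s


TSV_COLUMNS = ("genome", "replicon", "rank", "strand", "protein_id", "taxon_order")


def read_feature_table(path: str | Path, dialect: str = "tsv") -> GenomeAnnotation:
    """Read gene order from a 6-column TSV or a GFF3 file.

    TSV rows are (genome, replicon, rank, strand, protein_id, taxon_order);
    an optional header line repeating those names is skipped.  GFF3 CDS
    features are ordered per replicon by ascending start (1-based inclusive
    coordinates), ties broken by end then id, then re-indexed to consecutive
    0-based ranks.
    """
    if dialect == "tsv":
        return _read_feature_tsv(path)
    if dialect == "gff3":
        return _read_feature_gff3(path)
    raise ValueError(f"unknown feature-table dialect {dialect!r}")


def _read_feature_tsv(path: str | Path) -> GenomeAnnotation:
    per_replicon: dict[str, dict[int, GeneFeature]] = {}
    genome_id: str | None = None
    with open(path, newline="", encoding="utf-8") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or row[0].startswith("#"):
                continue
            if lineno == 1 and row[0] == "genome":
                continue  # header
            if len(row) < 5:
                raise FormatError(f"{path}:{lineno}: expected >=5 TSV columns")
            genome, replicon, rank_s, strand, protein_id = row[:5]
            taxon = row[5] if len(row) > 5 and row[5] else None
            if genome_id is None:
                genome_id = genome
            try:
                rank = int(rank_s)
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer rank {rank_s!r}")
            strand = _normalise_strand(strand)
            if strand not in STRANDS:
                raise FormatError(f"{path}:{lineno}: unknown strand {strand!r}")
            bucket = per_replicon.setdefault(replicon, {})
            if rank in bucket:
                raise FormatError(
                    f"{path}:{lineno}: duplicate rank {rank} on replicon "
                    f"{replicon!r}"
                )
            bucket[rank] = GeneFeature(genome, replicon, rank, strand, protein_id, taxon)
    if genome_id is None:
        raise FormatError(f"{path}: no feature rows found")
    replicons: dict[str, list[GeneFeature]] = {}
    for rep, bucket in per_replicon.items():
        ordered = [bucket[r] for r in sorted(bucket)]
        # re-index to consecutive 0-based ranks in input rank order
        replicons[rep] = [
            GeneFeature(f.genome_id, rep, i, f.strand, f.protein_id, f.taxon_order)
            for i, f in enumerate(ordered)
        ]
    return GenomeAnnotation(genome_id, replicons)


def _gff3_attributes(text: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for part in text.strip().split(";"):
        if "=" in part:
            k, v = part.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def _read_feature_gff3(path: str | Path) -> GenomeAnnotation:
    genome_id = Path(path).stem
    rows: dict[str, list[tuple[int, int, str, str]]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 GFF3 columns")
            seqid, _src, ftype, start_s, end_s, _score, strand, _phase, attrs = cols
            if ftype != "CDS":
                continue
            strand = _normalise_strand(strand)
            if strand not in STRANDS:
                raise FormatError(f"{path}:{lineno}: unknown strand {strand!r}")
            a = _gff3_attributes(attrs)
            protein_id = a.get("protein_id") or a.get("ID")
            if not protein_id:
                raise FormatError(
                    f"{path}:{lineno}: CDS without protein_id or ID attribute"
                )
            rows.setdefault(seqid, []).append(
                (int(start_s), int(end_s), protein_id, strand)
            )
    if not rows:
        raise FormatError(f"{path}: no CDS features found")
    replicons: dict[str, list[GeneFeature]] = {}
    for rep, feats in rows.items():
        feats.sort(key=lambda t: (t[0], t[1], t[2]))
        replicons[rep] = [
            GeneFeature(genome_id, rep, i, strand, pid)
            for i, (_s, _e, pid, strand) in enumerate(feats)
        ]
    return GenomeAnnotation(genome_id, replicons)


def write_feature_table(genome: GenomeAnnotation, path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(TSV_COLUMNS)
        for rep in genome.replicons:
            for f in genome.replicons[rep]:
                w.writerow(
                    [f.genome_id, f.replicon_id, f.rank, f.strand, f.protein_id,
                     f.taxon_order or ""]
                )


# ---------------------------------------------------------------------------
# system models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SystemModel:
    """Declarative description of a co-localized gene system.

    ``mandatory`` families must all be present for a complete system;
    ``accessory`` families are reported but never drive classification.
    Families in one ``exchangeable`` group are alternative profiles for the
    same logical component and are collapsed before locus detection.
    ``inter_gene_max_space`` is the maximum number of non-member genes
    allowed between two member genes of one locus.
    """

    name: str
    mandatory: frozenset[str]
    accessory: frozenset[str] = frozenset()
    exchangeable: tuple[tuple[str, ...], ...] = ()
    inter_gene_max_space: int = 5
    max_i_evalue: float = 1e-20
    min_profile_coverage: float = 0.8

    def __post_init__(self) -> None:
        if self.mandatory & self.accessory:
            raise ValidationError(
                f"model {self.name!r}: families both mandatory and accessory: "
                f"{sorted(self.mandatory & self.accessory)}"
            )
        declared = self.mandatory | self.accessory
        for group in self.exchangeable:
            for fam in group:
                if fam not in declared:
                    raise ValidationError(
                        f"model {self.name!r}: exchangeable family {fam!r} is "
                        f"not declared mandatory or accessory"
                    )
        if self.inter_gene_max_space < 0:
            raise ValidationError(
                f"model {self.name!r}: negative inter_gene_max_space"
            )
        if not (self.max_i_evalue > 0):
            raise ValidationError(f"model {self.name!r}: max_i_evalue must be > 0")
        if not (0.0 <= self.min_profile_coverage <= 1.0):
            raise ValidationError(
                f"model {self.name!r}: min_profile_coverage outside [0, 1]"
            )

    def logical_family(self, family: str) -> str:
        """Collapse an exchangeable-group member to its logical family name.

        The logical name of a group is its lexicographically first member, so
        collapsing is deterministic and idempotent.
        """
        for group in self.exchangeable:
            if family in group:
                return min(group)
        return family

    @property
    def logical_mandatory(self) -> frozenset[str]:
        return frozenset(self.logical_family(f) for f in self.mandatory)

    @property
    def logical_accessory(self) -> frozenset[str]:
        return frozenset(self.logical_family(f) for f in self.accessory)

    @property
    def logical_families(self) -> frozenset[str]:
        return self.logical_mandatory | self.logical_accessory


def system_model_from_dict(doc: Mapping, name: str = "system") -> SystemModel:
    return SystemModel(
        name=str(doc.get("name", name)),
        mandatory=frozenset(doc.get("mandatory", ())),
        accessory=frozenset(doc.get("accessory", ())),
        exchangeable=tuple(tuple(g) for g in doc.get("exchangeable", ())),
        inter_gene_max_space=int(doc.get("inter_gene_max_space", 5)),
        max_i_evalue=float(doc.get("max_i_evalue", 1e-20)),
        min_profile_coverage=float(doc.get("min_profile_coverage", 0.8)),
    )


def read_system_model(path: str | Path) -> SystemModel:
    """Read a system model from JSON (or YAML, same schema).

    ``max_i_evalue`` defaults to 1e-20 and ``min_profile_coverage`` to 0.8
    when omitted.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if path.suffix.lower() in {".yaml", ".yml"}:
        doc = yaml.safe_load(text)
    else:
        doc = json.loads(text)
    if not isinstance(doc, Mapping):
        raise FormatError(f"{path}: system model must be a mapping")
    return system_model_from_dict(doc, name=path.stem)


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

def _render(value) -> str:
    if isinstance(value, bool):
        return str(value)
    if isinstance(value, float):
        return format(value, ".6g")
    return str(value)


def write_tsv_report(rows: Sequence[Mapping], path: str | Path,
                     columns: Sequence[str] | None = None) -> None:
    """Write a list of homogeneous mappings as a UTF-8 TSV with header.

    Column order follows the first row (or ``columns``); floats are rendered
    with 6 significant digits.  Heterogeneous key sets raise an error
    listing the missing keys.
    """
    if columns is None:
        columns = list(rows[0].keys()) if rows else []
    colset = set(columns)
    for i, row in enumerate(rows):
        missing = colset - set(row.keys())
        extra = set(row.keys()) - colset
        if missing or extra:
            raise ValidationError(
                f"row {i}: heterogeneous keys (missing {sorted(missing)}, "
                f"unexpected {sorted(extra)})"
            )
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(columns)
        for row in rows:
            w.writerow([_render(row[c]) for c in columns])


def read_tsv_report(path: str | Path) -> list[dict[str, str]]:
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        return [dict(row) for row in reader]


def configure_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )
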