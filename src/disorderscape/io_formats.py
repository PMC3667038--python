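"""Readers and writers for the four tabular/sequence formats the pipeline touches.

All coordinates are 1-based inclusive (UniProt convention). Tabular outputs
are tab-delimited with a single header row beginning "#".

Formats
-------
* FASTA protein sequences (via Biopython); the header token up to the first
  whitespace is the record id, and an optional ``family=NAME`` key in the
  description carries the family label.
* Score tracks: ``protein_id \\t residue_index \\t score``, one row per
  residue, rows per protein contiguous and index-ascending.
* Domain tables: ``protein_id \\t name \\t start \\t end \\t category``
  (UniProt-feature-table-like).
* Edge lists: ``id_a \\t id_b \\t confidence`` (STRING-like, undirected).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "AMINO_ACIDS",
    "Orientation",
    "DomainCategory",
    "ProteinRecord",
    "ScoreTrack",
    "DomainAnnotation",
    "Edge",
    "read_fasta",
    "write_fasta",
    "read_score_track",
    "write_score_track",
    "read_domain_table",
    "write_domain_table",
    "read_edge_list",
    "write_edge_list",
    "validate_domains",
]

#: The 20 standard residues plus "X" for unknown.
AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWYX")


class Orientation(str, enum.Enum):
    """Direction of a disorder score scale.

    ``HIGH_IS_DISORDERED`` matches IUPred-style predictors (score in [0, 1],
    large = disordered); ``LOW_IS_DISORDERED`` matches FoldIndex-style
    unfoldability indices where negative values mark disorder. The
    orientation is always an explicit argument — never defaulted silently.
    """

    HIGH_IS_DISORDERED = "high_is_disordered"
    LOW_IS_DISORDERED = "low_is_disordered"


class DomainCategory(str, enum.Enum):
    E2_BINDING = "E2_BINDING"
    SUBSTRATE_RECOGNITION = "SUBSTRATE_RECOGNITION"
    OTHER_DOMAIN = "OTHER_DOMAIN"
    TRANSMEMBRANE = "TRANSMEMBRANE"


@dataclass(frozen=True)
class ProteinRecord:
    """One protein: the unit of every per-protein metric."""

    id: str
    family: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein id must be non-empty")
        seq = self.sequence.upper()
        if not seq:
            raise ValueError(f"{self.id}: sequence must be non-empty")
        for pos, aa in enumerate(seq, start=1):
            if aa not in AMINO_ACIDS:
                raise ValueError(
                    f"{self.id}: invalid residue {aa!r} at position {pos}"
                )
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ScoreTrack:
    """Per-residue disorder scores for one protein, with scale orientation."""

    protein_id: str
    scores: tuple[float, ...]
    orientation: Orientation

    def __post_init__(self) -> None:
        object.__setattr__(self, "scores", tuple(float(s) for s in self.scores))
        object.__setattr__(self, "orientation", Orientation(self.orientation))
        if len(self.scores) == 0:
            raise ValueError(f"{self.protein_id}: empty score track")

    def __len__(self) -> int:
        return len(self.scores)


@dataclass(frozen=True)
class DomainAnnotation:
    """A categorized interval on a protein, 1-based inclusive."""

    protein_id: str
    name: str
    start: int
    end: int
    category: DomainCategory

    def __post_init__(self) -> None:
        object.__setattr__(self, "category", DomainCategory(self.category))
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"{self.protein_id}/{self.name}: invalid interval "
                f"({self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "DomainAnnotation") -> bool:
        return self.start <= other.end and other.start <= self.end


@dataclass(frozen=True)
class Edge:
    """An undirected interaction edge; ids stored in canonical (sorted) order."""

    id_a: str
    id_b: str
    confidence: float

    def __post_init__(self) -> None:
        if self.id_a == self.id_b:
            raise ValueError(f"self-loop edge on {self.id_a}")
        if not (0.0 <= self.confidence <= 1.0):
            raise ValueError(
                f"confidence {self.confidence} outside [0, 1] "
                f"for edge ({self.id_a}, {self.id_b})"
            )
        if self.id_b < self.id_a:
            a, b = self.id_b, self.id_a
            object.__setattr__(self, "id_a", a)
            object.__setattr__(self, "id_b", b)

    @property
    def pair(self) -> tuple[str, str]:
        return (self.id_a, self.id_b)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def _family_from_description(description: str) -> str:
    for token in description.split()[1:]:
        if token.startswith("family="):
            return token[len("family="):]
    return "NA"


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read protein records; duplicate ids and invalid residues are hard errors."""
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(
            ProteinRecord(
                id=rec.id,
                family=_family_from_description(rec.description),
                sequence=str(rec.seq),
            )
        )
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.id, description=f"family={r.family}")
        for r in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Score tracks
# ---------------------------------------------------------------------------

def _data_lines(path: str | Path) -> Iterable[tuple[int, list[str]]]:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            yield lineno, line.split("\t")


def read_score_track(
    path: str | Path, orientation: Orientation | str
) -> list[ScoreTrack]:
    """Read per-residue score tracks.

    Rows for one protein must be contiguous with 1-based, gap-free,
    ascending residue indices; any gap or duplicate is an error (scores are
    never imputed).
    """
    orientation = Orientation(orientation)
    tracks: list[ScoreTrack] = []
    seen: set[str] = set()
    cur_id: str | None = None
    cur_scores: list[float] = []

    def flush() -> None:
        if cur_id is not None:
            tracks.append(ScoreTrack(cur_id, tuple(cur_scores), orientation))

    for lineno, fields in _data_lines(path):
        if len(fields) != 3:
            raise ValueError(f"{path}:{lineno}: expected 3 columns, got {len(fields)}")
        pid, idx_s, score_s = fields
        try:
            idx = int(idx_s)
        except ValueError:
            raise ValueError(f"{path}:{lineno}: non-integer residue index {idx_s!r}")
        try:
            score = float(score_s)
        except ValueError:
            raise ValueError(f"{path}:{lineno}: non-numeric score {score_s!r}")
        if pid != cur_id:
            flush()
            if pid in seen:
                raise ValueError(
                    f"{path}:{lineno}: rows for {pid!r} are not contiguous"
                )
            seen.add(pid)
            cur_id, cur_scores = pid, []
        expected = len(cur_scores) + 1
        if idx != expected:
            raise ValueError(
                f"{path}:{lineno}: {pid}: expected residue index {expected}, "
                f"got {idx} (missing or duplicated row)"
            )
        cur_scores.append(score)
    flush()
    return tracks


def write_score_track(tracks: Iterable[ScoreTrack], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#protein_id\tresidue_index\tscore\n")
        for track in tracks:
            for i, score in enumerate(track.scores, start=1):
                fh.write(f"{track.protein_id}\t{i}\t{score:.6g}\n")


# ---------------------------------------------------------------------------
# Domain tables
# ---------------------------------------------------------------------------

def validate_domains(annotations: Sequence[DomainAnnotation]) -> None:
    """Reject overlapping annotations on the same protein.

    The domain-partition arithmetic requires a proper partition, so overlaps
    are an error rather than being merged.
    """
    by_protein: dict[str, list[DomainAnnotation]] = {}
    for ann in annotations:
        by_protein.setdefault(ann.protein_id, []).append(ann)
    for pid, anns in by_protein.items():
        anns = sorted(anns, key=lambda a: (a.start, a.end))
        for prev, cur in zip(anns, anns[1:]):
            if prev.overlaps(cur):
                raise ValueError(
                    f"{pid}: overlapping annotations {prev.name} "
                    f"({prev.start}-{prev.end}) and {cur.name} "
                    f"({cur.start}-{cur.end})"
                )


def read_domain_table(path: str | Path) -> list[DomainAnnotation]:
    """Read domain annotations; categories are matched case-insensitively."""
    annotations: list[DomainAnnotation] = []
    for lineno, fields in _data_lines(path):
        if len(fields) != 5:
            raise ValueError(f"{path}:{lineno}: expected 5 columns, got {len(fields)}")
        pid, name, start_s, end_s, cat_s = fields
        try:
            start, end = int(start_s), int(end_s)
        except ValueError:
            raise ValueError(f"{path}:{lineno}: non-integer coordinates")
        try:
            category = DomainCategory(cat_s.strip().upper())
        except ValueError:
            raise ValueError(f"{path}:{lineno}: unknown category {cat_s!r}")
        annotations.append(DomainAnnotation(pid, name, start, end, category))
    validate_domains(annotations)
    return annotations


def write_domain_table(
    annotations: Iterable[DomainAnnotation], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("#protein_id\tname\tstart\tend\tcategory\n")
        for ann in annotations:
            fh.write(
                f"{ann.protein_id}\t{ann.name}\t{ann.start}\t{ann.end}\t"
                f"{ann.category.value}\n"
            )


# ---------------------------------------------------------------------------
# Edge lists
# ---------------------------------------------------------------------------

def read_edge_list(path: str | Path, min_confidence: float = 0.7) -> list[Edge]:
    """Read an undirected edge list.

    Edges with confidence below ``min_confidence`` and self-loops are
    dropped; duplicate undirected pairs are collapsed keeping the maximum
    confidence. The default cutoff 0.7 is the STRING "high confidence" tier.
    """
    best: dict[tuple[str, str], float] = {}
    order: list[tuple[str, str]] = []
    for lineno, fields in _data_lines(path):
        if len(fields) != 3:
            raise ValueError(f"{path}:{lineno}: expected 3 columns, got {len(fields)}")
        a, b, conf_s = fields
        try:
            conf = float(conf_s)
        except ValueError:
            raise ValueError(f"{path}:{lineno}: non-numeric confidence {conf_s!r}")
        if not (0.0 <= conf <= 1.0):
            raise ValueError(f"{path}:{lineno}: confidence {conf} outside [0, 1]")
        if a == b:
            continue  # self-loop removal
        if conf < min_confidence:
            continue
        pair = (a, b) if a <= b else (b, a)
        if pair not in best:
            order.append(pair)
            best[pair] = conf
        else:
            best[pair] = max(best[pair], conf)
    return [Edge(a, b, best[(a, b)]) for a, b in order]


def write_edge_list(edges: Iterable[Edge], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#id_a\tid_b\tconfidence\n")
        for e in edges:
            fh.write(f"{e.id_a}\t{e.id_b}\t{e.confidence:.6g}\n")
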