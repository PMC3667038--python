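"""Greedy identity-based redundancy filtering (CD-HIT-style curation step).

Sequences are sorted by an explicit "best annotated" priority, then each
sequence joins the first existing cluster whose *representative* it matches
at or above the identity threshold, or founds a new cluster. Because the
greedy order is the priority order, representatives are always the
highest-priority members of their clusters.

Identity is defined as the number of identical aligned positions in an
optimal Needleman-Wunsch global alignment (match +1, mismatch 0, linear
gap -1), divided by the length of the shorter sequence — mirroring
CD-HIT's short-sequence normalisation. No k-mer screening is done: the
datasets here are hundreds of sequences and all-pairs alignment is cheap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from Bio import Align

from .io_formats import ProteinRecord

__all__ = ["ClusteringParams", "Cluster", "pairwise_identity", "greedy_cluster"]


@dataclass(frozen=True)
class ClusteringParams:
    """Threshold and "best annotated" priority for greedy clustering.

    Priority chain (first difference wins): user-supplied rank (lower is
    better) if present, then the reviewed flag, then the longer sequence,
    then lexicographic id. The chain makes the editorial "best annotated"
    criterion explicit and deterministic.
    """

    identity_threshold: float = 0.85
    rank: Mapping[str, float] | None = None
    reviewed: frozenset[str] | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.identity_threshold <= 1.0):
            raise ValueError("identity_threshold must be in (0, 1]")

    def sort_key(self, record: ProteinRecord):
        rank = self.rank.get(record.id, float("inf")) if self.rank else float("inf")
        reviewed = record.id in self.reviewed if self.reviewed else False
        return (rank, not reviewed, -len(record.sequence), record.id)


@dataclass
class Cluster:
    representative_id: str
    member_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.representative_id not in self.member_ids:
            self.member_ids.insert(0, self.representative_id)


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = -1.0
    aligner.extend_gap_score = -1.0
    return aligner


_ALIGNER = _make_aligner()


def pairwise_identity(seq_a: str, seq_b: str) -> float:
    """Identical aligned positions / length of the shorter sequence, in [0, 1]."""
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    alignment = _ALIGNER.align(seq_a, seq_b)[0]
    identities = alignment.counts().identities
    return identities / min(len(seq_a), len(seq_b))


def greedy_cluster(
    records: Sequence[ProteinRecord], params: ClusteringParams | None = None
) -> list[Cluster]:
    """Greedy representative clustering; clusters returned in founding order.

    Every non-representative member has identity >= threshold to its
    cluster's representative; the output is a partition of the input ids.
    """
    params = params or ClusteringParams()
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate protein ids in input")
    ordered = sorted(records, key=params.sort_key)
    clusters: list[Cluster] = []
    representatives: list[ProteinRecord] = []
    for rec in ordered:
        for cluster, rep in zip(clusters, representatives):
            if pairwise_identity(rec.sequence, rep.sequence) >= params.identity_threshold:
                cluster.member_ids.append(rec.id)
                break
        else:
            clusters.append(Cluster(representative_id=rec.id))
            representatives.append(rec)
    return clusters
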