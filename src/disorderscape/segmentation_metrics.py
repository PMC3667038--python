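"""Disordered-segment extraction, long-disordered-region (LDR) detection,
and the per-protein disorder metrics.

An LDR is a stretch containing at least ``min_ldr_length`` (default 30)
predicted disordered residues, where short intervening ordered gaps of at
most ``max_gap`` (default 3) residues are ignored. Chaining is transitive:
runs A-B-C form one chain whenever each consecutive gap is tolerable.

Two length conventions exist for the "at least 30" rule — counting only the
disordered residues of a chain, or the whole chained span including the
tolerated ordered gaps. Counting disordered residues is the default
(``ldr_length_mode="disordered_residue_count"``); span-length mode is
available for sensitivity analysis.

The "longest consecutive disordered segment" metric deliberately uses raw
runs without gap merging: the merge rule exists only for LDR detection.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Sequence

from .disorder_scoring import DisorderTrack

__all__ = [
    "LdrLengthMode",
    "SegmentationParams",
    "SegmentSet",
    "segment_calls",
    "detect_ldrs",
    "protein_metrics",
]

Interval = tuple[int, int]  # 1-based inclusive


class LdrLengthMode(str, enum.Enum):
    DISORDERED_RESIDUE_COUNT = "disordered_residue_count"
    SPAN_LENGTH = "span_length"


@dataclass(frozen=True)
class SegmentationParams:
    min_ldr_length: int = 30
    max_gap: int = 3
    ldr_length_mode: LdrLengthMode = LdrLengthMode.DISORDERED_RESIDUE_COUNT

    def __post_init__(self) -> None:
        if self.min_ldr_length < 1:
            raise ValueError("min_ldr_length must be >= 1")
        if self.max_gap < 0:
            raise ValueError("max_gap must be >= 0")
        object.__setattr__(self, "ldr_length_mode", LdrLengthMode(self.ldr_length_mode))


@dataclass(frozen=True)
class SegmentSet:
    """Segments, LDRs and derived metrics for one protein.

    Metrics:

    * ``n_disordered`` — number of residues called disordered.
    * ``disorder_content`` — 100 * n_disordered / length ("disorder content").
    * ``longest_run`` — length of the longest maximal disordered run
      (no gap merging).
    * ``n_ldrs`` — number of long disordered regions.
    * ``n_ldr_residues`` — disordered residues lying inside LDR spans.
    * ``ldr_fraction`` — 100 * n_ldr_residues / length.
    * ``od_class`` — "O" (mostly ordered) if disordered ratio < 0.5,
      else "D" (mostly disordered); a ratio of exactly 0.5 is "D".
    """

    protein_id: str
    length: int
    raw_segments: tuple[Interval, ...]
    ldrs: tuple[Interval, ...]
    n_disordered: int
    disorder_content: float
    longest_run: int
    n_ldrs: int
    n_ldr_residues: int
    ldr_fraction: float
    od_class: str


def segment_calls(calls: Sequence[bool]) -> list[Interval]:
    """Maximal runs of disordered calls, as sorted 1-based inclusive intervals."""
    if len(calls) == 0:
        raise ValueError("empty call list")
    segments: list[Interval] = []
    start: int | None = None
    for i, call in enumerate(calls, start=1):
        if call and start is None:
            start = i
        elif not call and start is not None:
            segments.append((start, i - 1))
            start = None
    if start is not None:
        segments.append((start, len(calls)))
    return segments


def detect_ldrs(
    segments: Sequence[Interval], params: SegmentationParams | None = None
) -> list[Interval]:
    """Chain segments across tolerable ordered gaps and keep qualifying chains.

    Adjacent segments separated by an ordered gap of at most ``max_gap``
    residues belong to one chain (transitively). A chain qualifies as an
    LDR when its disordered-residue count (default mode) or its span length
    reaches ``min_ldr_length``. The reported span runs from the first to
    the last disordered residue of the chain.
    """
    params = params or SegmentationParams()
    segments = sorted(segments)
    for (s1, e1), (s2, e2) in zip(segments, segments[1:]):
        if s2 <= e1:
            raise ValueError("segments must be non-overlapping")

    ldrs: list[Interval] = []
    chain: list[Interval] = []

    def flush() -> None:
        if not chain:
            return
        span = (chain[0][0], chain[-1][1])
        if params.ldr_length_mode is LdrLengthMode.SPAN_LENGTH:
            size = span[1] - span[0] + 1
        else:
            size = sum(e - s + 1 for s, e in chain)
        if size >= params.min_ldr_length:
            ldrs.append(span)

    for seg in segments:
        if chain and seg[0] - chain[-1][1] - 1 <= params.max_gap:
            chain.append(seg)
        else:
            flush()
            chain = [seg]
    flush()
    return ldrs


def protein_metrics(
    track: DisorderTrack, params: SegmentationParams | None = None
) -> SegmentSet:
    """All per-protein disorder metrics for one binary call track."""
    params = params or SegmentationParams()
    length = len(track)
    if length == 0:
        raise ValueError(f"{track.protein_id}: zero-length track")
    raw = segment_calls(track.calls)
    ldrs = detect_ldrs(raw, params)
    n_dis = sum(e - s + 1 for s, e in raw)
    longest = max((e - s + 1 for s, e in raw), default=0)
    n_ldr_res = sum(
        1
        for s, e in ldrs
        for i in range(s, e + 1)
        if track.calls[i - 1]
    )
    ratio = n_dis / length
    return SegmentSet(
        protein_id=track.protein_id,
        length=length,
        raw_segments=tuple(raw),
        ldrs=tuple(ldrs),
        n_disordered=n_dis,
        disorder_content=100.0 * ratio,
        longest_run=longest,
        n_ldrs=len(ldrs),
        n_ldr_residues=n_ldr_res,
        ldr_fraction=100.0 * n_ldr_res / length,
        od_class="O" if ratio < 0.5 else "D",
    )
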