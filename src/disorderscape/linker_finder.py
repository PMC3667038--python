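"""Inter-domain linker extraction and summary statistics.

A linker is the un-annotated interval between an E2-binding domain (RING or
U-box) and an adjacent substrate-recognition domain, in either order,
uninterrupted by any other domain or transmembrane segment. "Adjacent"
means no annotation of any category lies between the pair, so candidate
pairs are simply consecutive annotations in position-sorted order. Proteins
whose only annotation is the E2-binding domain yield no linkers. If one
E2-binding domain has substrate-recognition neighbours on both sides, both
linkers are reported.

Whether a domain counts as substrate-recognition is carried by the
``category`` column of the annotation input; :data:`DEFAULT_SRD_NAMES` is
an editable default mapping of common substrate-recognition domain names
for labelling raw UniProt-style feature tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .io_formats import DomainAnnotation, DomainCategory, ScoreTrack
from .stats_tests import pearson_r

__all__ = [
    "Linker",
    "DEFAULT_SRD_NAMES",
    "find_linkers",
    "linker_summary",
    "LENGTH_BIN_EDGES",
]

#: Editable default set of domain names commonly capable of substrate
#: recognition in single-subunit RING/U-box ligases. Users curating their
#: own annotations should supply explicit categories instead.
DEFAULT_SRD_NAMES: frozenset[str] = frozenset(
    {
        "TKB", "SH2", "SH3", "WD40", "WD repeat", "Kelch", "LRR",
        "Ankyrin repeat", "MATH", "SPRY", "B30.2/SPRY", "PHD",
        "Bromo", "Chromo", "PDZ", "FYVE", "CARD", "DEATH", "KH",
        "RRM", "TPR", "ARM", "Filamin",
    }
)

#: Length histogram bins: short (<=50), medium (50-200], long (>200).
LENGTH_BIN_EDGES: tuple[float, float] = (50.0, 200.0)


@dataclass(frozen=True)
class Linker:
    protein_id: str
    start: int
    end: int
    flank_e2: str
    flank_srd: str

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"{self.protein_id}: empty linker interval")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def find_linkers(
    protein_id: str, length: int, domains: Sequence[DomainAnnotation]
) -> list[Linker]:
    """Linkers between adjacent E2-binding / substrate-recognition domain pairs.

    Annotation input order is irrelevant (sorted by position internally).
    """
    anns = sorted(domains, key=lambda a: a.start)
    for ann in anns:
        if ann.end > length:
            raise ValueError(
                f"{protein_id}: annotation {ann.name} out of bounds "
                f"for length {length}"
            )
    wanted = {DomainCategory.E2_BINDING, DomainCategory.SUBSTRATE_RECOGNITION}
    linkers: list[Linker] = []
    for left, right in zip(anns, anns[1:]):
        if {left.category, right.category} != wanted:
            continue
        start, end = left.end + 1, right.start - 1
        if start > end:
            continue  # domains abut: zero-length gap
        e2, srd = (
            (left, right)
            if left.category is DomainCategory.E2_BINDING
            else (right, left)
        )
        linkers.append(
            Linker(
                protein_id=protein_id,
                start=start,
                end=end,
                flank_e2=e2.name,
                flank_srd=srd.name,
            )
        )
    return linkers


def bin_linker_lengths(lengths: Sequence[int]) -> tuple[int, int, int]:
    """Counts in the short/medium/long bins [1,50], (50,200], (200,inf)."""
    lo, hi = LENGTH_BIN_EDGES
    short = sum(1 for x in lengths if x <= lo)
    medium = sum(1 for x in lengths if lo < x <= hi)
    long_ = sum(1 for x in lengths if x > hi)
    return short, medium, long_


def linker_summary(
    linkers: Sequence[Linker],
    tracks: Mapping[str, ScoreTrack],
    threshold: float = 0.5,
) -> tuple[pd.DataFrame, dict]:
    """Per-linker table plus cohort statistics.

    For each linker the mean raw disorder score over its interval is
    reported (a call-fraction column, using ``threshold`` with the track's
    orientation semantics, is emitted alongside). Cohort statistics: the
    short/medium/long length histogram and the Pearson correlation between
    linker length and mean score (NaN when fewer than two linkers or when
    either variable is constant).
    """
    from .disorder_scoring import binarize_track  # local to avoid cycle

    rows = []
    for lk in linkers:
        if lk.protein_id not in tracks:
            raise KeyError(f"no score track for {lk.protein_id}")
        track = tracks[lk.protein_id]
        window = track.scores[lk.start - 1 : lk.end]
        if len(window) != lk.length:
            raise ValueError(
                f"{lk.protein_id}: linker ({lk.start}, {lk.end}) outside track"
            )
        calls = binarize_track(track, threshold).calls[lk.start - 1 : lk.end]
        rows.append(
            {
                "protein_id": lk.protein_id,
                "start": lk.start,
                "end": lk.end,
                "length": lk.length,
                "flank_e2": lk.flank_e2,
                "flank_srd": lk.flank_srd,
                "mean_score": sum(window) / len(window),
                "call_fraction": sum(calls) / len(calls),
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "protein_id", "start", "end", "length",
            "flank_e2", "flank_srd", "mean_score", "call_fraction",
        ],
    )
    lengths = [lk.length for lk in linkers]
    short, medium, long_ = bin_linker_lengths(lengths)
    try:
        corr = pearson_r(table["length"], table["mean_score"]) if len(table) >= 2 else math.nan
    except ValueError:  # constant lengths or scores
        corr = math.nan
    stats = {
        "n_linkers": len(linkers),
        "length_bins": {"<=50": short, "50-200": medium, ">200": long_},
        "length_score_correlation": corr,
    }
    return table, stats
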