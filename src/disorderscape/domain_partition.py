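"""Domain-partitioned disorder: E2-binding domains vs the rest of the chain.

Single-subunit E3 ligases carry both an E2-binding domain (RING, U-box or
HECT) and substrate/adaptor-binding regions on one polypeptide. To ask
where the disorder lives, each protein is split into three interval
classes:

* ``e2_binding`` — all annotated E2-binding domains;
* ``transmembrane`` — annotated membrane-spanning segments, excluded from
  the comparison entirely;
* ``remainder`` — everything else (other domains and substrate-recognition
  domains stay inside the remainder).

The three classes are pairwise disjoint and jointly cover the chain, so
region-wise residue counts always add up to the whole-protein count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .disorder_scoring import DisorderTrack
from .io_formats import DomainAnnotation, DomainCategory
from .stats_tests import Tail, mann_whitney

__all__ = [
    "RegionPartition",
    "partition_protein",
    "region_disorder",
    "family_region_summary",
]

Interval = tuple[int, int]


@dataclass
class RegionPartition:
    protein_id: str
    length: int
    e2_binding: tuple[Interval, ...]
    transmembrane: tuple[Interval, ...]
    remainder: tuple[Interval, ...]
    #: percent disorder per region class; None (missing) when a class is empty
    e2_disorder: float | None = None
    remainder_disorder: float | None = None


def _total(intervals: Sequence[Interval]) -> int:
    return sum(e - s + 1 for s, e in intervals)


def partition_protein(
    protein_id: str, length: int, domains: Sequence[DomainAnnotation]
) -> RegionPartition:
    """Split 1..length into E2-binding, transmembrane, and remainder intervals.

    ``domains`` must be validated (non-overlapping) annotations of this one
    protein; annotations extending past ``length`` are an error.
    """
    anns = sorted(domains, key=lambda a: a.start)
    for ann in anns:
        if ann.end > length:
            raise ValueError(
                f"{protein_id}: annotation {ann.name} ({ann.start}-{ann.end}) "
                f"out of bounds for length {length}"
            )
    e2 = tuple((a.start, a.end) for a in anns if a.category is DomainCategory.E2_BINDING)
    tm = tuple((a.start, a.end) for a in anns if a.category is DomainCategory.TRANSMEMBRANE)
    removed = sorted(e2 + tm)
    remainder: list[Interval] = []
    cursor = 1
    for s, e in removed:
        if s > cursor:
            remainder.append((cursor, s - 1))
        cursor = e + 1
    if cursor <= length:
        remainder.append((cursor, length))
    return RegionPartition(
        protein_id=protein_id,
        length=length,
        e2_binding=e2,
        transmembrane=tm,
        remainder=tuple(remainder),
    )


def _percent_disordered(intervals: Sequence[Interval], calls: Sequence[bool]) -> float | None:
    total = _total(intervals)
    if total == 0:
        return None
    dis = sum(
        1 for s, e in intervals for i in range(s, e + 1) if calls[i - 1]
    )
    return 100.0 * dis / total


def region_disorder(partition: RegionPartition, track: DisorderTrack) -> RegionPartition:
    """Fill per-region disorder percentages from a call track.

    An empty region class yields a missing value (None), never 0, so empty
    classes drop out of family averages instead of dragging them down.
    """
    if len(track) != partition.length:
        raise ValueError(
            f"{partition.protein_id}: track length {len(track)} != "
            f"protein length {partition.length}"
        )
    partition.e2_disorder = _percent_disordered(partition.e2_binding, track.calls)
    partition.remainder_disorder = _percent_disordered(partition.remainder, track.calls)
    return partition


def family_region_summary(
    partitions: Sequence[RegionPartition],
    families: Mapping[str, str],
    include_total: bool = True,
) -> pd.DataFrame:
    """Per-family region-wise disorder summary.

    Per-protein region percentages are averaged without weighting within
    each family; significance of the disorder excess in the remainder is a
    one-tailed Mann-Whitney U test (alternative: remainder more disordered
    than E2-binding domains), treating the two region-value lists as
    independent samples. Rows where either sample is empty report missing
    (NaN) values.

    Columns: family, n_proteins, avg_e2_disorder, avg_remainder_disorder,
    p_value.
    """
    groups: dict[str, list[RegionPartition]] = {}
    for part in partitions:
        fam = families.get(part.protein_id, "NA")
        groups.setdefault(fam, []).append(part)
    if include_total and len(groups) > 1:
        groups["Total"] = list(partitions)

    rows = []
    for fam, parts in groups.items():
        e2_vals = [p.e2_disorder for p in parts if p.e2_disorder is not None]
        rem_vals = [p.remainder_disorder for p in parts if p.remainder_disorder is not None]
        avg_e2 = sum(e2_vals) / len(e2_vals) if e2_vals else math.nan
        avg_rem = sum(rem_vals) / len(rem_vals) if rem_vals else math.nan
        if e2_vals and rem_vals:
            p = mann_whitney(rem_vals, e2_vals, tail=Tail.ONE_GREATER).p_value
        else:
            p = math.nan
        rows.append(
            {
                "family": fam,
                "n_proteins": len(parts),
                "avg_e2_disorder": avg_e2,
                "avg_remainder_disorder": avg_rem,
                "p_value": p,
            }
        )
    return pd.DataFrame(rows)
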