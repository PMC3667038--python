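"""Synthetic cohorts with controlled disorder architecture.

The generator emulates the statistical structure of single-subunit E3
ligase families: each protein is a block architecture of a disordered
N-terminal tail, an ordered E2-binding domain (RING-like), a disordered
inter-domain linker, an ordered substrate-recognition domain, and a
disordered C-terminal tail. Per-residue scores are drawn from a
low-mean distribution in ordered blocks and a high-mean distribution in
disordered blocks, smoothed with a moving average to give realistic
autocorrelated profiles, and clipped to [0, 1] (high-is-disordered
orientation, threshold 0.5).

The whole-protein disorder target is realised by sizing the disordered
blocks to the requested fraction of the chain; interaction networks are
generated with exact pinned degrees (each protein is wired to the
requested number of distinct partners, which may be external stub nodes)
or with heavy-tailed Zipf-distributed degrees.

Sequences are generated to be consistent with their tracks: disordered
blocks are enriched in disorder-promoting residues (E, K, S, P, G, Q, A,
R, D), ordered blocks in order-promoting ones (I, L, V, F, W, Y, M, ...),
so the built-in charge-hydropathy predictor recovers the block structure
qualitatively.

All generators are deterministic given the spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .io_formats import DomainAnnotation, DomainCategory, Edge, Orientation, ProteinRecord, ScoreTrack

__all__ = [
    "CohortSpec",
    "generate_cohort",
    "generate_network",
    "inject_effect",
    "linker_demo_cohort",
]

# residue alphabets for the two structural flavours
_DIS_RESIDUES = list("EKSPGQARD")
_DIS_WEIGHTS = np.array([0.16, 0.14, 0.14, 0.12, 0.12, 0.10, 0.10, 0.06, 0.06])
_ORD_RESIDUES = list("ILVFWYMCNHTAG")
_ORD_WEIGHTS = np.array(
    [0.13, 0.13, 0.12, 0.09, 0.05, 0.07, 0.05, 0.04, 0.07, 0.05, 0.08, 0.07, 0.05]
)


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions for a synthetic cohort.

    ``target_disorder`` is the fraction of each chain allocated to
    disordered blocks (tails + linker); ``ordered_level`` /
    ``disordered_level`` are the per-residue probabilities that a residue
    inside an ordered / disordered block is locally disordered before
    smoothing. Score noise is Gaussian around the two block means,
    smoothed with a centered moving average of ``autocorrelation`` residues.
    """

    families: Mapping[str, int] = field(
        default_factory=lambda: {"sRF": 12, "HECT": 4, "U-box": 4}
    )
    length_mean: float = 500.0
    length_sd: float = 100.0
    min_length: int = 200
    target_disorder: float = 0.20
    e2_len_range: tuple[int, int] = (45, 65)
    min_srd_len: int = 30
    ordered_level: float = 0.02
    disordered_level: float = 0.98
    ordered_score_mean: float = 0.15
    disordered_score_mean: float = 0.85
    score_sd: float = 0.12
    autocorrelation: int = 9
    threshold: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.target_disorder < 1.0):
            raise ValueError("target_disorder must be in [0, 1)")
        for p in (self.ordered_level, self.disordered_level):
            if not (0.0 <= p <= 1.0):
                raise ValueError("block disorder levels must be probabilities")
        if self.autocorrelation < 1 or self.autocorrelation % 2 == 0:
            raise ValueError("autocorrelation must be an odd positive integer")


def _smooth(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with truncated windows at the termini."""
    if window == 1:
        return x
    kernel = np.ones(window)
    sums = np.convolve(x, kernel, mode="same")
    counts = np.convolve(np.ones_like(x), kernel, mode="same")
    return sums / counts


def _block_layout(
    length: int, spec: CohortSpec, rng: np.random.Generator
) -> list[tuple[str, int, bool]]:
    """(block name, length, is_disordered) tuples covering the chain."""
    n_dis = int(round(spec.target_disorder * length))
    n_ord = length - n_dis
    e2_len = int(rng.integers(spec.e2_len_range[0], spec.e2_len_range[1] + 1))
    srd_len = n_ord - e2_len
    if srd_len < spec.min_srd_len:
        raise ValueError(
            f"infeasible spec: ordered budget {n_ord} cannot hold an "
            f"E2-binding domain of {e2_len} plus a substrate-recognition "
            f"domain of >= {spec.min_srd_len} residues"
        )
    # split the disordered budget over N-tail, linker, C-tail
    if n_dis >= 3:
        cuts = np.sort(rng.integers(0, n_dis + 1, size=2))
        tail_n, linker, tail_c = cuts[0], cuts[1] - cuts[0], n_dis - cuts[1]
    else:
        tail_n, linker, tail_c = 0, n_dis, 0
    blocks = [
        ("TAIL_N", int(tail_n), True),
        ("RING", e2_len, False),
        ("LINKER", int(linker), True),
        ("SRD", srd_len, False),
        ("TAIL_C", int(tail_c), True),
    ]
    return [b for b in blocks if b[1] > 0]


def _sample_sequence(n: int, disordered: bool, rng: np.random.Generator) -> str:
    if disordered:
        return "".join(rng.choice(_DIS_RESIDUES, size=n, p=_DIS_WEIGHTS))
    return "".join(rng.choice(_ORD_RESIDUES, size=n, p=_ORD_WEIGHTS))


def generate_cohort(
    spec: CohortSpec,
) -> tuple[list[ProteinRecord], dict[str, ScoreTrack], list[DomainAnnotation]]:
    """Generate proteins, score tracks and matching domain annotations.

    Deterministic given ``spec.seed``: the same spec yields byte-identical
    outputs on every call.
    """
    rng = np.random.default_rng(spec.seed)
    records: list[ProteinRecord] = []
    tracks: dict[str, ScoreTrack] = {}
    annotations: list[DomainAnnotation] = []

    for family, count in spec.families.items():
        for i in range(count):
            pid = f"{family}_{i + 1:03d}"
            length = max(
                spec.min_length, int(round(rng.normal(spec.length_mean, spec.length_sd)))
            )
            blocks = _block_layout(length, spec, rng)

            seq_parts: list[str] = []
            means = np.empty(length)
            pos = 1
            for name, blen, is_dis in blocks:
                seq_parts.append(_sample_sequence(blen, is_dis, rng))
                level = spec.disordered_level if is_dis else spec.ordered_level
                local_dis = rng.random(blen) < level
                block_means = np.where(
                    local_dis, spec.disordered_score_mean, spec.ordered_score_mean
                )
                means[pos - 1 : pos - 1 + blen] = block_means
                if name == "RING":
                    annotations.append(
                        DomainAnnotation(
                            pid, "RING", pos, pos + blen - 1, DomainCategory.E2_BINDING
                        )
                    )
                elif name == "SRD":
                    annotations.append(
                        DomainAnnotation(
                            pid, "SRD", pos, pos + blen - 1,
                            DomainCategory.SUBSTRATE_RECOGNITION,
                        )
                    )
                pos += blen

            noisy = means + rng.normal(0.0, spec.score_sd, size=length)
            scores = np.clip(_smooth(noisy, spec.autocorrelation), 0.0, 1.0)
            records.append(ProteinRecord(pid, family, "".join(seq_parts)))
            tracks[pid] = ScoreTrack(
                pid, tuple(float(s) for s in scores), Orientation.HIGH_IS_DISORDERED
            )
    return records, tracks, annotations


def generate_network(
    ids: Sequence[str],
    seed: int,
    pinned_degrees: Mapping[str, int] | None = None,
    powerlaw_exponent: float = 2.5,
    max_degree: int = 200,
    confidence_range: tuple[float, float] = (0.7, 1.0),
) -> list[Edge]:
    """Edge list realising exact pinned degrees or Zipf-distributed degrees.

    Each protein is wired to its requested number of distinct partners.
    Partners are external stub nodes (``EXT...``), which matches how
    database degrees count all partners, not only proteins in the analysed
    set, and guarantees every degree exactly.
    """
    if len(ids) < 2:
        raise ValueError("need at least two ids")
    rng = np.random.default_rng(seed)
    pinned = dict(pinned_degrees or {})
    edges: list[Edge] = []
    ext = 0
    lo, hi = confidence_range
    for pid in ids:
        if pid in pinned:
            k = int(pinned[pid])
            if k < 0:
                raise ValueError(f"negative degree requested for {pid}")
        else:
            k = min(int(rng.zipf(powerlaw_exponent)) - 1, max_degree)
        for _ in range(k):
            partner = f"EXT{ext:06d}"
            ext += 1
            conf = float(rng.uniform(lo, hi))
            edges.append(Edge(pid, partner, conf))
    return edges


def inject_effect(
    tracks: Mapping[str, ScoreTrack],
    group_ids: Sequence[str],
    delta: float,
    seed: int,
    threshold: float = 0.5,
) -> dict[str, ScoreTrack]:
    """Raise the disorder content of a group by ``delta`` percentage points.

    For each protein in the group, ``round(delta / 100 * length)`` residues
    currently called ordered are chosen uniformly at random and their
    scores raised above the threshold, so each protein's content — and
    hence the group's unweighted mean content — rises by ``delta`` up to
    rounding. Tracks outside the group are returned unchanged.
    """
    if delta < 0:
        raise ValueError("delta must be non-negative")
    rng = np.random.default_rng(seed)
    out = dict(tracks)
    for pid in group_ids:
        track = tracks[pid]
        n = len(track)
        n_flips = int(round(delta / 100.0 * n))
        if n_flips == 0:
            continue
        scores = np.array(track.scores)
        ordered_idx = np.flatnonzero(scores < threshold)
        if len(ordered_idx) < n_flips:
            raise ValueError(
                f"{pid}: delta {delta} exceeds headroom "
                f"({len(ordered_idx)} ordered residues, need {n_flips})"
            )
        chosen = rng.choice(ordered_idx, size=n_flips, replace=False)
        scores[chosen] = rng.uniform(
            threshold + 0.2 * (1 - threshold), threshold + 0.9 * (1 - threshold),
            size=n_flips,
        )
        out[pid] = replace(track, scores=tuple(float(s) for s in scores))
    return out


def linker_demo_cohort() -> tuple[
    list[ProteinRecord], dict[str, ScoreTrack], list[DomainAnnotation]
]:
    """A fixed 12-protein cohort with hand-constructed domain architectures.

    Covers every branch of the linker rule: simple RING-SRD pairs in both
    orientations, a transmembrane interruption, an other-domain
    interruption, abutting domains (zero-length gap), a single-RING
    protein, an SRD-RING-SRD protein with linkers on both sides, and
    proteins with no annotations at all. Scores are constant per protein so
    linker mean scores are exactly predictable.
    """
    spec = [
        # pid, length, score, [(name, start, end, category)]
        ("L01", 200, 0.7, [("RING", 10, 60, "E2_BINDING"),
                           ("SRD", 100, 150, "SUBSTRATE_RECOGNITION")]),
        ("L02", 200, 0.3, [("SRD", 20, 60, "SUBSTRATE_RECOGNITION"),
                           ("RING", 90, 140, "E2_BINDING")]),
        ("L03", 220, 0.6, [("RING", 10, 60, "E2_BINDING"),
                           ("TM", 70, 90, "TRANSMEMBRANE"),
                           ("SRD", 100, 150, "SUBSTRATE_RECOGNITION")]),
        ("L04", 220, 0.6, [("RING", 10, 60, "E2_BINDING"),
                           ("ZnF", 70, 90, "OTHER_DOMAIN"),
                           ("SRD", 100, 150, "SUBSTRATE_RECOGNITION")]),
        ("L05", 150, 0.5, [("RING", 10, 60, "E2_BINDING"),
                           ("SRD", 61, 100, "SUBSTRATE_RECOGNITION")]),
        ("L06", 150, 0.4, [("RING", 50, 100, "E2_BINDING")]),
        ("L07", 300, 0.8, [("SRD1", 10, 50, "SUBSTRATE_RECOGNITION"),
                           ("RING", 100, 150, "E2_BINDING"),
                           ("SRD2", 200, 250, "SUBSTRATE_RECOGNITION")]),
        ("L08", 100, 0.2, []),
        ("L09", 180, 0.9, [("SRD", 30, 80, "SUBSTRATE_RECOGNITION"),
                           ("ZnF", 90, 120, "OTHER_DOMAIN")]),
        ("L10", 250, 0.55, [("RING", 5, 50, "E2_BINDING"),
                            ("SRD", 52, 110, "SUBSTRATE_RECOGNITION")]),
        ("L11", 400, 0.65, [("RING", 100, 150, "E2_BINDING"),
                            ("SRD", 380, 400, "SUBSTRATE_RECOGNITION")]),
        ("L12", 160, 0.35, [("TM", 10, 30, "TRANSMEMBRANE"),
                            ("RING", 40, 90, "E2_BINDING"),
                            ("SRD", 120, 150, "SUBSTRATE_RECOGNITION")]),
    ]
    records, tracks, annotations = [], {}, []
    for pid, length, score, anns in spec:
        records.append(ProteinRecord(pid, "sRF", "A" * length))
        tracks[pid] = ScoreTrack(
            pid, tuple([score] * length), Orientation.HIGH_IS_DISORDERED
        )
        for name, start, end, cat in anns:
            annotations.append(
                DomainAnnotation(pid, name, start, end, DomainCategory(cat))
            )
    return records, tracks, annotations
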