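"""Per-residue disorder calls from score tracks, plus a built-in baseline predictor.

External per-residue predictors are ingested as :class:`~disorderscape.io_formats.ScoreTrack`
objects and binarized here. The package also ships a simple
charge-hydropathy baseline (an unfoldability index computed over a sliding
window) so that every pipeline stage can be exercised from sequence alone.

Boundary semantics
------------------
For high-is-disordered tracks (IUPred-style, scores in [0, 1]) a residue is
called disordered when its score is **greater than or equal to** the
threshold (default 0.5). For low-is-disordered tracks (FoldIndex-style
unfoldability index) a residue is disordered when the score is **strictly
below** the threshold (default 0.0): negative values mark unfolded
residues, zero is treated as ordered.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .io_formats import Orientation, ScoreTrack

__all__ = [
    "KYTE_DOOLITTLE",
    "CHARGE",
    "PredictorConfig",
    "DisorderTrack",
    "binarize_track",
    "baseline_fold_score",
    "default_threshold",
]

#: Kyte-Doolittle hydropathy scale; "X" is imputed as neutral (0.0).
KYTE_DOOLITTLE: dict[str, float] = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
    "X": 0.0,
}

#: Side-chain net charge at neutral pH; "X" imputed as 0.
CHARGE: dict[str, int] = {
    **{aa: 0 for aa in "ACFGILMNPQSTVWYX"},
    "D": -1, "E": -1, "K": 1, "R": 1, "H": 0,
}


@dataclass(frozen=True)
class PredictorConfig:
    """Parameters of the charge-hydropathy baseline predictor.

    The per-residue score is ``a * <H> - |<R>| - b`` over a centered window,
    where ``<H>`` is the mean Kyte-Doolittle hydropathy rescaled to [0, 1]
    (``(KD + 4.5) / 9``) and ``<R>`` the mean net charge. Positive values
    mean foldable, negative values mean unfolded — a low-is-disordered
    track. The coefficients are the published unfoldability-index constants.
    """

    window: int = 51
    a: float = 2.785
    b: float = 1.151
    hydropathy_scale: dict[str, float] = field(default_factory=lambda: dict(KYTE_DOOLITTLE))
    charge_map: dict[str, int] = field(default_factory=lambda: dict(CHARGE))

    def __post_init__(self) -> None:
        if self.window < 1 or self.window % 2 == 0:
            raise ValueError("window must be an odd positive integer")
        for aa in "ACDEFGHIKLMNPQRSTVWY":
            if aa not in self.hydropathy_scale or aa not in self.charge_map:
                raise ValueError(f"residue {aa!r} missing from predictor maps")


@dataclass(frozen=True)
class DisorderTrack:
    """Scores plus the binary disorder calls derived from them."""

    protein_id: str
    scores: tuple[float, ...]
    orientation: Orientation
    threshold: float
    calls: tuple[bool, ...]

    def __post_init__(self) -> None:
        if len(self.calls) != len(self.scores):
            raise ValueError("calls and scores must have equal length")

    def __len__(self) -> int:
        return len(self.scores)

    @property
    def n_disordered(self) -> int:
        return sum(self.calls)


def default_threshold(orientation: Orientation | str) -> float:
    """0.5 for IUPred-style tracks, 0.0 for unfoldability-index tracks."""
    orientation = Orientation(orientation)
    return 0.5 if orientation is Orientation.HIGH_IS_DISORDERED else 0.0


def binarize_track(track: ScoreTrack, threshold: float | None = None) -> DisorderTrack:
    """Turn a score track into binary disorder calls.

    ``threshold=None`` selects the conventional default for the track's
    orientation (0.5 high-is-disordered, 0.0 low-is-disordered).
    """
    if threshold is None:
        threshold = default_threshold(track.orientation)
    if any(math.isnan(s) for s in track.scores):
        raise ValueError(f"{track.protein_id}: NaN score in track")
    if track.orientation is Orientation.HIGH_IS_DISORDERED:
        calls = tuple(s >= threshold for s in track.scores)
    else:
        calls = tuple(s < threshold for s in track.scores)
    return DisorderTrack(
        protein_id=track.protein_id,
        scores=track.scores,
        orientation=track.orientation,
        threshold=threshold,
        calls=calls,
    )


def baseline_fold_score(
    sequence: str,
    config: PredictorConfig | None = None,
    protein_id: str = "baseline",
) -> ScoreTrack:
    """Charge-hydropathy unfoldability profile of a sequence.

    Returns a low-is-disordered :class:`ScoreTrack` (negative = unfolded).
    Residues within half a window of either terminus use the truncated
    window. The sequence must be at least one window long; for shorter
    peptides compute a single whole-sequence window by passing a config
    with ``window`` equal to an odd number <= the sequence length.
    """
    config = config or PredictorConfig()
    seq = sequence.upper()
    n = len(seq)
    if n < config.window:
        raise ValueError(
            f"sequence length {n} is shorter than window {config.window}; "
            "use a PredictorConfig with a smaller (odd) window for "
            "single-window scoring of short peptides"
        )
    half = config.window // 2
    h = [((config.hydropathy_scale[aa] + 4.5) / 9.0) for aa in seq]
    r = [float(config.charge_map[aa]) for aa in seq]
    # prefix sums for O(n) windowed means
    ch = [0.0]
    cr = [0.0]
    for i in range(n):
        ch.append(ch[-1] + h[i])
        cr.append(cr[-1] + r[i])
    scores = []
    for i in range(n):
        lo = max(0, i - half)
        hi = min(n, i + half + 1)
        w = hi - lo
        mean_h = (ch[hi] - ch[lo]) / w
        mean_r = (cr[hi] - cr[lo]) / w
        scores.append(config.a * mean_h - abs(mean_r) - config.b)
    return ScoreTrack(
        protein_id=protein_id,
        scores=tuple(scores),
        orientation=Orientation.LOW_IS_DISORDERED,
    )
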