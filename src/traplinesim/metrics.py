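"""Outcome metrics: route similarity and foraging success.

The similarity index (SI) quantifies how much two visitation sequences
share ordered subsequences. Both sequences are decomposed into all
contiguous subsequences of a fixed window length (3 by default) with a
sliding window, nest visits excluded. Every visitation (sequence
position) covered by at least one subsequence occurring in *both*
sequences is marked; with S_ab the total number of marked positions
across both sequences and l_ab = max(p, q) the longer sequence length,

    SI_ab = S_ab / (2 * l_ab).

SI is 1 for identical sequences and 0 for sequences sharing no
window-length subsequence. Foraging success is nectar collected per unit
bout time (microlitres per second).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .engine import BoutRecord

__all__ = [
    "SimilarityResult",
    "similarity_index",
    "foraging_success",
    "similarity_series",
    "bout_metrics_frame",
]

DEFAULT_WINDOW = 3


@dataclass(frozen=True)
class SimilarityResult:
    """Similarity index with its ingredients.

    ``si`` is NaN (undefined) only when both sequences are empty; a pair
    with one empty or sub-window sequence has ``si == 0`` with no marked
    positions.
    """

    si: float
    shared_visit_count: int  # S_ab: marked positions across both sequences
    normalizer: int  # l_ab = max(p, q)
    window: int

    @property
    def defined(self) -> bool:
        return not math.isnan(self.si)


def _covered(seq: Sequence[int], shared: set[tuple[int, ...]], window: int) -> int:
    flags = [False] * len(seq)
    for k in range(len(seq) - window + 1):
        if tuple(seq[k : k + window]) in shared:
            for i in range(k, k + window):
                flags[i] = True
    return sum(flags)


def similarity_index(
    a: Sequence[int], b: Sequence[int], window: int = DEFAULT_WINDOW
) -> SimilarityResult:
    """Similarity index between two visit sequences.

    Parameters
    ----------
    a, b
        Ordered feeding-site ids of two bouts (nest entries already
        stripped). Repeats are allowed; positions, not unique ids, are
        what gets counted.
    window
        Subsequence length n (default 3).

    Notes
    -----
    A subsequence occurring anywhere in both sequences marks *every*
    position it covers in either sequence, including multiple
    occurrences (positional-cover reading).
    """
    if window < 1:
        raise ValueError(f"window must be >= 1, got {window}")
    p, q = len(a), len(b)
    if p == 0 and q == 0:
        return SimilarityResult(float("nan"), 0, 0, window)
    subs_a = {tuple(a[k : k + window]) for k in range(p - window + 1)}
    subs_b = {tuple(b[k : k + window]) for k in range(q - window + 1)}
    shared = subs_a & subs_b
    s_ab = _covered(a, shared, window) + _covered(b, shared, window)
    l_ab = max(p, q)
    return SimilarityResult(s_ab / (2 * l_ab), s_ab, l_ab, window)


def foraging_success(bout: BoutRecord) -> float:
    """Nectar collected per second over one bout (microlitres/second)."""
    if bout.bout_duration <= 0:
        raise ValueError(
            f"bout duration must be > 0, got {bout.bout_duration}"
        )
    return bout.nectar_collected / bout.bout_duration


def similarity_series(
    bouts: Sequence[BoutRecord], lag: int = 1, window: int = DEFAULT_WINDOW
) -> list[SimilarityResult]:
    """SI between bout k and bout k + lag for each valid k of one bee.

    lag 1 compares consecutive bouts; lag 2 compares every other bout
    (high lag-2 with low lag-1 is the signature of a bee alternating
    between two routes).
    """
    if lag < 1:
        raise ValueError(f"lag must be >= 1, got {lag}")
    bouts = sorted(bouts, key=lambda b: b.bout_index)
    return [
        similarity_index(
            bouts[k].visit_sequence, bouts[k + lag].visit_sequence, window
        )
        for k in range(len(bouts) - lag)
    ]


def bout_metrics_frame(
    bouts: Sequence[BoutRecord], window: int = DEFAULT_WINDOW
) -> pd.DataFrame:
    """Per-bout metrics table for one bee.

    Columns: bout_index, n_visits, nectar_collected, bout_duration,
    success, si_lag1, si_lag2 (SI between this bout and the bout one or
    two later; NaN where no such bout exists or SI is undefined).
    """
    bouts = sorted(bouts, key=lambda b: b.bout_index)
    rows = []
    for k, bout in enumerate(bouts):
        row = {
            "bout_index": bout.bout_index,
            "n_visits": len(bout.visits),
            "nectar_collected": bout.nectar_collected,
            "bout_duration": bout.bout_duration,
            "success": foraging_success(bout),
        }
        for lag in (1, 2):
            key = f"si_lag{lag}"
            if k + lag < len(bouts):
                row[key] = similarity_index(
                    bout.visit_sequence, bouts[k + lag].visit_sequence, window
                ).si
            else:
                row[key] = float("nan")
        rows.append(row)
    return pd.DataFrame(rows)
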