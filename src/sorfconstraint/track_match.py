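"""Pair genomic elements with interval score tracks by averaging.

Two track shapes are supported: windowed tracks (chrom, start, end, score),
possibly overlapping as produced by sliding-window scores such as the 1 kb
Gnocchi constraint z-score slid by 100 bp, and per-position tracks
(chrom, pos, score) such as phyloP conservation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

GNOCCHI_CUTOFF = 4.0


class ScoreTrack:
    """Sorted windowed score intervals, indexed per chromosome."""

    def __init__(self, df: pd.DataFrame):
        required = {"chrom", "start", "end", "score"}
        if not required.issubset(df.columns):
            raise ValueError(f"score track needs columns {sorted(required)}")
        if not np.isfinite(df["score"]).all():
            raise ValueError("track scores must be finite")
        df = df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
        self._by_chrom = {
            str(chrom): sub.reset_index(drop=True) for chrom, sub in df.groupby("chrom")
        }

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ScoreTrack":
        return cls(pd.read_csv(path, sep="\t", comment="#"))

    def chrom(self, chrom: str) -> pd.DataFrame | None:
        return self._by_chrom.get(chrom)


@dataclass
class MatchResult:
    """Mean track score paired to an element."""

    score: float
    n_intervals: int
    used_fallback: bool


def match_element(
    span: tuple[str, int, int],
    track: ScoreTrack,
    mode: str = "containment",
    fallback: bool = True,
) -> MatchResult | None:
    """Mean score of the track intervals matching an element span.

    In ``containment`` mode an interval matches when it lies fully inside
    the element span; in ``any_overlap`` mode any positive overlap counts.
    When nothing matches and ``fallback`` is enabled, the two closest
    intervals by distance are averaged instead (one from each side when
    both sides tie).  The mean is unweighted.  Returns ``None`` when the
    chromosome has no track data.
    """
    chrom, start, end = span
    sub = track.chrom(chrom)
    if sub is None or len(sub) == 0:
        return None
    t_start = sub["start"].to_numpy()
    t_end = sub["end"].to_numpy()
    scores = sub["score"].to_numpy(dtype=float)

    if mode == "containment":
        mask = (t_start >= start) & (t_end <= end)
    elif mode == "any_overlap":
        mask = (t_start < end) & (t_end > start)
    else:
        raise ValueError(f"unknown match mode {mode!r}")

    if mask.any():
        return MatchResult(
            score=float(scores[mask].mean()), n_intervals=int(mask.sum()), used_fallback=False
        )
    if not fallback:
        return None

    # distance from the element span to each interval (0 would mean overlap)
    dist = np.maximum(t_start - end, start - t_end)
    dist = np.maximum(dist, 0)
    if len(dist) == 1:
        return MatchResult(score=float(scores[0]), n_intervals=1, used_fallback=True)
    order = np.lexsort((t_start, dist))
    side = np.where(t_end <= start, -1, np.where(t_start >= end, 1, 0))
    first = int(order[0])
    second = int(order[1])
    # when several intervals tie for second-closest, prefer one on the
    # opposite side of the element from the first
    for idx in order[2:]:
        idx = int(idx)
        if dist[idx] != dist[second]:
            break
        if side[idx] != side[first] and side[second] == side[first]:
            second = idx
            break
    chosen = [first, second]
    return MatchResult(
        score=float(scores[chosen].mean()), n_intervals=2, used_fallback=True
    )


@dataclass
class BlockMatchResult:
    """Mean per-position score over an element's coding blocks."""

    score: float
    n_positions: int
    coverage: float  # fraction of block positions with a track value


def match_blocks(
    chrom: str,
    blocks: Sequence[tuple[int, int]],
    positions: pd.DataFrame,
) -> BlockMatchResult | None:
    """Unweighted mean of per-position scores across coding blocks.

    ``positions`` has columns (chrom, pos, score) with 0-based positions.
    Positions missing from the track are skipped; the coverage fraction
    reports how much of the blocks the track informed.  Returns ``None``
    when no block position has a score.
    """
    sub = positions[positions["chrom"] == chrom]
    lookup = dict(zip(sub["pos"].astype(int), sub["score"].astype(float)))
    total = 0
    found: list[float] = []
    for start, end in blocks:
        for pos in range(start, end):
            total += 1
            if pos in lookup:
                found.append(lookup[pos])
    if not found:
        return None
    return BlockMatchResult(
        score=float(np.mean(found)), n_positions=len(found), coverage=len(found) / total
    )


def gnocchi_constrained(score: float, cutoff: float = GNOCCHI_CUTOFF) -> bool:
    """True when a Gnocchi-style constraint z-score reaches the cut-off.

    The boundary is inclusive: the published cut-off of 4 marks the border
    of the most constrained percentile of the genome.
    """
    return score >= cutoff
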