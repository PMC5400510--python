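"""Consensus nucleosome peak calling and cross-condition landscape comparison.

Consensus dyad positions are strict local maxima of the normalized density
track above a height threshold (default 2), with maxima closer than a minimum
separation (default 120 bp, just under the ~147 bp nucleosome footprint)
suppressed greedily in descending height.  Peak lists from two conditions can
be paired to report per-nucleosome dyad shifts, e.g. a flanking nucleosome
moving towards the origin under a different chromatin remodeler.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .coords import TemplateCoordinateSystem
from .track import DyadTrack

DEFAULT_THRESHOLD = 2.0
DEFAULT_MIN_SEPARATION = 120
DEFAULT_PAIRING_WINDOW = 100


@dataclass(frozen=True)
class ConsensusPeak:
    """A called nucleosome dyad position with its normalized density height."""

    position_abs: int
    position_acs: int
    height: float
    rank: int


@dataclass(frozen=True)
class DyadShift:
    """Displacement of one dyad between a reference and an alternate condition.

    Unpaired peaks from either list are reported with ``paired=False`` and the
    missing partner position set to None.
    """

    ref_position: Optional[int]
    alt_position: Optional[int]
    shift_bp: Optional[int]
    paired: bool


def _plateau_maxima(values: np.ndarray) -> list[int]:
    """Strict local maxima of a discrete track, plateaus reduced to one position.

    A plateau (maximal run of equal values) is a maximum when both flanking
    values exist and are strictly lower; its representative position is the
    plateau centre, left-of-centre for even-length plateaus.  Plateaus touching
    the track edge are not called.
    """
    n = len(values)
    maxima: list[int] = []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and values[j + 1] == values[i]:
            j += 1
        left_lower = i > 0 and values[i - 1] < values[i]
        right_lower = j < n - 1 and values[j + 1] < values[i]
        if left_lower and right_lower:
            maxima.append((i + j) // 2)
        i = j + 1
    return maxima


def call_consensus_positions(
    track: DyadTrack,
    coords: TemplateCoordinateSystem,
    threshold: float = DEFAULT_THRESHOLD,
    min_separation: int = DEFAULT_MIN_SEPARATION,
) -> list[ConsensusPeak]:
    """Call consensus dyad positions from a normalized density track.

    Returns strict local maxima with height > threshold; among maxima closer
    than ``min_separation`` only the highest is kept (ties broken leftmost),
    applied greedily in descending height.  The result is sorted by position
    and ranked by height (rank 1 = highest).
    """
    if not track.normalized:
        raise ValueError("peak threshold is defined on the normalized track; normalize first")
    if threshold <= 0:
        raise ValueError(f"threshold must be positive, got {threshold}")
    if min_separation < 0:
        raise ValueError(f"min_separation must be >= 0, got {min_separation}")

    values = track.values
    candidates = [p for p in _plateau_maxima(values) if values[p] > threshold]
    # greedy non-maximum suppression, highest first, leftmost on ties
    candidates.sort(key=lambda p: (-values[p], p))
    kept: list[int] = []
    for pos in candidates:
        if all(abs(pos - k) >= min_separation for k in kept):
            kept.append(pos)

    by_height = {pos: rank for rank, pos in enumerate(kept, start=1)}
    kept.sort()
    return [
        ConsensusPeak(
            position_abs=pos,
            position_acs=coords.to_acs_relative(pos),
            height=float(values[pos]),
            rank=by_height[pos],
        )
        for pos in kept
    ]


def pair_and_shift(
    ref_peaks: Sequence[ConsensusPeak],
    alt_peaks: Sequence[ConsensusPeak],
    pairing_window: int = DEFAULT_PAIRING_WINDOW,
) -> list[DyadShift]:
    """Pair peaks across two conditions and report per-dyad shifts.

    Pairing is one-to-one on ACS-relative positions: candidate pairs within
    ``pairing_window`` are accepted closest-first (ties to the smaller
    alternate position).  ``shift_bp = alt - ref`` for paired dyads; unpaired
    peaks from either list are reported with ``paired=False``.
    """
    ref_pos = [p.position_acs for p in ref_peaks]
    alt_pos = [p.position_acs for p in alt_peaks]
    pairs = sorted(
        (
            (abs(a - r), a, ri, ai)
            for ri, r in enumerate(ref_pos)
            for ai, a in enumerate(alt_pos)
            if abs(a - r) <= pairing_window
        ),
    )
    ref_used: dict[int, int] = {}
    alt_used: set[int] = set()
    for _dist, _a, ri, ai in pairs:
        if ri in ref_used or ai in alt_used:
            continue
        ref_used[ri] = ai
        alt_used.add(ai)

    shifts: list[DyadShift] = []
    for ri, r in enumerate(ref_pos):
        if ri in ref_used:
            a = alt_pos[ref_used[ri]]
            shifts.append(DyadShift(ref_position=r, alt_position=a, shift_bp=a - r, paired=True))
        else:
            shifts.append(DyadShift(ref_position=r, alt_position=None, shift_bp=None, paired=False))
    for ai, a in enumerate(alt_pos):
        if ai not in alt_used:
            shifts.append(DyadShift(ref_position=None, alt_position=a, shift_bp=None, paired=False))
    return shifts


def estimate_spacing(peaks: Sequence[ConsensusPeak]) -> tuple[float, float]:
    """Mean inter-dyad distance and sample SD of successive gaps.

    The SD is a regularity score: 0 for a perfectly phased array.  With
    exactly two peaks there is a single gap and the sample SD is NaN.
    Fewer than two peaks is an error (spacing undefined).
    """
    if len(peaks) < 2:
        raise ValueError("spacing undefined for fewer than 2 peaks")
    positions = np.array(sorted(p.position_abs for p in peaks), dtype=float)
    gaps = np.diff(positions)
    sd = float(np.std(gaps, ddof=1)) if len(gaps) > 1 else float("nan")
    return float(np.mean(gaps)), sd
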