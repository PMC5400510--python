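"""Size selection and dyad-proxy midpoint extraction.

Mononucleosome-sized MNase fragments (125-175 bp by default) protect roughly
one nucleosome's worth of DNA, so their midpoints approximate dyad positions.
Filtering and midpoint extraction are separate steps so each is testable on
its own.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .coords import FragmentRecord

DEFAULT_SIZE_LO = 125
DEFAULT_SIZE_HI = 175


@dataclass
class MidpointSet:
    """Fragment midpoints retained after size selection.

    ``midpoints`` is an ordered multiset (duplicates meaningful) of 0-based
    coordinates; ``n_input_fragments`` counts fragments before filtering so
    the retained fraction is recoverable.
    """

    template_id: str
    midpoints: np.ndarray
    n_input_fragments: int
    size_lo: int = DEFAULT_SIZE_LO
    size_hi: int = DEFAULT_SIZE_HI

    def __post_init__(self) -> None:
        self.midpoints = np.asarray(self.midpoints, dtype=np.int64)
        if self.size_lo > self.size_hi:
            raise ValueError(f"size_lo {self.size_lo} > size_hi {self.size_hi}")
        if len(self.midpoints) > self.n_input_fragments:
            raise ValueError("more midpoints than input fragments")

    def __len__(self) -> int:
        return len(self.midpoints)


def filter_by_length(
    fragments: list[FragmentRecord],
    size_lo: int = DEFAULT_SIZE_LO,
    size_hi: int = DEFAULT_SIZE_HI,
) -> list[FragmentRecord]:
    """Retain fragments with size_lo <= length <= size_hi (bounds inclusive).

    Input order is preserved and the input list is not modified.
    """
    if size_lo < 1:
        raise ValueError(f"size_lo must be >= 1, got {size_lo}")
    if size_lo > size_hi:
        raise ValueError(f"inverted bounds: size_lo {size_lo} > size_hi {size_hi}")
    return [f for f in fragments if size_lo <= f.length <= size_hi]


def compute_midpoints(
    fragments: list[FragmentRecord],
    *,
    n_input_fragments: int | None = None,
    size_lo: int = DEFAULT_SIZE_LO,
    size_hi: int = DEFAULT_SIZE_HI,
) -> MidpointSet:
    """Extract one midpoint per fragment: floor((start + end) / 2).

    Even-length fragments have no integer centre; floor rounding is applied
    uniformly (at most 0.5 bp bias, symmetric across a landscape).
    ``n_input_fragments`` defaults to the number of fragments given, but the
    pre-filter count can be passed through for bookkeeping.
    """
    template_id = fragments[0].template_id if fragments else ""
    mids = np.array([(f.start + f.end) // 2 for f in fragments], dtype=np.int64)
    return MidpointSet(
        template_id=template_id,
        midpoints=mids,
        n_input_fragments=len(fragments) if n_input_fragments is None else n_input_fragments,
        size_lo=size_lo,
        size_hi=size_hi,
    )


def extract_midpoints(
    fragments: list[FragmentRecord],
    size_lo: int = DEFAULT_SIZE_LO,
    size_hi: int = DEFAULT_SIZE_HI,
) -> MidpointSet:
    """Convenience: size-filter then extract midpoints, keeping the input count."""
    kept = filter_by_length(fragments, size_lo, size_hi)
    return compute_midpoints(
        kept, n_input_fragments=len(fragments), size_lo=size_lo, size_hi=size_hi
    )
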