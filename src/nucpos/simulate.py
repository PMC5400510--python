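"""Synthetic MNase-seq fragment libraries from parameterized nucleosome landscapes.

The generator emulates libraries sequenced from a short (~3.8 kb) origin
template whose chromatin was assembled by a chromatin-remodeling enzyme (CRE):
a set of weighted, fuzzy dyad positions, optionally a nucleosome-free region
(NFR) over the origin, and a uniform background of sub- or over-digested
fragments.  Presets encode the landscapes of the remodeled ARS1 templates:

* ``ISW1a`` -- NFR over the origin with well-positioned flanking nucleosomes,
  downstream flank dyad at +222 bp from the ACS.
* ``ISW2`` -- a nucleosome encroaching on the origin (dyad at -54) and the
  downstream flank shifted in to +168.
* ``irregular`` -- dyads placed by random sequential adsorption with a 147 bp
  exclusion, modelling remodelers that do not build phased arrays.
* ``single_dyad`` -- one perfectly positioned nucleosome; a pipeline fixture.

Phased arrays decay away from their positioning anchor, so tiled dyads get
geometrically decreasing weight and slowly growing fuzz with distance from
the anchors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .coords import FragmentRecord, TemplateCoordinateSystem

PRESETS = ("ISW1a", "ISW2", "irregular", "single_dyad")

# canonical nucleosome footprint; also the hard-core distance for random placement
NUCLEOSOME_FOOTPRINT = 147

DEFAULT_SPACING = 165           # inter-dyad repeat for tiled (phased) presets
DEFAULT_FUZZ_SD = 10.0          # positional SD of anchor dyads, bp
DEFAULT_BACKGROUND_FRAC = 0.1
DEFAULT_NFR = (-120, 120)       # ACS-relative interval kept dyad-free
DEFAULT_ISW1A_UPSTREAM = -200   # upstream flanking dyad for the NFR presets
TILE_WEIGHT_DECAY = 0.8         # occupancy decay per repeat away from an anchor
TILE_FUZZ_GROWTH = 2.0          # extra positional SD per repeat, bp
EDGE_MARGIN = 80                # dyads closer than this to an edge are not tiled

DEFAULT_FRAG_LEN_MEAN = 147.0
DEFAULT_FRAG_LEN_SD = 10.0
DEFAULT_FRAG_LEN_BOUNDS = (100, 200)

_MAX_RETRIES = 100


@dataclass(frozen=True)
class Dyad:
    """One nucleosome position: ACS-relative dyad, sampling weight, positional SD."""

    position_acs: int
    weight: float
    fuzz_sd: float


@dataclass
class NucleosomeLandscape:
    """Ground truth for the simulator: weighted fuzzy dyads, NFR, background."""

    coords: TemplateCoordinateSystem
    dyads: list[Dyad]
    nfr: Optional[tuple[int, int]] = None
    background_frac: float = DEFAULT_BACKGROUND_FRAC
    irregular: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.background_frac < 1):
            raise ValueError(f"background_frac must be in [0, 1), got {self.background_frac}")
        total = sum(d.weight for d in self.dyads)
        if self.dyads:
            if total <= 0:
                raise ValueError("dyad weights must sum to a positive value")
            self.dyads = [
                Dyad(d.position_acs, d.weight / total, d.fuzz_sd) for d in self.dyads
            ]
        for d in self.dyads:
            self.coords.from_acs_relative(d.position_acs)  # raises if off-template
            if self.nfr is not None and self.nfr[0] < d.position_acs < self.nfr[1]:
                raise ValueError(f"dyad at {d.position_acs} lies inside the NFR {self.nfr}")


@dataclass
class SimulatedLibrary:
    """A reproducible simulated fragment library plus its generating landscape."""

    fragments: list[FragmentRecord]
    landscape: NucleosomeLandscape
    n: int
    seed: int
    frag_len_mean: float = DEFAULT_FRAG_LEN_MEAN
    frag_len_sd: float = DEFAULT_FRAG_LEN_SD
    frag_len_bounds: tuple[int, int] = DEFAULT_FRAG_LEN_BOUNDS


def _acs_bounds(coords: TemplateCoordinateSystem, margin: int) -> tuple[int, int]:
    """ACS-relative coordinates of the tileable span [margin, length - margin)."""
    lo_abs, hi_abs = margin, coords.length_bp - 1 - margin
    a = coords.to_acs_relative(lo_abs)
    b = coords.to_acs_relative(hi_abs)
    return (min(a, b), max(a, b))


def _tile_from_anchor(
    anchor: int,
    direction: int,
    spacing: int,
    fuzz_sd: float,
    span: tuple[int, int],
) -> list[Dyad]:
    """Dyads phased off an anchor in one direction, decaying in weight and precision."""
    dyads = []
    k = 1
    while True:
        pos = anchor + direction * spacing * k
        if not (span[0] <= pos <= span[1]):
            break
        dyads.append(Dyad(pos, TILE_WEIGHT_DECAY**k, fuzz_sd + TILE_FUZZ_GROWTH * k))
        k += 1
    return dyads


def make_landscape_preset(
    name: str,
    coords: TemplateCoordinateSystem,
    seed: int = 0,
    *,
    fuzz_sd: float = DEFAULT_FUZZ_SD,
    spacing: int = DEFAULT_SPACING,
    background_frac: float | None = None,
    nfr: tuple[int, int] = DEFAULT_NFR,
    isw1a_upstream: int = DEFAULT_ISW1A_UPSTREAM,
) -> NucleosomeLandscape:
    """Build a named nucleosome landscape on the given template.

    ``seed`` only matters for the ``irregular`` preset, whose dyads are placed
    by a random sequential process.  ``background_frac`` defaults to 0.1 for
    the remodeled-template presets and 0 for the noise-free ``single_dyad``
    fixture.
    """
    span = _acs_bounds(coords, EDGE_MARGIN)

    if name == "single_dyad":
        return NucleosomeLandscape(
            coords=coords,
            dyads=[Dyad(0, 1.0, fuzz_sd)],
            nfr=None,
            background_frac=0.0 if background_frac is None else background_frac,
        )
    if background_frac is None:
        background_frac = DEFAULT_BACKGROUND_FRAC

    if name == "ISW2":
        # nucleosome encroaching on the origin plus the pulled-in downstream flank
        anchors = [Dyad(-54, 1.0, fuzz_sd), Dyad(168, 1.0, fuzz_sd)]
        dyads = (
            anchors
            + _tile_from_anchor(-54, -1, spacing, fuzz_sd, span)
            + _tile_from_anchor(168, +1, spacing, fuzz_sd, span)
        )
        return NucleosomeLandscape(
            coords=coords, dyads=dyads, nfr=None, background_frac=background_frac
        )

    if name == "ISW1a":
        anchors = [Dyad(isw1a_upstream, 1.0, fuzz_sd), Dyad(222, 1.0, fuzz_sd)]
        dyads = (
            anchors
            + _tile_from_anchor(isw1a_upstream, -1, spacing, fuzz_sd, span)
            + _tile_from_anchor(222, +1, spacing, fuzz_sd, span)
        )
        return NucleosomeLandscape(
            coords=coords, dyads=dyads, nfr=nfr, background_frac=background_frac
        )

    if name == "irregular":
        rng = np.random.default_rng(seed)
        placed: list[int] = []
        failures = 0
        while failures < 200:
            pos = int(rng.integers(span[0], span[1] + 1))
            in_nfr = nfr[0] < pos < nfr[1]
            too_close = any(abs(pos - p) < NUCLEOSOME_FOOTPRINT for p in placed)
            if in_nfr or too_close:
                failures += 1
                continue
            placed.append(pos)
        dyads = [Dyad(p, 1.0, fuzz_sd) for p in sorted(placed)]
        return NucleosomeLandscape(
            coords=coords, dyads=dyads, nfr=nfr, background_frac=background_frac, irregular=True
        )

    raise ValueError(f"unknown landscape preset {name!r}; expected one of {PRESETS}")


def simulate_mnase_library(
    landscape: NucleosomeLandscape,
    n: int,
    seed: int,
    frag_len_mean: float = DEFAULT_FRAG_LEN_MEAN,
    frag_len_sd: float = DEFAULT_FRAG_LEN_SD,
    frag_len_bounds: tuple[int, int] = DEFAULT_FRAG_LEN_BOUNDS,
) -> SimulatedLibrary:
    """Draw a reproducible MNase fragment library from a landscape.

    Each fragment is, with probability ``background_frac``, a uniform-start
    background fragment; otherwise a dyad is drawn by weight, the fragment
    centre is the dyad plus rounded Normal(0, fuzz_sd) jitter, and the
    fragment is ``[centre - len//2, centre - len//2 + len)`` with length drawn
    from Normal(mean, sd) truncated by redrawing to ``frag_len_bounds``.
    Fragments crossing template edges are redrawn (bounded retries).
    """
    if n < 0:
        raise ValueError(f"n must be >= 0, got {n}")
    coords = landscape.coords
    length_bp = coords.length_bp
    lo, hi = frag_len_bounds
    if not (1 <= lo <= hi <= length_bp):
        raise ValueError(f"frag_len_bounds {frag_len_bounds} invalid for template {length_bp}")

    rng = np.random.default_rng(seed)
    if n == 0:
        return SimulatedLibrary([], landscape, 0, seed, frag_len_mean, frag_len_sd, frag_len_bounds)

    dyad_abs = np.array(
        [coords.from_acs_relative(d.position_acs) for d in landscape.dyads], dtype=np.int64
    )
    weights = np.array([d.weight for d in landscape.dyads])
    fuzz = np.array([d.fuzz_sd for d in landscape.dyads])
    if dyad_abs.size == 0 and landscape.background_frac == 0:
        raise ValueError("landscape has no dyads and no background; nothing to simulate")

    starts = np.zeros(n, dtype=np.int64)
    lens = np.zeros(n, dtype=np.int64)
    todo = np.arange(n)
    tries = 0
    while todo.size:
        if tries >= _MAX_RETRIES:
            raise RuntimeError(
                f"could not place {todo.size} fragments after {_MAX_RETRIES} retries; "
                "parameters make valid placement impossible"
            )
        tries += 1
        m = todo.size
        is_bg = rng.random(m) < landscape.background_frac
        new_lens = np.rint(rng.normal(frag_len_mean, frag_len_sd, size=m)).astype(np.int64)
        new_starts = np.empty(m, dtype=np.int64)
        bg_idx = np.flatnonzero(is_bg)
        nuc_idx = np.flatnonzero(~is_bg)
        if bg_idx.size:
            new_starts[bg_idx] = rng.integers(0, length_bp, size=bg_idx.size)
        if nuc_idx.size:
            if dyad_abs.size == 0:
                raise ValueError("landscape has no dyads but background_frac < 1")
            which = rng.choice(dyad_abs.size, size=nuc_idx.size, p=weights)
            jitter = np.rint(rng.normal(0.0, 1.0, size=nuc_idx.size) * fuzz[which]).astype(np.int64)
            centers = dyad_abs[which] + jitter
            new_starts[nuc_idx] = centers - new_lens[nuc_idx] // 2
        starts[todo] = new_starts
        lens[todo] = new_lens
        bad = (
            (new_lens < lo)
            | (new_lens > hi)
            | (new_starts < 0)
            | (new_starts + new_lens > length_bp)
        )
        todo = todo[bad]

    fragments = [
        FragmentRecord(coords.template_id, int(s), int(s + l)) for s, l in zip(starts, lens)
    ]
    return SimulatedLibrary(
        fragments, landscape, n, seed, frag_len_mean, frag_len_sd, frag_len_bounds
    )


def write_landscape_table(landscape: NucleosomeLandscape, path) -> None:
    """Write the ground-truth dyads as a TSV side-car (position, weight, fuzz)."""
    coords = landscape.coords
    with open(path, "w") as handle:
        handle.write("position_acs\tposition_abs\tweight\tfuzz_sd\n")
        for d in landscape.dyads:
            handle.write(
                f"{d.position_acs}\t{coords.from_acs_relative(d.position_acs)}\t"
                f"{d.weight:.9g}\t{d.fuzz_sd:.9g}\n"
            )
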