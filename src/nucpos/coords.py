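"""Coordinate conventions and I/O for fragments, tracks, and peak tables.

All internal coordinates are 0-based half-open intervals on a single short
template (e.g. a ~3.8 kb origin-containing restriction fragment).  SAM input
uses 1-based positions and is converted on ingestion; BED is native.

Positions can be re-expressed relative to the ACS (ARS consensus sequence),
the ORC-binding element that anchors origin-centric plots: ACS-relative
coordinate 0 is the first nucleotide of the ACS, and coordinates increase in
the configured orientation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pysam

logger = logging.getLogger(__name__)

FRAGMENT_FORMATS = ("bed3", "bedpe", "sam")


@dataclass(frozen=True)
class TemplateCoordinateSystem:
    """A single linear template plus the ACS anchor for relative coordinates.

    Parameters
    ----------
    template_id : str
        Name of the template sequence (must match input chromosome fields).
    length_bp : int
        Template length in base pairs (default 3800, a 3.8 kb origin fragment).
    acs_offset : int
        Absolute 0-based position of the first nucleotide of the ACS.
    orientation : {"forward", "reverse"}
        Direction in which ACS-relative coordinates increase.  ``reverse``
        supports templates where the ACS is on the minus strand.
    """

    template_id: str
    acs_offset: int
    length_bp: int = 3800
    orientation: str = "forward"

    def __post_init__(self) -> None:
        if self.length_bp <= 0:
            raise ValueError(f"length_bp must be positive, got {self.length_bp}")
        if not (0 <= self.acs_offset < self.length_bp):
            raise ValueError(
                f"acs_offset {self.acs_offset} outside template [0, {self.length_bp})"
            )
        if self.orientation not in ("forward", "reverse"):
            raise ValueError(f"orientation must be forward/reverse, got {self.orientation!r}")

    def to_acs_relative(self, position: int) -> int:
        """Map an absolute 0-based position to an ACS-relative coordinate."""
        if not (0 <= position < self.length_bp):
            raise ValueError(
                f"position {position} outside template [0, {self.length_bp})"
            )
        if self.orientation == "forward":
            return position - self.acs_offset
        return self.acs_offset - position

    def from_acs_relative(self, rel: int) -> int:
        """Inverse of :meth:`to_acs_relative`; round-trips exactly."""
        if self.orientation == "forward":
            position = rel + self.acs_offset
        else:
            position = self.acs_offset - rel
        if not (0 <= position < self.length_bp):
            raise ValueError(
                f"ACS-relative {rel} maps outside template [0, {self.length_bp})"
            )
        return position


@dataclass(frozen=True)
class FragmentRecord:
    """One sequenced MNase fragment as a 0-based half-open interval."""

    template_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(f"invalid interval [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


def to_acs_relative(position: int, coords: TemplateCoordinateSystem) -> int:
    """Functional alias for :meth:`TemplateCoordinateSystem.to_acs_relative`."""
    return coords.to_acs_relative(position)


def _check_fragment(
    start: int, end: int, coords: TemplateCoordinateSystem, lineno: int, path
) -> None:
    if start < 0 or end > coords.length_bp or end <= start:
        raise ValueError(
            f"{path}:{lineno}: interval [{start}, {end}) outside template "
            f"[0, {coords.length_bp}) or empty"
        )


def read_fragments(
    path, format: str, coords: TemplateCoordinateSystem
) -> list[FragmentRecord]:
    """Read aligned fragments from BED3, BEDPE, or SAM into FragmentRecords.

    BED3 rows map directly (0-based half-open).  BEDPE rows span from the
    leftmost mate start to the rightmost mate end.  SAM proper pairs are
    reduced to one fragment each via the mate with a positive template-length
    field: 1-based POS ``P`` and TLEN ``T`` give ``[P-1, P-1+T)``.

    Records on templates other than ``coords.template_id`` are skipped with a
    logged count, as are SAM pairs with TLEN 0.  Duplicates are retained.
    """
    if format not in FRAGMENT_FORMATS:
        raise ValueError(f"unknown fragment format {format!r}; expected one of {FRAGMENT_FORMATS}")
    path = Path(path)
    if format == "sam":
        return _read_sam(path, coords)

    fragments: list[FragmentRecord] = []
    n_other = 0
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            try:
                if format == "bed3":
                    chrom, start, end = fields[0], int(fields[1]), int(fields[2])
                else:  # bedpe
                    chrom = fields[0]
                    if fields[3] != chrom:
                        n_other += 1
                        continue
                    start = min(int(fields[1]), int(fields[4]))
                    end = max(int(fields[2]), int(fields[5]))
            except (IndexError, ValueError) as exc:
                raise ValueError(f"{path}:{lineno}: unparseable {format} line: {line!r}") from exc
            if chrom != coords.template_id:
                n_other += 1
                continue
            _check_fragment(start, end, coords, lineno, path)
            fragments.append(FragmentRecord(chrom, start, end))
    if n_other:
        logger.info("skipped %d records on other templates in %s", n_other, path)
    return fragments


def _read_sam(path: Path, coords: TemplateCoordinateSystem) -> list[FragmentRecord]:
    fragments: list[FragmentRecord] = []
    n_other = 0
    n_zero_tlen = 0
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped or not rec.is_proper_pair:
                continue
            tlen = rec.template_length
            # one fragment per pair: only the leftmost mate (TLEN > 0) emits
            if tlen == 0:
                n_zero_tlen += 1
                continue
            if tlen < 0:
                continue
            if rec.reference_name != coords.template_id:
                n_other += 1
                continue
            start = rec.reference_start  # pysam is already 0-based
            end = start + tlen
            _check_fragment(start, end, coords, rec.query_name, path)
            fragments.append(FragmentRecord(coords.template_id, start, end))
    if n_other:
        logger.info("skipped %d SAM pairs on other templates in %s", n_other, path)
    if n_zero_tlen:
        logger.info("skipped %d SAM records with TLEN=0 in %s", n_zero_tlen, path)
    return fragments


def write_fragments_bed3(fragments: Iterable[FragmentRecord], path) -> None:
    """Write fragments as BED3, one 0-based half-open interval per row."""
    with open(path, "w") as handle:
        for frag in fragments:
            handle.write(f"{frag.template_id}\t{frag.start}\t{frag.end}\n")


def write_track_bedgraph(track, coords: TemplateCoordinateSystem, path) -> None:
    """Write a per-base track as bedGraph, merging runs of equal value.

    Values are rendered with 9 significant digits so a read-back reproduces
    the track within 1e-6.
    """
    values = np.asarray(track.values, dtype=float)
    if values.shape[0] != coords.length_bp:
        raise ValueError(
            f"track length {values.shape[0]} != template length {coords.length_bp}"
        )
    # run-length encode equal consecutive values
    change = np.flatnonzero(np.diff(values)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [values.shape[0]]))
    with open(path, "w") as handle:
        for s, e in zip(starts, ends):
            handle.write(f"{coords.template_id}\t{s}\t{e}\t{values[s]:.9g}\n")


def read_track_bedgraph(path, coords: TemplateCoordinateSystem) -> np.ndarray:
    """Read a bedGraph written by :func:`write_track_bedgraph` back to per-base values."""
    values = np.zeros(coords.length_bp)
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            try:
                chrom, start, end, value = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
            except (IndexError, ValueError) as exc:
                raise ValueError(f"{path}:{lineno}: unparseable bedGraph line") from exc
            if chrom != coords.template_id:
                continue
            values[start:end] = value
    return values


def write_peaks_bed6(peaks: Sequence, coords: TemplateCoordinateSystem, path) -> None:
    """Write called peaks as BED6 (name = peak id, score = density height)."""
    with open(path, "w") as handle:
        for i, peak in enumerate(peaks, start=1):
            handle.write(
                f"{coords.template_id}\t{peak.position_abs}\t{peak.position_abs + 1}\t"
                f"peak_{i}\t{peak.height:.9g}\t.\n"
            )


def write_peaks_table(peaks: Sequence, path) -> None:
    """Write peaks as a TSV with absolute and ACS-relative positions."""
    with open(path, "w") as handle:
        handle.write("position_abs\tposition_acs\theight\trank\n")
        for peak in peaks:
            handle.write(
                f"{peak.position_abs}\t{peak.position_acs}\t{peak.height:.9g}\t{peak.rank}\n"
            )


def write_shifts_table(shifts: Sequence, path) -> None:
    """Write dyad shifts as a TSV; unpaired peaks have empty partner fields."""
    with open(path, "w") as handle:
        handle.write("ref_position\talt_position\tshift_bp\tpaired\n")
        for shift in shifts:
            ref = "" if shift.ref_position is None else str(shift.ref_position)
            alt = "" if shift.alt_position is None else str(shift.alt_position)
            sb = "" if shift.shift_bp is None else str(shift.shift_bp)
            handle.write(f"{ref}\t{alt}\t{sb}\t{str(shift.paired).lower()}\n")


def read_config(path) -> dict[str, str]:
    """Read a key-value config file (``key = value`` per line, # comments)."""
    config: dict[str, str] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value', got {line!r}")
            key, _, value = line.partition("=")
            config[key.strip()] = value.strip()
    return config


def write_config(config: dict, path) -> None:
    with open(path, "w") as handle:
        for key, value in config.items():
            handle.write(f"{key} = {value}\n")


def coords_from_config(config: dict[str, str]) -> TemplateCoordinateSystem:
    """Build a coordinate system from config keys template_id/length_bp/acs_offset/orientation."""
    return TemplateCoordinateSystem(
        template_id=config.get("template_id", "template"),
        length_bp=int(config.get("length_bp", 3800)),
        acs_offset=int(config["acs_offset"]),
        orientation=config.get("orientation", "forward"),
    )
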