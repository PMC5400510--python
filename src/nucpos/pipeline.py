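"""End-to-end pipeline: fragments (read or simulated) -> midpoints -> track -> peaks.

A :class:`PipelineConfig` carries every parameter of every stage plus either
an input-fragment path or a simulation block; :func:`run_pipeline` executes
the stages and writes a reproducible artifact set (bedGraph track, peak
tables, optional shift table, and a run log recording every applied
parameter).  Reruns with an identical config produce byte-identical peak
tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import pandas as pd

from . import coords as coords_io
from .coords import TemplateCoordinateSystem
from .midpoints import extract_midpoints, DEFAULT_SIZE_LO, DEFAULT_SIZE_HI
from .track import build_track, normalize_track, DEFAULT_BANDWIDTH, DEFAULT_TRUNCATION_SD
from .peaks import (
    call_consensus_positions,
    pair_and_shift,
    ConsensusPeak,
    DEFAULT_THRESHOLD,
    DEFAULT_MIN_SEPARATION,
    DEFAULT_PAIRING_WINDOW,
)
from .simulate import (
    make_landscape_preset,
    simulate_mnase_library,
    write_landscape_table,
    DEFAULT_FUZZ_SD,
    DEFAULT_FRAG_LEN_MEAN,
    DEFAULT_FRAG_LEN_SD,
    DEFAULT_FRAG_LEN_BOUNDS,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Every tunable of the pipeline, round-trippable through a key-value file."""

    # coordinate system
    template_id: str = "ARS1_template"
    length_bp: int = 3800
    acs_offset: int = 1000
    orientation: str = "forward"
    # input (exactly one of input_path / sim_preset must be set)
    input_path: Optional[str] = None
    input_format: str = "bed3"
    # simulation block
    sim_preset: Optional[str] = None
    sim_n: int = 50000
    seed: int = 1
    sim_fuzz_sd: float = DEFAULT_FUZZ_SD
    # None -> the preset's own default (0.1, or 0 for single_dyad)
    sim_background_frac: Optional[float] = None
    sim_frag_len_mean: float = DEFAULT_FRAG_LEN_MEAN
    sim_frag_len_sd: float = DEFAULT_FRAG_LEN_SD
    sim_frag_len_lo: int = DEFAULT_FRAG_LEN_BOUNDS[0]
    sim_frag_len_hi: int = DEFAULT_FRAG_LEN_BOUNDS[1]
    # size selection
    size_lo: int = DEFAULT_SIZE_LO
    size_hi: int = DEFAULT_SIZE_HI
    # track
    bandwidth: float = DEFAULT_BANDWIDTH
    truncation_sd: float = DEFAULT_TRUNCATION_SD
    # peak calling
    threshold: float = DEFAULT_THRESHOLD
    min_separation: int = DEFAULT_MIN_SEPARATION
    pairing_window: int = DEFAULT_PAIRING_WINDOW
    # optional comparison: peak table of a reference condition
    compare_to: Optional[str] = None
    # outputs
    output_dir: str = "nucpos_out"

    def coords(self) -> TemplateCoordinateSystem:
        return TemplateCoordinateSystem(
            template_id=self.template_id,
            length_bp=self.length_bp,
            acs_offset=self.acs_offset,
            orientation=self.orientation,
        )

    def to_file(self, path) -> None:
        items = {k: v for k, v in asdict(self).items() if v is not None}
        coords_io.write_config(items, path)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        raw = coords_io.read_config(path)
        kwargs: dict = {}
        for f_name, f_type in cls.__dataclass_fields__.items():
            if f_name not in raw:
                continue
            value = raw[f_name]
            typ = f_type.type
            if typ in ("int", "Optional[int]"):
                kwargs[f_name] = int(value)
            elif typ in ("float", "Optional[float]"):
                kwargs[f_name] = float(value)
            else:
                kwargs[f_name] = value
        return cls(**kwargs)


@dataclass
class PipelineResult:
    """In-memory results plus the paths of the written artifacts."""

    peaks: list[ConsensusPeak]
    track: object
    n_fragments: int
    n_filtered: int
    artifacts: dict[str, Path] = field(default_factory=dict)


def read_peaks_table(path) -> pd.DataFrame:
    """Read a peak TSV written by the pipeline (position_abs, position_acs, height, rank)."""
    return pd.read_csv(path, sep="\t")


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute read/simulate -> filter -> midpoints -> track -> normalize -> peaks.

    Writes track.bedgraph, peaks.tsv, peaks.bed, optionally shifts.tsv and the
    simulated fragments/landscape, plus run.log with every applied parameter.
    On failure, partially written outputs are removed.
    """
    if (config.input_path is None) == (config.sim_preset is None):
        raise ValueError("config must set exactly one of input_path or sim_preset")

    coords = config.coords()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _out(name: str) -> Path:
        path = outdir / name
        written.append(path)
        return path

    try:
        if config.sim_preset is not None:
            landscape = make_landscape_preset(
                config.sim_preset,
                coords,
                seed=config.seed,
                fuzz_sd=config.sim_fuzz_sd,
                background_frac=config.sim_background_frac,
            )
            library = simulate_mnase_library(
                landscape,
                config.sim_n,
                seed=config.seed,
                frag_len_mean=config.sim_frag_len_mean,
                frag_len_sd=config.sim_frag_len_sd,
                frag_len_bounds=(config.sim_frag_len_lo, config.sim_frag_len_hi),
            )
            fragments = library.fragments
            coords_io.write_fragments_bed3(fragments, _out("fragments.bed"))
            write_landscape_table(landscape, _out("landscape.tsv"))
        else:
            fragments = coords_io.read_fragments(config.input_path, config.input_format, coords)

        midpoint_set = extract_midpoints(fragments, config.size_lo, config.size_hi)
        raw = build_track(midpoint_set, coords, config.bandwidth, config.truncation_sd)
        norm = normalize_track(raw)
        peaks = call_consensus_positions(norm, coords, config.threshold, config.min_separation)

        coords_io.write_track_bedgraph(norm, coords, _out("track.bedgraph"))
        coords_io.write_peaks_table(peaks, _out("peaks.tsv"))
        coords_io.write_peaks_bed6(peaks, coords, _out("peaks.bed"))

        if config.compare_to is not None:
            ref = read_peaks_table(config.compare_to)
            ref_peaks = [
                ConsensusPeak(int(r.position_abs), int(r.position_acs), float(r.height), int(r.rank))
                for r in ref.itertuples()
            ]
            shifts = pair_and_shift(ref_peaks, peaks, config.pairing_window)
            coords_io.write_shifts_table(shifts, _out("shifts.tsv"))

        log_items = dict(asdict(config))
        log_items["n_fragments"] = len(fragments)
        log_items["n_filtered"] = len(midpoint_set)
        log_items["n_peaks"] = len(peaks)
        coords_io.write_config(log_items, _out("run.log"))
        logger.info(
            "pipeline done: %d fragments, %d in [%d, %d] bp, %d peaks",
            len(fragments), len(midpoint_set), config.size_lo, config.size_hi, len(peaks),
        )
    except Exception:
        for path in written:
            path.unlink(missing_ok=True)
        raise

    return PipelineResult(
        peaks=peaks,
        track=norm,
        n_fragments=len(fragments),
        n_filtered=len(midpoint_set),
        artifacts={p.name: p for p in written},
    )
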