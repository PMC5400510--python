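"""Coordinate conventions and fragment/track I/O."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nucpos import (
    TemplateCoordinateSystem,
    FragmentRecord,
    read_fragments,
    write_fragments_bed3,
    write_track_bedgraph,
    read_track_bedgraph,
)
from nucpos.coords import read_config, write_config
from nucpos.track import DyadTrack

SAM_HEADER = "@HD\tVN:1.6\tSO:coordinate\n@SQ\tSN:ARS1_template\tLN:3800\n"


def _sam_pair(name, chrom, pos, tlen, flag_fwd=99, flag_rev=147):
    fwd = f"{name}\t{flag_fwd}\t{chrom}\t{pos}\t42\t{tlen}M\t=\t{pos}\t{tlen}\t*\t*\n"
    rev = f"{name}\t{flag_rev}\t{chrom}\t{pos}\t42\t{tlen}M\t=\t{pos}\t{-tlen}\t*\t*\n"
    return fwd + rev


class TestAcsMapping:
    def test_anchor_maps_to_zero(self, coords):
        assert coords.to_acs_relative(coords.acs_offset) == 0

    def test_forward_subtraction(self, coords):
        assert coords.to_acs_relative(946) == -54

    def test_reverse_orientation(self):
        coords = TemplateCoordinateSystem("t", acs_offset=1000, orientation="reverse")
        assert coords.to_acs_relative(832) == 168

    def test_out_of_range_position_rejected(self, coords):
        with pytest.raises(ValueError):
            coords.to_acs_relative(3800)
        with pytest.raises(ValueError):
            coords.to_acs_relative(-1)

    @given(pos=st.integers(min_value=0, max_value=3799),
           orientation=st.sampled_from(["forward", "reverse"]))
    @settings(max_examples=50, deadline=None)
    def test_round_trip_bijection(self, pos, orientation):
        coords = TemplateCoordinateSystem("t", acs_offset=1900, orientation=orientation)
        assert coords.from_acs_relative(coords.to_acs_relative(pos)) == pos

    def test_invalid_coordinate_system_rejected(self):
        with pytest.raises(ValueError):
            TemplateCoordinateSystem("t", acs_offset=4000, length_bp=3800)
        with pytest.raises(ValueError):
            TemplateCoordinateSystem("t", acs_offset=10, orientation="sideways")


class TestReadFragments:
    def test_bed3_direct_parse(self, coords, tmp_path):
        path = tmp_path / "frags.bed"
        path.write_text("ARS1_template\t100\t250\n")
        (frag,) = read_fragments(path, "bed3", coords)
        assert (frag.start, frag.end, frag.length) == (100, 250, 150)

    def test_empty_file_gives_empty_collection(self, coords, tmp_path):
        path = tmp_path / "empty.bed"
        path.write_text("")
        assert read_fragments(path, "bed3", coords) == []

    def test_other_template_skipped(self, coords, tmp_path):
        path = tmp_path / "frags.bed"
        path.write_text("ARS1_template\t100\t250\nother\t5\t160\n")
        assert len(read_fragments(path, "bed3", coords)) == 1

    def test_unparseable_line_names_line_number(self, coords, tmp_path):
        path = tmp_path / "bad.bed"
        path.write_text("ARS1_template\t100\t250\nARS1_template\tnot_an_int\t9\n")
        with pytest.raises(ValueError, match=":2"):
            read_fragments(path, "bed3", coords)

    def test_unknown_format_rejected(self, coords, tmp_path):
        path = tmp_path / "frags.bed"
        path.write_text("")
        with pytest.raises(ValueError, match="format"):
            read_fragments(path, "wig", coords)

    def test_bedpe_spans_both_mates(self, coords, tmp_path):
        path = tmp_path / "frags.bedpe"
        path.write_text("ARS1_template\t100\t136\tARS1_template\t214\t250\tp1\t0\t+\t-\n")
        (frag,) = read_fragments(path, "bedpe", coords)
        assert (frag.start, frag.end) == (100, 250)

    def test_sam_pair_yields_one_fragment(self, coords, tmp_path):
        path = tmp_path / "frags.sam"
        path.write_text(SAM_HEADER + _sam_pair("r1", "ARS1_template", 101, 150))
        (frag,) = read_fragments(path, "sam", coords)
        assert (frag.start, frag.end) == (100, 250)

    def test_sam_zero_tlen_skipped(self, coords, tmp_path):
        path = tmp_path / "frags.sam"
        rec = "r2\t99\tARS1_template\t101\t42\t150M\t=\t101\t0\t*\t*\n"
        path.write_text(SAM_HEADER + rec)
        assert read_fragments(path, "sam", coords) == []

    def test_sam_tlen_matches_interval_length(self, coords, tmp_path):
        path = tmp_path / "frags.sam"
        path.write_text(
            SAM_HEADER
            + _sam_pair("a", "ARS1_template", 11, 147)
            + _sam_pair("b", "ARS1_template", 500, 131)
        )
        for frag, tlen in zip(read_fragments(path, "sam", coords), (147, 131)):
            assert frag.length == tlen

    @given(intervals=st.lists(
        st.tuples(st.integers(0, 3600), st.integers(1, 200)), max_size=20))
    @settings(max_examples=25, deadline=None)
    def test_bed3_round_trip(self, coords, tmp_path_factory, intervals):
        frags = [FragmentRecord("ARS1_template", s, s + l) for s, l in intervals]
        path = tmp_path_factory.mktemp("rt") / "frags.bed"
        write_fragments_bed3(frags, path)
        assert read_fragments(path, "bed3", coords) == frags


class TestBedgraph:
    def test_all_zero_track_is_single_line(self, coords, tmp_path):
        track = DyadTrack("ARS1_template", np.zeros(3800), n_midpoints=0)
        path = tmp_path / "zero.bedgraph"
        write_track_bedgraph(track, coords, path)
        lines = path.read_text().strip().split("\n")
        assert lines == ["ARS1_template\t0\t3800\t0"]

    def test_single_nonzero_base_gives_three_runs(self, coords, tmp_path):
        values = np.zeros(3800)
        values[500] = 1.5
        track = DyadTrack("ARS1_template", values, n_midpoints=1)
        path = tmp_path / "one.bedgraph"
        write_track_bedgraph(track, coords, path)
        lines = path.read_text().strip().split("\n")
        assert len(lines) == 3
        assert lines[1] == "ARS1_template\t500\t501\t1.5"

    def test_round_trip_within_1e6(self, coords, tmp_path):
        rng = np.random.default_rng(0)
        values = rng.gamma(2.0, 1.0, size=3800)
        track = DyadTrack("ARS1_template", values, n_midpoints=100)
        path = tmp_path / "track.bedgraph"
        write_track_bedgraph(track, coords, path)
        back = read_track_bedgraph(path, coords)
        assert np.max(np.abs(back - values)) < 1e-6


def test_config_round_trip(tmp_path):
    config = {"template_id": "ARS1_template", "length_bp": "3800", "acs_offset": "1000"}
    path = tmp_path / "run.config"
    write_config(config, path)
    assert read_config(path) == config
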