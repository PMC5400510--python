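# Methods

## Problem and model

`nucpos` maps nucleosome positions on a short linear template — the motivating
case is a 3.8 kb *S. cerevisiae* fragment carrying the *ARS1* replication
origin, chromatinized in vitro by a chromatin-remodeling enzyme (CRE) — from
paired-end MNase-seq. MNase digests linker DNA and leaves ~147 bp
nucleosome-protected fragments, so the midpoint of a mononucleosome-sized
fragment is a noisy estimate of the dyad (the central base pair of the
wrapped DNA). The pipeline is:

1. **Size selection.** Keep fragments with length in [125, 175] bp (bounds
   inclusive). This brackets the mononucleosome footprint and discards
   sub-nucleosomal and di-nucleosomal material.
2. **Midpoint extraction.** One midpoint per fragment,
   `floor((start + end) / 2)`. Even-length fragments have no integer center;
   floor rounding is applied uniformly, a ≤ 0.5 bp bias that is symmetric
   across a landscape.
3. **Kernel density track.** Each midpoint contributes a unit-mass Gaussian
   with σ = 20 bp evaluated on the integer base grid, truncated at ±3σ
   (0.27% mass loss, not renormalized); the kernels are summed into a
   per-base track. No edge reflection: mass falling off the template is lost.
   The implementation convolves the midpoint histogram with the sampled
   kernel; tests check it against a literal per-(position, midpoint) double
   loop to 1e-9.
4. **Depth normalization.** The track is scaled by `1e6 / n_midpoints`
   (signal per million size-selected fragments), making libraries of
   different depth comparable. The scale constant is recorded on the track
   so any alternative depth convention is a multiplicative change.
5. **Consensus peak calling.** Consensus dyads are strict local maxima of
   the normalized track above a height threshold (default 2). Discrete
   tracks can plateau; a plateau counts as one maximum at its center
   (left-of-center when even), and plateaus touching the template edge are
   not called. Maxima closer than a minimum separation (default 120 bp, just
   under the 147 bp footprint — two dyads cannot be closer than a footprint
   allows) are resolved greedily: highest first, leftmost on ties.
6. **Landscape comparison.** Peak lists from two conditions are paired
   one-to-one on ACS-relative positions, closest pairs first within a
   100 bp window; each pair reports `shift_bp = alt − ref`, unpaired peaks
   are flagged. Mean and sample SD of successive inter-dyad gaps summarize
   spacing and regularity.

Coordinates are 0-based half-open internally; SAM's 1-based positions are
converted on input, BED is native. Plot-style coordinates are expressed
relative to the ACS (ARS consensus sequence, the ORC binding element):
0 is its first nucleotide, and a `reverse` orientation is supported because
the element's strand on a given template is a property of the construct,
not of the method. One SAM proper pair yields exactly one fragment (the
mate with positive TLEN), preventing double counting; duplicates are
retained (no deduplication step is part of the procedure).

## Parameters that matter

| parameter | default | units | meaning |
|---|---|---|---|
| `size_lo`, `size_hi` | 125, 175 | bp | inclusive mononucleosome size window |
| `bandwidth_bp` | 20 | bp | Gaussian kernel σ |
| `truncation_sd` | 3 | σ | kernel support half-width |
| `threshold` | 2 | per-million signal | minimum peak height |
| `min_separation` | 120 | bp | non-maximum suppression radius |
| `pairing_window` | 100 | bp | max ref–alt distance when pairing dyads |

"20 bp Gaussian kernel" is read as σ = 20 bp, the common convention in
midpoint-smoothing pipelines; FWHM or full-window readings would be
narrower, and the bandwidth is exposed as a parameter for that reason.
Likewise the peak threshold's unit depends on the depth-normalization
convention; per-million is this package's recorded choice, and on a
~4 kb template normalized values are large (mean ≈ 263 per million per
base), so the default threshold of 2 excludes only near-empty regions.
Both knobs are configurable rather than baked in.

## Synthetic libraries

The generator (`nucpos.simulate`) emulates sequencing of an MNase digest of
a remodeled template. A `NucleosomeLandscape` is a list of dyads, each with
an ACS-relative position, a sampling weight, and a positional SD ("fuzz"),
plus an optional nucleosome-free region (NFR) and a uniform background
fraction. A fragment is drawn by: (background with probability
`background_frac`, uniform start) or (dyad by weight → center = dyad +
rounded Normal(0, fuzz) → length = rounded Normal(147, 10) redrawn until in
[100, 200] → interval `[center − len//2, center − len//2 + len)`).
Edge-crossing draws are redrawn, preserving the length distribution.
Everything is reproducible from a single seed.

Presets encode the landscapes of CRE-remodeled origin templates:

- **ISW1a** — NFR over the origin ([−120, +120], a configurable default:
  NFR boundaries are construct-specific), flanking dyads at −200
  (configurable; only the downstream flank has a canonical value) and +222.
- **ISW2** — nucleosome encroaching on the origin (dyad −54) and the
  downstream flank pulled in to +168; no NFR.
- **irregular** — random sequential placement with a 147 bp exclusion zone,
  NFR preserved; models remodelers that do not phase arrays.
- **single_dyad** — one perfectly positioned nucleosome at ACS+0 with zero
  background; a clean pipeline fixture.

Tiled presets extend the anchor dyads into phased arrays at 165 bp repeat
(nucleosome repeat lengths in this range are typical; the exact value is
configurable). Phasing decays with distance from the positioning anchor, as
in real barrier-phased arrays: tiled dyads have weight 0.8^k and fuzz
10 + 2k bp at the k-th repeat, while anchors keep fuzz 10 bp. The fragment
length model Normal(147, 10) on [100, 200] makes the 125–175 bp filter do
real work (it retains ~79% of nucleosomal fragments).

What the generator does *not* emulate: MNase sequence-dependent cut bias,
partial unwrapping, GC/amplification bias, multi-template contamination,
and overlapping/alternative nucleosome configurations. Pipeline tests on
these libraries therefore demonstrate correctness of the computation and
parameter-recovery behavior under the stated noise model, not performance
on real sequencing data.

## Replicate quantification

Band/blot intensities (densitometry output, consumed as a tidy
condition/replicate/intensity table) are expressed as
`100 × intensity / mean(reference intensities)`; the reference condition's
mean is exactly 100% by construction, and per-condition spread is the
sample SD (n − 1 denominator, the convention for small biological-replicate
counts such as n = 3). Percentages are invariant to any global rescale of
the raw intensities. Conditions with one replicate report SD 0.

## Numerical and design notes

- Peak calling on unnormalized tracks is refused, keeping threshold units
  well defined; double normalization is likewise an error.
- Greedy highest-first suppression with leftmost tie-break makes peak sets
  deterministic and independent of input order.
- `estimate_spacing` with exactly two peaks returns a NaN SD (one gap;
  sample SD undefined).
- Simulation problem sizes in tests and in the reproduction script are
  n = 20,000–50,000 fragments on a 3.8 kb template — ample for sub-bp
  standard error on anchor dyad positions while keeping runs to seconds.
- With 10% uniform background and the per-million threshold of 2,
  background-only local maxima can exceed the threshold; the minimum
  separation keeps them suppressed wherever dyads tile the template, but a
  wide dyad-free gap (e.g. an NFR much wider than twice the separation) can
  admit a background peak. Raising the threshold toward the background
  level (≈ `background_frac × 1e6 / length_bp`) removes these.

## Known limitations

- Single-template analyses only; no multi-chromosome support, and BAM files
  should be converted to SAM (or BED) upstream.
- The peak caller is a local-maximum scanner, not an HMM or
  template-matching positioner; closely overlapping alternative nucleosome
  configurations are reported as single consensus positions.
- Read alignment is out of scope: the pipeline consumes aligned fragments.
  (For the record, the upstream alignments motivating the defaults were
  produced with Bowtie `-n 2 -l 20 --best --strata`.)
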