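# Methods

This note documents the model, the numerical choices and the open design
decisions behind `diamotion`, and what the synthetic-data tests do and do
not establish.

## Coordinate conventions

Frames are 2-D rasters with row 0 at the superior edge and columns
running anterior (y = 0) to posterior. All vertical positions use a
superior-positive pixel coordinate, `z = n_rows − 1 − row`, so
inspiratory diaphragm descent decreases z and end-expiration is a local
*maximum* of the motion waveform. Y positions are 0-based column
indices; physical units come from the isotropic in-plane pixel spacing
(default 1.5 mm/px).

## Profile extraction

The diaphragm *field* mask is collapsed to a 1-D profile by taking the
superior-most foreground pixel per column. This is a design choice: the
field's upper boundary is the moving air–tissue interface, and a band- or
region-shaped segmentation moves rigidly with it. A per-column centroid
collapse is available (`collapse="centroid"`) for segmentations whose
thickness varies with respiration; all downstream statistics are
unchanged in form.

Gap handling, unspecified by any physical model, is graded by size:
single-column interior gaps (flag pattern 1,0,1) are segmentation
dropouts and are repaired by linear interpolation of z; interior gaps of
two or more columns usually mean the mask is unreliable in that region,
so the frame's profile is truncated to its longest contiguous run.
Frames with empty masks are excluded with a warning; more than 10% empty
frames (configurable) is a hard error, since the series is then not a
usable motion record.

## Common-range selection

The common Y-range over frames is `[y_start_max, y_end_min]`. If its
length exceeds the threshold (default 80 px) all frames are kept.
Otherwise the range is extended on the *start* side only: the new start
is the median of per-frame starts, and frames starting after it are
discarded. Two details are deliberately pinned down:

* **Lower median.** For an even number of frames the median of the start
  list is taken as the lower middle order statistic. This makes the
  retained set {frames with y_start ≤ median} provably contain at least
  ⌈M/2⌉ frames, which the randomized selection-contract tests verify.
* **Ties retained.** Frames whose start equals the median are kept
  (≤, not <).

The end `y_end_min` is computed over all valid frames before any
discarding. Waveforms are the N = y_end_min − y_start columns starting
at the selected start; each is centered by its temporal mean over the
retained frames only, so every waveform has mean zero by construction
(checked to 1e-9).

## Cycle detection

No detection algorithm is canonical for quiet-breathing waveforms, so a
standard prominence-based peak finder is used (`scipy.signal.find_peaks`):
end-expiratory peaks must have prominence ≥ 0.5 × waveform SD and be
≥ 1.5 s apart. Both defaults are configurable; they are conservative for
breathing periods of 2–8 s sampled at ~8 f/s. Periods are successive
peak-time differences; the peak amplitude is the centered waveform value
at the peak (baseline 0), *not* peak-to-trough — both readings are
defensible, this one is documented. Fewer than two peaks is an error
("insufficient cycles"); the subject-level pipeline downgrades it to a
QC flag because the NCC and amplitude metrics remain well defined.

Group comparisons of per-subject SDs (and of the subject-level metrics)
default to a two-sided Welch t-test, with Mann–Whitney U as an option;
the small, unequal-variance groups typical of this design make Welch a
reasonable default, and no multiple-testing correction is applied by
default. No specific published p-value is claimed to be reproduced,
since the underlying patient data are not available and the original
test is unnamed.

## NCC map

The NCC operates on the already-centered waveforms; it never re-centers,
avoiding a double-centering ambiguity. Constant (zero-energy) waveforms
have no defined NCC; at the single-pair level this is an error, at the
map level the position is excluded with a warning — a frozen column is a
data-quality problem, not "zero similarity". The map mean R̄ averages
the strict upper triangle (N(N−1)/2 pairs). Rendering clamps the color
scale to [0, 1] so maps are comparable across subjects; negative values
survive in the CSV.

## Mid-position and mean absolute amplitude

`y_mid` is ⌊grand mean + 0.5⌋ — explicit round-half-up, not banker's
rounding — of the per-frame mean flagged column, computed over *all*
valid frames. The amplitude metric likewise uses all valid frames, not
the selection-filtered subset: it samples 2K+1 = 11 columns at 5 px
spacing around y_mid (K and y_int configurable), centers each column's
series by its own temporal mean over the frames where the column is
flagged, and averages |ẑ| over time then over columns. A sampled column
missing in ≤ 10% of frames is averaged over its available frames;
missing more often is a hard error, since near the mid-position the
profile should essentially always exist. Values are reported in pixels
and in mm (× pixel spacing) because the field has no single convention.

## Synthetic generator

The generator states a world resembling the target acquisition: 256×256
px frames at 8.33 f/s and 1.5 mm/px, 1200 frames (~2.4 min). Defaults
chosen where no external value exists, fixed once:

| parameter | default | rationale |
|---|---|---|
| dome span / apex / drop | columns 40–215, z 150, −30 px | mid-thorax dome, > 80 px common range |
| amplitude_px | 8 px (12 mm) | quiet-breathing diaphragm excursion ~1–2 cm |
| period_s | 4 s | 15 breaths/min |
| period_jitter_sd | 0.4 s | ~10% cycle-to-cycle variation |
| amplitude_jitter_sd | 0.8 px | ~10% breath-depth variation |
| field thickness | 8 px | band under the curve; only the top edge matters |
| noise_sd_px | 0 (tests often 0.3) | sub-pixel segmentation jitter |

Motion is `z(y,t) = z0(y) − A(t)·sin(θ(t) + φ(y)) + ε` with θ advancing
2π per breath through per-cycle period draws N(period_s, jitter²)
(clipped positive) and A(t) interpolating linearly between consecutive
per-cycle amplitude draws (truncated at 0), keeping the surface
continuous across cycle boundaries. The initial phase places an
end-expiratory peak exactly at each cycle start, so the drawn per-cycle
periods and amplitudes are recoverable one-to-one from detected peaks in
the noiseless case — a deliberate choice that makes parameter-recovery
tests exact rather than biased by peak-position mixing of adjacent
cycles. φ(y) ramps linearly 0 → φ_max anterior to posterior; a
paradoxical anterior fraction is set to φ = π outright.

Masks are rasterized as a fixed-thickness band whose top row is the
rounded curve, giving a 0.5 px round-trip bound through profile
extraction.

**What a green test establishes.** The simulator produces ideal
piecewise-sinusoidal motion with Gaussian pixel noise. It does not
emulate MRI intensities, segmentation failure modes (holes, spurious
blobs beyond the injected noise), cardiac motion, bulk patient motion,
or non-sinusoidal flow-limited breath shapes. Green tests therefore
establish the *correctness of the computations* (identities, closed
forms, contracts, recovery of injected structure), not clinical validity
on patient data.

## Numerical notes

* NCC values are clipped to [−1, 1] after the vectorized Gram-matrix
  computation (float round-off only); the diagonal is set to exactly 1.
* The NCC map equals a brute-force double-loop evaluation within 1e-12
  (tested at N=10, M=50).
* Closed forms used as oracles: phase-shifted equal-frequency sinusoids
  over integer cycles have NCC = cos φ (discrete orthogonality makes
  this exact); |A sin| has temporal mean 2A/π and SD A/√2.
* Ties in the longest-run truncation and in `find_peaks` are resolved
  first-wins; selection retains frames with start ≤ lower median.

## Known limitations

* Only the start side of the common range is extended; series whose
  *end* coordinate varies strongly can lose range that a symmetric rule
  would keep.
* The profile collapse assumes one diaphragm surface per column; masks
  that fold (two interfaces in one column) are collapsed to the superior
  one.
* Periods are peak-to-peak; a missed peak merges two cycles rather than
  flagging one.
* p-values are reported raw; with three groups and two metrics a
  correction may be appropriate depending on the analysis design.
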