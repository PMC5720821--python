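# Methods

This note documents the conventions, models and numerical choices behind
`myoflow`, and what its synthetic benchmarks do and do not establish.

## Coordinate and angle conventions

All physical coordinates are micrometres in a right-handed frame: x along
image columns, y growing *upward*. The image-row axis (which grows downward)
is flipped exactly once, at the pixel↔physical boundary in
`myoflow.geometry`, and nowhere else — a single authoritative convention
that prevents sign errors in angles. Movement directions are degrees in
[0°, 360°) measured from the anterior direction (`ap_angle`, the direction
of the chamber's anterior within the frame), increasing toward "Up".
Axial quantities (cell elongation, the local Myo-II axis) live in
[0°, 180°). Frames are 0-indexed everywhere.

Quadrants are half-open 90° sectors: Anterior [315°, 360°) ∪ [0°, 45°),
Up [45°, 135°), Posterior [135°, 225°), Down [225°, 315°). A boundary angle
belongs to the quadrant it opens, so assignment is deterministic on the
measure-zero boundaries.

## Synthetic-data generator

The generator emulates the imaging regime the pipeline targets: dot-like
puncta of ~0.36 µm FWHM (default dot-to-dot dispersion 0.05 µm, exposed as
`diameter_sd`) with a sparse ~1 µm intense population, moving at
2–2.5 µm/min; 6 s frame interval and 300–600 s movies (default 51 frames =
300 s); 0.1 µm/pixel (a 63×/1.45 confocal regime); polygonal cells of
~25 µm² tiling the field; and whole-tissue translation at 0.2–0.65 µm/min
(default 0.5 µm/min).

*Puncta* are rendered as isotropic 2D Gaussians whose "size" is defined as
FWHM throughout the package, so generator and estimator agree on one
convention. Per-step displacement length is exactly speed × Δt; step
directions come from one of three models: a fixed angle, a von Mises(μ, κ)
distribution, or a quadrant mixture that places a step in the retrograde
(Down) quadrant with probability `p_retro` and uniformly over the remaining
270° otherwise. A `per_cell_direction` flag converts the model into a
per-cell bias (each cell commits to a direction drawn once), emulating the
per-cell opposing asymmetries of non-rotating chambers. Dots reflect at the
field boundary; reflected steps are flagged so ground-truth speed summaries
can exclude them. An optional `min_separation` places puncta by rejection
sampling; it exists because two puncta closer than the PSF physically merge
into one wider blob, so size-calibration scenes must contain *resolvable*
dots for "mean estimated diameter" to be well defined.

*Cell sheets* are Voronoi tessellations of jittered grid centroids under an
anisotropic metric (distances shrunk along the elongation axis), giving
convex polygonal cells elongated by `elongation_ratio` along
`elongation_angle`; the sheet translates rigidly along ±Up at
`tissue_translation_speed`. Labels tile the frame with no overlaps by
construction.

*Pulse series* model the intensity of one cell as a noisy oscillation
around baseline 1.0 with amplitude `pulse_amplitude` (default 0.3) and
period `pulse_period` (default 60 s); the area deviation is the
sign-flipped intensity deviation delayed by `intensity_to_area_lag` frames
plus independent noise, so the area-reduction *rate* equals the intensity
rate delayed by the lag — the structure the cross-correlogram is designed
to detect. Pulses are deliberately not clock-like: each cell's period is
drawn with coefficient of variation `pulse_period_cv` (default 0.15) and a
random phase. A strictly periodic population would have autocorrelation 1
at a full-period shift, making the correlogram peak ambiguous whenever the
offset window reaches one period; cell-to-cell period variability — a
realistic feature of actomyosin pulsing — removes this common-period alias
from cross-cell averages while leaving the true lag aligned.

All randomness flows from one seed through named
`numpy.random.SeedSequence` child streams in a documented order (tracks,
cells, noise, pulses); identical seeds give bit-identical outputs.

**What the generator does not emulate:** photobleaching, focal drift, dot
appearance/disappearance (blinking), intensity fluctuations along a track,
cell rearrangement or division, membrane signal, non-Gaussian PSFs, and
mechanical coupling between neighbouring cells. Passing tests therefore
show the *measurement chain* is correct and unbiased under the stated
statistical structure — not that detection or linking would be equally
reliable on data with heavy blinking, drift or clutter.

## Spot detection and linking

Detection is a scale-normalized Laplacian-of-Gaussian band-pass with
σ = FWHM/2.355/√2 (the LoG scale whose response peaks for a Gaussian blob
of the expected size), followed by 8-connected local maxima above
`snr_threshold` (default 5) times a robust noise scale (1.4826 × MAD of the
band-pass response), then sub-pixel refinement. Refinement is a local 2D
Gaussian fit (amplitude, centre, σ, offset) in a window of ±max(3, ⌈FWHM⌉)
pixels; if the fitted σ presses against the window (σ > 0.55 × half-width),
the spot is wider than the expected scale and is refit in a window matched
to the fitted width — this makes one detection pass size-accurate for
mixtures of small and large dots. When only positions are needed
(`estimate_size=False`), the centre is the intensity-weighted centroid of
the background-subtracted window. Diameters are reported as FWHM = 2.355 σ.

Linking is per-frame-pair optimal assignment (Hungarian algorithm on
squared distances) gated by `max_step` (default 3 × expected speed × Δt),
with no gap closing — dots are dense and short-lived, and gap closing would
fabricate steps — and tracks shorter than `min_track_length` (default 3
spots) are discarded. Speeds are the mean of per-step lengths (not
endpoint displacement) divided by the frame interval; zero-length steps are
excluded from angle statistics (an angle is undefined) but counted and
reported.

## Directional statistics

Rotation unification mirrors Down-rotating chambers by θ → 360° − θ, an
involution that preserves Anterior/Posterior fractions and swaps Up/Down.
The retrograde fraction is the per-chamber fraction of events in the Down
quadrant after unification; pooled values are unweighted means over
chambers (each chamber is one biological replicate).

Per-cell ratios use retro = Down-quadrant events and antero = Up-quadrant
events; Anterior/Posterior events are excluded from the ratio but retained
in the record. "Weighted" chamber summaries weight each cell's log₂ ratio
by its event count; raw counts are always retained so alternative
weightings can be recomputed, and the weighting choice is written into the
output header. The ½ pseudocount is applied only when a count is zero,
keeping nonzero ratios exact while making log₂ finite. For static chambers
the dominant of {Up, Down} is decided from pooled chamber counts (an exact
tie defaults to Up and is flagged) and per-cell ratios are
dominant/opposite.

Symmetry calls use the dominant fraction f of n = Up + Down events and an
exact two-sided binomial test against 0.5: *strong* if f ≥ 0.70 and
p < 0.01, *weak* if f ≥ 0.60 and p < 0.05, else *symmetric*; n ≥ 20
required. The thresholds are package defaults (config-exposed) chosen so
the three labels separate chambers with clearly dominant, marginally
dominant and balanced movement; the binomial gate gives the classifier its
specificity on uniform data (the suite checks ≥ 94% "symmetric" at
n = 100).

Angular correction computes each cell's predominant direction μ as the
circular (vector-sum) mean of its full 0–360° step angles — not an axial
0–180° mean, because the procedure targets a *directed* axis (90° or 270°)
and the |δ| < 90° bound only holds under the nearer-of-two-targets rule.
δ is the signed smallest rotation to the nearer target; at the measure-zero
tie (μ exactly 0° or 180°, |δ| = 90°) the rotation is taken toward 90° and
flagged. Cells with fewer than 5 events (configurable) or zero resultant
length are left uncorrected and flagged. Being rigid rotations, corrections
preserve within-cell circular variance to machine precision.

Group comparisons are classical two-sample, two-sided Student t-tests with
per-group SEM; significance stars follow the <0.001 (***), <0.01 (**),
<0.05 (*) convention. Two zero-variance groups with equal means are
reported as p = 1 and flagged rather than undefined.

## Shape, chirality, rotation speed

Orientation and ellipse axes come from the second central moments of the
region's pixel coordinates (with the 1/12-pixel variance of the unit square
added, which removes the rasterization bias for thin regions); the major
axis length is L = 4√λ₁, matching the ellipse-of-equal-moments convention.
Roundness is fixed to 4A/(πL²) — the common "roundness" of image-analysis
practice, 1 for a circle and b/a for an ellipse — and circularity 4πA/P²
is exported alongside for comparison. Regions under 20 px are rejected;
regions touching the image border are flagged as biased.

The relative angle between a cell's elongation axis and its local Myo-II
axis (the axial circular mean of the cell's step angles mod 180°) is the
minimal axial difference in [0°, 90°]; "in plane" means ≤ 20° by default,
matching the 20° binning used for orientation histograms.

Membrane chirality qualifies edge segments whose axial angle is within
±45° of the circumferential (90°) axis, excluding exact-0° tilts; the tilt
sign (axial angle below/above 90°) gives the CW/ACW call, and fractions are
compared across chambers by t-test. Rotation speed is the mean per-frame
displacement of matched cell centroids along the circumferential axis
(µm/min, Up positive); cells touching the image border in either frame of a
pair are excluded because clipped centroids do not move with the tissue.

## Pulse analysis

Rates are first differences divided by the frame interval (shortest memory
at 6 s sampling; an optional 3-point moving average exists but is off by
default, and the smoothing mode is recorded in output metadata). The
area-reduction rate is the negated area rate, so positive means
contraction. Amplitudes are max − min of the (optionally linearly
detrended — off by default, the 300 s window being short) series.

The cross-correlogram is R(τ) = corr(x(t), y(t+τ)) at integer-frame offsets
in ±10 frames (±60 s) by default, with ≥ 10 overlapping points required at
every offset; positive τ means the intensity rate precedes the
area-reduction rate. The condition-level curve is the *unweighted mean of
per-cell correlations at each offset* (one curve per condition); the
alternative reading — a scalar average over offsets — is also exported
(`Correlogram.mean_R`). The peak is the argmax of the averaged curve with
ties broken toward the smallest |offset| (then the earlier offset). Cells
with a zero-variance segment at an offset are excluded there and logged.

## Pipeline

`pipeline.run` executes simulate → track → angles → shape → pulses from a
single nested config; a frozen config copy is written to the output
directory and every CSV opens with a comment line carrying the config hash
and seed. Stages are resumable from the on-disk intermediates, and the
whole run is byte-deterministic under a fixed seed. Four named fixture
profiles (fast-rotation, slow-rotation, static-pulsing, clone-mosaic)
parameterize the generator to the regimes above at small size (≤ 64 cells,
≤ 100 frames).

## Benchmark problem sizes

The bundled benchmarks use: a 320×320 px, 51-frame movie with 105 tracks at
2.44 µm/min for speed recovery; one 512×512 px frame with 136 × 0.363 µm
and 50 × 1.01 µm resolvable puncta for size recovery; 10 chambers × 100
events at 77% retrograde probability for the fraction recovery; and 56
one-frame-lag / 28 zero-lag pulse-series pairs (51 points at 6 s) for lag
recovery — sizes chosen to match the sample sizes of the study design the
package targets while keeping a full run under a few minutes on one CPU.

## Known limitations

- Detection assumes isotropic, roughly Gaussian puncta; elongated or
  filamentous signal (fixed-tissue appearance) will be fragmented or missed.
- No gap closing means blinking dots yield split tracks and shorter
  per-track statistics; this biases track counts but not per-step speeds.
- The PCC and roundness procedures are documented package conventions, not
  reproductions of any external implementation.
- The Voronoi cell sheet has no junction mechanics; shape statistics on it
  validate the measurement code, not tissue mechanics.
- Intensity extraction uses a per-frame median outside all cells as
  background; when labels tile the whole frame the background is 0 and
  intensities are raw means over the mask.
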