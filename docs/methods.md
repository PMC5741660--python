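# Methods

This note documents the models, parameter choices and numerical decisions
behind `wavetrack`, and what the synthetic benchmarks do and do not show
about real data.

## The measurement model

A developing neurite is modelled as a 1-D arc-length coordinate system: the
origin is the projection of the soma centroid onto the detected neurite, the
hillock anchors the proximal end, and the neurite edge (tip of the growth
cone, GC) sits at arc position `L(t)`. An actin wave is a point `s(t)` on
this axis, `0 ≤ s(t) ≤ L(t)`. All kinematic quantities derive from these two
series: per-wave velocity `(s_last − s_first)/(t_last − t_first)` in µm/min;
the length-normalized transit rate `(1/T)(d/L)` in 1/min (kept strictly
separate — the two are not interchangeable and are never mixed in one
summary); wave frequency as events per hour; pulling events as drawdowns of
`L(t)` gated on wave proximity.

## Phase-congruency neurite detection

Line features are detected with the log-Gabor phase-congruency measure:
quadrature filter responses over 4 scales (minimum wavelength 3 px, scale
multiplier 2.1, bandwidth σ/f = 0.55) and 6 orientations are combined into a
noise-compensated, amplitude-normalized phase-coherence score in [0, 1].
The per-orientation noise floor is Rayleigh-based: the median amplitude of
the smallest-scale response gives the noise scale τ, extrapolated
geometrically across scales, and the threshold is the noise mean plus
`noise_k = 2` standard deviations. A sigmoid filter-spread weight
suppresses single-scale (noise-like) responses. These are standard values
for the method; all are configurable under the `imageproc:` config block.
The map is binarized at 0.3 and specks under 20 px are removed (the
smallest real structure at the high-magnification preset, a filopodium,
spans tens of pixels).

Phase congruency marks *lines and edges*: blob structures — soma, GC, the
wave's lamellipodial flare — appear as rims, not filled regions, and the
response fades where the thin shaft emerges from the bright soma. The
tracker therefore unions the binary map with a background-relative
intensity mask (≥ 1.5× the frame median, the same factor used for wave
candidacy) and applies a morphological closing (disk radius 2) so one
neurite stays one 8-connected component. This mirrors the background
subtraction + thresholding step interactive workflows apply before
measuring, and substitutes for an operator bridging obvious dropouts.

## Geodesic length

`L(t)` and `s(t)` are exact 8-connected geodesics (axial step 1, diagonal
√2) on the binary map, computed with a minimum-cost-path search on a uniform
cost field and converted by the pixel calibration. Ties between equal-cost
paths are irrelevant: only the cost is reported. Known bias: the GC is a
filled disc, so the farthest component pixel overshoots the backbone tip by
roughly the GC radius (~4–6 µm at the default area). The bias is nearly
constant within a movie, cancels in every difference-based quantity
(velocities, retraction amplitudes, elongations), and is accounted for in
the tip-exclusion band (15 µm) that keeps GC-rim intensity peaks from being
scored as waves, and in the completion tolerance (25 µm) that marks a wave
as having reached the tip.

## Tracking and supervision

Frame-0 seeds come from a JSON file (the simulator emits one); subsequent
frames re-localize each point within `search_radius_px = 15` of its previous
position. During the pulling phase the tip can retract tens of µm within
one frame interval; when no candidate lies inside the search window the
tracker doubles it (up to 4×) and flags the frame, standing in for the
manual supervision of the original interactive workflow. An optional
per-frame corrections file overrides any automatic choice. When two waves
coexist the most distal candidate is tracked and the rest are logged;
event segmentation starts a new wave event at backward jumps > 10 µm (the
leading wave merged, a trailing one takes over) or presence gaps > 2
frames.

## The synthetic generator (study conditions)

Defaults encode the regime the package is designed for, and they are the
conditions under which all benchmarks run:

| parameter | default | unit | rationale |
|---|---|---|---|
| wave speed | N(2.2, 0.4²), truncated > 0 | µm/min | observed anterograde AW speeds |
| inception rate | 2.5 | waves/h | observed 2–3 /h median |
| GC retraction | 15 (amplitude), trigger at 20 µm gap | µm | observed 15–20 µm pulling |
| GC area | 50 baseline, ×2 on merge, −50% of peak over 45 min (10 min hold) | µm² | observed two-fold increase, 30–70% loss in 30–60 min |
| tip growth | 0.9 wave-free / 0.5 with waves | µm/min | see below |
| pixel size | 0.65 (20×) / 0.16 (40×) / 0.025 (STED) | µm/px | plausible for the stated objectives; unstated in the source data, declared assumptions |
| noise | Poisson shot + Gaussian read (σ=5), 12-bit clip | — | CCD at 12-bit depth |

Wave-free growth speed: reported long-term elongation (up to 400–450 µm in
8 h) implies ~0.9 µm/min on average, while short epochs of free growth can
reach 2–3 µm/min. The default uses 0.9 so that 8-h cohort simulations
reproduce the elongation envelope; the fast/slow alternation (2.5 vs 0.5
µm/min) is passed explicitly where that regime is the subject (the
frequency–velocity time course).

Retraction geometry: retracting 15 µm while the wave closes the remaining
~17 µm of a 20 µm approach window forces a retraction speed of ≈7.5× the
wave speed — near-vertical edge drops at minute-scale sampling, as real
pulling events appear in edge trajectories. Speeds are drawn once per wave
and held constant (observed transits are near-linear). The GC is rendered
as a soft-edged disc whose pixel area equals the simulated area state, so
area-recovery tests have exact truth; a fan-shaped extension would add
shape realism but no additional testable state. Waves arriving in quick
succession chain their retractions into one observable drop;
`simgen.planted_pulling_events` merges overlapping retraction intervals
into the observable event list used as detection truth.

What the generator does **not** emulate: filopodia, branching, drift,
photobleaching, focus changes, multi-neurite fields, and mid-neurite wave
death. Passing benchmarks therefore demonstrate correctness of the
measurement operations under the stated regime, not robustness to every
artefact of real microscopy.

## Morphometry

Manual outlining is replaced by seeded threshold segmentation: an Otsu
threshold inside a window (default 40 px) around the propagated seed, then
the connected region holding the seed, area = pixel count × pixel size².
The GC response takes the fold change as mean area in the 10 min after
arrival over the equal window before (the post-arrival hold in the
generator makes the planted fold exact), and the loss as
(peak − mean area in the 30–60 min window)/peak.

## Line scans

The half-max baseline is the median of the lowest 10% of trace values; the
front crossing is found by walking from the profile maximum toward the GC
and interpolating the (baseline + peak)/2 crossing, falling back to the
rising edge for step-like profiles that stay high to the trace end.
Averaging divides each trace by its mean intensity (making the result
invariant to per-trace scaling), smooths with a 5-sample moving average,
aligns the front half-max to arc 0 and resamples to a common grid at the
finest input step.

## STED puncta

Detection: median-background subtraction, light smoothing (σ = 0.5 px),
threshold (default 0.3× the 99.9th percentile of the subtracted image),
connected components filtered by punctum diameter bounds (40–400 nm),
splitting at local maxima separated by at least the minimum diameter. Two
puncta closer than that are spatially unresolvable; the detector
compensates by intensity quantization — each component's flux, integrated
over the component dilated by 3 px so Gaussian tails are not cut at the
threshold, is compared with the median flux of isolated single-peak
detections, and clear multiples add counts at the component centroid. At
the densest regime (10.5 puncta/µm², nearest-neighbour spacing ~150 nm)
this removes the ~10–15% undercount plain component counting incurs.
Actin normalization divides density by the ROI's relative actin intensity
(ROI mean over the scene-wise maximum ROI mean), leaving the region at the
actin maximum unchanged; the convention is recorded in the output so the
inverse reading remains computable. Tendency classes use the 12% stability
band on the relative change; a zero reference density yields the
`undefined` flag rather than a class.

## Statistics

Two-sided throughout. Welch (unequal-variance) *t* rather than pooled,
since group variances in this kind of data visibly differ; the choice is
recorded in the result object. Mann–Whitney uses full enumeration of group
assignments over pooled mid-ranks when n₁+n₂ ≤ 12 (exact even under ties;
p = min(1, 2·min(tail probabilities))), otherwise the tie-corrected normal
approximation. No multiple-testing correction is applied.

## Benchmark problem sizes

Chosen as the package's standard verification workload: 20 rendered
two-hour movies (160×360 px, 2-min frames) for speed recovery; 20 × 8 h
dynamics runs for frequency; 20 × 4 h runs for pulling detection; a
50-neurite 8-h cohort for the elongation correlation; 16 traces for
line-scan alignment; 2 × 20 STED scenes (640×640 px at 25 nm) for puncta
recovery; 200 enumeration draws and 1000 null simulations for the test
oracles. Dynamics-only paths are used where the quantity under test is a
function of the (t, L, s) series alone — the rendered-movie path is
exercised end-to-end by the speed-recovery and GC-response benchmarks.

## Known limitations

- Single neurite per movie; no branch handling or multi-neurite somata.
- The geodesic tip bias (≈ GC radius) offsets absolute lengths; only
  differences are bias-free.
- Wave completion is inferred from proximity to the tip at the last tracked
  sample; a wave dying within the completion tolerance of the tip would be
  misclassified as complete.
- The exact Mann–Whitney enumerates C(n₁+n₂, n₁) assignments; the n ≤ 12
  cutoff keeps this ≤ 924 and matches where the normal approximation
  becomes adequate.
- Puncta below the minimum-diameter separation are counted by flux, not
  resolved; their reported centroids coincide.
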